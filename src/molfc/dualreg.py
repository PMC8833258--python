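"""Two-step multivariate regression producing molecular-enriched FC maps.

Step 1 regresses each BOLD volume (across voxels, within the analysis
mask) on the K molecular density templates, yielding a T x K matrix of
dominant system time series.  Step 2 regresses each voxel's time course
(across time, over the whole brain mask — including voxels excluded from
step 1) on the standardized step-1 series, yielding one beta map per
system.  Both data and design are demeaned in the orientation of each
regression; step-1 series are scaled to unit standard deviation before
step 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import VolumeGrid, check_same_grid
from .preprocess import Bold4D
from .templates import AnalysisMask, MolecularTemplate

#: condition number above which the template design is treated as singular
CONDITION_LIMIT = 1e8

# population SD convention (divide by N) for all standardization here
def _pop_sd(a: np.ndarray, axis=0) -> np.ndarray:
    return np.std(a, axis=axis, ddof=0)


@dataclass
class SubjectSystemSeries:
    """T x K dominant BOLD fluctuations, one column per molecular system."""

    series: np.ndarray
    system_names: list[str]
    demeaned: bool = False
    unit_sd: bool = False

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be T x K")
        if self.series.shape[1] != len(self.system_names):
            raise ValueError("one system name per column required")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_systems(self) -> int:
        return self.series.shape[1]


@dataclass
class EnrichedFcMaps:
    """K per-subject 3D FC maps (step-2 output), on beta or z scale."""

    maps: np.ndarray  # (K, x, y, z)
    system_names: list[str]
    grid: VolumeGrid
    scale: str = "beta"
    subject_id: str = "sub-unknown"
    brain_mask: np.ndarray | None = None
    zero_variance_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4 or self.maps.shape[0] != len(self.system_names):
            raise ValueError("maps must be (K, x, y, z) with one name per map")
        if self.maps.shape[1:] != self.grid.shape:
            raise ValueError("map shape does not match grid")
        if self.scale not in ("beta", "z"):
            raise ValueError("scale must be 'beta' or 'z'")

    def map_for(self, system: str) -> np.ndarray:
        return self.maps[self.system_names.index(system)]


def _solve_ls(X: np.ndarray, Y: np.ndarray, names: list[str]) -> tuple[np.ndarray, float]:
    """QR least squares with a condition-number guard.

    Returns (coefficients, condition number); raises on near-singular
    designs, naming the most collinear pair of systems.
    """
    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > CONDITION_LIMIT:
        worst = ""
        if X.shape[1] >= 2:
            C = np.corrcoef(X.T)
            iu = np.triu_indices(X.shape[1], 1)
            k = int(np.argmax(np.abs(C[iu])))
            i, j = iu[0][k], iu[1][k]
            worst = f" (most collinear: {names[i]!r} vs {names[j]!r}, |r|={abs(C[i, j]):.4f})"
        raise ValueError(f"design matrix is rank deficient, condition={cond:.3g}{worst}")
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    return beta, cond


def fit_spatial_glm(
    bold: Bold4D,
    templates: list[MolecularTemplate],
    mask: AnalysisMask | np.ndarray,
) -> SubjectSystemSeries:
    """Step 1: across-voxel regression of each volume on the templates.

    Data (per time point) and template columns are demeaned across the
    voxels of the analysis mask before fitting.
    """
    m = mask.mask if isinstance(mask, AnalysisMask) else np.asarray(mask, dtype=bool)
    if m.shape != bold.grid.shape:
        raise ValueError("analysis mask shape does not match BOLD grid")
    names = [t.system_name for t in templates]
    for t in templates:
        check_same_grid(bold.grid, t.grid, what=f"template {t.system_name!r}")
    K = len(templates)
    if int(m.sum()) <= K:
        raise ValueError("analysis mask must contain more voxels than systems")
    X = np.column_stack([t.data[m] for t in templates])  # (V, K)
    X = X - X.mean(axis=0)
    Y = bold.data[m]  # (V, T)
    Y = Y - Y.mean(axis=0)
    beta, _ = _solve_ls(X, Y, names)  # (K, T)
    return SubjectSystemSeries(series=beta.T, system_names=names)


def standardize_series(series: SubjectSystemSeries) -> SubjectSystemSeries:
    """Demean each column and scale it to unit (population) SD."""
    s = series.series
    mu = s.mean(axis=0)
    sd = _pop_sd(s, axis=0)
    for k, v in enumerate(sd):
        if v <= 0:
            raise ValueError(
                f"system {series.system_names[k]!r} has a constant time series"
            )
    return replace(series, series=(s - mu) / sd, demeaned=True, unit_sd=True)


def fit_temporal_glm(
    bold: Bold4D,
    series: SubjectSystemSeries,
    brain_mask: np.ndarray,
) -> EnrichedFcMaps:
    """Step 2: per-voxel regression of time courses on the system series.

    Runs over ``brain_mask`` — voxels excluded from step 1 (reference
    regions) are included here, since BOLD is measured everywhere.
    Zero-variance voxels receive beta 0 and are flagged.
    """
    if not (series.demeaned and series.unit_sd):
        raise ValueError("series must be standardized before the temporal GLM")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != bold.grid.shape:
        raise ValueError("brain mask shape does not match BOLD grid")
    T, K = series.series.shape
    if bold.n_volumes != T:
        raise ValueError(f"series has {T} time points, BOLD has {bold.n_volumes}")
    if T <= K:
        raise ValueError("need more time points than systems")
    X = series.series  # (T, K), standardized
    Y = bold.data[brain_mask]  # (V, T)
    Y = Y - Y.mean(axis=1, keepdims=True)
    zero_var = _pop_sd(Y, axis=1) <= 0
    beta, _ = _solve_ls(X, Y.T, series.system_names)  # (K, V)
    beta[:, zero_var] = 0.0
    maps = np.zeros((K, *bold.grid.shape))
    maps[:, brain_mask] = beta
    zv = np.zeros(bold.grid.shape, dtype=bool)
    zv[brain_mask] = zero_var
    return EnrichedFcMaps(
        maps=maps,
        system_names=list(series.system_names),
        grid=bold.grid,
        scale="beta",
        subject_id=bold.subject_id,
        brain_mask=brain_mask,
        zero_variance_mask=zv,
    )


def to_zscore_maps(maps: EnrichedFcMaps) -> EnrichedFcMaps:
    """Standardize each beta map across voxels of the brain mask (z scale)."""
    if maps.scale != "beta":
        raise ValueError("maps are already on z scale")
    if maps.brain_mask is None:
        raise ValueError("brain mask required for z scaling")
    out = np.zeros_like(maps.maps)
    for k in range(maps.maps.shape[0]):
        vals = maps.maps[k][maps.brain_mask]
        sd = _pop_sd(vals)
        if sd <= 0:
            raise ValueError(
                f"map {maps.system_names[k]!r} has zero across-voxel variance"
            )
        out[k][maps.brain_mask] = (vals - vals.mean()) / sd
    return replace(maps, maps=out, scale="z")


def run_react(
    bold: Bold4D,
    templates: list[MolecularTemplate],
    analysis_mask: AnalysisMask | np.ndarray,
    brain_mask: np.ndarray,
    zscore: bool = False,
) -> tuple[EnrichedFcMaps, SubjectSystemSeries, dict]:
    """Full two-step pipeline for one subject.

    Returns the FC maps, the standardized step-1 series, and a log dict
    with mask sizes and flag counts.
    """
    raw = fit_spatial_glm(bold, templates, analysis_mask)
    series = standardize_series(raw)
    maps = fit_temporal_glm(bold, series, brain_mask)
    if zscore:
        maps = to_zscore_maps(maps)
    m = analysis_mask.mask if isinstance(analysis_mask, AnalysisMask) else analysis_mask
    log = {
        "subject_id": bold.subject_id,
        "n_step1_voxels": int(np.asarray(m, bool).sum()),
        "n_step2_voxels": int(np.asarray(brain_mask, bool).sum()),
        "n_zero_variance": int(maps.zero_variance_mask.sum()),
        "systems": list(series.system_names),
    }
    return maps, series, log
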