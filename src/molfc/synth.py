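"""Synthetic templates, BOLD cohorts and clinical outcomes with ground truth.

Templates are smoothed, rectified Gaussian random fields (non-negative,
tunable pairwise overlap, receptor-atlas-like).  Subject BOLD series are
template-weighted mixtures of per-system time series plus Gaussian noise.
Group FC effects are injected by amplifying one system's template-driven
component inside a known effect mask — an FC difference, not a mean-signal
difference, which is exactly what the step-2 regression estimates.
Clinical outcomes couple percentage analgesia to the subject's true FC
strength in the effect mask with a configurable linear coefficient.

All generators are pure functions of (spec, seed); per-subject child
seeds are derived from the master seed by fixed arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VolumeGrid
from .preprocess import Bold4D
from .templates import MolecularTemplate

_CHILD_SEED_STRIDE = 100_003  # prime stride: child i = master * stride + i


def child_seed(master_seed: int, index: int) -> int:
    return int(master_seed) * _CHILD_SEED_STRIDE + int(index)


@dataclass
class SynthGroundTruth:
    """Everything needed to verify downstream estimates bit-for-bit."""

    true_templates: np.ndarray  # (K, x, y, z), non-negative
    true_series: list  # per subject: (T, K)
    effect_mask: np.ndarray
    effect_size: float
    noise_sd: float
    seed: int
    effect_system: int = 0
    subject_gains: np.ndarray | None = None  # template amplification per subject
    subject_amps: np.ndarray | None = None  # overall series amplitude per subject
    fc_scores: np.ndarray | None = None  # true mean FC strength in effect_mask

    def __post_init__(self) -> None:
        if np.any(self.true_templates < 0):
            raise ValueError("true templates must be non-negative")
        for k in range(self.true_templates.shape[0]):
            if np.ptp(self.true_templates[k]) <= 0:
                raise ValueError(f"true template {k} is constant")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass
class SynthCohortSpec:
    """Cohort layout and generative parameters.

    ``n_per_group`` maps a group label to a subject count; labels of the
    form ``"arm:R"`` / ``"arm:NR"`` populate the arm and response columns
    of the covariate table.  ``effect_groups`` lists the labels whose
    members receive the injected FC effect.
    """

    n_per_group: dict
    T: int = 150
    tr: float = 2.5
    noise_sd: float = 1.0
    effect_size: float = 0.0
    effect_system: int = 0
    effect_groups: tuple = ()
    effect_radius_vox: float = 3.0
    subject_amp_sd: float = 0.15
    vas_coupling: float = 0.0
    vas_intercept: float = 25.0
    vas_noise_sd: float = 5.0
    age_mean: float = 57.0
    age_sd: float = 7.0
    seed: int = 0

    def validate(self, n_systems: int) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group is empty")
        for label, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {label!r} needs >= 2 subjects, got {n}")
        if self.T < 2 * n_systems:
            raise ValueError(f"T={self.T} must be >= 2*K={2 * n_systems}")
        if self.tr <= 0:
            raise ValueError("TR must be > 0")
        if not (0 <= self.effect_system < n_systems):
            raise ValueError("effect_system out of range")
        for label in self.effect_groups:
            if label not in self.n_per_group:
                raise ValueError(f"effect group {label!r} not in n_per_group")


@dataclass
class SynthCohort:
    bolds: list  # Bold4D per subject
    table: pd.DataFrame
    ground_truth: SynthGroundTruth
    templates: list = field(default_factory=list)


def corner_region_mask(grid: VolumeGrid, index: int, fraction: float = 6.0) -> np.ndarray:
    """Deterministic small block at one of the 8 grid corners.

    Used as the designated tracer reference region of synthetic template
    ``index`` (corners are cycled).
    """
    nx, ny, nz = grid.shape
    bx, by, bz = (max(2, int(np.ceil(n / fraction))) for n in grid.shape)
    cx, cy, cz = (index >> 0) & 1, (index >> 1) & 1, (index >> 2) & 1
    mask = np.zeros(grid.shape, dtype=bool)
    sx = slice(0, bx) if cx == 0 else slice(nx - bx, nx)
    sy = slice(0, by) if cy == 0 else slice(ny - by, ny)
    sz = slice(0, bz) if cz == 0 else slice(nz - bz, nz)
    mask[sx, sy, sz] = True
    return mask


def _smooth_unit_field(rng: np.random.Generator, grid: VolumeGrid, sigma_vox) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma_vox, mode="wrap")
    return (f - f.mean()) / f.std()


def make_templates(
    K: int,
    grid: VolumeGrid,
    smoothness_mm: float = 6.0,
    overlap: float = 0.0,
    seed: int = 0,
) -> list[MolecularTemplate]:
    """Generate K smooth, non-negative, partially overlapping density fields.

    Each field is a rectified mixture of a private and a shared smooth
    Gaussian field; the mixing weight sets the expected pairwise spatial
    correlation to ``overlap``.  Fails explicitly if the requested (K,
    overlap) combination cannot be realized on the grid (measured pairwise
    correlation above ``overlap + 0.15``, or more templates than corner
    reference regions).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if smoothness_mm <= 0:
        raise ValueError("smoothness_mm must be > 0")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    if K > 8:
        raise ValueError(
            f"grid supports at most 8 templates (corner reference regions), got K={K}"
        )
    rng = np.random.default_rng(seed)
    sigma_vox = tuple(smoothness_mm / v for v in grid.voxel_size)
    shared = _smooth_unit_field(rng, grid, sigma_vox)
    shared_unit = shared.ravel() / np.linalg.norm(shared)
    # Private fields are orthogonalized against the shared component so the
    # pre-rectification pairwise correlation is exactly `overlap`.
    # Rectification is nonlinear and can reintroduce sampling correlation on
    # coarse grids, so each field is redrawn (deterministically) until the
    # measured bound holds; exhausting the retries is the explicit failure
    # mode for a (K, overlap) combination the grid cannot support.
    max_tries = 25
    fields = []
    for k in range(K):
        for attempt in range(max_tries):
            g = _smooth_unit_field(rng, grid, sigma_vox).ravel()
            g = g - (g @ shared_unit) * shared_unit
            norm = np.linalg.norm(g)
            if norm <= 1e-8:
                continue
            g = (g / g.std()).reshape(grid.shape)
            h = np.sqrt(overlap) * shared + np.sqrt(1.0 - overlap) * g
            r = np.clip(h, 0.0, None)
            if r.max() <= 0:
                continue
            r = r / r.max()
            flat = r.ravel()
            if all(
                float(np.corrcoef(flat, f.ravel())[0, 1]) <= overlap + 0.15
                for f in fields
            ):
                fields.append(r)
                break
        else:
            raise ValueError(
                f"could not generate template {k} with pairwise correlation "
                f"<= overlap + 0.15 = {overlap + 0.15:.3f} after {max_tries} "
                f"tries; grid cannot support K={K} at this overlap/smoothness"
            )
    return [
        MolecularTemplate(
            system_name=f"system-{k}",
            data=fields[k],
            valid_mask=np.ones(grid.shape, dtype=bool),
            grid=grid,
            reference_region=f"corner-{k % 8}",
            provenance=[f"synthetic(seed={seed}, overlap={overlap})"],
        )
        for k in range(K)
    ]


def make_subject_bold(
    templates: list[MolecularTemplate],
    series: np.ndarray,
    noise_sd: float,
    grid: VolumeGrid,
    seed: int = 0,
    tr: float = 2.5,
    subject_id: str = "sub-synth",
    smooth_fwhm_mm: float = 0.0,
) -> Bold4D:
    """Template-weighted mixture: y(v,t) = sum_k D_k(v) s_k(t) + noise."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != len(templates):
        raise ValueError(
            f"series must be T x K with K={len(templates)}, got {series.shape}"
        )
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    for t in templates:
        if not t.grid.matches(grid):
            raise ValueError(f"template {t.system_name!r} not on the requested grid")
    D = np.stack([t.data for t in templates])  # (K, x, y, z)
    data = np.einsum("kxyz,tk->xyzt", D, series)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=data.shape)
        if smooth_fwhm_mm > 0:
            sigma = grid.sigma_voxels(smooth_fwhm_mm)
            noise = ndimage.gaussian_filter(noise, sigma=(*sigma, 0.0), mode="reflect")
        data = data + noise
    return Bold4D(data=data, grid=grid, tr=tr, subject_id=subject_id)


def default_effect_mask(grid: VolumeGrid, radius_vox: float = 3.0) -> np.ndarray:
    """Ball of the given voxel radius at the grid centre."""
    centre = (np.array(grid.shape) - 1) / 2.0
    coords = np.indices(grid.shape).reshape(3, -1).T
    d2 = ((coords - centre) ** 2).sum(axis=1)
    return (d2 <= radius_vox**2).reshape(grid.shape)


def make_cohort(
    spec: SynthCohortSpec,
    templates: list[MolecularTemplate],
    effect_mask: np.ndarray | None = None,
) -> SynthCohort:
    """Generate a full cohort of BOLD subjects with covariates and truth.

    Subjects in ``spec.effect_groups`` have the effect-system's
    template-driven signal multiplied by ``(1 + effect_size)`` inside the
    effect mask.  Each subject also carries a random overall amplitude on
    the effect-system series, giving inter-subject FC variability that the
    clinical outcome model can couple to.
    """
    K = len(templates)
    spec.validate(K)
    grid = templates[0].grid
    if effect_mask is None:
        effect_mask = default_effect_mask(grid, spec.effect_radius_vox)
    effect_mask = np.asarray(effect_mask, dtype=bool)
    if effect_mask.shape != grid.shape:
        raise ValueError("effect mask shape does not match grid")
    if not effect_mask.any():
        raise ValueError("effect mask is empty")

    D_eff = templates[spec.effect_system].data
    labels = [
        (label, i) for label in spec.n_per_group for i in range(spec.n_per_group[label])
    ]
    master = np.random.default_rng(child_seed(spec.seed, 0))
    rows, bolds, all_series = [], [], []
    gains = np.empty(len(labels))
    amps = np.empty(len(labels))
    for idx, (label, _) in enumerate(labels):
        rng = np.random.default_rng(child_seed(spec.seed, idx + 1))
        series = rng.standard_normal((spec.T, K))
        amp = max(0.2, 1.0 + spec.subject_amp_sd * rng.standard_normal())
        series[:, spec.effect_system] *= amp
        in_effect = label in spec.effect_groups
        gain = 1.0 + (spec.effect_size if in_effect else 0.0)
        subj_templates = list(templates)
        if gain != 1.0:
            boosted = np.where(effect_mask, D_eff * gain, D_eff)
            subj_templates = list(templates)
            subj_templates[spec.effect_system] = replace(
                templates[spec.effect_system], data=boosted
            )
        sid = f"sub-{idx + 1:02d}"
        bold = make_subject_bold(
            subj_templates,
            series,
            noise_sd=spec.noise_sd,
            grid=grid,
            seed=child_seed(spec.seed, 10_000 + idx),
            tr=spec.tr,
            subject_id=sid,
        )
        age = float(master.normal(spec.age_mean, spec.age_sd))
        gender = int(master.integers(0, 2))
        arm, response = (label.split(":", 1) + ["none"])[:2] if ":" in label else (
            "none",
            "none",
        )
        rows.append(
            {
                "subject_id": sid,
                "age": round(age, 1),
                "gender": gender,
                "group": label,
                "arm": arm,
                "response": response,
            }
        )
        bolds.append(bold)
        all_series.append(series)
        gains[idx] = gain
        amps[idx] = amp

    mean_density = float(D_eff[effect_mask].mean())
    fc_scores = gains * amps * mean_density
    truth = SynthGroundTruth(
        true_templates=np.stack([t.data for t in templates]),
        true_series=all_series,
        effect_mask=effect_mask,
        effect_size=spec.effect_size,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        effect_system=spec.effect_system,
        subject_gains=gains,
        subject_amps=amps,
        fc_scores=fc_scores,
    )
    return SynthCohort(
        bolds=bolds,
        table=pd.DataFrame(rows),
        ground_truth=truth,
        templates=list(templates),
    )


def make_clinical_outcomes(
    cohort: SynthCohort,
    ground_truth: SynthGroundTruth,
    spec: SynthCohortSpec,
) -> pd.DataFrame:
    """Attach baseline (3 repeats) and post-treatment VAS to the cohort.

    Percentage analgesia is generated as
    ``intercept + vas_coupling * fc_score + noise`` and converted to a
    post-treatment VAS from the averaged triple baseline; responder labels
    (>= 20% decrease) are then derivable from the emitted columns alone.
    """
    if not np.isfinite(spec.vas_coupling):
        raise ValueError("vas_coupling must be finite")
    fc = ground_truth.fc_scores
    n = len(cohort.table)
    rng = np.random.default_rng(child_seed(spec.seed, 777))
    base_centre = rng.uniform(4.0, 9.0, size=n)
    repeats = np.clip(
        base_centre[:, None] + rng.normal(0.0, 0.3, size=(n, 3)), 0.5, 10.0
    )
    baseline = repeats.mean(axis=1)
    pct = (
        spec.vas_intercept
        + spec.vas_coupling * fc
        + rng.normal(0.0, spec.vas_noise_sd, size=n)
    )
    pct = np.clip(pct, -40.0, 95.0)
    post = np.clip(baseline * (1.0 - pct / 100.0), 0.0, 10.0)
    out = cohort.table.copy()
    for j in range(3):
        out[f"vas_baseline_{j + 1}"] = repeats[:, j]
    out["vas_baseline"] = baseline
    out["vas_post"] = post
    return out
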