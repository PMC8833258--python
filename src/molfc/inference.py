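"""Nonparametric group inference with max-cluster-size FWE correction.

Voxelwise t / F statistic maps are thresholded at a configurable
cluster-forming threshold, connected components are labelled, and
family-wise-error-corrected cluster p-values are obtained from the
permutation null distribution of the maximum cluster size across the
image.  Nuisance covariates are handled by Freedman–Lane residual
permutation: the residuals of the reduced (nuisance-only) model are
permuted, the reduced-model fit is added back, and the full model is
refit on each permuted dataset.

When the contrast is a plain two-group comparison with no covariates and
the number of distinct relabelings does not exceed ``n_perm``, the
engine enumerates all relabelings exhaustively instead of sampling, and
p-values become exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage, stats


@dataclass
class DesignSpec:
    """Group design matrix with named columns and a nuisance column set."""

    design: np.ndarray  # (n, p)
    columns: list[str]
    nuisance_cols: tuple = ()

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be n x p")
        n, p = self.design.shape
        if len(self.columns) != p:
            raise ValueError("one name per design column required")
        if n <= p:
            raise ValueError(f"need more subjects ({n}) than design columns ({p})")
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]


@dataclass
class Cluster:
    label: int
    size: int
    peak_stat: float
    peak_voxel: tuple
    p_fwe: float | None = None


@dataclass
class ClusterInferenceResult:
    stat_map: np.ndarray
    cf_threshold: float
    clusters: list
    null_max_sizes: np.ndarray
    n_perm: int
    stat_name: str = "t"
    exhaustive: bool = False
    label_map: np.ndarray | None = None


def connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(
    stat_map: np.ndarray, cf_threshold: float, connectivity: int = 26
) -> tuple[np.ndarray, list[Cluster]]:
    """Connected components of {voxel : stat > threshold}.

    Returns the label map and clusters sorted by decreasing size; peaks
    are reported in voxel coordinates.  An empty suprathreshold set gives
    zero clusters.
    """
    if not np.isfinite(cf_threshold):
        raise ValueError("cluster-forming threshold must be finite")
    stat_map = np.asarray(stat_map, dtype=float)
    supra = stat_map > cf_threshold
    label_map, n_labels = ndimage.label(supra, structure=connectivity_structure(connectivity))
    clusters = []
    for lab in range(1, n_labels + 1):
        where = label_map == lab
        vals = stat_map[where]
        peak_flat = np.flatnonzero(where.ravel())[np.argmax(vals)]
        peak = tuple(int(i) for i in np.unravel_index(peak_flat, stat_map.shape))
        clusters.append(
            Cluster(
                label=lab,
                size=int(where.sum()),
                peak_stat=float(vals.max()),
                peak_voxel=peak,
            )
        )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return label_map, clusters


def _max_cluster_size(stat_flat, mask, shape, threshold, structure) -> int:
    vol = np.zeros(shape, dtype=bool)
    vol[mask] = stat_flat > threshold
    label_map, n_labels = ndimage.label(vol, structure=structure)
    if n_labels == 0:
        return 0
    return int(np.bincount(label_map.ravel())[1:].max())


class _GlmEngine:
    """Precomputed pieces of the full and reduced models on a fixed design."""

    def __init__(self, X: np.ndarray, test_cols: tuple, contrast: np.ndarray | None):
        self.X = X
        self.n, self.p = X.shape
        self.df = self.n - self.p
        if self.df < 1:
            raise ValueError("no residual degrees of freedom")
        self.Q_full, _ = np.linalg.qr(X)
        self.pinv = np.linalg.pinv(X)
        self.contrast = contrast
        self.test_cols = tuple(test_cols)
        keep = [j for j in range(self.p) if j not in self.test_cols]
        self.X_reduced = X[:, keep] if keep else None
        if self.X_reduced is not None:
            self.Q_red, _ = np.linalg.qr(self.X_reduced)
        else:
            self.Q_red = None
        if contrast is not None:
            XtXinv = np.linalg.inv(X.T @ X)
            self.c_var = float(contrast @ XtXinv @ contrast)
            self.c_pinv = contrast @ self.pinv  # (n,)

    def _rss(self, Y: np.ndarray, Q: np.ndarray | None) -> np.ndarray:
        tot = np.einsum("nv,nv->v", Y, Y)
        if Q is None:
            return tot
        proj = Q.T @ Y
        return tot - np.einsum("pv,pv->v", proj, proj)

    def t_stat(self, Y: np.ndarray) -> np.ndarray:
        """t for the contrast; Y is (n, V) and should be column-centred or
        the design must contain an intercept."""
        effect = self.c_pinv @ Y
        sigma2 = self._rss(Y, self.Q_full) / self.df
        se = np.sqrt(np.maximum(sigma2 * self.c_var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / se, 0.0)
        return t

    def f_stat(self, Y: np.ndarray) -> np.ndarray:
        q = len(self.test_cols)
        rss_full = self._rss(Y, self.Q_full)
        rss_red = self._rss(Y, self.Q_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(
                rss_full > 0,
                ((rss_red - rss_full) / q) / (rss_full / self.df),
                0.0,
            )
        return np.maximum(f, 0.0)


def _freedman_lane_parts(Y: np.ndarray, Z: np.ndarray | None):
    """Reduced-model fit and residuals for residual permutation."""
    if Z is None:
        return np.zeros_like(Y), Y
    gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted = Z @ gamma
    return fitted, Y - fitted


def _two_group_exhaustible(design: DesignSpec, contrast, n_perm: int):
    """Detect a pure two-sample design whose relabelings can be enumerated.

    Requires: contrast loads a single binary column, all other columns
    are (at most) an intercept, and C(n, n1) <= n_perm.
    """
    c = np.asarray(contrast, dtype=float)
    loaded = np.flatnonzero(c != 0)
    if len(loaded) != 1:
        return None
    g = design.design[:, loaded[0]]
    if not set(np.unique(g)) <= {0.0, 1.0}:
        return None
    others = [j for j in range(design.p) if j != loaded[0]]
    for j in others:
        if np.ptp(design.design[:, j]) > 0:  # anything beyond an intercept
            return None
    n1 = int(g.sum())
    n_total = comb(design.n, n1)
    if n_total > n_perm:
        return None
    return loaded[0], n1, n_total


def _cluster_p_values(
    stat_map_flat, mask, shape, threshold, structure, null_max, exhaustive
):
    vol = np.zeros(shape)
    vol[mask] = stat_map_flat
    label_map, clusters = label_clusters(
        np.where(mask, vol, -np.inf), threshold, connectivity=_struct_to_conn(structure)
    )
    null_max = np.asarray(null_max)
    for cl in clusters:
        if exhaustive:
            cl.p_fwe = float((null_max >= cl.size).mean())
        else:
            cl.p_fwe = float((1 + (null_max >= cl.size).sum()) / (1 + len(null_max)))
    return vol, label_map, clusters


def _struct_to_conn(structure: np.ndarray) -> int:
    return {7: 6, 19: 18, 27: 26}[int(structure.sum())]


def _as_subject_matrix(maps, mask):
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, x, y, z)")
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    return maps[:, mask], mask


def permutation_ttest_clusters(
    maps: np.ndarray,
    design: DesignSpec,
    contrast,
    n_perm: int = 5000,
    cft_p: float = 0.01,
    cf_threshold: float | None = None,
    connectivity: int = 26,
    seed: int = 0,
    mask: np.ndarray | None = None,
    exhaustive: str | bool = "auto",
) -> ClusterInferenceResult:
    """Permutation cluster inference for a one-sided t contrast.

    The cluster-forming threshold defaults to the parametric t quantile
    for one-sided p < ``cft_p`` at the model's residual df (the threshold
    is a reporting choice, not part of the null machinery, so this is
    explicit and configurable).  p_FWE per cluster uses the null
    distribution of the maximum cluster size.
    """
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (design.p,):
        raise ValueError("contrast length must equal number of design columns")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
    loaded = np.flatnonzero(contrast != 0)
    for j in loaded:
        col = design.design[:, j]
        uniq = np.unique(col)
        if set(uniq) <= {0.0, 1.0}:
            n1 = int(col.sum())
            if min(n1, design.n - n1) < 2:
                raise ValueError("need at least 2 subjects per group")
    Y, mask = _as_subject_matrix(maps, mask)
    if Y.shape[0] != design.n:
        raise ValueError("one map per design row required")
    engine = _GlmEngine(design.design, test_cols=tuple(loaded), contrast=contrast)
    if cf_threshold is None:
        cf_threshold = float(stats.t.isf(cft_p, engine.df))
    structure = connectivity_structure(connectivity)
    shape = mask.shape

    obs_t = engine.t_stat(Y)

    exh = _two_group_exhaustible(design, contrast, n_perm) if exhaustive in ("auto", True) else None
    if exhaustive is True and exh is None:
        raise ValueError("exhaustive enumeration not available for this design")
    null_max = []
    if exh is not None:
        gcol, n1, _ = exh
        Xbase = design.design
        for subset in combinations(range(design.n), n1):
            g = np.zeros(design.n)
            g[list(subset)] = 1.0
            Xp = Xbase.copy()
            Xp[:, gcol] = g
            cp = contrast
            eng_p = _GlmEngine(Xp, test_cols=(gcol,), contrast=cp)
            tp = eng_p.t_stat(Y)
            null_max.append(_max_cluster_size(tp, mask, shape, cf_threshold, structure))
        is_exhaustive = True
    else:
        Z = design.design[:, list(design.nuisance_cols)] if design.nuisance_cols else None
        if Z is None:
            # reduced model: all non-tested columns
            keep = [j for j in range(design.p) if j not in set(loaded)]
            Z = design.design[:, keep] if keep else None
        fitted, resid = _freedman_lane_parts(Y, Z)
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(design.n)
            tp = engine.t_stat(fitted + resid[perm])
            null_max.append(_max_cluster_size(tp, mask, shape, cf_threshold, structure))
        is_exhaustive = False

    stat_map, label_map, clusters = _cluster_p_values(
        obs_t, mask, shape, cf_threshold, structure, null_max, is_exhaustive
    )
    return ClusterInferenceResult(
        stat_map=stat_map,
        cf_threshold=cf_threshold,
        clusters=clusters,
        null_max_sizes=np.asarray(null_max),
        n_perm=len(null_max),
        stat_name="t",
        exhaustive=is_exhaustive,
        label_map=label_map,
    )


def permutation_interaction_f(
    maps: np.ndarray,
    design: DesignSpec,
    interaction_cols,
    n_perm: int = 5000,
    cft_p: float = 0.01,
    cf_threshold: float | None = None,
    connectivity: int = 26,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ClusterInferenceResult:
    """Permutation cluster inference for an F-test on interaction columns.

    The observed F-map compares the full model with the model excluding
    ``interaction_cols``; Freedman–Lane permutes the residuals of that
    reduced model.
    """
    interaction_cols = tuple(int(j) for j in np.atleast_1d(interaction_cols))
    if not interaction_cols:
        raise ValueError("no interaction columns given")
    Y, mask = _as_subject_matrix(maps, mask)
    if Y.shape[0] != design.n:
        raise ValueError("one map per design row required")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
    engine = _GlmEngine(design.design, test_cols=interaction_cols, contrast=None)
    q = len(interaction_cols)
    if cf_threshold is None:
        cf_threshold = float(stats.f.isf(cft_p, q, engine.df))
    structure = connectivity_structure(connectivity)
    shape = mask.shape

    obs_f = engine.f_stat(Y)
    fitted, resid = _freedman_lane_parts(Y, engine.X_reduced)
    rng = np.random.default_rng(seed)
    null_max = []
    for _ in range(n_perm):
        perm = rng.permutation(design.n)
        fp = engine.f_stat(fitted + resid[perm])
        null_max.append(_max_cluster_size(fp, mask, shape, cf_threshold, structure))

    stat_map, label_map, clusters = _cluster_p_values(
        obs_f, mask, shape, cf_threshold, structure, null_max, exhaustive=False
    )
    return ClusterInferenceResult(
        stat_map=stat_map,
        cf_threshold=cf_threshold,
        clusters=clusters,
        null_max_sizes=np.asarray(null_max),
        n_perm=n_perm,
        stat_name="F",
        exhaustive=False,
        label_map=label_map,
    )


def bonferroni_adjust(p_values, m: int):
    """p_adj = min(1, m * p) across ``m`` tests (systems x contrasts)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = np.minimum(1.0, m * p)
    return float(adj) if np.isscalar(p_values) or p.ndim == 0 else adj


def extract_cluster_means(
    maps: np.ndarray, cluster_masks, average: bool = True
) -> np.ndarray:
    """Mean map value per subject within significant cluster(s).

    ``cluster_masks`` may be a single binary mask or a list of masks; with
    ``average=True`` the per-cluster means are averaged into one scalar
    per subject.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, x, y, z)")
    if isinstance(cluster_masks, np.ndarray) and cluster_masks.ndim == 3:
        cluster_masks = [cluster_masks]
    per_cluster = []
    for cm in cluster_masks:
        cm = np.asarray(cm, dtype=bool)
        if cm.shape != maps.shape[1:]:
            raise ValueError("cluster mask shape does not match maps")
        if not cm.any():
            raise ValueError("cluster mask is empty")
        per_cluster.append(maps[:, cm].mean(axis=1))
    out = np.column_stack(per_cluster)
    return out.mean(axis=1) if average else out
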