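"""Preparation of molecular density templates for the spatial regression.

Raw transporter/receptor density maps are turned into analysis-ready
regressors: reference regions (unquantifiable in the source tracer data)
are masked out, a grey-matter mask is applied, values are min-max scaled
to [0, 1] preserving the intensity distribution, and everything is
resampled onto one common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid, check_same_grid

#: Tracer quantification reference region per transporter/receptor system:
#: occipital cortex for DAT, NET and the mu-opioid receptor, cerebellum for
#: SERT.  Used by config-driven preparation when no explicit region is given.
DEFAULT_REFERENCE_REGIONS = {
    "DAT": "occipital",
    "NET": "occipital",
    "MOR": "occipital",
    "SERT": "cerebellum",
}


@dataclass
class MolecularTemplate:
    """Density map for one molecular system, with its validity mask.

    ``data`` is zero outside ``valid_mask``; after :func:`minmax_normalize`
    the values over ``valid_mask`` span exactly [0, 1].
    """

    system_name: str
    data: np.ndarray
    valid_mask: np.ndarray
    grid: VolumeGrid
    reference_region: str | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if self.valid_mask.shape != self.grid.shape:
            raise ValueError("valid_mask shape does not match grid")
        if not self.valid_mask.any():
            raise ValueError(f"template {self.system_name!r}: empty valid_mask")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def with_mask(self, mask: np.ndarray, note: str) -> "MolecularTemplate":
        """Restrict the template to ``valid_mask & mask`` and zero outside."""
        new_mask = self.valid_mask & mask.astype(bool)
        if not new_mask.any():
            raise ValueError(
                f"template {self.system_name!r}: masking with {note!r} removes "
                "all valid voxels"
            )
        data = np.where(new_mask, self.data, 0.0)
        return replace(
            self,
            data=data,
            valid_mask=new_mask,
            provenance=[*self.provenance, note],
        )


@dataclass
class AnalysisMask:
    """Voxel set over which the spatial (step-1) regression is run.

    ``mask`` is the default step-1 mask; per-system masks and their union
    are kept for the per-system mode and step-2 reporting.
    """

    mask: np.ndarray
    per_system: dict
    union: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.union = np.asarray(self.union, dtype=bool)
        if not self.mask.any():
            raise ValueError("analysis mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def mask_reference_region(
    template: MolecularTemplate, region_mask: np.ndarray, region_name: str = "reference"
) -> MolecularTemplate:
    """Remove the tracer quantification reference region from a template.

    Voxels inside ``region_mask`` are dropped from ``valid_mask`` and
    zeroed in ``data``.  An empty region mask is an identity operation.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != template.grid.shape:
        raise ValueError("region_mask shape does not match template grid")
    if not region_mask.any():
        return replace(
            template, provenance=[*template.provenance, f"ref-mask:{region_name}(empty)"]
        )
    out = template.with_mask(~region_mask, note=f"ref-mask:{region_name}")
    out.reference_region = region_name
    return out


def apply_gm_mask(template: MolecularTemplate, gm_mask: np.ndarray) -> MolecularTemplate:
    """Intersect the template's validity mask with a grey-matter mask.

    Probabilistic masks are binarized at 0.5.
    """
    gm = np.asarray(gm_mask)
    if gm.shape != template.grid.shape:
        raise ValueError("gm_mask shape does not match template grid")
    if gm.dtype != bool:
        gm = gm > 0.5
    return template.with_mask(gm, note="gm-mask")


def minmax_normalize(template: MolecularTemplate) -> MolecularTemplate:
    """Linearly rescale valid voxel values onto [0, 1].

    Affine, so ranks and relative spacing of the intensity distribution
    are preserved.  Fails on a constant image (scale undefined).
    """
    vals = template.data[template.valid_mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo <= 0:
        raise ValueError(
            f"template {template.system_name!r} is constant over its valid mask; "
            "min-max normalization undefined"
        )
    data = np.zeros_like(template.data)
    data[template.valid_mask] = (vals - lo) / (hi - lo)
    return replace(
        template, data=data, provenance=[*template.provenance, "minmax-normalize"]
    )


def resample_to_grid(
    template: MolecularTemplate, grid: VolumeGrid, order: int = 1
) -> MolecularTemplate:
    """Resample a template onto a target grid via the two affines.

    Densities are interpolated at ``order`` (default trilinear); the
    validity mask is resampled nearest-neighbour and re-binarized.  Voxels
    outside the source support become invalid.  If the target grid equals
    the source grid the template is returned bit-identical.
    """
    if template.grid.matches(grid):
        return replace(
            template,
            data=template.data.copy(),
            valid_mask=template.valid_mask.copy(),
            provenance=[*template.provenance, "resample:identity"],
        )
    # target voxel -> world -> source voxel
    M = np.linalg.inv(template.grid.affine) @ grid.affine
    matrix, offset = M[:3, :3], M[:3, 3]
    data = ndimage.affine_transform(
        template.data, matrix, offset=offset, output_shape=grid.shape,
        order=order, mode="constant", cval=0.0,
    )
    mask = ndimage.affine_transform(
        template.valid_mask.astype(np.uint8), matrix, offset=offset,
        output_shape=grid.shape, order=0, mode="constant", cval=0,
    ).astype(bool)
    if not mask.any():
        raise ValueError("resampled template has no valid voxels on target grid")
    data = np.where(mask, data, 0.0)
    return MolecularTemplate(
        system_name=template.system_name,
        data=data,
        valid_mask=mask,
        grid=grid,
        reference_region=template.reference_region,
        provenance=[*template.provenance, f"resample:order={order}"],
    )


def build_analysis_mask(
    templates: list[MolecularTemplate], combine: str = "intersection"
) -> AnalysisMask:
    """Combine per-template validity masks into the step-1 analysis mask.

    Because reference regions differ between systems, the default step-1
    mask is the intersection of all per-system masks (one joint design
    matrix needs a common voxel set); ``combine="union"`` is available,
    and the per-system masks and their union are carried along for the
    per-system mode and for reporting.
    """
    if not templates:
        raise ValueError("no templates given")
    if combine not in ("intersection", "union"):
        raise ValueError("combine must be 'intersection' or 'union'")
    grid = templates[0].grid
    for t in templates[1:]:
        check_same_grid(grid, t.grid, what=f"template {t.system_name!r}")
    per_system = {t.system_name: t.valid_mask.copy() for t in templates}
    inter = np.logical_and.reduce([t.valid_mask for t in templates])
    union = np.logical_or.reduce([t.valid_mask for t in templates])
    mask = inter if combine == "intersection" else union
    if not mask.any():
        raise ValueError(f"{combine} of template masks is empty")
    if int(mask.sum()) <= len(templates):
        raise ValueError("analysis mask smaller than the number of templates")
    return AnalysisMask(mask=mask, per_system=per_system, union=union)
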