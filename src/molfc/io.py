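"""NIfTI-1 reading/writing helpers built on nibabel."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import VolumeGrid
from .preprocess import Bold4D
from .templates import MolecularTemplate


def grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
    )


def save_volume(data: np.ndarray, grid: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_size[: data.ndim])
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), grid_from_nifti(img)


def load_mask(path) -> tuple[np.ndarray, VolumeGrid]:
    data, grid = load_volume(path)
    return data > 0.5, grid


def load_bold(path, tr: float | None = None, subject_id: str | None = None) -> Bold4D:
    img = nib.load(str(path))
    grid = grid_from_nifti(img)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise ValueError(f"TR not present in {path}; pass it explicitly")
    sid = subject_id or Path(str(path)).name.split("_")[0]
    return Bold4D(data=np.asarray(img.get_fdata(), dtype=float), grid=grid, tr=tr, subject_id=sid)


def save_bold(bold: Bold4D, path) -> None:
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), bold.grid.affine)
    img.header.set_zooms((*bold.grid.voxel_size, bold.tr))
    nib.save(img, str(path))


def load_template(path, system_name: str, reference_region: str | None = None) -> MolecularTemplate:
    data, grid = load_volume(path)
    return MolecularTemplate(
        system_name=system_name,
        data=data,
        valid_mask=data != 0,
        grid=grid,
        reference_region=reference_region,
        provenance=[f"loaded:{path}"],
    )


def save_template(template: MolecularTemplate, path, sidecar: bool = True) -> None:
    save_volume(template.data, template.grid, path)
    if sidecar:
        meta = {
            "system_name": template.system_name,
            "reference_region": template.reference_region,
            "provenance": template.provenance,
            "n_valid": template.n_valid,
        }
        Path(str(path)).with_suffix("").with_suffix(".json").write_text(
            json.dumps(meta, indent=2)
        )


def write_cohort_bids_like(cohort, outdir) -> None:
    """BIDS-like layout: sub-XX/func/*_bold.nii.gz, templates/, TSV, truth."""
    out = Path(outdir)
    (out / "templates").mkdir(parents=True, exist_ok=True)
    for k, t in enumerate(cohort.templates):
        save_template(t, out / "templates" / f"template-{k:02d}_{t.system_name}.nii.gz")
    for bold in cohort.bolds:
        func = out / bold.subject_id / "func"
        func.mkdir(parents=True, exist_ok=True)
        save_bold(bold, func / f"{bold.subject_id}_bold.nii.gz")
    cohort.table.to_csv(out / "participants.tsv", sep="\t", index=False)
    gt = cohort.ground_truth
    truth = {
        "effect_size": gt.effect_size,
        "noise_sd": gt.noise_sd,
        "seed": gt.seed,
        "effect_system": gt.effect_system,
        "n_effect_voxels": int(gt.effect_mask.sum()),
        "subject_gains": gt.subject_gains.tolist(),
        "subject_amps": gt.subject_amps.tolist(),
        "fc_scores": gt.fc_scores.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    save_volume(gt.effect_mask.astype(np.uint8), cohort.templates[0].grid, out / "effect_mask.nii.gz")
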