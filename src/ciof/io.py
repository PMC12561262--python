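"""Reading and writing cohorts: PNG/NIfTI masks and the CSV manifest.

A cohort on disk is a directory of mask files plus a manifest CSV with
header ``patient_id,slice_id,role,model_id,path`` where ``role`` is
``ground_truth`` or ``prediction`` (``model_id`` empty for ground truth).
Slice order within a patient follows the manifest, never filename sorting.

PNG masks are 8-bit grayscale: 0 is background, any nonzero value reads as
lesion. NIfTI files hold one volume per patient per (model or ground
truth), slices stacked along the third axis; values above a probability
threshold (default 0.5) read as lesion.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .masks import Cohort, SliceRecord, stack_predictions

__all__ = [
    "read_mask_png",
    "write_mask_png",
    "read_mask_volume",
    "write_mask_volume",
    "write_cohort",
    "read_cohort",
]

MANIFEST_COLUMNS = ["patient_id", "slice_id", "role", "model_id", "path"]


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a PNG slice mask; any nonzero pixel maps to 1."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.max(axis=2)
    return (arr > 0).astype(np.uint8)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit grayscale PNG (lesion = 255)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def read_mask_volume(path: str | Path, threshold: float = 0.5) -> np.ndarray:
    """Read a NIfTI mask volume as (n_slices, h, w); values > threshold map to 1.

    The threshold binarizes probability maps; exact 0/1 volumes pass
    through unchanged at the default 0.5.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume in {path}, got shape {data.shape}")
    binary = (data > threshold).astype(np.uint8)
    return np.moveaxis(binary, 2, 0)  # slices along the third axis on disk


def write_mask_volume(slices: list[np.ndarray], path: str | Path) -> None:
    """Write stacked binary slice masks as a NIfTI volume (identity affine)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(np.stack(slices).astype(np.uint8), 0, 2)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_cohort(cohort: Cohort, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write a cohort's masks plus manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    if fmt == "png":
        for s in cohort.slices:
            gt_path = out / s.patient_id / f"{s.slice_id}_gt.png"
            write_mask_png(s.ground_truth, gt_path)
            rows.append((s.patient_id, s.slice_id, "ground_truth", "",
                         str(gt_path.relative_to(out))))
            for i, m in enumerate(s.predictions.masks):
                mp = out / s.patient_id / f"{s.slice_id}_model{i:02d}.png"
                write_mask_png(m, mp)
                rows.append((s.patient_id, s.slice_id, "prediction", f"model{i:02d}",
                             str(mp.relative_to(out))))
    elif fmt == "nii":
        by_patient = cohort.by_patient()
        for pid, recs in by_patient.items():
            gt_path = out / pid / "gt.nii.gz"
            write_mask_volume([r.ground_truth for r in recs], gt_path)
            for j, r in enumerate(recs):
                rows.append((pid, r.slice_id, "ground_truth", "",
                             f"{gt_path.relative_to(out)}#{j}"))
            m_count = recs[0].predictions.m
            for i in range(m_count):
                mp = out / pid / f"model{i:02d}.nii.gz"
                write_mask_volume([r.predictions.masks[i] for r in recs], mp)
                for j, r in enumerate(recs):
                    rows.append((pid, r.slice_id, "prediction", f"model{i:02d}",
                                 f"{mp.relative_to(out)}#{j}"))
    else:
        raise ValueError(f"unknown cohort format {fmt!r} (use 'png' or 'nii')")
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path, threshold: float = 0.5) -> Cohort:
    """Load a cohort from its manifest CSV.

    Paths are resolved relative to the manifest's directory. NIfTI entries
    use ``path#index`` to address a slice within a volume; volumes are
    cached so each file is read once.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")

    volumes: dict[str, np.ndarray] = {}

    def load(path_field: str, row_idx: int) -> np.ndarray:
        if "#" in path_field:
            file_part, idx_part = path_field.rsplit("#", 1)
            full = base / file_part
            if str(full) not in volumes:
                volumes[str(full)] = read_mask_volume(full, threshold)
            return volumes[str(full)][int(idx_part)]
        full = base / path_field
        if not full.exists():
            raise ValueError(f"manifest row {row_idx + 2}: file not found: {full}")
        if full.suffix == ".png":
            return read_mask_png(full)
        raise ValueError(f"manifest row {row_idx + 2}: unsupported mask file {full}")

    slices: list[SliceRecord] = []
    # preserve manifest order of (patient, slice) pairs
    seen: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        key = (str(row.patient_id), str(row.slice_id))
        if key not in seen:
            seen[key] = {"gt": None, "preds": []}
            order.append(key)
        mask = load(str(row.path), idx)
        if row.role == "ground_truth":
            seen[key]["gt"] = mask
        elif row.role == "prediction":
            seen[key]["preds"].append((str(row.model_id), mask))
        else:
            raise ValueError(
                f"manifest row {idx + 2}: unknown role {row.role!r} "
                "(expected ground_truth or prediction)"
            )
    for pid, sid in order:
        entry = seen[(pid, sid)]
        if entry["gt"] is None:
            raise ValueError(f"slice {pid}/{sid} has no ground truth in manifest")
        if not entry["preds"]:
            raise ValueError(f"slice {pid}/{sid} has no predictions in manifest")
        entry["preds"].sort(key=lambda t: t[0])  # stable model order by id
        slices.append(
            SliceRecord(
                patient_id=pid,
                slice_id=sid,
                ground_truth=entry["gt"],
                predictions=stack_predictions([m for _, m in entry["preds"]]),
            )
        )
    return Cohort(slices=slices)
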