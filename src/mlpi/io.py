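"""Readers/writers for the pipeline's on-disk formats.

Volumes are NIfTI (tissue labels as integers, densities and channels as
float32); biopsy tables are CSV with 0-based voxel coordinates
(``patient_id, i, j, k, density, is_bat``; ``k`` may be blank for 2D
grids).  NIfTI affines are used only for voxel spacing — inputs are
assumed co-registered, so no reorientation is applied.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import BiopsyRecord
from .pi_model import DensityField, TissueMap

logger = logging.getLogger(__name__)

SPACING_TOL = 1e-3  # mm


def _as_3d(arr: np.ndarray) -> np.ndarray:
    return arr[:, :, None] if arr.ndim == 2 else arr


def write_volume(path: str | Path, values: np.ndarray, spacing: tuple[float, ...], dtype=np.float32) -> None:
    arr = _as_3d(np.asarray(values)).astype(dtype)
    zooms = tuple(spacing) + (1.0,) * (3 - len(spacing))
    affine = np.diag(list(zooms) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path: str | Path, squeeze: bool = True) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[: arr.ndim]
    if squeeze and arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
        zooms = zooms[:2]
    return np.asarray(arr), tuple(float(z) for z in zooms)


def write_tissue(path: str | Path, tissue: TissueMap) -> None:
    write_volume(path, tissue.labels, tissue.spacing, dtype=np.int16)


def read_tissue(path: str | Path) -> TissueMap:
    arr, spacing = read_volume(path)
    return TissueMap(arr.astype(int), spacing)


def write_density(path: str | Path, field: DensityField) -> None:
    write_volume(path, field.values, field.spacing, dtype=np.float32)


def read_density(path: str | Path) -> DensityField:
    arr, spacing = read_volume(path)
    return DensityField(np.clip(arr.astype(float), 0.0, 1.0), spacing)


def write_biopsies(path: str | Path, biopsies: list[BiopsyRecord]) -> None:
    rows = []
    for b in biopsies:
        loc = list(b.location) + [""] * (3 - len(b.location))
        rows.append({
            "patient_id": b.patient_id, "i": loc[0], "j": loc[1], "k": loc[2],
            "density": b.density, "is_bat": int(b.is_bat),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_biopsies(path: str | Path) -> list[BiopsyRecord]:
    df = pd.read_csv(path)
    required = {"patient_id", "i", "j", "density"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biopsy CSV missing columns: {sorted(missing)}")
    records = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        density = float(d["density"])
        if not 0.0 <= density <= 1.0:
            raise ValueError(f"row {row_num}: density {density} outside [0, 1]")
        loc = [int(d["i"]), int(d["j"])]
        k = d.get("k")
        if k is not None and not (isinstance(k, float) and np.isnan(k)) and str(k) != "":
            loc.append(int(k))
        records.append(BiopsyRecord(
            patient_id=str(d["patient_id"]), location=tuple(loc),
            density=density, is_bat=bool(int(d.get("is_bat", 0) or 0)),
        ))
    return records


def load_case(
    channel_paths: list[str | Path],
    roi_path: str | Path,
    biopsy_path: str | Path | None = None,
    tissue_path: str | Path | None = None,
    pi_path: str | Path | None = None,
):
    """Load a co-registered case, checking shapes and spacings agree.

    Returns a dict with keys ``channels``, ``spacing``, ``roi``, and
    optionally ``biopsies``, ``tissue``, ``pi``.  A file whose shape or
    spacing disagrees with the first channel is rejected by name.
    """
    channels, spacings, names = [], [], []
    for p in channel_paths:
        arr, sp = read_volume(p)
        channels.append(arr.astype(float))
        spacings.append(sp)
        names.append(str(p))
    ref_shape, ref_spacing = channels[0].shape, spacings[0]

    def check(name, shape, spacing):
        if shape != ref_shape:
            raise ValueError(f"{name}: shape {shape} does not match {names[0]} {ref_shape}")
        if len(spacing) != len(ref_spacing) or any(
            abs(a - b) > SPACING_TOL for a, b in zip(spacing, ref_spacing)
        ):
            raise ValueError(f"{name}: spacing {spacing} does not match {names[0]} {ref_spacing}")

    for name, ch, sp in zip(names, channels, spacings):
        check(name, ch.shape, sp)
    roi, sp = read_volume(roi_path)
    check(str(roi_path), roi.shape, sp)
    case = {"channels": channels, "spacing": ref_spacing, "roi": roi.astype(bool)}
    if tissue_path is not None:
        tissue = read_tissue(tissue_path)
        check(str(tissue_path), tissue.shape, tissue.spacing)
        case["tissue"] = tissue
    if pi_path is not None:
        pi = read_density(pi_path)
        check(str(pi_path), pi.shape, pi.spacing)
        case["pi"] = pi
    if biopsy_path is not None:
        biopsies = read_biopsies(biopsy_path)
        for b in biopsies:
            if any(c < 0 or c >= n for c, n in zip(b.location, ref_shape)):
                raise ValueError(f"biopsy at {b.location} outside image bounds {ref_shape}")
        case["biopsies"] = biopsies
    logger.info("loaded case: %d channels, shape %s, spacing %s", len(channels), ref_shape, ref_spacing)
    return case


def write_case_dir(case, out_dir: str | Path) -> None:
    """Write a synthetic case in exactly the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = case.tissue.spacing
    from .synthetic import CHANNEL_NAMES

    for name, ch in zip(CHANNEL_NAMES, case.channels):
        write_volume(out / f"{name.replace('+', '').lower()}.nii.gz", ch, spacing)
    write_tissue(out / "tissue.nii.gz", case.tissue)
    write_density(out / "pi.nii.gz", case.pi_field)
    write_density(out / "true_density.nii.gz", case.true_density)
    write_volume(out / "roi.nii.gz", case.roi_mask.astype(np.int16), spacing, dtype=np.int16)
    write_biopsies(out / "biopsies.csv", case.biopsies)
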