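"""Box-mean feature extraction: biopsies and ROI voxels become samples.

Each sample is described by the mean intensity of every image channel over
an 8x8 in-plane voxel box at its location, plus the mean PI-predicted
density over the same box.  Samples carrying a pathologically measured
tumor cell density are *labeled*; samples placed on every ROI voxel of a
chosen slice are *unlabeled* and only inform the smoothness graph.

Box convention: an even-sized box "centered" on voxel ``c`` spans the
half-open index range ``[c - e//2, c + e - e//2)`` on each in-plane axis
(for ``e = 8``: ``[c-4, c+4)``), so boxes tile the grid exactly at stride
``e``.  For 3D volumes the box lies in the (axis-0, axis-1) plane at the
voxel's axis-2 slice.  All indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BOX_EDGE = 8


@dataclass(frozen=True)
class BiopsyRecord:
    """One tissue specimen: location and measured tumor cell fraction."""

    patient_id: str
    location: tuple[int, ...]
    density: float
    is_bat: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"biopsy density {self.density} outside [0, 1]")


@dataclass(frozen=True)
class Sample:
    """One observation: image-channel box means ``z`` plus the PI box mean.

    ``y`` is the measured density fraction and is present exactly when the
    sample is labeled; synthetic samples are training-only augmentations.
    """

    z: tuple[float, ...]
    pi: float
    patient_id: str
    location: tuple[int, ...]
    y: float | None = None
    is_synthetic: bool = False
    is_bat: bool = False

    def __post_init__(self) -> None:
        if self.y is not None and not 0.0 <= self.y <= 1.0:
            raise ValueError(f"label {self.y} outside [0, 1]")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite feature value")

    @property
    def is_labeled(self) -> bool:
        return self.y is not None

    @property
    def x(self) -> np.ndarray:
        """Concatenated feature vector (z, PI)."""
        return np.asarray(self.z + (self.pi,), dtype=float)


def feature_matrix(samples: list[Sample]) -> np.ndarray:
    """Stack sample feature vectors (z, PI) into an (n, d) array."""
    return np.asarray([s.x for s in samples], dtype=float)


def _box_slices(center: tuple[int, ...], box_edge: int, shape: tuple[int, ...]):
    """In-plane box slices, or None if the box leaves the image."""
    lo_off = box_edge // 2
    hi_off = box_edge - lo_off
    slices = []
    for ax in range(min(2, len(shape))):
        c = center[ax]
        lo, hi = c - lo_off, c + hi_off
        if lo < 0 or hi > shape[ax]:
            return None
        slices.append(slice(lo, hi))
    if len(shape) > 2:
        k = center[2]
        if k < 0 or k >= shape[2]:
            return None
        slices.append(k)
    return tuple(slices)


def extract_box_mean(channel: np.ndarray, center: tuple[int, ...], box_edge: int = DEFAULT_BOX_EDGE) -> float:
    """Mean of the in-plane ``box_edge``-square box at ``center``.

    Raises ``ValueError`` if the box extends past the image boundary; batch
    builders catch this and skip the offending record with a warning rather
    than silently truncating the box.
    """
    channel = np.asarray(channel)
    if len(center) != channel.ndim:
        raise ValueError("center dimensionality does not match the image")
    slices = _box_slices(tuple(int(i) for i in center), box_edge, channel.shape)
    if slices is None:
        raise ValueError(f"box of edge {box_edge} at {tuple(center)} extends past the image boundary")
    return float(np.mean(channel[slices]))


def _make_sample(
    channels: list[np.ndarray],
    pi_values: np.ndarray,
    location: tuple[int, ...],
    box_edge: int,
    **kwargs,
) -> Sample:
    z = tuple(extract_box_mean(ch, location, box_edge) for ch in channels)
    pi = extract_box_mean(pi_values, location, box_edge)
    return Sample(z=z, pi=pi, location=tuple(int(i) for i in location), **kwargs)


def standardize_channels(channels: list[np.ndarray], brain_mask: np.ndarray) -> list[np.ndarray]:
    """Z-score each channel within the brain mask.

    Raw MR intensities are on arbitrary scanner-dependent scales; the graph
    edge weights compare feature distances across channels, so channels must
    be commensurate.  Voxels outside the mask keep their standardized value
    (mean/SD come from the mask only).
    """
    out = []
    for ch in channels:
        vals = ch[brain_mask]
        sd = vals.std()
        out.append((ch - vals.mean()) / (sd if sd > 0 else 1.0))
    return out


def build_labeled_samples(
    channels: list[np.ndarray],
    pi_map,
    biopsies: list[BiopsyRecord],
    box_edge: int = DEFAULT_BOX_EDGE,
) -> list[Sample]:
    """One labeled sample per biopsy record; out-of-bounds records skipped."""
    pi_values = np.asarray(getattr(pi_map, "values", pi_map))
    _check_coregistered(channels, pi_values)
    samples = []
    for rec in biopsies:
        try:
            s = _make_sample(
                channels, pi_values, rec.location, box_edge,
                patient_id=rec.patient_id, y=rec.density, is_bat=rec.is_bat,
            )
        except ValueError as exc:
            logger.warning("skipping biopsy %s at %s: %s", rec.patient_id, rec.location, exc)
            continue
        samples.append(s)
    return samples


def build_unlabeled_samples(
    channels: list[np.ndarray],
    pi_map,
    roi_mask: np.ndarray,
    patient_id: str,
    slice_index: int | None = None,
    stride: int = 1,
    box_edge: int = DEFAULT_BOX_EDGE,
) -> list[Sample]:
    """One unlabeled sample per ROI voxel of the chosen slice at ``stride``.

    The slice protocol mirrors manual practice: one representative slice is
    picked per patient (for 2D grids the whole grid is the slice).  Voxels
    whose box leaves the image are skipped.
    """
    pi_values = np.asarray(getattr(pi_map, "values", pi_map))
    roi_mask = np.asarray(roi_mask, dtype=bool)
    _check_coregistered(channels, pi_values, roi_mask)
    if roi_mask.ndim == 3:
        if slice_index is None:
            raise ValueError("slice_index is required for 3D volumes")
        in_slice = np.zeros_like(roi_mask)
        in_slice[:, :, slice_index] = roi_mask[:, :, slice_index]
        roi_mask = in_slice
    if not roi_mask.any():
        raise ValueError("ROI is empty on the chosen slice")
    samples = []
    coords = np.argwhere(roi_mask)
    keep = np.all(coords[:, :2] % stride == 0, axis=1)
    for loc in coords[keep]:
        try:
            s = _make_sample(channels, pi_values, tuple(loc), box_edge, patient_id=patient_id)
        except ValueError:
            continue
        samples.append(s)
    return samples


def augment_synthetic_biopsies(
    channels: list[np.ndarray],
    pi_map,
    roi_mask: np.ndarray,
    existing: list[Sample],
    patient_id: str,
    max_per_patient: int = 6,
    low_density_threshold: float = 0.2,
    box_edge: int = DEFAULT_BOX_EDGE,
) -> list[Sample]:
    """Synthetic biopsies in expected-low-density regions.

    Real biopsies oversample high-density tissue; to debias the labels,
    up to ``max_per_patient`` training-only labeled samples are planted at
    locations whose PI box mean falls below ``low_density_threshold``.  The
    assigned label is the PI box mean itself (the region is low-density
    *by expectation under the PI model* — no pathology exists there), a
    reconstruction choice logged per patient.  Placements keep at least two
    box widths from each other and from existing samples so augmentations
    do not duplicate information.
    """
    pi_values = np.asarray(getattr(pi_map, "values", pi_map))
    roi_mask = np.asarray(roi_mask, dtype=bool)
    min_sep = 2 * box_edge
    taken = [np.asarray(s.location[:2], dtype=float) for s in existing]
    out: list[Sample] = []
    candidates = np.argwhere(roi_mask)
    for loc in candidates:
        if len(out) >= max_per_patient:
            break
        try:
            pi_mean = extract_box_mean(pi_values, tuple(loc), box_edge)
        except ValueError:
            continue
        if pi_mean >= low_density_threshold:
            continue
        p = np.asarray(loc[:2], dtype=float)
        if any(np.linalg.norm(p - q) < min_sep for q in taken):
            continue
        s = _make_sample(
            channels, pi_values, tuple(loc), box_edge,
            patient_id=patient_id, y=float(np.clip(pi_mean, 0.0, 1.0)), is_synthetic=True,
        )
        out.append(s)
        taken.append(p)
    if not out:
        logger.warning("patient %s: no qualifying low-density region for synthetic biopsies", patient_id)
    else:
        logger.info(
            "patient %s: %d synthetic biopsies (label = PI box mean, threshold %.2f)",
            patient_id, len(out), low_density_threshold,
        )
    return out


def _check_coregistered(channels: list[np.ndarray], *grids: np.ndarray) -> None:
    shapes = {np.asarray(ch).shape for ch in channels} | {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"grids are not co-registered: shapes {sorted(shapes)}")
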