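"""Phantom patients with the statistical structure the hybrid model assumes.

The clinical cohort behind this method (image-localized biopsies with
pathological density reads) cannot be redistributed, so every stage of the
pipeline is exercised on synthetic cases built to emulate its structure:

* a 2D tissue grid — circular brain, gray background crossed by white
  tracts — on which the PI model is simulated with patient-specific
  ``(D, rho)``;
* a ground-truth density field that *warps* the PI solution with smooth
  multiplicative noise, so truth shares the PI map's global shape but
  deviates regionally (``blend_weight`` sets how strongly truth follows
  PI: 1 means truth = PI, smaller values allow larger deviations);
* six image channels, each a channel-specific monotone response to the
  true density (one decreasing, emulating mean diffusivity's inverse
  relation to cellularity) plus a tissue offset, spatially correlated
  noise, and an arbitrary per-channel scanner gain/offset;
* biopsies sampled with probability proportional to
  ``exp(bias_strength * density)`` — mirroring the clinical bias of tissue
  acquisition toward suspected tumor — labeled with the true-density box
  mean plus measurement noise; non-enhancing locations are flagged BAT;
* an ROI mask covering the density abnormality.

What the phantoms do *not* emulate: MR physics, anatomy, registration
error, or inter-scanner effects.  Passing tests demonstrate the
machinery's correctness and the method's designed behavior, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluation import Cohort
from .features import (
    BiopsyRecord,
    Sample,
    augment_synthetic_biopsies,
    build_labeled_samples,
    build_unlabeled_samples,
    standardize_channels,
)
from .pi_model import GRAY, NONBRAIN, WHITE, DensityField, PIParams, TissueMap, simulate_pi, stable_dt, step_pi

LABEL_NOISE_SD = 0.03  # pathological density estimation error
BAT_THRESHOLD = 0.80   # PI box mean below this = non-enhancing (BAT)
ROI_LEVEL = 0.02
N_CHANNELS = 6

CHANNEL_NAMES = ["T1Gd", "T2W", "EPI+C", "MD", "FA", "rCBV"]


@dataclass
class SyntheticCase:
    """One phantom patient: geometry, truth, images, biopsies."""

    patient_id: str
    tissue: TissueMap
    pi_field: DensityField
    true_density: DensityField
    pi_truth_params: PIParams
    channels: list[np.ndarray]
    roi_mask: np.ndarray
    biopsies: list[BiopsyRecord]
    seed: int
    blend_weight: float


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially correlated Gaussian field, zero mean, unit SD."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = raw.std()
    return (raw - raw.mean()) / (sd if sd > 0 else 1.0)


def _make_tissue(rng: np.random.Generator, n: int) -> TissueMap:
    """Circular brain, gray background, a few white-matter bands."""
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    brain = (yy - c) ** 2 + (xx - c) ** 2 <= (0.47 * n) ** 2
    labels = np.where(brain, GRAY, NONBRAIN)
    for _ in range(3):
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(-0.3 * n, 0.3 * n)
        width = rng.uniform(2.0, 5.0)
        dist = np.abs((xx - c) * np.sin(theta) - (yy - c) * np.cos(theta) - offset)
        labels[(dist < width) & brain] = WHITE
    return TissueMap(labels, (1.0, 1.0))


def _grow_tumor(
    tissue: TissueMap, params: PIParams, seed_loc: tuple[int, int], target_fraction: float = 0.25
) -> DensityField:
    """Simulate PI until the abnormality covers ``target_fraction`` of the brain."""
    dt = 0.9 * stable_dt(tissue, params)
    field = simulate_pi(tissue, params, seed_loc, t_end=0.0)
    n_brain = int(tissue.brain_mask.sum())
    for _ in range(8000):
        field = step_pi(field, tissue, params, dt)
        if (field.values > ROI_LEVEL).sum() >= target_fraction * n_brain:
            break
    return field


# channel-specific monotone responses to true density; index 3 (MD role)
# decreases with cellularity
_RESPONSES = [
    lambda c: 1.0 / (1.0 + np.exp(-(c - 0.6) / 0.1)),
    lambda c: np.sqrt(c),
    lambda c: c,
    lambda c: 1.0 - c**0.8,
    lambda c: 0.5 * c + 0.25 * c**2,
    lambda c: c**2,
]


def generate_phantom(
    seed: int,
    grid_size: int = 64,
    pi_params_range: tuple[tuple[float, float], tuple[float, float]] = ((20.0, 60.0), (10.0, 20.0)),
    blend_weight: float = 0.5,
    n_biopsies: int = 6,
    bias_strength: float = 4.0,
    noise_sd: float = 0.35,
    patient_id: str | None = None,
) -> SyntheticCase:
    """One phantom patient, fully determined by ``seed``.

    ``pi_params_range`` gives uniform draw ranges for (D_white in mm^2/year,
    rho in 1/year); D_gray = D_white / 10.  ``blend_weight`` in [0, 1] is
    the share of the truth signal attributable to the PI field; the warp
    amplitude is ``0.6 * (1 - blend_weight)``.

    ``noise_sd`` scales the spatially correlated channel noise relative to
    the (roughly unit-range) density response.  The default 0.35 keeps the
    per-channel correlation with true density weak-to-moderate, matching
    how loosely any single MR intensity tracks cellularity; much smaller
    values would make every channel an almost noiseless density readout,
    which real sequences are not.
    """
    if grid_size < 32:
        raise ValueError("grid_size must be at least 32")
    if not 0.0 <= blend_weight <= 1.0:
        raise ValueError("blend_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pid = patient_id or f"P{seed:04d}"
    tissue = _make_tissue(rng, grid_size)

    (d_lo, d_hi), (r_lo, r_hi) = pi_params_range
    params = PIParams(
        D_white=float(rng.uniform(d_lo, d_hi)),
        D_gray=float(rng.uniform(d_lo, d_hi)) / 10.0,
        rho=float(rng.uniform(r_lo, r_hi)),
    )
    center = grid_size // 2
    jitter = rng.integers(-grid_size // 8, grid_size // 8 + 1, size=2)
    seed_loc = (int(center + jitter[0]), int(center + jitter[1]))
    if tissue.labels[seed_loc] == NONBRAIN:
        seed_loc = (center, center)
    pi_field = _grow_tumor(tissue, params, seed_loc)

    warp_amp = 0.6 * (1.0 - blend_weight)
    warp = _smooth_noise(rng, tissue.shape, sigma=6.0)
    truth = np.clip(pi_field.values * (1.0 + warp_amp * warp), 0.0, 1.0)
    truth[~tissue.brain_mask] = 0.0
    true_density = DensityField(truth, tissue.spacing)

    channels = []
    white = tissue.labels == WHITE
    for k, resp in enumerate(_RESPONSES[:N_CHANNELS]):
        img = resp(truth)
        img = img + 0.1 * ((-1) ** k) * white  # tissue-class offset
        img = img + noise_sd * _smooth_noise(rng, tissue.shape, sigma=2.0)
        gain = rng.uniform(0.5, 2.0)
        offset = rng.uniform(-1.0, 1.0)
        channels.append(gain * img + offset)  # arbitrary scanner scale

    roi = truth > ROI_LEVEL
    roi = ndimage.binary_closing(roi, structure=np.ones((3, 3))) & tissue.brain_mask

    biopsies = _sample_biopsies(rng, pid, truth, pi_field.values, roi, n_biopsies, bias_strength)
    return SyntheticCase(
        patient_id=pid, tissue=tissue, pi_field=pi_field, true_density=true_density,
        pi_truth_params=params, channels=channels, roi_mask=roi, biopsies=biopsies,
        seed=seed, blend_weight=blend_weight,
    )


def _box_mean_grid(values: np.ndarray, box_edge: int = 8) -> np.ndarray:
    """Box mean at every voxel under the [c-4, c+4) convention."""
    # for even sizes uniform_filter's window is [c - e//2, c + e - e//2), our span
    return ndimage.uniform_filter(values.astype(float), size=box_edge, mode="constant")


def _sample_biopsies(rng, pid, truth, pi_values, roi, n_biopsies, bias_strength) -> list[BiopsyRecord]:
    box = 8
    valid = np.zeros_like(roi)
    valid[4:-4, 4:-4] = True  # box must fit inside the grid
    # the full box must lie inside the ROI so ROI covers every biopsy box
    roi_all = ndimage.minimum_filter(roi.astype(np.uint8), size=box, mode="constant")
    candidates = np.argwhere(valid & (roi_all > 0))
    if len(candidates) < n_biopsies:
        raise ValueError(f"only {len(candidates)} candidate biopsy locations for {n_biopsies} biopsies")
    dens = truth[candidates[:, 0], candidates[:, 1]]
    p = np.exp(bias_strength * dens)
    p = p / p.sum()
    chosen = rng.choice(len(candidates), size=n_biopsies, replace=False, p=p)
    truth_bm = _box_mean_grid(truth)
    pi_bm = _box_mean_grid(pi_values)
    records = []
    for idx in chosen:
        loc = tuple(int(v) for v in candidates[idx])
        y = float(np.clip(truth_bm[loc] + rng.normal(0.0, LABEL_NOISE_SD), 0.0, 1.0))
        records.append(BiopsyRecord(
            patient_id=pid, location=loc, density=y, is_bat=bool(pi_bm[loc] < BAT_THRESHOLD),
        ))
    return records


def case_samples(
    case: SyntheticCase,
    standardize: bool = True,
    augment: bool = True,
    unlabeled_stride: int = 2,
    max_synthetic: int = 6,
) -> list[Sample]:
    """Labeled, synthetic-augmented, and unlabeled samples for one phantom."""
    channels = case.channels
    if standardize:
        channels = standardize_channels(channels, case.tissue.brain_mask)
    labeled = build_labeled_samples(channels, case.pi_field, case.biopsies)
    samples = list(labeled)
    if augment:
        samples += augment_synthetic_biopsies(
            channels, case.pi_field, case.roi_mask, labeled, case.patient_id,
            max_per_patient=max_synthetic,
        )
    samples += build_unlabeled_samples(
        channels, case.pi_field, case.roi_mask, case.patient_id, stride=unlabeled_stride,
    )
    return samples


def generate_cohort(
    n_patients: int,
    seed: int,
    per_patient_biopsy_range: tuple[int, int] = (2, 14),
    blend_weight: float = 0.5,
    grid_size: int = 64,
    **case_kw,
) -> list[SyntheticCase]:
    """Independent phantoms sharing one configuration; deterministic from seed."""
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    rng = np.random.default_rng(seed)
    lo, hi = per_patient_biopsy_range
    cases = []
    for i in range(n_patients):
        case_seed = int(rng.integers(0, 2**31 - 1))
        n_b = int(rng.integers(lo, hi + 1))
        cases.append(generate_phantom(
            case_seed, grid_size=grid_size, blend_weight=blend_weight,
            n_biopsies=n_b, patient_id=f"P{i:02d}", **case_kw,
        ))
    return cases


def cohort_from_cases(cases: list[SyntheticCase], **sample_kw) -> Cohort:
    return Cohort({c.patient_id: case_samples(c, **sample_kw) for c in cases})
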