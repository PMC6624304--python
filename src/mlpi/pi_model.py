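"""Proliferation-Invasion (PI) reaction-diffusion model of tumor growth.

The PI model describes tumor cell density ``c(x, t)`` as cells that both
invade surrounding tissue (diffusion with a tissue-dependent net rate
``D(x)``, piecewise constant between gray and white matter) and proliferate
logistically at net rate ``rho`` toward a carrying capacity ``K``:

    dc/dt = div(D(x) grad c) + rho * c * (1 - c / K)

Densities are expressed as fractions of the carrying capacity, so ``K`` is
normalized to 1 and fields live in ``[0, 1]``.

The solver is an explicit forward-Euler scheme with central-difference
fluxes, harmonic-mean interface diffusivities between tissue classes, and
no-flux boundaries at the brain / non-brain interface.  It is
dimension-agnostic (1D strips through 3D volumes share one code path).

Patient-specific ``(D, rho)`` are calibrated from the two abnormality radii
visible on contrast-enhanced T1 and T2-weighted imaging via the Fisher-KPP
traveling-wave argument: the asymptotic front speed ``2 * sqrt(D * rho)``
fixes the product of the rates, and the width of the density profile
between the two imaging thresholds fixes their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

WHITE = 1
GRAY = 2
NONBRAIN = 0

#: Default density thresholds for the imaging abnormality edges: the
#: contrast-enhancing rim on T1Gd corresponds to a high cell fraction, the
#: T2W abnormality edge to a much lower one.
DEFAULT_THRESHOLDS = (0.80, 0.16)


class StabilityError(ValueError):
    """Raised when an explicit time step violates the diffusion CFL bound."""


@dataclass(frozen=True)
class PIParams:
    """Net rates of the PI model; ``D`` in mm^2/year, ``rho`` in 1/year."""

    D_white: float
    D_gray: float
    rho: float
    K: float = 1.0

    def __post_init__(self) -> None:
        if not (self.D_white > 0 and self.D_gray > 0 and self.rho > 0):
            raise ValueError("D_white, D_gray and rho must be strictly positive")
        if self.K != 1.0:
            raise ValueError("carrying capacity is normalized to 1")


@dataclass(frozen=True)
class TissueMap:
    """Labeled voxel grid (WHITE / GRAY / NONBRAIN) with physical spacing."""

    labels: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != self.labels.ndim:
            raise ValueError("spacing must give one value per grid axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.any(self.labels != NONBRAIN):
            raise ValueError("tissue map contains no brain voxels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != NONBRAIN

    def diffusivity(self, params: PIParams) -> np.ndarray:
        """Voxel-wise D(x); zero outside the brain (enforces no-flux)."""
        D = np.zeros(self.shape, dtype=float)
        D[self.labels == WHITE] = params.D_white
        D[self.labels == GRAY] = params.D_gray
        return D


@dataclass(frozen=True)
class DensityField:
    """Normalized cell density fraction on a grid, zero outside the brain."""

    values: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != values.ndim:
            raise ValueError("spacing must give one value per grid axis")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("density values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def stable_dt(tissue: TissueMap, params: PIParams) -> float:
    """Largest explicit step allowed: h^2 / (2 * ndim * max(D))."""
    h = min(tissue.spacing)
    return h**2 / (2.0 * tissue.labels.ndim * max(params.D_white, params.D_gray))


def _harmonic_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(a)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def _diffusion_rate(c: np.ndarray, D: np.ndarray, spacing: tuple[float, ...]) -> np.ndarray:
    """div(D grad c) with harmonic-mean interface D and no-flux boundaries.

    Interfaces touching a voxel with D = 0 (non-brain, or the array edge)
    carry zero flux, so total mass is conserved when rho = 0.
    """
    rate = np.zeros_like(c)
    for ax in range(c.ndim):
        h2 = spacing[ax] ** 2
        lo = [slice(None)] * c.ndim
        hi = [slice(None)] * c.ndim
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        D_face = _harmonic_mean(D[lo], D[hi])
        flux = D_face * (c[hi] - c[lo]) / h2  # flux across each interior face
        rate[lo] += flux
        rate[hi] -= flux
    return rate


def step_pi(field: DensityField, tissue: TissueMap, params: PIParams, dt: float) -> DensityField:
    """One explicit forward-Euler update of the PI equation.

    Raises :class:`StabilityError` if ``dt`` exceeds the diffusion CFL
    bound, and ``ValueError`` on a grid mismatch.  The result is clipped to
    ``[0, K]`` and forced to zero on non-brain voxels.
    """
    if field.shape != tissue.shape:
        raise ValueError(f"field shape {field.shape} does not match tissue {tissue.shape}")
    bound = stable_dt(tissue, params)
    if dt > bound * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt:g} exceeds the explicit stability bound h^2/(2*ndim*max(D))={bound:g}"
        )
    c = field.values
    D = tissue.diffusivity(params)
    growth = params.rho * c * (1.0 - c / params.K)
    c_new = c + dt * (_diffusion_rate(c, D, field.spacing) + growth)
    np.clip(c_new, 0.0, params.K, out=c_new)
    c_new[~tissue.brain_mask] = 0.0
    return DensityField(c_new, field.spacing)


def gaussian_bolus(
    tissue: TissueMap, seed_location: tuple[int, ...], peak: float = 0.8, sigma_voxels: float = 1.0
) -> DensityField:
    """Initial condition: a small Gaussian density bolus at the seed voxel.

    A finite-width bolus avoids the grid artifact of a single-voxel delta.
    """
    seed = tuple(int(i) for i in seed_location)
    if len(seed) != tissue.labels.ndim:
        raise ValueError("seed coordinate dimensionality does not match the grid")
    if any(i < 0 or i >= n for i, n in zip(seed, tissue.shape)):
        raise ValueError(f"seed {seed} lies outside the grid {tissue.shape}")
    if tissue.labels[seed] == NONBRAIN:
        raise ValueError(f"seed voxel {seed} is outside brain tissue")
    grids = np.ogrid[tuple(slice(0, n) for n in tissue.shape)]
    d2 = sum((g - i) ** 2 for g, i in zip(grids, seed))
    values = peak * np.exp(-d2 / (2.0 * sigma_voxels**2))
    values[~tissue.brain_mask] = 0.0
    return DensityField(values, tissue.spacing)


def simulate_pi(
    tissue: TissueMap,
    params: PIParams,
    seed_location: tuple[int, ...],
    t_end: float,
    dt: float | None = None,
    bolus_sigma_voxels: float = 1.0,
) -> DensityField:
    """Grow a tumor from a Gaussian bolus at ``seed_location`` until ``t_end``.

    ``dt`` defaults to 90% of the explicit stability bound.  The bolus width
    is given in voxels (keep the physical width fixed across resolutions for
    convergence studies).  The run is deterministic: identical inputs yield
    bitwise-identical fields.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if dt is None:
        dt = 0.9 * stable_dt(tissue, params)
    field = gaussian_bolus(tissue, seed_location, sigma_voxels=bolus_sigma_voxels)
    if t_end == 0:
        return field
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps  # land exactly on t_end
    for _ in range(n_steps):
        field = step_pi(field, tissue, params, dt)
    return field


# ---------------------------------------------------------------------------
# Traveling-wave calibration
# ---------------------------------------------------------------------------

def _kpp_front_profile(n_points: int = 4000, xi_max: float = 60.0):
    """Minimal-speed Fisher-KPP front in nondimensional units (D = rho = 1).

    Integrates U'' + 2 U' + U(1 - U) = 0 from the saddle at U = 1 along its
    unstable manifold; the profile decays monotonically to 0 ahead of the
    front.  Returns (xi, U) with U decreasing in xi.
    """
    lam = np.sqrt(2.0) - 1.0  # unstable eigenvalue at (U, U') = (1, 0)
    eps = 1e-6
    y0 = [1.0 - eps, -eps * lam]

    def rhs(_, y):
        u, v = y
        return [v, -2.0 * v - u * (1.0 - u)]

    xi = np.linspace(0.0, xi_max, n_points)
    sol = solve_ivp(rhs, (0.0, xi_max), y0, t_eval=xi, rtol=1e-10, atol=1e-12)
    return sol.t, np.clip(sol.y[0], 0.0, 1.0)


def _profile_crossing(xi: np.ndarray, U: np.ndarray, level: float) -> float:
    """Position where the monotone front profile crosses ``level``."""
    idx = np.nonzero(U <= level)[0]
    if idx.size == 0:
        raise ValueError(f"profile never decays to level {level}")
    i = idx[0]
    if i == 0:
        return xi[0]
    # linear interpolation between bracketing points
    x0, x1, u0, u1 = xi[i - 1], xi[i], U[i - 1], U[i]
    return x0 + (u0 - level) * (x1 - x0) / (u0 - u1)


def kpp_threshold_separation(c_hi: float, c_lo: float) -> float:
    """Dimensionless distance between two density crossings of the KPP front."""
    xi, U = _kpp_front_profile()
    return _profile_crossing(xi, U, c_lo) - _profile_crossing(xi, U, c_hi)


def calibrate_from_radii(
    r_t1gd: float,
    r_t2: float,
    velocity: float,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> PIParams:
    """Recover ``(D, rho)`` from the two abnormality radii and a front speed.

    The traveling-wave front of the homogeneous Fisher-KPP equation moves at
    ``2 * sqrt(D * rho)`` and has a profile whose spatial scale is
    ``sqrt(D / rho)``.  The physical width of the "invisible rim" between the
    T1Gd and T2W density thresholds therefore pins ``sqrt(D / rho)``, while
    the supplied velocity pins ``sqrt(D * rho)``; together they determine
    both rates.  This is a traveling-wave realization of radius-based
    calibration, not a bit-level reproduction of any particular clinical
    pipeline.

    Parameters
    ----------
    r_t1gd, r_t2 : float
        Abnormality radii (mm) at the high and low density thresholds;
        ``r_t2 > r_t1gd`` is required.
    velocity : float
        Radial front expansion speed in mm/year.
    thresholds : (float, float)
        Density fractions ``(c_t1gd, c_t2)`` with ``0 < c_t2 < c_t1gd < 1``.
    """
    c_hi, c_lo = thresholds
    if not (0.0 < c_lo < c_hi < 1.0):
        raise ValueError("thresholds must satisfy 0 < c_t2 < c_t1gd < 1")
    if r_t1gd <= 0:
        raise ValueError("r_t1gd must be positive")
    if r_t2 <= r_t1gd:
        raise ValueError("invisible rim has non-positive width (r_t2 <= r_t1gd)")
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    width = r_t2 - r_t1gd
    xi_sep = kpp_threshold_separation(c_hi, c_lo)
    length_scale = width / xi_sep        # sqrt(D / rho), mm
    rate_scale = velocity / 2.0          # sqrt(D * rho), mm/year
    D = length_scale * rate_scale
    rho = rate_scale / length_scale
    return PIParams(D_white=D, D_gray=D / 10.0, rho=rho)


def front_radius(field: DensityField, center: tuple[int, ...], level: float) -> float:
    """Radial distance (mm) from ``center`` at which density crosses ``level``.

    Uses the profile along the positive first-axis ray from the center,
    linearly interpolated; intended for homogeneous-tissue simulations.
    """
    idx = tuple(int(i) for i in center)
    profile = field.values[(slice(idx[0], None),) + idx[1:]]
    h = field.spacing[0]
    below = np.nonzero(profile <= level)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError(f"no crossing of level {level} along the sampling ray")
    i = below[0]
    u0, u1 = profile[i - 1], profile[i]
    return h * ((i - 1) + (u0 - level) / (u0 - u1))
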