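"""Graph-based semi-supervised kernel regression with mechanistic regularization.

The hybrid model predicts tumor cell density ``f(x)`` from the feature
vector ``x = (z, PI)`` by minimizing

    (1/L) * sum_l (y_l - f(x_l))^2  +  gamma_A * ||f||_K^2
        +  (gamma_I / sum_ij w_ij) * f^T Omega f

over a reproducing kernel Hilbert space with RBF kernel
``K(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 eta^2))``.  The first term fits
the L labeled (biopsied) samples, the second is the usual kernel smoother,
and the third pulls predictions to vary smoothly over a similarity graph
spanning all L + U samples — through which both unbiopsied image regions
and the mechanistic PI prediction enter the fit.

Edge weights factor into an image-feature Gaussian and a PI Gaussian:

    w_ij = exp(-||z_i - z_j||^2 / (2 psi_z^2)) * exp(-(PI_i - PI_j)^2 / (2 psi_PI^2))

and ``Omega = diag(W 1) - W`` is the graph Laplacian.

By the representer property the minimizer is a kernel expansion over all
training samples, ``f*(x) = sum_i alpha_i K(x_i, x)``, whose coefficients
solve the linear system assembled in :func:`fit_mlpi`.  With ``gamma_I = 0``
and no unlabeled samples this reduces exactly to kernel ridge regression
(the supervised "ML-only" baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

from .features import Sample, feature_matrix
from .pi_model import DensityField

logger = logging.getLogger(__name__)

_JITTER = 1e-10


@dataclass(frozen=True)
class GraphSpec:
    """Sample-similarity graph: weights, Laplacian, and their bandwidths."""

    W: np.ndarray
    Omega: np.ndarray
    psi_z: float
    psi_pi: float

    @property
    def weight_sum(self) -> float:
        return float(self.W.sum())


@dataclass(frozen=True)
class MlpiModel:
    """Trained representer model: f*(x) = sum_i alpha_i K(x_i, x)."""

    alpha: np.ndarray
    eta: float
    X_train: np.ndarray
    gamma_a: float
    gamma_i: float


def median_bandwidths(samples: list[Sample]) -> tuple[float, float]:
    """Median-heuristic bandwidths (psi_z, psi_PI) over the training graph.

    The median pairwise distance keeps a non-degenerate spread of weights
    regardless of feature scaling; a zero median falls back to 1.
    """
    Z = np.asarray([s.z for s in samples], dtype=float)
    pi = np.asarray([s.pi for s in samples], dtype=float)
    psi_z = float(np.median(pdist(Z))) if len(samples) > 1 else 1.0
    psi_pi = float(np.median(pdist(pi[:, None]))) if len(samples) > 1 else 1.0
    return (psi_z if psi_z > 0 else 1.0, psi_pi if psi_pi > 0 else 1.0)


def edge_weights(samples: list[Sample], psi_z: float | None = None, psi_pi: float | None = None) -> GraphSpec:
    """Dense graph over the samples with product-Gaussian edge weights."""
    if len(samples) < 2:
        raise ValueError("graph needs at least two samples")
    if psi_z is None or psi_pi is None:
        med_z, med_pi = median_bandwidths(samples)
        psi_z = med_z if psi_z is None else psi_z
        psi_pi = med_pi if psi_pi is None else psi_pi
    if psi_z <= 0 or psi_pi <= 0:
        raise ValueError("bandwidths must be strictly positive")
    Z = np.asarray([s.z for s in samples], dtype=float)
    pi = np.asarray([s.pi for s in samples], dtype=float)
    dz2 = squareform(pdist(Z, "sqeuclidean"))
    dpi2 = (pi[:, None] - pi[None, :]) ** 2
    W = np.exp(-dz2 / (2.0 * psi_z**2)) * np.exp(-dpi2 / (2.0 * psi_pi**2))
    Omega = np.diag(W.sum(axis=1)) - W
    return GraphSpec(W=W, Omega=Omega, psi_z=float(psi_z), psi_pi=float(psi_pi))


def laplacian_quadratic(Omega: np.ndarray, f: np.ndarray) -> float:
    """f^T Omega f, the graph smoothness penalty (= 1/2 sum w_ij (f_i-f_j)^2)."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != Omega.shape[0]:
        raise ValueError("vector length does not match the Laplacian")
    return float(f @ Omega @ f)


def rbf_gram(X: np.ndarray, Y: np.ndarray, eta: float) -> np.ndarray:
    """RBF kernel matrix K(x_i, y_j) = exp(-||x_i - y_j||^2 / (2 eta^2))."""
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * eta**2))


def fit_mlpi(
    labeled: list[Sample],
    unlabeled: list[Sample],
    gamma_a: float,
    gamma_i: float,
    eta: float,
    graph: GraphSpec | None = None,
) -> MlpiModel:
    """Closed-form fit of the hybrid objective.

    Substituting the representer expansion ``f = K_g alpha`` into the
    objective and setting the gradient to zero yields

        (J K_g + gamma_A L I + (gamma_I L / sum_ij w_ij) Omega K_g) alpha = J y

    where ``K_g`` is the (L+U)x(L+U) Gram matrix on ``x = (z, PI)``,
    ``J = diag(1 labeled, 0 unlabeled)`` masks the loss to labeled samples
    (unlabeled entries of ``y`` are zeros and contribute nothing), and the
    graph term is normalized by the total edge weight.  A near-singular
    system (e.g. at the smallest ridge grid corner) is retried with a tiny
    diagonal jitter.
    """
    L, U = len(labeled), len(unlabeled)
    if L < 1:
        raise ValueError("at least one labeled sample is required")
    if gamma_a < 0 or gamma_i < 0 or eta <= 0:
        raise ValueError("require gamma_a >= 0, gamma_i >= 0, eta > 0")
    samples = list(labeled) + list(unlabeled)
    X = feature_matrix(samples)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite value in training features")
    y = np.zeros(L + U)
    y[:L] = [s.y for s in labeled]
    j_diag = np.zeros(L + U)
    j_diag[:L] = 1.0

    K = rbf_gram(X, X, eta)
    A = j_diag[:, None] * K + gamma_a * L * np.eye(L + U)
    if gamma_i > 0:
        if U > 0 and graph is None:
            graph = edge_weights(samples)
        if graph is not None:
            if graph.Omega.shape[0] != L + U:
                raise ValueError("graph size does not match L + U samples")
            A = A + (gamma_i * L / graph.weight_sum) * (graph.Omega @ K)
    b = j_diag * y
    alpha = _solve_with_jitter(A, b)
    return MlpiModel(alpha=alpha, eta=float(eta), X_train=X, gamma_a=float(gamma_a), gamma_i=float(gamma_i))


def _solve_with_jitter(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        alpha = linalg.solve(A, b)
        if np.all(np.isfinite(alpha)):
            return alpha
    except linalg.LinAlgError:
        pass
    logger.info("near-singular system; retrying with diagonal jitter %g", _JITTER)
    return linalg.solve(A + _JITTER * np.eye(A.shape[0]), b)


def objective_value(
    alpha: np.ndarray,
    K: np.ndarray,
    y: np.ndarray,
    j_diag: np.ndarray,
    gamma_a: float,
    gamma_i: float,
    Omega: np.ndarray | None,
    weight_sum: float,
) -> float:
    """Evaluate the hybrid objective at coefficients ``alpha``.

    Exposed so the closed-form solution can be checked against a direct
    numerical minimizer over alpha.
    """
    f = K @ alpha
    L = int(j_diag.sum())
    loss = float(np.sum(j_diag * (y - f) ** 2)) / L
    norm = float(alpha @ K @ alpha)  # ||f||_K^2 in the representer expansion
    val = loss + gamma_a * norm
    if gamma_i > 0 and Omega is not None:
        val += (gamma_i / weight_sum) * float(f @ Omega @ f)
    return val


def predict(model: MlpiModel, x_new: np.ndarray, clip: bool = True) -> np.ndarray:
    """Evaluate f*(x) = sum_i alpha_i K(x_i, x); clipped to [0, 1] by default.

    Density is a fraction, but the kernel expansion is unbounded — map and
    metric consumers see the clipped value, raw values are available with
    ``clip=False``.
    """
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature dimension {x_new.shape[1]} does not match training {model.X_train.shape[1]}"
        )
    f = rbf_gram(x_new, model.X_train, model.eta) @ model.alpha
    return np.clip(f, 0.0, 1.0) if clip else f


def predict_samples(model: MlpiModel, samples: list[Sample], clip: bool = True) -> np.ndarray:
    return predict(model, feature_matrix(samples), clip=clip)


def predict_density_map(
    model: MlpiModel,
    channels: list[np.ndarray],
    pi_map,
    roi_mask: np.ndarray,
    slice_index: int | None = None,
    box_edge: int = 8,
) -> DensityField:
    """Predicted density over every ROI voxel; zero outside the ROI."""
    from .features import build_unlabeled_samples

    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    samples = build_unlabeled_samples(
        channels, pi_map, roi_mask, patient_id="__map__",
        slice_index=slice_index, stride=1, box_edge=box_edge,
    )
    values = np.zeros(roi_mask.shape)
    preds = predict_samples(model, samples)
    for s, p in zip(samples, preds):
        values[s.location] = p
    spacing = getattr(pi_map, "spacing", None) or (1.0,) * roi_mask.ndim
    return DensityField(values, spacing)
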