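"""Relief-style feature contribution scoring for the hybrid model.

After training, each feature ``x`` (one per image channel, plus the PI
density) receives a score

    s(x) = P(x_i, x_ir differ | predictions differ)
         - P(x_i, x_ir differ | predictions similar)

over pairs formed by each sample ``i`` and its ``r`` nearest neighbors on
the sample graph (largest edge weight).  A feature that separates pairs
the model treats differently — and not pairs it treats alike — earns a
high score.

The probabilities are estimated RReliefF-style: each neighbor pair
contributes its normalized absolute feature difference
``|x_i - x_ir| / range(x)`` to the conditional frequency of whichever
class (prediction-different vs prediction-similar, split at threshold
``tau``) the pair falls in.  Scores therefore live in [-1, 1].

Per-patient scores are floored at zero, normalized to sum to one, and
summed across patients into the aggregated contribution profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import Sample, feature_matrix
from .ssl_core import GraphSpec, MlpiModel, edge_weights, predict_samples

logger = logging.getLogger(__name__)


@dataclass
class ReliefScores:
    """Raw (and optionally normalized/aggregated) per-feature scores."""

    raw: np.ndarray
    feature_names: list[str]
    r: int
    tau: float
    normalized: np.ndarray | None = None
    n_patients: int = 1

    def as_dict(self) -> dict[str, float]:
        vals = self.normalized if self.normalized is not None else self.raw
        return dict(zip(self.feature_names, (float(v) for v in vals)))


def default_feature_names(n_channels: int) -> list[str]:
    return [f"channel_{i}" for i in range(n_channels)] + ["PI"]


def relief_scores(
    model: MlpiModel,
    samples: list[Sample],
    graph: GraphSpec | None = None,
    r: int = 10,
    tau: float = 0.05,
    feature_names: list[str] | None = None,
) -> ReliefScores:
    """Raw Relief scores for one patient's sample set.

    ``r`` neighbors per sample are taken by decreasing graph edge weight;
    ``tau`` (on the density-fraction scale, default the 5% margin) splits
    pairs into prediction-different vs prediction-similar.  If either class
    is empty its conditional is reported as zero with a warning.
    """
    n = len(samples)
    if r >= n:
        raise ValueError(f"r={r} must be smaller than the number of samples ({n})")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if graph is None:
        graph = edge_weights(samples)
    X = feature_matrix(samples)
    yhat = predict_samples(model, samples)
    rng_x = X.max(axis=0) - X.min(axis=0)
    rng_x[rng_x == 0] = 1.0  # constant feature -> zero differences anyway

    W = graph.W.copy()
    np.fill_diagonal(W, -np.inf)
    nbr = np.argsort(-W, axis=1)[:, :r]

    i_idx = np.repeat(np.arange(n), r)
    j_idx = nbr.ravel()
    dy = np.abs(yhat[i_idx] - yhat[j_idx])
    diff_x = np.abs(X[i_idx] - X[j_idx]) / rng_x  # (pairs, features), each in [0, 1]
    different = dy > tau

    d = X.shape[1]
    scores = np.zeros(d)
    if different.any():
        p_diff = diff_x[different].mean(axis=0)
    else:
        logger.warning("no prediction-different neighbor pairs; conditional set to 0")
        p_diff = np.zeros(d)
    if (~different).any():
        p_sim = diff_x[~different].mean(axis=0)
    else:
        logger.warning("no prediction-similar neighbor pairs; conditional set to 0")
        p_sim = np.zeros(d)
    scores = p_diff - p_sim
    names = feature_names or default_feature_names(d - 1)
    return ReliefScores(raw=scores, feature_names=list(names), r=r, tau=tau)


def normalize_and_aggregate(per_patient: list[ReliefScores]) -> ReliefScores:
    """Floor at zero, normalize each patient's scores to sum to 1, then sum.

    Reported contributions are non-negative shares; negative raw scores
    (a feature separating similar pairs better than different ones) carry
    no contribution.  Patients whose scores are all zero are skipped.
    """
    if not per_patient:
        raise ValueError("need at least one patient's scores")
    names = per_patient[0].feature_names
    agg = np.zeros(len(names))
    used = 0
    for sc in per_patient:
        if sc.feature_names != names:
            raise ValueError("feature name mismatch across patients")
        floored = np.maximum(sc.raw, 0.0)
        total = floored.sum()
        if total == 0:
            logger.warning("all-zero score vector; patient skipped in aggregation")
            continue
        normalized = floored / total
        sc.normalized = normalized
        agg += normalized
        used += 1
    if used == 0:
        raise ValueError("every patient had an all-zero score vector")
    return ReliefScores(
        raw=agg, feature_names=names, r=per_patient[0].r, tau=per_patient[0].tau,
        normalized=agg, n_patients=used,
    )


def relief_for_cohort(
    cohort,
    tuning,
    r: int = 10,
    tau: float = 0.05,
    feature_names: list[str] | None = None,
    max_unlabeled_per_patient: int | None = 25,
) -> tuple[ReliefScores, dict[str, ReliefScores]]:
    """Aggregated contributions over a cohort's deployed per-patient models.

    For each patient, the deployed model is refit at that patient's
    selected tuning parameters under the leave-one-patient-out protocol
    (other patients' labeled samples in the loss; the unlabeled pool in the
    graph), and Relief is run over the patient's own labeled + unlabeled
    samples.  Returns the aggregated scores and the per-patient raw scores.
    """
    from .evaluation import _subsample_evenly
    from .ssl_core import fit_mlpi

    per_patient: dict[str, ReliefScores] = {}
    for target in cohort.patient_ids:
        if target not in tuning.selected:
            continue
        gamma_a, gamma_i, eta = tuning.selected[target]
        labeled = [
            s for pid in cohort.patient_ids if pid != target for s in cohort.training_labeled(pid)
        ]
        unlabeled = []
        for pid in cohort.patient_ids:
            pool = cohort.unlabeled(pid)
            if max_unlabeled_per_patient is not None:
                pool = _subsample_evenly(pool, max_unlabeled_per_patient)
            unlabeled.extend(pool)
        model = fit_mlpi(labeled, unlabeled, gamma_a, gamma_i, eta)
        own = cohort.real_labeled(target) + cohort.unlabeled(target)
        r_eff = min(r, len(own) - 1)
        if r_eff < 1:
            logger.warning("patient %s has too few samples for Relief; skipped", target)
            continue
        per_patient[target] = relief_scores(
            model, own, r=r_eff, tau=tau, feature_names=feature_names
        )
    agg = normalize_and_aggregate(list(per_patient.values()))
    return agg, per_patient
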