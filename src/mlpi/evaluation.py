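"""Margin-tolerant metrics, tuning strategies, and the model comparison.

Validation follows a leave-one-patient-out (LOPO) protocol: when scoring a
target patient, no real or synthetic biopsy of that patient enters the
supervised loss term.  The target patient's *unlabeled* samples may still
participate in the smoothness graph (the transductive use of unlabeled
data is the method's point); this is configurable.

Both accuracy metrics tolerate a +/-5% margin reflecting the uncertainty of
the pathological density estimate: a prediction within the margin of the
measured value counts as exactly correct.

Three strategies select the tuning triple (gamma_A, gamma_I, eta) on a
log-spaced grid:

* patient-specific — an independent triple per patient, minimizing that
  patient's own margin-MAPE on real biopsies;
* uniform — one global triple minimizing the pooled margin-MAPE;
* partially-uniform — two parameters global, the third free per patient.

Because every strategy is an argmin over the same per-patient prediction
tensors, the grid is evaluated once and the strategies reduce it.  Ties
are broken toward the least complex model: smallest gamma_I, then smallest
gamma_A, then smallest eta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import Sample
from .ssl_core import edge_weights, rbf_gram, _solve_with_jitter

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 0.05


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def margined_errors(y_true: np.ndarray, y_pred: np.ndarray, margin: float = DEFAULT_MARGIN) -> np.ndarray:
    """Per-sample absolute error, zeroed when within the margin."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValueError("empty input")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    e = np.abs(y_true - y_pred)
    e[e <= margin] = 0.0
    return e


def mape_margin(y_true, y_pred, margin: float = DEFAULT_MARGIN) -> tuple[float, float]:
    """Mean absolute prediction error with margin tolerance; returns (mean, SD)."""
    e = margined_errors(y_true, y_pred, margin)
    return float(e.mean()), float(e.std(ddof=1)) if e.size > 1 else 0.0


def pearson_margin(y_true, y_pred, margin: float = DEFAULT_MARGIN) -> float:
    """Pearson correlation after snapping within-margin predictions to truth.

    The margin rule says an in-margin prediction is exactly correct; the
    minimal correlation analogue replaces such predictions by the measured
    value before correlating.  Zero variance after snapping is undefined
    and reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float).copy()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    snap = np.abs(y_true - y_pred) <= margin
    y_pred[snap] = y_true[snap]
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        logger.warning("zero variance after margin snapping; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(y_true, y_pred).statistic)


# ---------------------------------------------------------------------------
# Cohort container and tuning grid
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """All samples of a multi-patient dataset, keyed by patient."""

    samples_by_patient: dict[str, list[Sample]]

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.samples_by_patient)

    def real_labeled(self, pid: str) -> list[Sample]:
        return [s for s in self.samples_by_patient[pid] if s.is_labeled and not s.is_synthetic]

    def training_labeled(self, pid: str) -> list[Sample]:
        """Labeled samples usable when training (real + synthetic)."""
        return [s for s in self.samples_by_patient[pid] if s.is_labeled]

    def unlabeled(self, pid: str) -> list[Sample]:
        return [s for s in self.samples_by_patient[pid] if not s.is_labeled]


def _log_grid(lo_exp: int, hi_exp: int) -> tuple[float, ...]:
    return tuple(10.0**e for e in range(lo_exp, hi_exp + 1))


@dataclass(frozen=True)
class TuningGrid:
    """Log-spaced search grid; defaults span the method's stated ranges."""

    gamma_a_values: tuple[float, ...] = field(default_factory=lambda: _log_grid(-10, 4))
    gamma_i_values: tuple[float, ...] = field(default_factory=lambda: _log_grid(-10, 4))
    eta_values: tuple[float, ...] = field(default_factory=lambda: _log_grid(-1, 2))

    def __post_init__(self) -> None:
        for name in ("gamma_a_values", "gamma_i_values", "eta_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} is empty")
            if any(v < 0 for v in vals) or any(v <= 0 for v in vals if name == "eta_values"):
                raise ValueError(f"{name} must be positive (gamma_I may include 0 for the ML baseline)")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, vals)

    @classmethod
    def coarse(cls) -> "TuningGrid":
        """Every-third-decade subgrid; used for phantom-scale studies."""
        return cls(
            gamma_a_values=tuple(10.0**e for e in range(-10, 5, 3)),
            gamma_i_values=tuple(10.0**e for e in range(-10, 5, 3)),
            eta_values=(0.1, 1.0, 10.0, 100.0),
        )


@dataclass
class TuningResult:
    """Selected tuning parameters and the metrics they achieve."""

    strategy: str
    selected: dict[str, tuple[float, float, float]]  # pid -> (gamma_a, gamma_i, eta)
    per_patient_mape: dict[str, float]
    per_patient_pearson: dict[str, float]
    pooled_mape: float
    pooled_mape_sd: float
    pooled_pearson: float
    margin: float
    subset: str = "all"


# ---------------------------------------------------------------------------
# Grid evaluation (LOPO prediction tensors)
# ---------------------------------------------------------------------------

@dataclass
class GridEvaluation:
    """LOPO predictions of every grid point for every patient's real biopsies.

    ``preds[pid]`` has shape ``(n_gamma_i, n_gamma_a, n_eta, n_biopsies)``;
    the axis order matches the tie-break preference so that a
    first-occurrence argmin over the flattened grid breaks ties toward the
    least complex model.
    """

    grid: TuningGrid
    preds: dict[str, np.ndarray]
    y_true: dict[str, np.ndarray]
    is_bat: dict[str, np.ndarray]

    def params_at(self, idx: tuple[int, int, int]) -> tuple[float, float, float]:
        i_gi, i_ga, i_eta = idx
        return (
            self.grid.gamma_a_values[i_ga],
            self.grid.gamma_i_values[i_gi],
            self.grid.eta_values[i_eta],
        )


def _subsample_evenly(items: list, k: int) -> list:
    if len(items) <= k:
        return list(items)
    idx = np.linspace(0, len(items) - 1, k).round().astype(int)
    return [items[i] for i in sorted(set(idx.tolist()))]


def evaluate_grid(
    cohort: Cohort,
    grid: TuningGrid,
    *,
    include_unlabeled: bool = True,
    include_target_unlabeled: bool = True,
    max_unlabeled_per_patient: int | None = 25,
) -> GridEvaluation:
    """Fit every grid point under LOPO and record test predictions.

    For each target patient the supervised term uses only the other
    patients' labeled samples (real and synthetic); the graph spans those
    plus the unlabeled pool.  The expensive pieces (graph, Gram per eta)
    are shared across the gamma sweep.
    """
    gas, gis, etas = grid.gamma_a_values, grid.gamma_i_values, grid.eta_values
    preds: dict[str, np.ndarray] = {}
    y_true: dict[str, np.ndarray] = {}
    is_bat: dict[str, np.ndarray] = {}
    for target in cohort.patient_ids:
        test = cohort.real_labeled(target)
        if not test:
            logger.warning("patient %s has no real biopsies; excluded from scoring", target)
            continue
        labeled = [s for pid in cohort.patient_ids if pid != target for s in cohort.training_labeled(pid)]
        unlabeled: list[Sample] = []
        if include_unlabeled:
            for pid in cohort.patient_ids:
                if pid == target and not include_target_unlabeled:
                    continue
                pool = cohort.unlabeled(pid)
                if max_unlabeled_per_patient is not None:
                    pool = _subsample_evenly(pool, max_unlabeled_per_patient)
                unlabeled.extend(pool)
        train = labeled + unlabeled
        L, U = len(labeled), len(unlabeled)
        X = np.asarray([s.x for s in train])
        X_test = np.asarray([s.x for s in test])
        y = np.zeros(L + U)
        y[:L] = [s.y for s in labeled]
        j_diag = np.zeros(L + U)
        j_diag[:L] = 1.0
        b = j_diag * y

        need_graph = any(g > 0 for g in gis) and len(train) >= 2
        graph = edge_weights(train) if need_graph else None

        out = np.empty((len(gis), len(gas), len(etas), len(test)))
        eye = np.eye(L + U)
        for i_eta, eta in enumerate(etas):
            K = rbf_gram(X, X, eta)
            K_test = rbf_gram(X_test, X, eta)
            JK = j_diag[:, None] * K
            OK = (graph.Omega @ K) if graph is not None else None
            for i_gi, gi in enumerate(gis):
                base = JK if (gi == 0 or OK is None) else JK + (gi * L / graph.weight_sum) * OK
                for i_ga, ga in enumerate(gas):
                    alpha = _solve_with_jitter(base + ga * L * eye, b)
                    out[i_gi, i_ga, i_eta] = np.clip(K_test @ alpha, 0.0, 1.0)
        preds[target] = out
        y_true[target] = np.asarray([s.y for s in test])
        is_bat[target] = np.asarray([s.is_bat for s in test])
    return GridEvaluation(grid=grid, preds=preds, y_true=y_true, is_bat=is_bat)


def _error_tensor(ev: GridEvaluation, margin: float) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Per-patient sum of margined errors at every grid point, plus counts."""
    sums, counts = {}, {}
    for pid, p in ev.preds.items():
        e = np.abs(p - ev.y_true[pid][None, None, None, :])
        e[e <= margin] = 0.0
        sums[pid] = e.sum(axis=-1)
        counts[pid] = ev.y_true[pid].size
    return sums, counts


def _argmin_first(arr: np.ndarray) -> tuple[int, int, int]:
    """First-occurrence argmin in (gamma_i, gamma_a, eta) C-order = tie-break."""
    return tuple(int(i) for i in np.unravel_index(np.argmin(arr), arr.shape))


def _finalize(ev: GridEvaluation, selected_idx: dict[str, tuple[int, int, int]], strategy: str, margin: float) -> TuningResult:
    selected, mapes, pearsons = {}, {}, {}
    all_y, all_p = [], []
    for pid, idx in selected_idx.items():
        selected[pid] = ev.params_at(idx)
        p = ev.preds[pid][idx]
        y = ev.y_true[pid]
        mapes[pid] = mape_margin(y, p, margin)[0]
        pearsons[pid] = pearson_margin(y, p, margin) if y.size >= 3 else float("nan")
        all_y.append(y)
        all_p.append(p)
    y_cat, p_cat = np.concatenate(all_y), np.concatenate(all_p)
    pooled, sd = mape_margin(y_cat, p_cat, margin)
    return TuningResult(
        strategy=strategy,
        selected=selected,
        per_patient_mape=mapes,
        per_patient_pearson=pearsons,
        pooled_mape=pooled,
        pooled_mape_sd=sd,
        pooled_pearson=pearson_margin(y_cat, p_cat, margin),
        margin=margin,
    )


def select_patient_specific(ev: GridEvaluation, margin: float = DEFAULT_MARGIN) -> TuningResult:
    sums, _ = _error_tensor(ev, margin)
    idx = {pid: _argmin_first(sums[pid]) for pid in sums}
    return _finalize(ev, idx, "patient_specific", margin)


def select_uniform(ev: GridEvaluation, margin: float = DEFAULT_MARGIN) -> TuningResult:
    sums, counts = _error_tensor(ev, margin)
    pooled = sum(sums.values()) / sum(counts.values())
    best = _argmin_first(pooled)
    return _finalize(ev, {pid: best for pid in sums}, "uniform", margin)


_FREE_AXIS = {"gamma_i": 0, "gamma_a": 1, "eta": 2}


def select_partial_uniform(ev: GridEvaluation, free_param: str, margin: float = DEFAULT_MARGIN) -> TuningResult:
    """Two parameters global, ``free_param`` chosen per patient."""
    if free_param not in _FREE_AXIS:
        raise ValueError(f"free_param must be one of {sorted(_FREE_AXIS)}")
    ax = _FREE_AXIS[free_param]
    sums, counts = _error_tensor(ev, margin)
    n_total = sum(counts.values())
    pids = list(sums)
    # per patient, best free index for every global combination (first-occurrence
    # argmin along the free axis breaks ties toward the smaller value)
    free_choice = {pid: np.argmin(np.moveaxis(sums[pid], ax, -1), axis=-1) for pid in pids}
    pooled = sum(
        np.take_along_axis(np.moveaxis(sums[pid], ax, -1), free_choice[pid][..., None], axis=-1)[..., 0]
        for pid in pids
    ) / n_total
    g = tuple(int(i) for i in np.unravel_index(np.argmin(pooled), pooled.shape))
    idx = {}
    for pid in pids:
        full = list(g)
        full.insert(ax, int(free_choice[pid][g]))
        idx[pid] = tuple(full)
    res = _finalize(ev, idx, f"partial_uniform({free_param})", margin)
    return res


def tune_patient_specific(cohort: Cohort, grid: TuningGrid | None = None, margin: float = DEFAULT_MARGIN, **kw) -> TuningResult:
    return select_patient_specific(evaluate_grid(cohort, grid or TuningGrid(), **kw), margin)


def tune_uniform(cohort: Cohort, grid: TuningGrid | None = None, margin: float = DEFAULT_MARGIN, **kw) -> TuningResult:
    return select_uniform(evaluate_grid(cohort, grid or TuningGrid(), **kw), margin)


def tune_partial_uniform(cohort: Cohort, free_param: str, grid: TuningGrid | None = None, margin: float = DEFAULT_MARGIN, **kw) -> TuningResult:
    return select_partial_uniform(evaluate_grid(cohort, grid or TuningGrid(), **kw), free_param, margin)


# ---------------------------------------------------------------------------
# Three-way model comparison
# ---------------------------------------------------------------------------

def _pooled_rows(ev: GridEvaluation, result: TuningResult):
    y, p, bat = [], [], []
    for pid in ev.y_true:
        i_ga = ev.grid.gamma_a_values.index(result.selected[pid][0])
        i_gi = ev.grid.gamma_i_values.index(result.selected[pid][1])
        i_eta = ev.grid.eta_values.index(result.selected[pid][2])
        y.append(ev.y_true[pid])
        p.append(ev.preds[pid][(i_gi, i_ga, i_eta)])
        bat.append(ev.is_bat[pid])
    return np.concatenate(y), np.concatenate(p), np.concatenate(bat)


def _metric_cells(y, p, bat, margin):
    cells = {}
    for tag, mask in (("all", np.ones_like(bat, dtype=bool)), ("bat", bat)):
        if mask.sum() == 0:
            cells[f"mape_{tag}"] = cells[f"mape_sd_{tag}"] = cells[f"pearson_{tag}"] = float("nan")
            continue
        m, sd = mape_margin(y[mask], p[mask], margin)
        cells[f"mape_{tag}"] = m
        cells[f"mape_sd_{tag}"] = sd
        cells[f"pearson_{tag}"] = (
            pearson_margin(y[mask], p[mask], margin) if mask.sum() >= 3 else float("nan")
        )
    return cells


def compare_models(
    cohort: Cohort,
    grid: TuningGrid | None = None,
    strategy: str = "patient_specific",
    margin: float = DEFAULT_MARGIN,
    **grid_kw,
) -> pd.DataFrame:
    """MAPE/Pearson table for ML-PI, the supervised ML baseline, and PI alone.

    The ML row uses the same machinery with ``gamma_I = 0`` and no unlabeled
    samples; the PI row needs no fitting — its prediction is the PI box mean
    at each biopsy.  Significance of each baseline against ML-PI is a
    two-sided paired Wilcoxon signed-rank test on per-sample margined
    absolute errors (a documented choice of test).
    """
    grid = grid or TuningGrid()
    selector = {
        "patient_specific": select_patient_specific,
        "uniform": select_uniform,
    }[strategy]

    ev_hybrid = evaluate_grid(cohort, grid, **grid_kw)
    res_hybrid = selector(ev_hybrid, margin)
    y, p_hybrid, bat = _pooled_rows(ev_hybrid, res_hybrid)

    ml_grid = TuningGrid(gamma_a_values=grid.gamma_a_values, gamma_i_values=(0.0,), eta_values=grid.eta_values)
    ev_ml = evaluate_grid(cohort, ml_grid, include_unlabeled=False)
    res_ml = selector(ev_ml, margin)
    _, p_ml, _ = _pooled_rows(ev_ml, res_ml)

    p_pi = np.concatenate([
        [s.pi for s in cohort.real_labeled(pid)] for pid in ev_hybrid.y_true
    ])

    rows = {}
    e_hybrid = margined_errors(y, p_hybrid, margin)
    for name, pred in (("ML-PI", p_hybrid), ("ML", p_ml), ("PI", p_pi)):
        cells = _metric_cells(y, pred, bat, margin)
        if name != "ML-PI":
            e_other = margined_errors(y, pred, margin)
            diff = e_other - e_hybrid
            if np.allclose(diff, 0):
                cells["p_vs_mlpi"] = float("nan")
            else:
                cells["p_vs_mlpi"] = float(stats.wilcoxon(e_other, e_hybrid).pvalue)
        else:
            cells["p_vs_mlpi"] = float("nan")
        rows[name] = cells
    return pd.DataFrame(rows).T
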