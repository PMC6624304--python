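"""Margin metrics, tuning strategies, and the model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_samples
from mlpi.evaluation import (
    Cohort,
    TuningGrid,
    compare_models,
    evaluate_grid,
    mape_margin,
    pearson_margin,
    select_partial_uniform,
    select_patient_specific,
    select_uniform,
)


class TestMapeMargin:
    def test_exact_predictions_score_zero(self):
        y = np.array([0.1, 0.5, 0.9])
        assert mape_margin(y, y)[0] == 0.0

    def test_margin_zero_is_plain_mae(self, rng):
        y, p = rng.uniform(size=20), rng.uniform(size=20)
        mean, _ = mape_margin(y, p, margin=0.0)
        assert mean == pytest.approx(np.mean(np.abs(y - p)), abs=1e-12)

    def test_hand_example(self):
        """Errors (0.04, 0.20) with 5% margin become (0, 0.20): MAPE 0.10."""
        mean, _ = mape_margin([0.50, 0.20], [0.54, 0.40], margin=0.05)
        assert mean == pytest.approx(0.10, abs=1e-12)

    @given(st.integers(min_value=0, max_value=500))
    def test_non_increasing_in_margin(self, seed):
        rng = np.random.default_rng(seed)
        y, p = rng.uniform(size=10), rng.uniform(size=10)
        margins = [0.0, 0.02, 0.05, 0.1, 0.5]
        vals = [mape_margin(y, p, m)[0] for m in margins]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mape_margin([], [])


class TestPearsonMargin:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.8, 0.9])
        assert pearson_margin(y, y) == pytest.approx(1.0)

    def test_affine_invariance_outside_margin(self):
        y = np.linspace(0.1, 0.7, 6)
        p = y + 0.2  # affine increasing map, every deviation exceeds the margin
        assert np.all(np.abs(p - y) > 0.05)
        assert pearson_margin(y, p) == pytest.approx(1.0)

    def test_matches_textbook_formula_at_zero_margin(self, rng):
        y, p = rng.uniform(size=15), rng.uniform(size=15)
        expected = np.corrcoef(y, p)[0, 1]
        assert pearson_margin(y, p, margin=0.0) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert np.isnan(pearson_margin([0.5, 0.5, 0.5], [0.9, 0.9, 0.9]))


def tiny_cohort(seed=0, n_patients=4, n_labeled=5, n_unlabeled=8):
    rng = np.random.default_rng(seed)
    data = {}
    for i in range(n_patients):
        pid = f"p{i}"
        data[pid] = (
            make_samples(rng, n_labeled, labeled=True, patient_id=pid)
            + make_samples(rng, n_unlabeled, labeled=False, patient_id=pid)
        )
    return Cohort(data)


SMALL_GRID = TuningGrid(
    gamma_a_values=(1e-4, 1e-1), gamma_i_values=(1e-4, 1e-1), eta_values=(0.5, 2.0)
)


class TestTuningStrategies:
    def test_single_grid_point_always_selected(self):
        cohort = tiny_cohort()
        grid = TuningGrid(gamma_a_values=(0.1,), gamma_i_values=(0.01,), eta_values=(1.0,))
        res = select_patient_specific(evaluate_grid(cohort, grid))
        assert all(v == (0.1, 0.01, 1.0) for v in res.selected.values())

    def test_selection_reproducible(self):
        a = select_patient_specific(evaluate_grid(tiny_cohort(3), SMALL_GRID))
        b = select_patient_specific(evaluate_grid(tiny_cohort(3), SMALL_GRID))
        assert a.selected == b.selected
        assert a.pooled_mape == b.pooled_mape

    def test_patient_ordering_invariance(self):
        cohort = tiny_cohort(1)
        reversed_cohort = Cohort(dict(reversed(list(cohort.samples_by_patient.items()))))
        a = select_uniform(evaluate_grid(cohort, SMALL_GRID))
        b = select_uniform(evaluate_grid(reversed_cohort, SMALL_GRID))
        assert a.selected == b.selected

    def test_nesting_of_hypothesis_spaces(self):
        """Per-patient freedom can only reduce pooled error: patient-specific
        <= each partially-uniform <= uniform."""
        ev = evaluate_grid(tiny_cohort(2), SMALL_GRID)
        ps = select_patient_specific(ev).pooled_mape
        un = select_uniform(ev).pooled_mape
        for free in ("gamma_a", "gamma_i", "eta"):
            pu = select_partial_uniform(ev, free).pooled_mape
            assert ps <= pu + 1e-12
            assert pu <= un + 1e-12
        assert ps <= un + 1e-12

    def test_partial_uniform_with_singleton_free_grid_equals_uniform(self):
        cohort = tiny_cohort(4)
        grid = TuningGrid(gamma_a_values=(1e-4, 1e-1), gamma_i_values=(1e-2,), eta_values=(0.5, 2.0))
        ev = evaluate_grid(cohort, grid)
        pu = select_partial_uniform(ev, "gamma_i")
        un = select_uniform(ev)
        assert pu.selected == un.selected

    def test_selected_params_are_grid_members(self):
        ev = evaluate_grid(tiny_cohort(5), SMALL_GRID)
        for res in (select_patient_specific(ev), select_uniform(ev),
                    select_partial_uniform(ev, "eta")):
            for ga, gi, eta in res.selected.values():
                assert ga in SMALL_GRID.gamma_a_values
                assert gi in SMALL_GRID.gamma_i_values
                assert eta in SMALL_GRID.eta_values

    def test_target_patient_labels_never_in_training(self):
        """Making one patient's labels adversarial must not change the other
        patients' fitted predictions (LOPO isolation)."""
        base = tiny_cohort(6, n_patients=3)
        ev1 = evaluate_grid(base, SMALL_GRID)
        poisoned = {pid: list(s) for pid, s in base.samples_by_patient.items()}
        from dataclasses import replace
        poisoned["p0"] = [
            replace(s, y=1.0) if s.is_labeled else s for s in poisoned["p0"]
        ]
        ev2 = evaluate_grid(Cohort(poisoned), SMALL_GRID)
        assert np.allclose(ev1.preds["p0"], ev2.preds["p0"])

    def test_planted_perfect_point_selected(self):
        """A grid point that achieves zero error for a patient is selected."""
        cohort = tiny_cohort(8, n_patients=3)
        ev = evaluate_grid(cohort, SMALL_GRID)
        pid = cohort.patient_ids[0]
        ev.preds[pid][1, 1, 1] = ev.y_true[pid]  # plant a perfect grid point
        res = select_patient_specific(ev)
        assert res.selected[pid] == ev.params_at((1, 1, 1))
        assert res.per_patient_mape[pid] == 0.0


class TestCompareModels:
    def test_pi_row_is_pi_feature(self, small_cohort):
        _, cohort = small_cohort
        grid = TuningGrid(gamma_a_values=(1e-2,), gamma_i_values=(1e-2,), eta_values=(1.0,))
        table = compare_models(cohort, grid)
        y, p = [], []
        for pid in cohort.patient_ids:
            for s in cohort.real_labeled(pid):
                y.append(s.y)
                p.append(s.pi)
        expected, _ = mape_margin(y, p)
        assert table.loc["PI", "mape_all"] == pytest.approx(expected, abs=1e-12)

    def test_bat_rows_use_only_bat_samples(self, small_cohort):
        _, cohort = small_cohort
        grid = TuningGrid(gamma_a_values=(1e-2,), gamma_i_values=(1e-2,), eta_values=(1.0,))
        table = compare_models(cohort, grid)
        y, p = [], []
        for pid in cohort.patient_ids:
            for s in cohort.real_labeled(pid):
                if s.is_bat:
                    y.append(s.y)
                    p.append(s.pi)
        expected, _ = mape_margin(y, p)
        assert table.loc["PI", "mape_bat"] == pytest.approx(expected, abs=1e-12)

    def test_synthetic_samples_never_scored(self, small_cohort):
        """Every scored prediction vector has the length of the real
        biopsies only — synthetic augmentations are excluded."""
        _, cohort = small_cohort
        ev = evaluate_grid(cohort, TuningGrid(
            gamma_a_values=(1e-2,), gamma_i_values=(1e-2,), eta_values=(1.0,)))
        for pid in ev.y_true:
            assert ev.y_true[pid].size == len(cohort.real_labeled(pid))


def test_grid_validation():
    with pytest.raises(ValueError, match="empty"):
        TuningGrid(gamma_a_values=())
    with pytest.raises(ValueError, match="sorted"):
        TuningGrid(eta_values=(1.0, 0.1))
    default = TuningGrid()
    assert len(default.gamma_a_values) == 15
    assert default.gamma_a_values[0] == pytest.approx(1e-10)
    assert default.gamma_a_values[-1] == pytest.approx(1e4)
    assert default.eta_values == (0.1, 1.0, 10.0, 100.0)
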