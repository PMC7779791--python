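import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tepnet.features import (LeakageError, build_feature_vector,
                             build_template, compute_feature_table,
                             compute_mfp, compute_slope, compute_stp,
                             compute_wfa)
from tepnet.preprocess import PROXIMAL_HOTSPOTS, preprocess_epochs

GRID = np.arange(20.0, 301.0, 1.0)


def ols_slope_oracle(t, y):
    """Independent closed-form sigma-formula OLS slope."""
    n = len(t)
    return ((n * np.sum(t * y) - np.sum(t) * np.sum(y))
            / (n * np.sum(t * t) - np.sum(t) ** 2))


class TestSlope:
    def test_exact_linear(self):
        y = 0.5 * GRID + 3.0
        assert compute_slope(y, GRID, 60, 100) == pytest.approx(0.5)
        assert compute_slope(y, GRID, 100, 180) == pytest.approx(0.5)

    def test_constant_is_zero(self):
        assert compute_slope(np.full_like(GRID, 4.2), GRID, 60, 100) == 0.0

    def test_quadratic_matches_closed_form_oracle(self):
        y = GRID ** 2
        mask = (GRID >= 60) & (GRID <= 100)
        expected = ols_slope_oracle(GRID[mask], y[mask])
        assert compute_slope(y, GRID, 60, 100) == pytest.approx(
            expected, rel=1e-12)

    def test_linearity_in_waveform(self):
        rng = np.random.default_rng(0)
        w1, w2 = rng.standard_normal((2, GRID.size))
        s = compute_slope(w1 + w2, GRID, 100, 180)
        assert s == pytest.approx(compute_slope(w1, GRID, 100, 180)
                                  + compute_slope(w2, GRID, 100, 180))

    def test_too_few_samples_error(self):
        t = np.array([20.0, 60.0, 100.0, 300.0])
        with pytest.raises(ValueError):
            compute_slope(np.zeros(4), t, 55, 65)

    def test_window_outside_grid_error(self):
        with pytest.raises(ValueError):
            compute_slope(np.zeros_like(GRID), GRID, 10, 100)


class TestWFA:
    def test_identity_is_one(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal(GRID.size)
        assert compute_wfa(w, w) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal(GRID.size)
        assert compute_wfa(-w, w) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal(GRID.size)
        assert compute_wfa(2.5 * w + 7.0, w) == pytest.approx(1.0)

    def test_zero_variance_flagged_missing(self):
        assert np.isnan(compute_wfa(np.zeros(10), np.arange(10.0)))

    def test_cosine_metric_not_offset_invariant(self):
        w = np.sin(GRID / 20.0)
        assert compute_wfa(w, w, metric="cosine") == pytest.approx(1.0)
        assert compute_wfa(w + 5.0, w, metric="cosine") < 1.0


class TestMFP:
    def test_constant_positive(self):
        assert compute_mfp(np.full(100, 5.0)) == pytest.approx(5.0)

    def test_constant_negative_rectified(self):
        assert compute_mfp(np.full(100, -5.0)) == pytest.approx(5.0)

    def test_unit_sinusoid_whole_periods(self):
        # analytic mean of |sin| is 2/pi; sample whole periods densely
        t = np.arange(28000) / 28000.0 * 10.0  # 10 periods
        y = np.sin(2 * np.pi * t)
        assert compute_mfp(y) == pytest.approx(2 / np.pi, abs=1e-3)


class TestSTP:
    def test_equal_inputs_zero(self):
        assert compute_stp(2.0, 2.0) == 0.0

    def test_three_one(self):
        assert compute_stp(3.0, 1.0) == pytest.approx(0.5)

    def test_antisymmetric_example(self):
        assert compute_stp(1.0, 3.0) == pytest.approx(-0.5)

    def test_both_zero_flagged_missing(self):
        assert np.isnan(compute_stp(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_stp(-1.0, 2.0)

    @given(st.floats(0.001, 1e6), st.floats(0.001, 1e6))
    def test_antisymmetry(self, a, b):
        assert compute_stp(a, b) == pytest.approx(-compute_stp(b, a))

    @given(st.floats(0.001, 1e3), st.floats(0.001, 1e3),
           st.floats(0.001, 1e3))
    def test_scale_invariance(self, a, b, k):
        assert compute_stp(k * a, k * b) == pytest.approx(
            compute_stp(a, b), abs=1e-9)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_bounded(self, a, b):
        if a + b > 0:
            assert -1.0 <= compute_stp(a, b) <= 1.0


@pytest.fixture(scope="module")
def teps(small_cohort_module):
    return small_cohort_module


@pytest.fixture(scope="module")
def small_cohort_module():
    from tepnet.simulate import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_healthy=8, n_injured=6, epochs_per_condition=6,
                           sampling_rate=500.0, noise_sd=1.5,
                           severity_mean=0.6, severity_sd=0.15, seed=7)
    epochs, fa, labels = simulate_cohort(cfg)
    tep_set, _ = preprocess_epochs(epochs)
    return tep_set, fa, labels


class TestTemplate:
    def test_identical_references_give_that_waveform(self, teps):
        tep_set, _, _ = teps
        ref = tep_set.subjects[:5]
        clones = tep_set.subset(ref)
        clones.data[:] = clones.data[:1]  # make all five identical
        template = build_template(clones, ref)
        assert np.allclose(template.data, clones.data[0, 0])

    def test_opposite_pair_yields_zero_template_and_nan_wfa(self, teps):
        tep_set, _, _ = teps
        ref = tep_set.subjects[:6]
        sub = tep_set.subset(ref)
        half = sub.data[:3].copy()
        sub.data[:3] = half
        sub.data[3:] = -half
        template = build_template(sub, ref)
        assert np.allclose(template.data, 0.0)
        assert np.isnan(compute_wfa(np.ones(5), np.zeros(5)))

    def test_monte_carlo_recovery(self):
        # [DERIVED] 50 noisy copies of a known waveform
        rng = np.random.default_rng(99)
        truth = np.sin(GRID / 30.0)
        sigma = 0.5
        noisy = truth[None, :] + sigma * rng.standard_normal((50, GRID.size))
        assert np.abs(noisy.mean(axis=0) - truth).max() < 3 * sigma / np.sqrt(50)

    def test_too_few_references_error(self, teps):
        tep_set, _, _ = teps
        with pytest.raises(ValueError):
            build_template(tep_set, tep_set.subjects[:3])

    def test_reference_evaluation_overlap_is_hard_error(self, teps):
        tep_set, _, _ = teps
        ref = tep_set.subjects[:5]
        with pytest.raises(LeakageError):
            build_template(tep_set, ref, evaluation_ids=tep_set.subjects)

    def test_feature_table_refuses_reference_subjects(self, teps):
        tep_set, _, _ = teps
        ref = tep_set.subjects[:5]
        template = build_template(tep_set, ref)
        with pytest.raises(LeakageError):
            compute_feature_table(tep_set, template, subjects=ref)


class TestFeatureTable:
    def test_stp_identity_holds_rowwise(self, teps):
        tep_set, _, _ = teps
        ref = tep_set.subjects[:5]
        template = build_template(tep_set, ref)
        table = compute_feature_table(tep_set, template)
        expect = ((table["mfp_single"] - table["mfp_i"])
                  / (table["mfp_single"] + table["mfp_i"]))
        assert np.allclose(table["stp"], expect)
        assert (table["mfp_single"] >= 0).all()
        assert table["wfa"].between(-1, 1).all()

    def test_injured_wfa_below_healthy(self, teps):
        tep_set, _, labels = teps
        ref = tep_set.subjects[:5]
        template = build_template(tep_set, ref)
        table = compute_feature_table(tep_set, template)
        merged = table.merge(labels.rename("group"), left_on="subject_id",
                             right_index=True)
        means = merged.groupby("group")["wfa"].mean()
        assert means["injured"] < means["healthy"]


class TestFeatureVector:
    def _table(self):
        rows = []
        rng = np.random.default_rng(11)
        for s in ("A", "B", "C"):
            for h in PROXIMAL_HOTSPOTS:
                rows.append({"subject_id": s, "hotspot": h,
                             "epd": rng.normal(), "lpd": rng.normal(),
                             "wfa": rng.uniform(-1, 1),
                             "mfp_single": 1.0, "mfp_i": 1.0,
                             "stp": rng.uniform(-1, 1)})
        return pd.DataFrame(rows)

    def test_sixteen_columns_in_documented_order(self):
        X, log = build_feature_vector(self._table())
        assert X.shape == (3, 16)
        expected = [f"{h}:{m}" for h in PROXIMAL_HOTSPOTS
                    for m in ("epd", "lpd", "wfa", "stp")]
        assert list(X.columns) == expected
        assert not log.imputed and not log.dropped

    def test_row_order_invariance(self):
        table = self._table()
        shuffled = table.sample(frac=1.0, random_state=5)
        X1, _ = build_feature_vector(table)
        X2, _ = build_feature_vector(shuffled)
        assert X1.equals(X2.loc[X1.index])

    def test_missing_cell_imputed_with_cohort_median(self):
        table = self._table()
        col = (table["subject_id"] == "A") & (table["hotspot"] == "temporal_left")
        table.loc[col, "wfa"] = np.nan
        X, log = build_feature_vector(table)
        others = table.loc[(table["hotspot"] == "temporal_left")
                           & (table["subject_id"] != "A"), "wfa"]
        assert X.loc["A", "temporal_left:wfa"] == pytest.approx(others.median())
        assert ("A", "temporal_left", "wfa") in log.imputed

    def test_subject_dropped_when_too_sparse(self):
        table = self._table()
        mask = table["subject_id"] == "B"
        table.loc[mask, ["epd", "lpd", "wfa", "stp"]] = np.nan
        X, log = build_feature_vector(table)
        assert "B" not in X.index
        assert "B" in log.dropped
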