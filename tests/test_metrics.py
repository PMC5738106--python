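import numpy as np
import pandas as pd
import pytest
from scipy import stats

from midasim.errors import DomainError, MidaError
from midasim.metrics import (
    compare_groups,
    conversion_degree,
    glucose_released,
    metrics_table,
    starch_hydrolysis_pct,
)
from midasim.synthetic import NoiseModel, generate_experiment, preset_design, run_design


class TestConversionDegree:
    @pytest.mark.parametrize(
        "s_i, s_t, expected",
        [
            (1.309, 0.317, 75.78),   # unfermented cream, end of oral phase
            (0.411, 0.202, 50.85),   # fermented cream, end of oral phase
            (0.411, 0.007, 98.29),   # fermented cream, 15 min into intestine
            (1.309, 0.179, 86.32),   # unfermented cream, 15 min into intestine
            (1.309, 0.004, 99.69),   # unfermented cream, end of run
        ],
    )
    def test_reported_conversion_pairs(self, s_i, s_t, expected):
        assert conversion_degree(s_i, s_t) == pytest.approx(expected, abs=0.05)

    def test_no_conversion_is_zero(self):
        assert conversion_degree(0.5, 0.5) == 0.0

    def test_noise_above_initial_warns_and_goes_negative(self):
        with pytest.warns(UserWarning):
            assert conversion_degree(1.0, 1.1) == pytest.approx(-10.0)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(DomainError):
            conversion_degree(0.0, 0.1)


class TestGlucoseReleased:
    def test_baseline_subtraction(self):
        assert glucose_released(0.750, 0.004) == pytest.approx(0.746)
        assert glucose_released(0.2, 0.2) == 0.0

    def test_negative_release_preserved_with_warning(self):
        with pytest.warns(UserWarning):
            assert glucose_released(0.2, 0.5) == pytest.approx(-0.3)


class TestStarchHydrolysisPct:
    def test_reported_values(self):
        # fermented product's end-of-run %SH exceeds 100: part of the released
        # glucose comes from non-starch fermentation saccharides
        assert starch_hydrolysis_pct(0.632, 0.411) == pytest.approx(138.40, abs=0.05)
        assert starch_hydrolysis_pct(0.115, 1.309) == pytest.approx(7.89, abs=0.1)
        assert starch_hydrolysis_pct(0.0, 5.0) == 0.0

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(DomainError):
            starch_hydrolysis_pct(0.1, 0.0)


class TestMetricsTable:
    def test_flat_gastric_series_gives_constant_conversion(self, basic_run):
        mt = metrics_table(basic_run)
        gastric = mt.per_sample[mt.per_sample["phase"] == "gastric"]
        assert gastric["conversion_pct"].max() - gastric["conversion_pct"].min() < 1e-9

    def test_sh_equals_conversion_without_glucogenic_pool(self, basic_design):
        # when every released glucose molecule derives from measured starch,
        # measurement is exact and no dilution separates the aliquots' bases,
        # 0.9*G_R = S_i - S(t), so %SH and the conversion degree coincide
        from midasim.simulator import Event, EventTimeline, KineticParams, simulate

        food = basic_design.food  # glucogenic_pool_g == 0
        events = [Event(0.0, "add_food", "oral", food.portion_volume_ml, label="food"),
                  Event(0.0, "sample", "food", 10.0, purpose="baseline")]
        events += [Event(float(t), "sample", "oral", 10.0, purpose="oral")
                   for t in (1, 2, 3)]
        ts = simulate(food, EventTimeline(events=tuple(events)),
                      KineticParams(k_oral=0.3, k_intestinal=0.0))
        mt = metrics_table(ts)
        oral = mt.per_sample[mt.per_sample["phase"] == "oral"]
        np.testing.assert_allclose(oral["sh_pct"].to_numpy(),
                                   oral["conversion_pct"].to_numpy(), rtol=1e-9)

    def test_order_and_relabeling_invariance(self, basic_design):
        ts = generate_experiment(basic_design, NoiseModel(assay_cv=0.1, seed=5))
        mt1 = metrics_table(ts)
        shuffled = ts.samples.sample(frac=1.0, random_state=0).copy()
        shuffled["replicate"] = shuffled["replicate"].map({0: 2, 1: 0, 2: 1})
        mt2 = metrics_table(shuffled)
        keys = ["time_min", "starch_g", "glucose_g"]
        a = mt1.per_sample.sort_values(keys).reset_index(drop=True)
        b = mt2.per_sample.sort_values(keys).reset_index(drop=True)
        pd.testing.assert_frame_equal(a.drop(columns="replicate"), b.drop(columns="replicate"))

    def test_glucogenic_pool_pushes_sh_above_100(self, premium_design):
        from dataclasses import replace

        design = replace(premium_design, sample_basis="compartment")
        mt = metrics_table(run_design(design))
        final = mt.per_sample[np.isclose(mt.per_sample["time_min"], 248.0)]
        assert float(final["sh_pct"].iloc[0]) > 100.0

    def test_missing_baseline_is_an_error(self, basic_run):
        df = basic_run.samples[basic_run.samples["purpose"] != "baseline"]
        with pytest.raises(MidaError, match="t=0"):
            metrics_table(df)

    def test_explicit_si_sources_require_value(self, basic_run):
        with pytest.raises(DomainError):
            metrics_table(basic_run, si_source="pre_treatment")
        mt = metrics_table(basic_run, si_source="explicit", s_i=2.0)
        assert all(v == 2.0 for v in mt.s_i.values())


def _ts(values_by_rep, time=1.0):
    rows = [
        {"time_min": time, "compartment": "gastric", "purpose": "gastric",
         "sample_volume_ml": 10.0, "starch_g": v, "glucose_g": 0.0, "replicate": r}
        for r, v in enumerate(values_by_rep)
    ]
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups(self):
        c = compare_groups(_ts([1.0, 1.0, 1.0]), _ts([1.0, 1.0, 1.0]), 1.0)
        assert c.t_statistic == 0.0 and c.p_value == 1.0 and c.zero_variance

    def test_separated_zero_variance_groups(self):
        c = compare_groups(_ts([0.0, 0.0, 0.0]), _ts([1.0, 1.0, 1.0]), 1.0)
        assert c.zero_variance and c.p_value <= np.finfo(float).eps
        assert c.significant_01

    def test_matches_scipy_student_t(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 3), rng.normal(0.5, 1, 3)
        c = compare_groups(_ts(a), _ts(b), 1.0)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert c.t_statistic == pytest.approx(t_ref)
        assert c.p_value == pytest.approx(p_ref)

    def test_insufficient_replicates(self):
        with pytest.raises(MidaError):
            compare_groups(_ts([1.0]), _ts([1.0, 2.0]), 1.0)

    def test_type_one_error_calibration_under_null(self):
        # simulated null pairs of triplicates: rejection rate at alpha=0.05
        # must be calibrated
        rng = np.random.default_rng(2024)
        n_pairs = 10_000
        a = rng.normal(0.5, 0.1, size=(n_pairs, 3))
        b = rng.normal(0.5, 0.1, size=(n_pairs, 3))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        rate = float(np.mean(p < 0.05))
        assert 0.04 <= rate <= 0.06
        # spot-check that compare_groups reproduces the vectorized p-values
        for i in (0, 1234, 9999):
            c = compare_groups(_ts(a[i]), _ts(b[i]), 1.0)
            assert c.p_value == pytest.approx(p[i])
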