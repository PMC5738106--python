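import math
from dataclasses import replace

import numpy as np
import pytest

from midasim.errors import DomainError, InfeasiblePlanError, MidaError
from midasim.protocol import SamplingPlan, default_sampling_plan, plan_fluid_volumes
from midasim.simulator import (
    KineticParams,
    build_timeline,
    fit_first_order_kinetics,
    simulate,
)
from midasim.synthetic import preset_design, run_design, standard_schedule

from _oracle import simulate_fixed_step


def _standard_timeline(food, food_class="rice_cream_basic", sampling=None):
    plan = plan_fluid_volumes(food.portion_volume_ml)
    schedule = standard_schedule(food_class, plan)
    if sampling is None:
        sampling = default_sampling_plan()
    return build_timeline(food, plan, sampling, schedule)


class TestTimeline:
    def test_standard_run_has_21_sampling_events(self, basic_design):
        tl = _standard_timeline(basic_design.food)
        assert tl.n_sample_events == 21

    def test_eight_gastric_samples_and_eight_feeds(self, basic_design):
        tl = _standard_timeline(basic_design.food)
        assert tl.count(kind="sample", purpose="gastric") == 8
        assert tl.count(kind="feed_pulse") == 8
        feed_times = [e.time_min for e in tl.events if e.kind == "feed_pulse"]
        assert feed_times == [2, 4, 6, 8, 10, 12, 14, 16]

    def test_pulses_start_at_gastric_end_and_match_schedule(self, basic_design):
        plan = plan_fluid_volumes(45.0)
        schedule = standard_schedule("rice_cream_basic", plan)
        tl = build_timeline(basic_design.food, plan, default_sampling_plan(), schedule)
        pulses = [e for e in tl.events if e.kind == "pyloric_pulse"]
        assert pulses[0].time_min == 122.0
        assert len(pulses) == sum(r.n_pulses for r in schedule.rows)
        assert sum(e.volume_ml for e in pulses) == pytest.approx(plan.chyme_delivered_ml)

    def test_empty_sampling_plan_keeps_other_events(self, basic_design):
        tl_full = _standard_timeline(basic_design.food)
        tl_none = _standard_timeline(basic_design.food, sampling=SamplingPlan(events=()))
        assert tl_none.n_sample_events == 0
        assert len(tl_none.events) == len(tl_full.events) - 21


class TestSimulate:
    def test_zero_rates_keep_concentrations_constant(self, basic_design):
        tl = _standard_timeline(basic_design.food)
        ts = simulate(basic_design.food, tl, KineticParams(k_oral=0, k_intestinal=0))
        df = ts.samples
        conc = df["starch_g"] / df["sample_volume_ml"]
        # within each compartment the concentration never changes
        for comp, group in conc.groupby(df["purpose"].map(
                lambda p: "intestinal" if p == "drain" else p)):
            if comp == "baseline":
                continue
            assert group.max() - group.min() < 1e-12

    def test_gastric_phase_is_exactly_flat(self, basic_run):
        gastric = basic_run.samples[basic_run.samples["purpose"] == "gastric"]
        assert len(gastric) == 8
        assert gastric["starch_g"].max() - gastric["starch_g"].min() < 1e-12

    def test_stoichiometric_ledger(self, premium_run):
        led = premium_run.ledger
        consumed = led["starch_consumed_g"] + led["glucogenic_consumed_g"]
        assert led["glucose_produced_g"] == pytest.approx(consumed / 0.9, abs=1e-9)

    def test_volume_conservation(self, basic_run):
        led = basic_run.ledger
        held = sum(s["volume_ml"] for s in basic_run.final_state.values())
        assert led["volume_in_ml"] - led["volume_sampled_ml"] == pytest.approx(held, abs=1e-9)

    def test_mass_conservation(self, premium_run):
        led = premium_run.ledger
        state = premium_run.final_state
        for species, consumed_key in (("starch", "starch_consumed_g"),
                                      ("glucogenic", "glucogenic_consumed_g")):
            total_in = led[f"{species}_in_g"]
            held = sum(s[f"{species}_g"] for s in state.values())
            out = led[f"{species}_sampled_g"] + led[consumed_key]
            assert total_in == pytest.approx(held + out, abs=1e-9)
        glucose_in = led["glucose_in_g"] + led["glucose_produced_g"]
        glucose_out = led["glucose_sampled_g"] + sum(
            s["glucose_g"] for s in state.values())
        assert glucose_in == pytest.approx(glucose_out, abs=1e-9)

    def test_intestinal_concentration_decays_after_inflow_ends(self, premium_run):
        df = premium_run.samples
        tail = df[(df["time_min"] >= 152)].sort_values("time_min")
        conc = (tail["starch_g"] / tail["sample_volume_ml"]).to_numpy()
        assert np.all(np.diff(conc) < 0)

    def test_oversized_sample_is_infeasible(self, basic_design):
        plan = plan_fluid_volumes(45.0)
        schedule = standard_schedule("rice_cream_basic", plan)
        bad = SamplingPlan(events=(
            default_sampling_plan().events[0],
            replace(default_sampling_plan().events[1], sample_volume_ml=95.0),
        ))
        tl = build_timeline(basic_design.food, plan, bad, schedule)
        with pytest.raises(InfeasiblePlanError, match="t=2"):
            simulate(basic_design.food, tl, KineticParams(k_oral=0.1, k_intestinal=0.1))

    def test_agrees_with_fixed_step_oracle(self, premium_design):
        food = premium_design.food
        tl = _standard_timeline(food, "rice_cream_premium")
        ts = simulate(food, tl, premium_design.kinetics)
        ref = simulate_fixed_step(food, tl, premium_design.kinetics, dt_min=0.01)
        for rec in ts.samples.itertuples():
            s_ref, g_ref = ref[(rec.time_min, rec.purpose)]
            assert rec.starch_g == pytest.approx(s_ref, rel=1e-3, abs=1e-9)
            assert rec.glucose_g == pytest.approx(g_ref, rel=1e-3, abs=1e-9)


class TestKineticsFit:
    def test_exact_recovery_from_noiseless_series(self, basic_design):
        design = replace(basic_design,
                         kinetics=replace(basic_design.kinetics, k_intestinal=0.2))
        ts = run_design(design)
        fit = fit_first_order_kinetics(ts, "intestinal", t_range=(150, 248))
        assert fit.rate_per_min == pytest.approx(0.2, abs=1e-6)

    def test_flat_phase_rate_not_distinguishable_from_zero(self, basic_design):
        from midasim.synthetic import NoiseModel, generate_experiment

        ts = generate_experiment(basic_design, NoiseModel(assay_cv=0.05, seed=3))
        fit = fit_first_order_kinetics(ts, "gastric")  # k_gastric = 0
        assert fit.ci_low <= 0.0 <= fit.ci_high

    def test_all_zero_starch_is_nothing_to_fit(self, basic_design):
        ts = run_design(basic_design)
        df = ts.samples.copy()
        df.loc[df["purpose"] == "gastric", "starch_g"] = 0.0
        with pytest.raises(MidaError, match="nothing to fit"):
            fit_first_order_kinetics(df, "gastric")

    def test_negative_rates_rejected(self):
        with pytest.raises(DomainError):
            KineticParams(k_oral=-0.1, k_intestinal=0.1)
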