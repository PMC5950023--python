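"""Event engine: FEL semantics, twin-pair sharing, pathway traces, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from aaasim.engine import (
    INVITED,
    NON_INVITED,
    Event,
    FutureEventList,
    IndividualRecord,
    SharedAttributes,
    TwinPair,
    create_twin_pair,
    run_main_analysis,
    simulate_individual,
    tally_record,
)
from aaasim.growth_rupture import NEVER, AortaTrajectory
from aaasim.parameters import ParameterBundle
from aaasim.policy import builtin_policy
from aaasim.psa import OversamplingPlan

POLICY = builtin_policy("current")


def bundle_variant(bundle, fixed=None, uncertain=None):
    d = bundle.to_dict()
    for k, v in (fixed or {}).items():
        d["global_fixed"][k] = v
    for k, v in (uncertain or {}).items():
        d["global_uncertain"][k] = v
    return ParameterBundle.from_dict(d)


class TestFutureEventList:
    def test_pop_returns_minimum_time(self):
        fel = FutureEventList()
        fel.schedule(Event(5.0, "censor"))
        fel.schedule(Event(2.0, "rupture"))
        fel.schedule(Event(3.0, "invitation"))
        assert fel.pop_next().kind == "rupture"
        assert fel.pop_next().kind == "invitation"

    def test_tie_broken_by_kind_priority_deaths_first(self):
        fel = FutureEventList()
        fel.schedule(Event(1.0, "censor"))
        fel.schedule(Event(1.0, "surveillance_scan"))
        fel.schedule(Event(1.0, "non_aaa_death"))
        fel.schedule(Event(1.0, "rupture"))
        kinds = [fel.pop_next().kind for _ in range(4)]
        assert kinds == ["non_aaa_death", "rupture", "surveillance_scan", "censor"]

    def test_reschedule_replaces_pending_event_of_same_kind(self):
        fel = FutureEventList()
        fel.schedule(Event(5.0, "surveillance_scan"))
        fel.schedule(Event(2.0, "surveillance_scan"))
        assert len(fel) == 1
        assert fel.pop_next().time == 2.0

    def test_cancel_removes_event(self):
        fel = FutureEventList()
        fel.schedule(Event(5.0, "rupture"))
        fel.cancel("rupture")
        assert "rupture" not in fel
        fel.cancel("rupture")  # idempotent

    def test_pop_empty_raises(self):
        with pytest.raises(IndexError):
            FutureEventList().pop_next()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Event(1.0, "teleportation")

    def test_infinite_time_rejected(self):
        with pytest.raises(ValueError):
            Event(math.inf, "censor")


class TestCreateTwinPair:
    def test_shared_fields_are_frozen(self, naaasp_bundle, means_draw, rng):
        pair = create_twin_pair(means_draw, naaasp_bundle, rng)
        with pytest.raises(AttributeError):
            pair.shared.non_aaa_death_time = 0.0  # type: ignore[misc]

    def test_zero_hazard_means_no_ruptures(self, naaasp_bundle, means_draw, rng):
        b = bundle_variant(
            naaasp_bundle,
            fixed={"rupture_hazard": {"intercept": -60.0, "slope": 0.0,
                                      "reference_diameter_cm": 5.5}},
        )
        for _ in range(300):
            pair = create_twin_pair(means_draw, b, rng)
            assert pair.shared.rupture_time == NEVER

    def test_baseline_prevalence_matches_configuration(self, naaasp_bundle, means_draw):
        """P(baseline >= 3.0 cm) ~ 1.6% for the contemporary programme bundle."""
        n = 100_000
        rng = np.random.default_rng(77)
        count = sum(
            create_twin_pair(means_draw, naaasp_bundle, rng).shared.trajectory.baseline_diameter
            >= 3.0
            for _ in range(n)
        )
        p = 0.016
        se = math.sqrt(p * (1 - p) / n)
        assert abs(count / n - p) < 3 * se + 2e-4

    def test_oversampling_reweights_to_prevalence(self, naaasp_bundle, means_draw):
        """Weighted AAA-stratum share equals the population share."""
        plan = OversamplingPlan.from_bundle(naaasp_bundle)
        rng = np.random.default_rng(11)
        n = 40_000
        w_total = w_aaa = 0.0
        for _ in range(n):
            pair = create_twin_pair(means_draw, naaasp_bundle, rng, oversampling_plan=plan)
            w_total += pair.weight
            if pair.shared.trajectory.baseline_diameter >= plan.stratum_threshold:
                w_aaa += pair.weight
        assert w_total / n == pytest.approx(1.0, abs=0.02)
        assert w_aaa / w_total == pytest.approx(plan.prevalence, rel=0.06)

    def test_below_cutoff_never_grows(self, naaasp_bundle, means_draw):
        rng = np.random.default_rng(13)
        for _ in range(2000):
            traj = create_twin_pair(means_draw, naaasp_bundle, rng).shared.trajectory
            if traj.baseline_diameter < 2.0:
                assert traj.zero_growth and traj.log_growth_rate == 0.0

    def test_censoring_shared_and_uniform_for_validation_bundle(
        self, mass_bundle, mass_means_draw
    ):
        rng = np.random.default_rng(3)
        times = [
            create_twin_pair(mass_means_draw, mass_bundle, rng).shared.censor_time
            for _ in range(3000)
        ]
        assert min(times) >= 3.0 and max(times) <= 5.25
        assert np.mean(times) == pytest.approx((3.0 + 5.25) / 2, abs=0.05)


def forced_pair(bundle, *, baseline, slope, zero_growth=False, rupture_time=NEVER,
                death_time=80.0, censor_time=None, attend=True, contra=False,
                surv_emerg=True, surv_elect=True, evar=False, weight=1.0):
    traj = AortaTrajectory(baseline, slope, zero_growth)
    shared = SharedAttributes(
        trajectory=traj,
        non_aaa_death_time=death_time,
        rupture_time=rupture_time,
        rupture_u=0.5,
        censor_time=bundle.time_horizon_years if censor_time is None else censor_time,
        would_attend=attend,
        contraindicated=contra,
        survives_emergency_surgery=surv_emerg,
        survives_elective_surgery=surv_elect,
        gets_evar=evar,
    )
    return TwinPair(shared=shared, weight=weight)


class TestSimulateIndividual:
    def test_small_aorta_screen_and_discharge(self, naaasp_bundle, means_draw, rng):
        pair = forced_pair(naaasp_bundle, baseline=1.8, slope=0.0, zero_growth=True)
        rec = simulate_individual(pair, INVITED, POLICY, means_draw, naaasp_bundle, rng)
        kinds = [e.kind for e in rec.events]
        assert kinds[0] == "invitation"
        assert kinds[1] == "screen_scan"
        assert kinds[-1] in ("censor", "non_aaa_death")
        assert not any(k in kinds for k in ("rupture", "aaa_death", "elective_surgery"))

    def test_large_aorta_full_surgical_pathway_timing(self, naaasp_bundle, means_draw, rng):
        """Screen -> consultation at +71 d -> elective surgery at +59 d more."""
        pair = forced_pair(naaasp_bundle, baseline=6.0, slope=0.0, zero_growth=False)
        rec = simulate_individual(pair, INVITED, POLICY, means_draw, naaasp_bundle, rng)
        by_kind = {e.kind: e for e in rec.events}
        assert "elective_surgery" in by_kind
        t_scan = by_kind["screen_scan"].time
        t_cons = by_kind["consultation"].time
        t_surg = by_kind["elective_surgery"].time
        assert t_cons - t_scan == pytest.approx(71 / 365.25)
        assert t_surg - t_cons == pytest.approx(59 / 365.25)
        assert rec.detection_state == "post_repair"

    def test_unscreened_twin_ruptures_and_dies(self, naaasp_bundle, means_draw):
        """Hand-traced twin contrast on fixed latent values."""
        pair = forced_pair(
            naaasp_bundle, baseline=6.0, slope=0.0, rupture_time=2.0, surv_emerg=False
        )
        rng_inv, rng_non = np.random.default_rng(1), np.random.default_rng(2)
        inv = simulate_individual(pair, INVITED, POLICY, means_draw, naaasp_bundle, rng_inv)
        non = simulate_individual(pair, NON_INVITED, POLICY, means_draw, naaasp_bundle, rng_non)
        assert inv.alive_at_censor  # repaired before the rupture time
        assert non.terminal_kind in ("aaa_death",)
        assert non.death_time == 2.0

    def test_contraindicated_exits_but_rupture_persists(self, naaasp_bundle, means_draw, rng):
        pair = forced_pair(
            naaasp_bundle, baseline=6.0, slope=0.0, contra=True, rupture_time=5.0,
            surv_emerg=False,
        )
        rec = simulate_individual(pair, INVITED, POLICY, means_draw, naaasp_bundle, rng)
        outcomes = [e.payload.get("outcome") for e in rec.events if e.kind == "consultation"]
        assert "contraindicated" in outcomes
        assert any(e.kind == "rupture" for e in rec.events)

    def test_screening_events_only_in_invited_arm(self, naaasp_bundle, means_draw, rng):
        pair = forced_pair(naaasp_bundle, baseline=4.0, slope=0.02)
        rec = simulate_individual(pair, NON_INVITED, POLICY, means_draw, naaasp_bundle, rng)
        kinds = {e.kind for e in rec.events}
        assert "invitation" not in kinds and "screen_scan" not in kinds

    def test_history_time_ordered_with_single_terminal(self, naaasp_bundle, means_draw):
        rng = np.random.default_rng(8)
        terminal = {"censor", "non_aaa_death", "aaa_death"}
        for i in range(300):
            pair = create_twin_pair(means_draw, naaasp_bundle, rng)
            for arm in (INVITED, NON_INVITED):
                rec = simulate_individual(
                    pair, arm, POLICY, means_draw, naaasp_bundle, np.random.default_rng(i)
                )
                times = [e.time for e in rec.events]
                assert times == sorted(times)
                assert sum(e.kind in terminal for e in rec.events) == 1
                assert rec.events[-1].kind in terminal

    def test_surveillance_spacing_matches_policy_interval(self, naaasp_bundle):
        """With certain attendance and no dropout, rescans are spaced exactly."""
        b = bundle_variant(
            naaasp_bundle,
            fixed={"ultrasound_sd_cm": 0.0, "incidental_detection_rate_per_year": 0.0},
            uncertain={
                "attendance": {"family": "fixed", "value": 1.0, "probability": True},
                "p_dropout_per_visit": {"family": "fixed", "value": 0.0, "probability": True},
            },
        )
        import aaasim

        draw = aaasim.fix_bundle_at_means(b)
        pair = forced_pair(b, baseline=3.05, slope=0.03)
        rec = simulate_individual(
            pair, INVITED, POLICY, draw, b, np.random.default_rng(0)
        )
        scans = [e.time for e in rec.events if e.kind in ("screen_scan", "surveillance_scan")]
        assert len(scans) > 3
        # yearly while measured < 4.5, i.e. until the trajectory reaches 4.5
        t_45 = math.log(4.5 / 3.05) / 0.03
        yearly = [t for t in scans if t < t_45]
        assert np.allclose(np.diff(yearly), 1.0)

    def test_incidental_detection_only_after_threshold_crossing(
        self, naaasp_bundle, means_draw
    ):
        b = bundle_variant(
            naaasp_bundle, fixed={"incidental_detection_rate_per_year": 5.0}
        )
        rng = np.random.default_rng(21)
        pair = forced_pair(b, baseline=2.4, slope=0.03)
        t_cross = math.log(3.0 / 2.4) / 0.03
        rec = simulate_individual(pair, NON_INVITED, POLICY, means_draw, b, rng)
        for e in rec.events:
            if e.kind == "incidental_detection":
                assert e.time >= t_cross


class TestRunMainAnalysis:
    def test_single_pair_smallest_run(self, naaasp_bundle, means_draw):
        res = run_main_analysis(1, means_draw, naaasp_bundle, POLICY, seed=0)
        assert res.n_pairs == 1

    def test_deterministic_under_same_seed(self, naaasp_bundle, means_draw):
        a = run_main_analysis(300, means_draw, naaasp_bundle, POLICY, seed=9)
        b = run_main_analysis(300, means_draw, naaasp_bundle, POLICY, seed=9)
        assert a.invited.mean_cost == b.invited.mean_cost
        assert a.invited.event_counts == b.invited.event_counts

    def test_null_risk_limit_no_aaa_deaths(self, naaasp_bundle):
        import aaasim

        b = bundle_variant(
            naaasp_bundle,
            fixed={"rupture_hazard": {"intercept": -60.0, "slope": 0.0,
                                      "reference_diameter_cm": 5.5}},
            uncertain={
                "p_death_elective_open": {"family": "fixed", "value": 0.0,
                                          "probability": True},
                "p_death_elective_evar": {"family": "fixed", "value": 0.0,
                                          "probability": True},
                "p_death_emergency": {"family": "fixed", "value": 0.0,
                                      "probability": True},
            },
        )
        draw = aaasim.fix_bundle_at_means(b)
        res = run_main_analysis(500, draw, b, POLICY, seed=4)
        assert res.invited.event_counts.get("aaa_death", 0) == 0
        assert res.non_invited.event_counts.get("aaa_death", 0) == 0

    def test_non_aaa_death_counts_identical_without_aaa_mortality(self, mass_bundle):
        """Shared latent death/censor times make non-AAA deaths match exactly
        once the competing AAA-death pathway is switched off."""
        import aaasim

        b = bundle_variant(
            mass_bundle,
            fixed={"rupture_hazard": {"intercept": -60.0, "slope": 0.0,
                                      "reference_diameter_cm": 5.5}},
            uncertain={
                "p_death_elective_open": {"family": "fixed", "value": 0.0,
                                          "probability": True},
                "p_death_elective_evar": {"family": "fixed", "value": 0.0,
                                          "probability": True},
                "p_death_emergency": {"family": "fixed", "value": 0.0,
                                      "probability": True},
            },
        )
        draw = aaasim.fix_bundle_at_means(b)
        res = run_main_analysis(4000, draw, b, POLICY, seed=5)
        assert res.invited.event_counts["non_aaa_death"] == (
            res.non_invited.event_counts["non_aaa_death"]
        )

    def test_non_aaa_death_difference_bounded_by_aaa_deaths(
        self, mass_bundle, mass_means_draw
    ):
        """With AAA mortality active, arms differ only via AAA-death preemption."""
        res = run_main_analysis(4000, mass_means_draw, mass_bundle, POLICY, seed=5)
        diff = abs(
            res.invited.event_counts["non_aaa_death"]
            - res.non_invited.event_counts["non_aaa_death"]
        )
        total_aaa = res.invited.event_counts.get("aaa_death", 0) + (
            res.non_invited.event_counts.get("aaa_death", 0)
        )
        assert diff <= total_aaa

    def test_invited_arm_costs_at_least_non_invited(self, naaasp_bundle, means_draw):
        res = run_main_analysis(2000, means_draw, naaasp_bundle, POLICY, seed=6,
                                oversampling_plan=OversamplingPlan.from_bundle(naaasp_bundle))
        assert res.invited.mean_cost >= res.non_invited.mean_cost


class TestTally:
    def test_rupture_death_tally(self):
        rec = IndividualRecord(
            arm=NON_INVITED,
            events=[
                Event(2.0, "rupture"),
                Event(2.0, "aaa_death", {"cause": "unoperated_rupture"}),
            ],
        )
        t = tally_record(rec)
        assert t["rupture"] == 1 and t["aaa_death"] == 1

    def test_elective_route_attribution(self):
        rec = IndividualRecord(
            arm=INVITED,
            events=[
                Event(1.0, "elective_surgery", {"modality": "open", "route": "incidental"}),
                Event(5.0, "censor"),
            ],
        )
        t = tally_record(rec)
        assert t["elective_operation"] == 1
        assert t["elective_operation_incidental"] == 1
        assert "elective_operation_screen" not in t
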