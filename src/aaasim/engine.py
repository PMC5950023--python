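"""Event-scheduling simulation engine.

Individuals are simulated in matched pairs ("twins"): one invited to
screening and one not, sharing every latent attribute that is independent of
the screening pathway — baseline diameter, latent growth rate, non-AAA death
time, the uniform draw behind the rupture time, censoring time, and binary
indicators (would attend, contraindicated, would survive emergency surgery,
would survive elective surgery, repaired by EVAR).  Differences in costs and
outcomes then arise only from the events the screening programme induces,
which removes most Monte Carlo noise from incremental estimates.

Each individual owns a future event list (FEL) holding at most one pending
event per kind.  The simulation clock repeatedly pops the earliest pending
event (ties broken by a fixed kind-priority order, deaths first), records it
in the history, and lets the handler schedule, reschedule or cancel other
events.  The loop terminates at a death or censoring event.

Reproducibility contract: all randomness derives from one master seed; each
pair gets three child streams (latent attributes, invited-arm events,
non-invited-arm events) spawned by pair index, so results are bit-identical
regardless of how pairs are distributed over parallel workers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr, ndtri

from . import economics
from .growth_rupture import (
    AortaTrajectory,
    MeasurementModel,
    RuptureHazardParams,
    diameter_at_time,
    measure_diameter,
    sample_rupture_time,
    time_to_threshold,
)
from .parameters import GlobalUncertainDraw, ParameterBundle
from .policy import Action, PolicySpec, classify_measurement

__all__ = [
    "EVENT_KINDS",
    "Event",
    "FutureEventList",
    "SharedAttributes",
    "TwinPair",
    "IndividualRecord",
    "ArmSummary",
    "MainResult",
    "create_twin_pair",
    "simulate_individual",
    "run_main_analysis",
    "tally_record",
]

INVITED = "invited"
NON_INVITED = "non_invited"

# deaths processed first on time ties, censoring last
_KIND_PRIORITY = (
    "non_aaa_death",
    "rupture",
    "aaa_death",
    "emergency_surgery",
    "elective_surgery",
    "consultation",
    "incidental_detection",
    "surveillance_scan",
    "screen_scan",
    "invitation",
    "dropout",
    "censor",
)
EVENT_KINDS = frozenset(_KIND_PRIORITY)
_PRIORITY = {k: i for i, k in enumerate(_KIND_PRIORITY)}

# detection states
UNDETECTED = "undetected"
UNDER_SURVEILLANCE = "under_surveillance"
REFERRED = "referred"
POST_REPAIR = "post_repair"
CONTRAINDICATED_EXIT = "contraindicated_exit"
DISCHARGED = "discharged"


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    payload: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (self.time >= 0.0 and math.isfinite(self.time)):
            raise ValueError(f"event time must be finite and >= 0, got {self.time}")


class FutureEventList:
    """Pending events for one individual, at most one per kind."""

    __slots__ = ("_pending",)

    def __init__(self) -> None:
        self._pending: dict[str, Event] = {}

    def schedule(self, event: Event) -> None:
        """Schedule or reschedule: replaces any pending event of the same kind."""
        self._pending[event.kind] = event

    def cancel(self, kind: str) -> None:
        self._pending.pop(kind, None)

    def peek(self, kind: str) -> Optional[Event]:
        return self._pending.get(kind)

    def __len__(self) -> int:
        return len(self._pending)

    def __contains__(self, kind: str) -> bool:
        return kind in self._pending

    def pop_next(self) -> Event:
        """Remove and return the earliest pending event (kind priority on ties)."""
        if not self._pending:
            raise IndexError("future event list is empty")
        kind = min(self._pending, key=lambda k: (self._pending[k].time, _PRIORITY[k]))
        return self._pending.pop(kind)


@dataclass(frozen=True)
class SharedAttributes:
    """Latent attributes shared by the two arms of a twin pair; never mutated."""

    trajectory: AortaTrajectory
    non_aaa_death_time: float
    rupture_time: float  # years, or NEVER
    rupture_u: float
    censor_time: float
    would_attend: bool
    contraindicated: bool
    survives_emergency_surgery: bool
    survives_elective_surgery: bool
    gets_evar: bool


@dataclass
class IndividualRecord:
    """Realized event history for one individual in one arm."""

    arm: str
    events: list[Event] = field(default_factory=list)
    detection_state: str = UNDETECTED
    death_time: Optional[float] = None
    alive_at_censor: bool = False

    @property
    def end_time(self) -> float:
        return self.events[-1].time if self.events else 0.0

    @property
    def terminal_kind(self) -> str:
        return self.events[-1].kind


@dataclass
class TwinPair:
    shared: SharedAttributes
    weight: float = 1.0
    index: int = 0
    invited: Optional[IndividualRecord] = None
    non_invited: Optional[IndividualRecord] = None


def _sample_baseline_diameter(rng, mu, sigma, plan):
    """Baseline diameter, optionally stratified-oversampled above a threshold.

    Returns (diameter_cm, weight).  With a plan, the AAA stratum (diameter at
    or above the stratum threshold, population share p) is sampled with
    probability q = kp / (1 + (k-1)p) — its sampling odds multiplied by k —
    and carries weight (1+(k-1)p)/k, the rest weight 1+(k-1)p, so weighted
    means are unbiased for the population mean.
    """
    def q(u: float) -> float:
        u = min(max(u, 1e-12), 1.0 - 1e-12)
        return math.exp(mu + sigma * ndtri(u))

    if plan is None or plan.multiplier == 1.0:
        return q(rng.random()), 1.0
    z_thr = (math.log(plan.stratum_threshold) - mu) / sigma
    p_lo = float(ndtr(z_thr))  # P(D < threshold)
    if rng.random() < plan.sampling_probability:
        # truncated to the AAA stratum: quantile in [p_lo, 1)
        return q(p_lo + rng.random() * (1.0 - p_lo)), plan.weight_oversampled
    return q(rng.random() * p_lo), plan.weight_rest


def _draw_growth_rate(rng, bundle: ParameterBundle, d0: float) -> tuple[float, bool]:
    cutoff = float(bundle.global_fixed["zero_growth_cutoff_cm"])
    if d0 < cutoff:
        return 0.0, True
    bands = bundle.global_fixed["growth_bands"]
    chosen = bands[0]
    for b in bands:
        if d0 >= b["lower_cm"]:
            chosen = b
    slope = rng.normal(chosen["mean"], chosen["sd"])
    return max(slope, 0.0), False


def _rupture_cap(bundle: ParameterBundle) -> float:
    return bundle.life_table.max_age - bundle.invitation_age


def create_twin_pair(
    draw: GlobalUncertainDraw,
    bundle: ParameterBundle,
    rng: np.random.Generator,
    oversampling_plan=None,
    index: int = 0,
) -> TwinPair:
    """Generate the shared latent attributes of one twin pair.

    Draw order is fixed (diameter, growth rate, death time, censoring,
    rupture u, then the five Bernoulli indicators) so a given rng stream
    always yields the same pair regardless of downstream policy.
    """
    bd = bundle.global_fixed["baseline_diameter"]
    d0, weight = _sample_baseline_diameter(rng, bd["mu"], bd["sigma"], oversampling_plan)
    slope, zero_growth = _draw_growth_rate(rng, bundle, d0)
    traj = AortaTrajectory(d0, slope, zero_growth)

    death_t = bundle.life_table.sample_death_time(bundle.invitation_age, rng)

    cens = bundle.global_fixed["censoring"]
    if cens["kind"] == "uniform":
        censor_t = rng.uniform(cens["low"], cens["high"])
    else:
        censor_t = bundle.time_horizon_years

    # strictly interior uniform for the inverse-transform rupture draw
    u = rng.random()
    u = min(max(u, 1e-15), 1.0 - 1e-15)
    hz_cfg = bundle.global_fixed["rupture_hazard"]
    hz = RuptureHazardParams(
        hz_cfg["intercept"], hz_cfg["slope"], hz_cfg["reference_diameter_cm"]
    )
    rupture_t = sample_rupture_time(traj, hz, u, t_max=_rupture_cap(bundle))

    p_attend = bundle.value("attendance", draw)
    p_contra = bundle.value("p_contraindicated", draw)
    p_die_emerg = bundle.value("p_death_emergency", draw)
    p_evar = bundle.value("evar_proportion", draw)
    gets_evar = rng.random() < p_evar
    p_die_elect = bundle.value(
        "p_death_elective_evar" if gets_evar else "p_death_elective_open", draw
    )
    shared = SharedAttributes(
        trajectory=traj,
        non_aaa_death_time=death_t,
        rupture_time=rupture_t,
        rupture_u=u,
        censor_time=censor_t,
        would_attend=rng.random() < p_attend,
        contraindicated=rng.random() < p_contra,
        survives_emergency_surgery=rng.random() >= p_die_emerg,
        survives_elective_surgery=rng.random() >= p_die_elect,
        gets_evar=gets_evar,
    )
    return TwinPair(shared=shared, weight=weight, index=index)


def simulate_individual(
    pair: TwinPair,
    arm: str,
    policy: PolicySpec,
    draw: GlobalUncertainDraw,
    bundle: ParameterBundle,
    rng: np.random.Generator,
) -> IndividualRecord:
    """Run the event loop for one arm of a twin pair until death or censoring."""
    if arm not in (INVITED, NON_INVITED):
        raise ValueError(f"unknown arm {arm!r}")
    sh = pair.shared
    traj = sh.trajectory
    mm = MeasurementModel(
        ultrasound_sd=float(bundle.global_fixed["ultrasound_sd_cm"]),
        ct_sd=float(bundle.global_fixed["ct_sd_cm"]),
        ct_offset=float(bundle.global_fixed["ct_offset_cm"]),
    )
    wait1 = bundle.wait_discovery_to_consultation_years
    wait2 = bundle.wait_consultation_to_surgery_years
    p_dropout = bundle.value("p_dropout_per_visit", draw)
    p_emerg_access = bundle.value("prob_emergency_surgery_given_rupture", draw)
    incidental_rate = bundle.value("incidental_detection_rate_per_year", draw)
    t_diag_cross = time_to_threshold(traj, policy.diagnosis_threshold)

    # purpose-keyed substreams: the n-th measurement error, dropout decision,
    # incidental waiting time or emergency-access draw is the same number under
    # any policy run from the same master seed, which keeps common-random-number
    # policy comparisons tightly coupled even when pathways diverge.
    rng_measure, rng_dropout, rng_incidental, rng_emergency = rng.spawn(4)

    rec = IndividualRecord(arm=arm)
    fel = FutureEventList()
    fel.schedule(Event(sh.censor_time, "censor"))
    fel.schedule(Event(sh.non_aaa_death_time, "non_aaa_death"))
    if math.isfinite(sh.rupture_time):
        fel.schedule(Event(sh.rupture_time, "rupture"))

    def schedule_incidental(now: float) -> None:
        if not math.isfinite(t_diag_cross) or incidental_rate <= 0.0:
            return
        base = max(now, t_diag_cross)
        fel.schedule(
            Event(base + rng_incidental.exponential(1.0 / incidental_rate), "incidental_detection")
        )

    if arm == INVITED:
        fel.schedule(Event(0.0, "invitation"))
    schedule_incidental(0.0)

    # how the AAA was first detected ('screen' | 'incidental'); persists
    # through surveillance, cleared on discharge or loss to follow-up
    route = None

    def handle_scan(ev: Event, kind: str) -> None:
        nonlocal route
        true_d = diameter_at_time(traj, ev.time)
        m = measure_diameter(true_d, "ultrasound", mm, rng_measure)
        rec.events.append(Event(ev.time, kind, {"measured": m}))
        action = classify_measurement(policy, m)
        if action.kind == "discharge" and kind == "surveillance_scan":
            # a detected AAA stays under surveillance even when one scan reads
            # below the diagnosis threshold (measurement error, not regression);
            # rescan at the smallest band's interval
            action = Action("rescan", policy.surveillance_intervals[0])
        if action.kind == "refer":
            rec.detection_state = REFERRED
            if route is None:
                route = "screen"
            fel.cancel("incidental_detection")
            fel.schedule(Event(ev.time + wait1, "consultation", {"route": route}))
        elif action.kind == "rescan":
            rec.detection_state = UNDER_SURVEILLANCE
            if route is None:
                route = "screen"
            fel.cancel("incidental_detection")
            fel.schedule(Event(ev.time + action.interval, "surveillance_scan"))
        else:  # discharge: one-off, but incidental detection still applies
            rec.detection_state = DISCHARGED
            route = None
            if "incidental_detection" not in fel:
                schedule_incidental(ev.time)

    def exit_pathway() -> None:
        """Leave the AAA pathway for good (post-repair)."""
        for k in (
            "rupture",
            "incidental_detection",
            "surveillance_scan",
            "screen_scan",
            "consultation",
            "elective_surgery",
        ):
            fel.cancel(k)

    while True:
        ev = fel.pop_next()
        kind = ev.kind

        if kind == "censor":
            rec.events.append(ev)
            rec.alive_at_censor = True
            break

        if kind == "non_aaa_death":
            rec.events.append(ev)
            rec.death_time = ev.time
            break

        if kind == "invitation":
            rec.events.append(ev)  # invitation cost accrues regardless of attendance
            if sh.would_attend:
                fel.schedule(Event(ev.time, "screen_scan"))
            continue

        if kind == "screen_scan":
            handle_scan(ev, "screen_scan")
            continue

        if kind == "surveillance_scan":
            if rng_dropout.random() < p_dropout:
                # lost to recall follow-up: back to the incidental-detection process
                rec.events.append(Event(ev.time, "dropout"))
                rec.detection_state = UNDETECTED
                route = None
                schedule_incidental(ev.time)
            else:
                handle_scan(ev, "surveillance_scan")
            continue

        if kind == "incidental_detection":
            if rec.detection_state in (UNDETECTED, DISCHARGED):
                rec.events.append(ev)
                rec.detection_state = REFERRED
                route = "incidental"
                fel.schedule(Event(ev.time + wait1, "consultation", {"route": route}))
            continue

        if kind == "consultation":
            true_d = diameter_at_time(traj, ev.time)
            m = measure_diameter(true_d, "ct", mm, rng_measure)
            this_route = (ev.payload or {}).get("route", route)
            if m >= policy.referral_threshold:
                if sh.contraindicated:
                    rec.events.append(
                        Event(ev.time, "consultation",
                              {"measured": m, "route": this_route,
                               "outcome": "contraindicated"})
                    )
                    # unfit for repair: exits the programme, rupture risk persists
                    rec.detection_state = CONTRAINDICATED_EXIT
                else:
                    rec.events.append(
                        Event(ev.time, "consultation",
                              {"measured": m, "route": this_route, "outcome": "refer_surgery"})
                    )
                    fel.schedule(
                        Event(ev.time + wait2, "elective_surgery", {"route": this_route})
                    )
            else:
                action = classify_measurement(policy, m)
                rec.events.append(
                    Event(ev.time, "consultation",
                          {"measured": m, "route": this_route, "outcome": "return"})
                )
                # referred men return to surveillance; a sub-diagnosis CT
                # reading keeps them at the smallest band's interval
                interval = (
                    action.interval
                    if action.kind == "rescan"
                    else policy.surveillance_intervals[0]
                )
                rec.detection_state = UNDER_SURVEILLANCE
                fel.schedule(Event(ev.time + interval, "surveillance_scan"))
            continue

        if kind == "elective_surgery":
            modality = "evar" if sh.gets_evar else "open"
            rec.events.append(
                Event(ev.time, "elective_surgery",
                      {"modality": modality, "route": (ev.payload or {}).get("route")})
            )
            if sh.survives_elective_surgery:
                rec.detection_state = POST_REPAIR
                exit_pathway()
            else:
                rec.events.append(Event(ev.time, "aaa_death", {"cause": "elective_surgery"}))
                rec.death_time = ev.time
                break
            continue

        if kind == "rupture":
            rec.events.append(ev)
            if rng_emergency.random() < p_emerg_access:
                modality = "evar" if sh.gets_evar else "open"
                rec.events.append(
                    Event(ev.time, "emergency_surgery", {"modality": modality})
                )
                if sh.survives_emergency_surgery:
                    rec.detection_state = POST_REPAIR
                    exit_pathway()
                    continue
                rec.events.append(Event(ev.time, "aaa_death", {"cause": "emergency_surgery"}))
            else:
                rec.events.append(Event(ev.time, "aaa_death", {"cause": "unoperated_rupture"}))
            rec.death_time = ev.time
            break

        raise AssertionError(f"unhandled event kind {kind!r}")  # pragma: no cover

    return rec


def tally_record(record: IndividualRecord) -> Counter:
    """Event-category counts for one history (validation-table categories)."""
    c: Counter = Counter()
    for ev in record.events:
        k = ev.kind
        pl = ev.payload or {}
        if k == "elective_surgery":
            c["elective_operation"] += 1
            c[f"elective_operation_{pl.get('route') or 'screen'}"] += 1
        elif k == "emergency_surgery":
            c["emergency_operation"] += 1
        elif k == "rupture":
            c["rupture"] += 1
        elif k == "consultation" and pl.get("outcome") == "contraindicated":
            c["contraindicated"] += 1
            c[f"contraindicated_{pl.get('route') or 'screen'}"] += 1
        elif k == "aaa_death":
            c["aaa_death"] += 1
        elif k == "non_aaa_death":
            c["non_aaa_death"] += 1
        elif k == "dropout":
            c["loss_to_recall"] += 1
        elif k in ("invitation", "screen_scan", "surveillance_scan", "incidental_detection"):
            c[k] += 1
        elif k == "consultation":
            c["consultation"] += 1
    return c


@dataclass
class ArmSummary:
    """Weighted per-arm means of discounted cost, life-years and QALYs."""

    mean_cost: float
    mean_life_years: float
    mean_qalys: float
    event_counts: Counter


@dataclass
class MainResult:
    n_pairs: int
    invited: ArmSummary
    non_invited: ArmSummary
    sum_weights: float
    records: Optional[list[TwinPair]] = None

    def arm(self, arm: str) -> ArmSummary:
        return self.invited if arm == INVITED else self.non_invited


def _pair_streams(seed: int, index: int):
    """Latent / invited / non-invited rng streams for pair ``index``."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    latent, inv, non = ss.spawn(3)
    return (
        np.random.default_rng(latent),
        np.random.default_rng(inv),
        np.random.default_rng(non),
    )


def _simulate_chunk(lo, hi, seed, draw, bundle, policy, plan, costs, utilities,
                    rate_c, rate_e, collect):
    rows = np.empty((hi - lo, 7))
    counts_inv: Counter = Counter()
    counts_non: Counter = Counter()
    pairs = [] if collect else None
    for i in range(lo, hi):
        rng_latent, rng_inv, rng_non = _pair_streams(seed, i)
        pair = create_twin_pair(draw, bundle, rng_latent, plan, index=i)
        rec_inv = simulate_individual(pair, INVITED, policy, draw, bundle, rng_inv)
        rec_non = simulate_individual(pair, NON_INVITED, policy, draw, bundle, rng_non)
        ci, li, qi = economics.accrue(rec_inv, costs, utilities, rate_c, rate_e)
        cn, ln, qn = economics.accrue(rec_non, costs, utilities, rate_c, rate_e)
        rows[i - lo] = (pair.weight, ci, cn, li, ln, qi, qn)
        counts_inv.update(tally_record(rec_inv))
        counts_non.update(tally_record(rec_non))
        if collect:
            pair.invited = rec_inv
            pair.non_invited = rec_non
            pairs.append(pair)
    return rows, counts_inv, counts_non, pairs


def run_main_analysis(
    n_pairs: int,
    draw: GlobalUncertainDraw,
    bundle: ParameterBundle,
    policy: PolicySpec,
    seed: int,
    oversampling_plan=None,
    n_workers: int = 1,
    collect_records: bool = False,
    chunk_size: int = 4096,
) -> MainResult:
    """Simulate ``n_pairs`` twin pairs and return weighted per-arm summaries.

    Deterministic given ``seed`` and invariant to ``n_workers``: pairs are cut
    into fixed-size chunks whose per-chunk results are reduced in chunk order,
    so the floating-point summation order never depends on the worker count.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    costs = economics.CostSchedule.from_bundle(bundle, draw)
    utilities = economics.utility_array(
        bundle.global_fixed["utilities"], bundle.invitation_age, bundle.time_horizon_years
    )
    rate_c = float(bundle.global_fixed["discount_rate_costs"])
    rate_e = float(bundle.global_fixed["discount_rate_effects"])

    bounds = [(lo, min(lo + chunk_size, n_pairs)) for lo in range(0, n_pairs, chunk_size)]
    args = (seed, draw, bundle, policy, oversampling_plan, costs, utilities,
            rate_c, rate_e, collect_records)
    if n_workers > 1 and len(bounds) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_workers, backend="loky")(
            delayed(_simulate_chunk)(lo, hi, *args) for lo, hi in bounds
        )
    else:
        results = [_simulate_chunk(lo, hi, *args) for lo, hi in bounds]

    rows = np.concatenate([r[0] for r in results], axis=0)
    counts_inv: Counter = Counter()
    counts_non: Counter = Counter()
    all_pairs = [] if collect_records else None
    for _, ci, cn, pairs in results:
        counts_inv.update(ci)
        counts_non.update(cn)
        if collect_records:
            all_pairs.extend(pairs)

    w = rows[:, 0]
    sum_w = float(w.sum())
    # deterministic-normalization weighted means (unbiased under oversampling)
    means = rows[:, 1:] * w[:, None]
    m = means.sum(axis=0) / n_pairs
    invited = ArmSummary(m[0], m[2], m[4], counts_inv)
    non_invited = ArmSummary(m[1], m[3], m[5], counts_non)
    return MainResult(
        n_pairs=n_pairs,
        invited=invited,
        non_invited=non_invited,
        sum_weights=sum_w,
        records=all_pairs,
    )
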