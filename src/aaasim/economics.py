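"""Cost, life-year and QALY accrual, discounting, and incremental analysis.

Because the simulation is event-driven there are no cycles: costs attach to
exact event times and person-time is integrated continuously, so no
half-cycle correction is needed.  Discounting uses the annually-compounded
factor (1 + r)^(-t) evaluated at continuous t; discounted person-time over
[t0, t1] has the closed form ((1+r)^(-t0) - (1+r)^(-t1)) / log(1+r).

QALYs weight person-time by age-specific population-norm utilities applied
per integer year of age; no event-specific utility decrements are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CostSchedule",
    "CEResult",
    "discount_factor",
    "discounted_person_time",
    "utility_array",
    "accrue",
    "icer",
    "classify_icer",
    "inmb",
    "ceac",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
SOUTHWEST = "southwest"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs (GBP) attached to event occurrences."""

    invitation: float
    ultrasound_scan: float
    consultation: float
    elective_open: float
    elective_evar: float
    emergency_open: float
    emergency_evar: float

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) < 0:
                raise ValueError(f"cost {f!r} must be >= 0")

    @classmethod
    def from_bundle(cls, bundle, draw=None) -> "CostSchedule":
        return cls(**{f: bundle.cost(f, draw) for f in cls.__dataclass_fields__})


def discount_factor(t: float, rate: float) -> float:
    """(1 + rate)^(-t) at continuous time t (years)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0.0:
        return 1.0
    return math.exp(-t * math.log1p(rate))


def discounted_person_time(t0: float, t1: float, rate: float) -> float:
    """Integral of the discount factor over [t0, t1] (discounted years)."""
    if not 0 <= t0 <= t1:
        raise ValueError("need 0 <= t0 <= t1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0.0:
        return t1 - t0
    lr = math.log1p(rate)
    # expm1 keeps the small-rate limit (-> t1 - t0) numerically exact
    return -math.exp(-t0 * lr) * math.expm1(-(t1 - t0) * lr) / lr


def utility_array(bands: Sequence[dict], entry_age: float, horizon: float) -> np.ndarray:
    """Per-integer-age utility weights from ``entry_age`` to beyond the horizon.

    ``bands`` is a list of {'from_age': a, 'weight': w}, ordered by age; the
    weight applies from that age until the next band.
    """
    n = int(math.ceil(horizon)) + 1
    ages = entry_age + np.arange(n)
    out = np.empty(n)
    ordered = sorted(bands, key=lambda b: b["from_age"])
    if not ordered or ordered[0]["from_age"] > entry_age:
        raise ValueError("utility bands must cover the entry age")
    for b in ordered:
        out[ages >= b["from_age"]] = b["weight"]
    return out


# event kind -> CostSchedule attribute; surgery kinds resolved via payload
_EVENT_COST_ATTR = {
    "invitation": "invitation",
    "screen_scan": "ultrasound_scan",
    "surveillance_scan": "ultrasound_scan",
    "consultation": "consultation",
}


def event_cost(kind: str, payload: Optional[dict], costs: CostSchedule) -> float:
    attr = _EVENT_COST_ATTR.get(kind)
    if attr is not None:
        return getattr(costs, attr)
    if kind == "elective_surgery":
        return costs.elective_evar if payload and payload.get("modality") == "evar" else costs.elective_open
    if kind == "emergency_surgery":
        return costs.emergency_evar if payload and payload.get("modality") == "evar" else costs.emergency_open
    return 0.0


def accrue(
    record,
    costs: CostSchedule,
    utilities: np.ndarray | float,
    rate_costs: float,
    rate_effects: float,
) -> tuple[float, float, float]:
    """Discounted (cost, life-years, QALYs) for one simulated event history.

    ``utilities`` is either a scalar weight or the per-integer-year array from
    :func:`utility_array`, indexed by whole years since entry.
    """
    total_cost = 0.0
    for ev in record.events:
        c = event_cost(ev.kind, ev.payload, costs)
        if c:
            total_cost += c * discount_factor(ev.time, rate_costs)
    t_end = record.end_time
    life_years = discounted_person_time(0.0, t_end, rate_effects)
    if np.isscalar(utilities):
        qalys = float(utilities) * life_years
    else:
        qalys = 0.0
        k = 0
        while k < t_end:
            seg_end = min(k + 1.0, t_end)
            qalys += utilities[k] * discounted_person_time(k, seg_end, rate_effects)
            k += 1
    return total_cost, life_years, qalys


def classify_icer(delta_cost: float, delta_effect: float) -> tuple[str, float]:
    """Quadrant classification of an incremental (cost, effect) pair.

    Returns (label, value): label 'ratio' carries the plain ICER;
    'dominant' (strictly cheaper, no effect loss) carries -inf as a sortable
    stand-in; 'dominated' (effect loss or zero gain at positive cost) carries
    +inf; 'southwest' (cheaper but less effective) carries the ratio, which
    must be read as a cost saved per effect forgone; 'undefined' is the null
    comparison (0, 0).
    """
    if delta_cost == 0.0 and delta_effect == 0.0:
        return UNDEFINED, math.nan
    if delta_effect > 0.0 and delta_cost >= 0.0:
        return "ratio", delta_cost / delta_effect
    if delta_cost < 0.0 and delta_effect >= 0.0:
        return DOMINANT, -math.inf
    if delta_effect <= 0.0 and delta_cost >= 0.0:
        return DOMINATED, math.inf
    return SOUTHWEST, delta_cost / delta_effect


def icer(delta_cost: float, delta_effect: float):
    """ICER of an incremental pair: a ratio, or 'dominant'/'dominated'.

    A strictly cost-saving, non-harmful comparison returns the string
    'dominant'; effect loss at non-negative cost returns 'dominated'
    (treated as an infinite ICER in PSA summaries); the degenerate (0, 0)
    comparison returns 'undefined'.  The south-west quadrant returns the
    ratio value with a negative-effect caveat left to the caller.
    """
    label, value = classify_icer(delta_cost, delta_effect)
    if label in ("ratio", SOUTHWEST):
        return value
    return label


def inmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Incremental net monetary benefit lambda*dE - dC at willingness-to-pay lambda."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_effect - delta_cost


def ceac(increments: Sequence[tuple[float, float]], wtp_grid: Sequence[float]) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of PSA samples
    (delta_cost, delta_effect) with positive INMB.
    """
    if len(increments) == 0:
        raise ValueError("need at least one PSA sample")
    dc = np.array([x[0] for x in increments])
    de = np.array([x[1] for x in increments])
    grid = np.asarray(wtp_grid, dtype=float)
    return np.array([(lam * de - dc > 0).mean() for lam in grid])


@dataclass
class CEResult:
    """Incremental cost-effectiveness comparison of two strategies."""

    cost_ref: float
    effect_ref: float
    cost_alt: float
    effect_alt: float
    wtp: float = 20000.0
    label_ref: str = "reference"
    label_alt: str = "alternative"
    lifeyears_ref: Optional[float] = None
    lifeyears_alt: Optional[float] = None
    psa_intervals: dict = field(default_factory=dict)

    @property
    def delta_cost(self) -> float:
        return self.cost_alt - self.cost_ref

    @property
    def delta_effect(self) -> float:
        return self.effect_alt - self.effect_ref

    @property
    def icer(self):
        return icer(self.delta_cost, self.delta_effect)

    @property
    def icer_class(self) -> str:
        return classify_icer(self.delta_cost, self.delta_effect)[0]

    @property
    def inmb(self) -> float:
        return inmb(self.delta_cost, self.delta_effect, self.wtp)

    def to_dict(self) -> dict:
        ic = self.icer
        return {
            "reference": self.label_ref,
            "alternative": self.label_alt,
            "cost_reference": self.cost_ref,
            "cost_alternative": self.cost_alt,
            "effect_reference": self.effect_ref,
            "effect_alternative": self.effect_alt,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": ic if not isinstance(ic, str) else ic,
            "icer_class": self.icer_class,
            "wtp": self.wtp,
            "inmb": self.inmb,
            **self.psa_intervals,
        }
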