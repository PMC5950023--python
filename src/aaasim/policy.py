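"""Declarative screening/surveillance policies.

A policy partitions the measured-diameter axis into half-open bands
[lower, next_lower) with one action per band: below the diagnosis threshold a
man is discharged, within a surveillance band he is rescanned after the
band's interval, and at or above the referral threshold he is referred for a
surgical consultation.  Changing a surveillance protocol is just editing the
threshold and interval lists — e.g. extending surveillance to sub-aneurysmal
aortas means inserting 2.5 into the thresholds and 5 (years) into the
intervals.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional

__all__ = ["Action", "PolicySpec", "classify_measurement", "builtin_policy", "BUILTIN_POLICIES"]


@dataclass(frozen=True)
class Action:
    """Outcome of classifying one measurement: discharge, rescan or refer."""

    kind: str  # 'discharge' | 'rescan' | 'refer'
    interval: Optional[float] = None  # years until next scan, for 'rescan'


@dataclass(frozen=True)
class PolicySpec:
    """Surveillance band partition plus invitation age and referral threshold."""

    name: str
    surveillance_thresholds: tuple[float, ...]
    surveillance_intervals: tuple[float, ...]
    referral_threshold: float
    invitation_age: float = 65.0

    def __post_init__(self) -> None:
        th = tuple(float(x) for x in self.surveillance_thresholds)
        iv = tuple(float(x) for x in self.surveillance_intervals)
        object.__setattr__(self, "surveillance_thresholds", th)
        object.__setattr__(self, "surveillance_intervals", iv)
        if not th:
            raise ValueError("need at least one surveillance threshold")
        if len(th) != len(iv):
            raise ValueError(
                f"{len(th)} thresholds but {len(iv)} intervals; lists must align"
            )
        if list(th) != sorted(set(th)):
            raise ValueError("surveillance thresholds must be strictly increasing")
        if any(i <= 0 for i in iv):
            raise ValueError("surveillance intervals must be positive")
        if self.referral_threshold <= th[-1]:
            raise ValueError("referral threshold must exceed the last surveillance band edge")

    @property
    def diagnosis_threshold(self) -> float:
        """Smallest measured diameter entering surveillance."""
        return self.surveillance_thresholds[0]


def classify_measurement(policy: PolicySpec, measured_d: float) -> Action:
    """Map one measured diameter to the policy's action (total, deterministic)."""
    if measured_d < 0:
        raise ValueError("measured diameter must be >= 0")
    if measured_d >= policy.referral_threshold:
        return Action("refer")
    if measured_d < policy.diagnosis_threshold:
        return Action("discharge")
    i = bisect_right(policy.surveillance_thresholds, measured_d) - 1
    return Action("rescan", policy.surveillance_intervals[i])


BUILTIN_POLICIES: dict[str, PolicySpec] = {
    # current NAAASP programme: 1-y rescans for 3.0-4.4 cm, 3-mo for 4.5-5.4 cm,
    # refer at 5.5 cm
    "current": PolicySpec(
        name="current",
        surveillance_thresholds=(3.0, 4.5),
        surveillance_intervals=(1.0, 0.25),
        referral_threshold=5.5,
    ),
    # lengthened interval for the smallest AAAs: 2-y for 3.0-3.9 cm
    "scenario1": PolicySpec(
        name="scenario1",
        surveillance_thresholds=(3.0, 4.0, 4.5),
        surveillance_intervals=(2.0, 1.0, 0.25),
        referral_threshold=5.5,
    ),
    # sub-aneurysmal surveillance: diagnosis lowered to 2.5 cm, 5-y rescans
    # for 2.5-2.9 cm, current intervals above 3.0 cm
    "scenario2": PolicySpec(
        name="scenario2",
        surveillance_thresholds=(2.5, 3.0, 4.5),
        surveillance_intervals=(5.0, 1.0, 0.25),
        referral_threshold=5.5,
    ),
}


def builtin_policy(name: str) -> PolicySpec:
    """Look up a built-in policy by name ('current', 'scenario1', 'scenario2')."""
    try:
        return BUILTIN_POLICIES[name]
    except KeyError:
        raise ValueError(
            f"unknown policy {name!r}; valid names: {sorted(BUILTIN_POLICIES)}"
        ) from None
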