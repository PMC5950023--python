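"""Validation surfaces against MASS-trial-style observed data.

The 4-y validation re-creates the trial design: group sizes of 33,961
(control) and 33,839 (invited), censoring at Uniform(3, 5.25) years shared
within a pair (the trial's "4-y" follow-up had censoring times close to this
distribution), life-years discounted at 1.5%/y and costs at 6%/y.  Outputs
are event-count tables by arm and category, ratios of simulated to observed
counts (as rounded percentages), per-arm cost/life-year summaries, and
cumulative event curves.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    INVITED,
    NON_INVITED,
    IndividualRecord,
    MainResult,
    run_main_analysis,
    tally_record,
)
from .parameters import GlobalUncertainDraw, ParameterBundle, fix_bundle_at_means
from .policy import PolicySpec, builtin_policy

__all__ = [
    "TABLE2_CATEGORIES",
    "MASS_4Y_OBSERVED",
    "MASS_GROUP_SIZES",
    "mass_censoring_times",
    "event_count_table",
    "percent_of_observed",
    "cumulative_event_curve",
    "run_mass_validation",
]

#: categories of the key-event table, per arm
TABLE2_CATEGORIES = (
    "elective_operation",
    "elective_operation_screen",
    "elective_operation_incidental",
    "emergency_operation",
    "rupture",
    "contraindicated",
    "contraindicated_screen",
    "contraindicated_incidental",
    "aaa_death",
    "non_aaa_death",
    "loss_to_recall",
)

#: key events observed in the MASS 4-y follow-up (trial-reported counts,
#: used as comparison data only)
MASS_4Y_OBSERVED = {
    NON_INVITED: {
        "elective_operation": 100,
        "emergency_operation": 62,
        "rupture": 138,
        "aaa_death": 113,
        "non_aaa_death": 3750,
    },
    INVITED: {
        "elective_operation_screen": 295,
        "elective_operation_incidental": 31,
        "emergency_operation": 28,
        "rupture": 66,
        "contraindicated_screen": 41,
        "aaa_death": 65,
        "non_aaa_death": 3694,
        "loss_to_recall": 290,
    },
}

#: trial group sizes (control, invited)
MASS_GROUP_SIZES = (33961, 33839)


def mass_censoring_times(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent Uniform(3, 5.25)-year censoring times (one per pair)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.uniform(3.0, 5.25, size=n)


def event_count_table(
    records_by_arm: dict[str, Iterable[IndividualRecord]],
    categories: Sequence[str] = TABLE2_CATEGORIES,
) -> pd.DataFrame:
    """Integer event counts per arm and category.

    Each individual contributes once per realized event (an individual with
    several dropout events counts several times in loss_to_recall).
    """
    unknown = [c for c in categories if c not in TABLE2_CATEGORIES]
    if unknown:
        raise ValueError(
            f"unknown categories {unknown}; valid: {list(TABLE2_CATEGORIES)}"
        )
    data = {}
    for arm, records in records_by_arm.items():
        tally = sum((tally_record(r) for r in records), start=Counter())
        data[arm] = [int(tally.get(c, 0)) for c in categories]
    return pd.DataFrame(data, index=list(categories))


def percent_of_observed(model_count: float, observed_count: float) -> Optional[int]:
    """round(100 * model / observed) to the nearest integer, half away from zero.

    Returns None (reported as not-available) when the observed count is zero.
    """
    if observed_count == 0:
        return None
    x = 100.0 * model_count / observed_count
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cumulative_event_curve(
    records: Iterable[IndividualRecord], kind: str, arm: Optional[str] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Non-decreasing step function (times, cumulative counts) for one event kind.

    The final value equals the corresponding event-count-table entry.
    """
    times = []
    for r in records:
        if arm is not None and r.arm != arm:
            continue
        for ev in r.events:
            if ev.kind == kind:
                times.append(ev.time)
    t = np.sort(np.asarray(times, dtype=float))
    uniq, counts = np.unique(t, return_counts=True)
    return uniq, np.cumsum(counts)


def run_mass_validation(
    bundle: ParameterBundle,
    n_pairs: int,
    seed: int,
    draw: Optional[GlobalUncertainDraw] = None,
    policy: Optional[PolicySpec] = None,
    n_workers: int = 1,
    collect_records: bool = False,
) -> tuple[MainResult, pd.DataFrame, pd.DataFrame]:
    """MASS-style validation run (no oversampling; raw event counts).

    Returns the main result, the event-count table with percent-of-observed
    columns scaled to the trial group sizes, and a cost/life-year summary
    table in the trial layout.
    """
    if draw is None:
        draw = fix_bundle_at_means(bundle)
    if policy is None:
        policy = builtin_policy(str(bundle.global_fixed.get("policy", "current")))
    res = run_main_analysis(
        n_pairs, draw, bundle, policy, seed,
        oversampling_plan=None, n_workers=n_workers, collect_records=collect_records,
    )
    # scale simulated counts to the trial group sizes before comparing
    scale = {NON_INVITED: MASS_GROUP_SIZES[0] / n_pairs, INVITED: MASS_GROUP_SIZES[1] / n_pairs}
    rows = []
    for arm in (NON_INVITED, INVITED):
        counts = res.arm(arm).event_counts
        observed = MASS_4Y_OBSERVED[arm]
        for cat in TABLE2_CATEGORIES:
            model = counts.get(cat, 0) * scale[arm]
            obs = observed.get(cat)
            rows.append(
                {
                    "arm": arm,
                    "category": cat,
                    "model_count": round(model),
                    "observed_count": obs,
                    "percent_of_observed": (
                        percent_of_observed(model, obs) if obs else None
                    ),
                }
            )
    events = pd.DataFrame(rows)

    summary = pd.DataFrame(
        {
            "life_years": [res.non_invited.mean_life_years, res.invited.mean_life_years],
            "cost": [res.non_invited.mean_cost, res.invited.mean_cost],
        },
        index=[NON_INVITED, INVITED],
    )
    summary.loc["difference"] = summary.loc[INVITED] - summary.loc[NON_INVITED]
    return res, events, summary
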