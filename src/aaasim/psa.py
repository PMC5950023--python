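"""Probabilistic sensitivity analysis, oversampling, and policy comparison.

Model outputs are driven almost entirely by the small fraction of men with an
AAA at baseline, so AAA-stratum baselines are oversampled and every summary
reweighted to restore population proportions — a large Monte Carlo variance
reduction at fixed pair count.  PSA repeats the main analysis under fresh
draws of the global uncertain parameters; percentile intervals and the
cost-effectiveness acceptability curve summarize the resulting distribution
of incremental costs and effects.  Policy comparisons reuse one master seed
for both policies (common random numbers): the twin-pair latent streams are
identical, so between-policy differences are driven by the policies alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import economics
from .economics import CEResult
from .engine import MainResult, run_main_analysis
from .parameters import (
    GlobalUncertainDraw,
    ParameterBundle,
    draw_global_uncertain,
    fix_bundle_at_means,
)
from .policy import PolicySpec

__all__ = [
    "OversamplingPlan",
    "PSAResult",
    "simulate_with_oversampling",
    "run_psa",
    "compare_policies",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class OversamplingPlan:
    """Stratified oversampling of baselines above a diameter threshold.

    ``multiplier`` k >= 1 multiplies the sampling *odds* of the AAA stratum
    (population prevalence ``prevalence`` = P(D0 >= threshold)), giving
    sampling probability q = kp / (1 + (k-1)p).  Oversampled pairs carry
    weight (1 + (k-1)p)/k and the rest 1 + (k-1)p, so the weighted stratum
    proportions equal the population prevalence exactly and weighted means
    are unbiased.
    """

    stratum_threshold: float
    multiplier: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.multiplier < 1.0:
            raise ValueError("oversampling multiplier must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def sampling_probability(self) -> float:
        k, p = self.multiplier, self.prevalence
        return k * p / (1.0 + (k - 1.0) * p)

    @property
    def weight_oversampled(self) -> float:
        k, p = self.multiplier, self.prevalence
        return (1.0 + (k - 1.0) * p) / k

    @property
    def weight_rest(self) -> float:
        k, p = self.multiplier, self.prevalence
        return 1.0 + (k - 1.0) * p

    @classmethod
    def from_bundle(
        cls, bundle: ParameterBundle, multiplier: Optional[float] = None
    ) -> "OversamplingPlan":
        """Plan for a bundle; default multiplier targets the configured stratum share."""
        cfg = bundle.global_fixed["oversampling"]
        thr = float(cfg["stratum_threshold_cm"])
        bd = bundle.global_fixed["baseline_diameter"]
        p = 1.0 - float(ndtr((math.log(thr) - bd["mu"]) / bd["sigma"]))
        if multiplier is None:
            target = float(cfg.get("target_stratum_fraction", 0.5))
            # q = target  =>  k = target(1-p) / ((1-target) p)
            multiplier = max(1.0, target * (1.0 - p) / ((1.0 - target) * p))
        return cls(stratum_threshold=thr, multiplier=float(multiplier), prevalence=p)


def simulate_with_oversampling(
    n_pairs: int,
    plan: OversamplingPlan,
    draw: GlobalUncertainDraw,
    bundle: ParameterBundle,
    policy: PolicySpec,
    seed: int,
    **kwargs,
) -> MainResult:
    """Main analysis with AAA-stratum oversampling and reweighted summaries."""
    return run_main_analysis(
        n_pairs, draw, bundle, policy, seed, oversampling_plan=plan, **kwargs
    )


def default_wtp_grid() -> np.ndarray:
    return np.arange(0.0, 50001.0, 1000.0)


@dataclass
class PSAResult:
    """Per-iteration incrementals and their summaries."""

    iterations: pd.DataFrame  # delta_cost, delta_qalys, delta_life_years, icer, inmb
    wtp: float
    wtp_grid: np.ndarray
    ceac: np.ndarray
    seed: int = 0

    @property
    def mean_delta_cost(self) -> float:
        return float(self.iterations["delta_cost"].mean())

    @property
    def mean_delta_qalys(self) -> float:
        return float(self.iterations["delta_qalys"].mean())

    @property
    def mean_delta_life_years(self) -> float:
        return float(self.iterations["delta_life_years"].mean())

    @property
    def mean_inmb(self) -> float:
        return float(self.iterations["inmb"].mean())

    def percentile_interval(self, column: str, level: float = 0.95) -> tuple[float, float]:
        """Central percentile interval; infinite ICERs sort above all finite values."""
        x = np.asarray(self.iterations[column], dtype=float)
        lo = (1.0 - level) / 2.0
        # interpolation is undefined against +/-inf; fall back to order
        # statistics so an infinite ICER propagates into the tail
        method = "linear" if np.all(np.isfinite(x)) else "nearest"
        return (
            float(np.quantile(x, lo, method=method)),
            float(np.quantile(x, 1.0 - lo, method=method)),
        )

    def prob_cost_effective(self, wtp: Optional[float] = None) -> float:
        lam = self.wtp if wtp is None else wtp
        dc = self.iterations["delta_cost"].to_numpy()
        de = self.iterations["delta_qalys"].to_numpy()
        return float((lam * de - dc > 0).mean())


def _iteration_increments(res: MainResult) -> tuple[float, float, float]:
    dc = res.invited.mean_cost - res.non_invited.mean_cost
    dq = res.invited.mean_qalys - res.non_invited.mean_qalys
    dly = res.invited.mean_life_years - res.non_invited.mean_life_years
    return dc, dq, dly


def run_psa(
    n_iterations: int,
    n_pairs: int,
    bundle: ParameterBundle,
    policy: PolicySpec,
    seed: int,
    wtp: float = 20000.0,
    wtp_grid: Optional[Sequence[float]] = None,
    oversampling_plan: Optional[OversamplingPlan] = None,
    n_workers: int = 1,
) -> PSAResult:
    """PSA: repeat the main analysis under fresh global-uncertain draws.

    Iteration i uses parameter-draw and simulation seeds derived from the
    master seed by SeedSequence spawning, so the whole PSA is reproducible
    and independent of worker count.  ICERs with effect loss at positive cost
    are recorded as +inf before interval computation.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if oversampling_plan is None:
        oversampling_plan = OversamplingPlan.from_bundle(bundle)
    rows = []
    for i in range(n_iterations):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(1_000_000 + i,))
        draw_ss, sim_ss = ss.spawn(2)
        draw = draw_global_uncertain(bundle, draw_ss, draw_index=i)
        sim_seed = int(sim_ss.generate_state(1, np.uint32)[0])
        res = run_main_analysis(
            n_pairs, draw, bundle, policy, sim_seed,
            oversampling_plan=oversampling_plan, n_workers=n_workers,
        )
        dc, dq, dly = _iteration_increments(res)
        label, icer_val = economics.classify_icer(dc, dq)
        if label == economics.DOMINANT:
            icer_val = -math.inf
        rows.append(
            {
                "iteration": i,
                "delta_cost": dc,
                "delta_qalys": dq,
                "delta_life_years": dly,
                "icer": icer_val,
                "icer_class": label,
                "inmb": economics.inmb(dc, dq, wtp),
            }
        )
    df = pd.DataFrame(rows)
    grid = np.asarray(wtp_grid if wtp_grid is not None else default_wtp_grid(), float)
    curve = economics.ceac(list(zip(df["delta_cost"], df["delta_qalys"])), grid)
    return PSAResult(iterations=df, wtp=wtp, wtp_grid=grid, ceac=curve, seed=seed)


def compare_policies(
    policy_a: PolicySpec,
    policy_b: PolicySpec,
    n_pairs: int,
    bundle: ParameterBundle,
    seed: int,
    draw: Optional[GlobalUncertainDraw] = None,
    wtp: float = 20000.0,
    oversampling_plan: Optional[OversamplingPlan] = None,
    n_workers: int = 1,
) -> CEResult:
    """Incremental comparison of policy_b against policy_a under common random numbers.

    Both policies run on identical twin-pair streams (same master seed); the
    result compares the two policies' own (invited - non-invited) increments,
    i.e. the additional cost and effect of running programme b instead of a.
    """
    if draw is None:
        draw = fix_bundle_at_means(bundle)
    if oversampling_plan is None:
        oversampling_plan = OversamplingPlan.from_bundle(bundle)
    res_a = run_main_analysis(
        n_pairs, draw, bundle, policy_a, seed,
        oversampling_plan=oversampling_plan, n_workers=n_workers,
    )
    res_b = run_main_analysis(
        n_pairs, draw, bundle, policy_b, seed,
        oversampling_plan=oversampling_plan, n_workers=n_workers,
    )
    dca, dqa, dla = _iteration_increments(res_a)
    dcb, dqb, dlb = _iteration_increments(res_b)
    return CEResult(
        cost_ref=dca,
        effect_ref=dqa,
        cost_alt=dcb,
        effect_alt=dqb,
        wtp=wtp,
        label_ref=policy_a.name,
        label_alt=policy_b.name,
        lifeyears_ref=dla,
        lifeyears_alt=dlb,
    )
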