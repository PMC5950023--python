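"""Joint continuous-time aortic growth and rupture model.

Each individual carries a latent trajectory: a baseline diameter drawn from
the population distribution and a latent growth rate acting multiplicatively,

    D(t) = D0 * exp(beta * t),

i.e. linear growth on the log-diameter scale.  Individuals below a cutoff
(2.0 cm by default) do not grow at all.  Rupture follows an inhomogeneous
Poisson first-event process whose hazard is log-linear in the current true
diameter,

    h(d) = exp(intercept + slope * (d - d_ref)),

so the cumulative hazard along a growing trajectory,

    H(t) = int_0^t h(D(s)) ds,

has a closed form in terms of the exponential integral Ei:
substituting u = D0 * exp(beta * s) gives
H(t) = exp(intercept - slope * d_ref) / beta * [Ei(slope*D(t)) - Ei(slope*D0)].
Rupture times are sampled by inverse transform, solving H(t) = -log(u) by
monotone bisection; times whose cumulative hazard never reaches the target
before a hard age cap are reported as "never" (math.inf).

Scan measurements add a fresh, event-specific error per call: ultrasound is
unbiased; CT reads an offset (0.24 cm by default) larger than ultrasound
because it measures outer-to-outer rather than inner-to-inner diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expi

__all__ = [
    "NEVER",
    "AortaTrajectory",
    "RuptureHazardParams",
    "MeasurementModel",
    "diameter_at_time",
    "time_to_threshold",
    "cumulative_rupture_hazard",
    "sample_rupture_time",
    "measure_diameter",
]

NEVER = math.inf

#: inversion tolerance for rupture-time sampling (years)
_TIME_TOL = 1e-9
#: arguments beyond this overflow exp(); treat the hazard integral as +inf
_EXP_OVERFLOW = 700.0


@dataclass(frozen=True)
class AortaTrajectory:
    """Latent aortic growth curve for one individual (shared by a twin pair)."""

    baseline_diameter: float
    log_growth_rate: float
    zero_growth: bool = False

    def __post_init__(self) -> None:
        if self.baseline_diameter <= 0:
            raise ValueError("baseline_diameter must be positive")


@dataclass(frozen=True)
class RuptureHazardParams:
    """Log-linear diameter-dependent rupture hazard."""

    intercept: float
    slope: float
    reference_diameter: float

    def hazard(self, d: float) -> float:
        x = self.intercept + self.slope * (d - self.reference_diameter)
        return math.exp(min(x, _EXP_OVERFLOW))


@dataclass(frozen=True)
class MeasurementModel:
    """Scan measurement-error model (event-specific errors)."""

    ultrasound_sd: float
    ct_sd: float
    ct_offset: float

    def __post_init__(self) -> None:
        if self.ultrasound_sd < 0 or self.ct_sd < 0:
            raise ValueError("measurement SDs must be >= 0")


def diameter_at_time(traj: AortaTrajectory, t: float) -> float:
    """True aortic diameter (cm) at ``t`` years after entry."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if traj.zero_growth:
        return traj.baseline_diameter
    return traj.baseline_diameter * math.exp(traj.log_growth_rate * t)


def time_to_threshold(traj: AortaTrajectory, threshold: float) -> float:
    """Smallest t >= 0 with D(t) >= threshold, or NEVER if unreachable."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if traj.baseline_diameter >= threshold:
        return 0.0
    if traj.zero_growth or traj.log_growth_rate <= 0:
        return NEVER
    return math.log(threshold / traj.baseline_diameter) / traj.log_growth_rate


def cumulative_rupture_hazard(
    traj: AortaTrajectory, hz: RuptureHazardParams, t: float
) -> float:
    """H(t) = int_0^t h(D(s)) ds, in closed form (may be inf on overflow)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    beta = 0.0 if traj.zero_growth else traj.log_growth_rate
    b = hz.slope
    if beta == 0.0 or b == 0.0:
        return t * hz.hazard(traj.baseline_diameter)
    d0 = traj.baseline_diameter
    dt_exp = beta * t
    if dt_exp > _EXP_OVERFLOW:
        return math.inf
    d_t = d0 * math.exp(dt_exp)
    if b * d_t > _EXP_OVERFLOW:
        return math.inf
    c = math.exp(hz.intercept - b * hz.reference_diameter) / beta
    val = c * (expi(b * d_t) - expi(b * d0))
    return float(val)


def sample_rupture_time(
    traj: AortaTrajectory,
    hz: RuptureHazardParams,
    u: float,
    t_max: float = 85.0,
) -> float:
    """Inverse-transform sample of the rupture time.

    Solves H(t) = -log(u) by bisection on [0, t_max]; returns NEVER when the
    cumulative hazard up to ``t_max`` (the age cap) never reaches the target.
    ``u`` is a Uniform(0, 1) draw; larger u means earlier rupture.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie strictly in (0, 1)")
    target = -math.log(u)
    h_max = cumulative_rupture_hazard(traj, hz, t_max)
    if h_max < target:
        return NEVER
    lo, hi = 0.0, t_max
    while hi - lo > _TIME_TOL:
        mid = 0.5 * (lo + hi)
        if cumulative_rupture_hazard(traj, hz, mid) >= target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def measure_diameter(
    true_d: float,
    modality: str,
    mm: MeasurementModel,
    rng: np.random.Generator,
) -> float:
    """One scan measurement of a true diameter, truncated below at 0."""
    if true_d < 0:
        raise ValueError("true_d must be >= 0")
    if modality == "ultrasound":
        m = true_d + rng.normal(0.0, mm.ultrasound_sd) if mm.ultrasound_sd > 0 else true_d
    elif modality == "ct":
        m = true_d + mm.ct_offset
        if mm.ct_sd > 0:
            m += rng.normal(0.0, mm.ct_sd)
    else:
        raise ValueError(f"unknown modality {modality!r}; expected 'ultrasound' or 'ct'")
    return max(m, 0.0)
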