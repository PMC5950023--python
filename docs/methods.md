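# Methods

## Scope and design

`aaasim` is an event-scheduling microsimulation of AAA screening. Each
simulated man owns a future event list (FEL) with at most one pending event
per kind; the clock repeatedly pops the earliest pending event (time ties
broken by a fixed kind priority: non-AAA death, rupture, AAA death, emergency
surgery, elective surgery, consultation, incidental detection, scans,
invitation, dropout, censor — deaths first, censoring last) and lets the
handler schedule, reschedule or cancel other events, until a death or the
censoring event terminates the history. There are no cycles and no health
states: diameter is continuous, and every cost and person-time quantity
accrues at exact event times.

Men are simulated as matched twin pairs (invited / not invited) sharing all
latent attributes that do not depend on the programme: baseline diameter,
latent growth rate, non-AAA death time, the uniform variate behind the
rupture time, the censoring time, and five Bernoulli indicators (would
attend, contraindicated for surgery, would survive emergency surgery, would
survive elective surgery, repaired by EVAR). The shared record is a frozen
object; both arms read it and it is never mutated. Incremental estimates are
therefore differences of strongly positively correlated quantities, which is
what makes policy questions answerable at 10^4–10^5 pairs rather than 10^7.

## Growth and rupture

Aortic diameter follows log-linear growth, `D(t) = D0 exp(beta t)`, with
`beta` drawn per individual from a normal distribution whose mean/SD depend
on the baseline-diameter band (negative draws truncated to zero), and
`beta = 0` below the 2.0 cm zero-growth cutoff. This form admits closed-form
threshold crossing, `t* = log(c/D0)/beta`, used both for referral logic and
to gate incidental detection.

Rupture is the first event of an inhomogeneous Poisson process with hazard
log-linear in the current true diameter,

    h(d) = exp(a + b (d − d_ref)),   d_ref = 5.5 cm.

Substituting the trajectory gives a cumulative hazard in closed form via the
exponential integral:

    H(t) = exp(a − b d_ref)/beta · [Ei(b D(t)) − Ei(b D0)]   (beta, b > 0),

with the constant-hazard form `H(t) = t·h(D0)` when either slope is zero.
Rupture times are sampled by inverse transform, solving `H(t) = −log u` by
monotone bisection to 1e-9 y on [0, t_cap]; `t_cap` is age 150. When
`H(t_cap) < −log u` the rupture is "never" (+inf), the common case — most
aortas never reach dangerous diameters. Arguments that would overflow
`exp` are treated as an infinite integral, which the bisection handles
transparently. The test suite checks the sampler against an independent
quadrature-plus-root-finding oracle (`scipy.integrate.quad` + `brentq`) to
1e-6 y and checks the implied survival function against `exp(−H(t))`.

Scans add a fresh, event-specific measurement error: ultrasound
`N(0, 0.2 cm)`, CT `0.24 + N(0, 0.2) cm` (CT measures outer-to-outer
diameters). Errors are independent across scans.

## Policies

A policy is an ordered list of diameter cut-points with one rescan interval
per band, a diagnosis threshold (the first cut-point) and a referral
threshold. Bands are half-open `[a, b)`, making classification total and
deterministic. Built-ins: `current` (3.0–4.4 cm yearly, 4.5–5.4 cm
3-monthly, refer at 5.5), `scenario1` (3.0–3.9 cm 2-yearly, 4.0–4.4 yearly,
4.5–5.4 3-monthly), `scenario2` (diagnosis lowered to 2.5 cm with 5-yearly
rescans below 3.0 cm, current bands above).

At a *screening* scan, a measurement below the diagnosis threshold means
discharge (permanent, except for the incidental-detection process). At a
*surveillance* rescan, a measurement below the diagnosis threshold keeps the
man under surveillance at the smallest band's interval rather than
discharging him: with a 0.2 cm measurement SD, borderline 3.0–3.3 cm AAAs
would otherwise churn out of surveillance at a rate proportional to the scan
frequency, so that comparing rescan intervals would mostly compare discharge
rates — an artifact, and not how surveillance programmes treat a single
sub-threshold reading on an established AAA.

Incidental detection (discovery outside the programme) is a constant-rate
exponential clock that can only fire after the trajectory crosses the
diagnosis threshold; it applies in both arms to anyone not currently under
surveillance, and leads to the same consultation pathway. Referral uses the
measured (not true) diameter; consultation happens 71 days after discovery
and elective surgery 59 days after consultation. Surgical contraindication
is evaluated once, at the first consultation, from the shared indicator;
contraindicated men exit the pathway but keep their rupture risk. After a
successful repair (elective, or emergency following rupture — offered with a
configured probability) no further AAA events occur: there is no
re-intervention or post-EVAR surveillance pathway.

Dropout from surveillance ("loss to recall") is a per-scheduled-visit
Bernoulli; lost men revert to the incidental-detection process.

## Parameters

Parameters form a strict hierarchy: global fixed (scalars and structures in
the bundle), global uncertain (distribution specs drawn once per PSA
iteration: beta for probabilities, normal/lognormal/gamma/point-mass
otherwise), pair-specific latents, the individual's arm, and event-specific
measurement errors. Bundles are single YAML files; days are converted to
years (365.25 d/y) on load; unknown or missing keys are rejected by name.
Costs are global fixed by default, and any cost can be made uncertain by
adding a `cost_<item>` spec.

The two shipped bundles are *documented approximations* of their settings —
each value carries a provenance note in the file, and nothing downstream
asserts their exactness:

* `mass-validation` — trial-era 4-y configuration: ~4.9% prevalence
  (lognormal μ=0.183, σ=0.554 on log-cm), attendance ~80%, 7%/visit loss to
  recall, open repair only (elective 30-d mortality ~6%, emergency ~37%),
  Gompertz non-AAA mortality ≈2.3%/y at 65, costs in 2000s GBP, life-years
  discounted at 1.5%/y and costs at 6%/y, censoring Uniform(3, 5.25) y
  shared within a pair, utilities ≡ 1 (life-years).
* `naaasp-basecase` — contemporary 30-y configuration: ~1.6% prevalence
  (μ=0.134, σ=0.45), attendance ~75%, 1%/visit surveillance loss (recall
  systems re-book most non-attendances), 60% EVAR (elective mortality: open
  4.2%, EVAR 1.6%), Gompertz non-AAA mortality ≈1.2%/y at 65,
  population-norm utilities by age band (0.78 / 0.75 / 0.71), both discount
  rates 3.5%/y, 30-y horizon.

The rupture hazard uses steepness from surveillance meta-analyses — rupture
rates roughly double per 0.27 cm of diameter (`b = 2.6 /cm`), anchored at
~3.5%/y (base case) to ~5%/y (trial era) at 5.5 cm. Growth-rate bands:
mean 0.020/y (SD 0.010) on the log scale for 2.0–2.9 cm baselines, 0.055/y
(SD 0.025) at 3.0 cm and above.

## Economics

Discounting uses the annually-compounded factor `(1+r)^{−t}` at continuous
`t`; discounted person-time over `[t0, t1]` is
`((1+r)^{−t0} − (1+r)^{−t1})/log(1+r)` (computed with `expm1` so the r → 0
limit is exact). QALYs multiply person-time in each integer year of age by
that age's utility weight; no event-related utility decrements are applied.
ICERs are classified by quadrant: a ratio for ΔE > 0, ΔC ≥ 0; *dominant* for
strict cost saving without effect loss; *dominated* (infinite ICER) for
effect loss — or zero effect gain — at positive cost; the south-west
quadrant returns a flagged ratio. The CEAC reports, per willingness-to-pay
λ, the fraction of PSA samples with `λ·ΔE − ΔC > 0`.

## Oversampling and PSA

Model outputs are driven by the small AAA-prone minority, so baselines above
a stratum threshold are oversampled by multiplying their sampling *odds* by
k ≥ 1: sampling probability `q = kp/(1+(k−1)p)`, weights `(1+(k−1)p)/k`
(oversampled) and `1+(k−1)p` (rest). The weighted stratum proportions equal
the population prevalence exactly, and weighted means (normalized by the
pair count) are unbiased for any k — verified by exact enumeration on a
two-point toy population. The default stratum threshold is the 2.0 cm
zero-growth cutoff: men below it can never develop an AAA, so every
policy-sensitive pair is oversampled while the uninformative majority is
down-weighted; the default multiplier makes the stratum half the simulated
pairs.

PSA repeats the main analysis under fresh draws of the uncertain parameters;
iteration seeds are spawned from the master seed. ICERs with effect loss at
positive cost are set to +inf before interval computation, and percentile
intervals fall back to order statistics when infinities are present.

## Reproducibility and common random numbers

All randomness descends from one master seed. Pair i gets three child
streams (latents, invited-arm events, non-invited-arm events) via
`SeedSequence(seed, spawn_key=(i,))`, and each individual's event randomness
is further split into purpose-keyed substreams — measurement errors, dropout
decisions, incidental waiting times, emergency-surgery access — so that the
n-th draw of each purpose is identical under any policy run from the same
seed. Policy comparisons therefore stay tightly coupled even where pathways
diverge, which is what makes directional comparisons (e.g. a ±£1 per-invitee
cost difference) resolvable at 5×10^4 pairs. Pairs are processed in
fixed-size chunks reduced in chunk order, so results are bit-identical for
any worker count.

## Problem sizes and numerical choices

Default analysis sizes (30,000 pairs for base-case and scenario summaries,
50,000 for directional checks, 20,000–34,000 for trial-style validation,
small PSAs of tens of iterations) were chosen so a full run completes in
minutes on one CPU while leaving the headline quantities' Monte Carlo error
well inside the differences being reported; they are package defaults, not
model content, and scale freely. Bisection tolerance for rupture times is
1e-9 y; the quadrature oracle in tests uses absolute tolerance 1e-12;
uniform draws feeding inverse transforms are clamped away from {0, 1}.

## What the bundles do and do not show

The shipped bundles reproduce the *structure* of published screening
evaluations — prevalence, pathway, discounting conventions, the ordering and
rough magnitude of event counts and cost-effectiveness ratios — and the
package's tests validate mechanisms (sampler correctness, twin cancellation,
unbiased reweighting, determinism), not the bundled values themselves.
Because the underlying parameter tables of the published analyses are not
public, numeric agreement with any specific published table should not be
expected beyond order of magnitude, and conclusions about real programmes
require replacing the fixture values with estimates from data.

Known limitations: no re-intervention or EVAR-surveillance after successful
repair; no women-specific parametrization; growth is monotone log-linear
(no plateaus or shrinkage); measurement errors are independent within
person; the incidental-detection rate is diameter- and time-constant;
attendance is a single shared indicator rather than a per-invitation
process; parameters are drawn independently in PSA (no correlation
structure).
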