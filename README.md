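# aaasim

Individual-level **discrete event simulation (DES) of abdominal aortic
aneurysm (AAA) screening programmes**, for health economists and screening
programme analysts evaluating surveillance policies.

A one-off ultrasound invitation for 65-y-old men, followed by surveillance of
detected AAAs (aortic diameter >= 3.0 cm) and referral for elective repair at
5.5 cm, is the design of the UK screening programme. Whether variations of
that protocol — longer rescan intervals for small AAAs, surveillance of
sub-aneurysmal (2.5–2.9 cm) aortas, different thresholds — are cost-effective
is an open policy question that cohort Markov models handle poorly, because
every protocol change forces structural re-programming. `aaasim` instead
simulates event sequences per individual in continuous time: any partition of
the diameter axis with per-band rescan intervals is a valid policy object.

## Model

* **Twin pairs.** Individuals are simulated in matched pairs, one invited to
  screening and one not, sharing every latent attribute independent of the
  programme: baseline diameter D0, latent growth rate, non-AAA death time,
  the uniform draw behind the rupture time, censoring time, and indicators
  (attendance, surgical contraindication, operative survival, EVAR).
  Incremental costs and effects are then estimated with far less Monte Carlo
  error (common random numbers).
* **Growth–rupture model.** Log-linear growth `D(t) = D0 * exp(beta * t)`
  (zero below 2.0 cm), with a rupture hazard log-linear in current diameter,
  `h(d) = exp(a + b (d - 5.5))`. The cumulative hazard along a growing
  trajectory has a closed form in the exponential integral Ei, and rupture
  times are drawn by inverse transform.
* **Event engine.** Per-individual future event list (at most one pending
  event per kind), explicit clock, handlers for invitation, screening and
  surveillance scans (with measurement error; CT reads 0.24 cm above
  ultrasound), incidental detection, consultation (71 d wait), elective
  surgery (59 d more), rupture/emergency surgery, dropout, death, censoring.
* **Economics.** Costs attach to event times; life-years and QALYs (age-banded
  population-norm utilities) accrue continuously; discounting is
  `(1+r)^(-t)` at continuous t, so no cycle corrections are needed. ICER with
  dominance classification, INMB, CEAC.
* **Oversampling + PSA.** AAA-prone baselines are oversampled with exact
  reweighting (unbiased), and probabilistic sensitivity analysis re-runs the
  main analysis under fresh draws of the uncertain parameters.

Two documented parameter bundles ship with the package: `mass-validation`
(a 4-y randomized-trial-era configuration with Uniform(3, 5.25) y censoring)
and `naaasp-basecase` (a contemporary 30-y configuration, ~1.6% prevalence,
EVAR, 3.5%/y discounting). Their values are documented approximations
assembled from public sources; see the provenance notes inside each file.

## Worked example

```python
import aaasim

bundle = aaasim.load_bundle("naaasp-basecase")
draw = aaasim.fix_bundle_at_means(bundle)          # deterministic base case
plan = aaasim.OversamplingPlan.from_bundle(bundle)
policy = aaasim.builtin_policy("current")           # 1 y / 3 mo bands, refer 5.5

res = aaasim.run_main_analysis(30_000, draw, bundle, policy, seed=1,
                               oversampling_plan=plan)
dc = res.invited.mean_cost - res.non_invited.mean_cost
dq = res.invited.mean_qalys - res.non_invited.mean_qalys
print(f"dC = {dc:.2f} GBP, dQ = {dq:.5f} QALYs, ICER = {dc/dq:,.0f} GBP/QALY")
```

prints (seed 1, 30,000 pairs):

```
dC = 61.22 GBP, dQ = 0.01235 QALYs, ICER = 4,957 GBP/QALY
```

i.e. under the bundled base-case approximation, a one-off invitation costs
about £61 extra per man invited, gains ~0.012 QALYs, and lands well below a
£20,000/QALY willingness-to-pay — screening is highly cost-effective, in line
with published UK analyses. Policy variants are one-liners:

```python
ce = aaasim.compare_policies(policy, aaasim.builtin_policy("scenario2"),
                             30_000, bundle, seed=1)
print(ce.delta_cost, ce.delta_effect, ce.icer)
```

The same machinery is scriptable from a shell:

```bash
aaasim simulate --bundle naaasp-basecase --pairs 30000 --seed 1 --out out/
aaasim compare  --baseline current --alternative scenario1 --pairs 50000 \
                --seed 1 --out out/
aaasim validate --pairs 33900 --seed 1 --out out/
aaasim psa      --iterations 100 --pairs 5000 --seed 1 --out out/
```

## Layout

| module | contents |
| --- | --- |
| `aaasim.parameters` | hierarchical parameter bundles, distribution specs, PSA draws |
| `aaasim.growth_rupture` | trajectories, threshold crossing, rupture sampling, scan error |
| `aaasim.policy` | diameter-band policies; `current`, `scenario1`, `scenario2` |
| `aaasim.engine` | future event list, twin pairs, event handlers, main analysis |
| `aaasim.economics` | discounting, accrual, ICER/INMB/CEAC |
| `aaasim.psa` | oversampling plans, PSA orchestration, policy comparison |
| `aaasim.validation` | trial-style event tables, percent-of-observed, event curves |
| `aaasim.cli` | `aaasim` command-line entry points |

See `docs/methods.md` for modelling assumptions, parameter provenance and
known limitations.
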