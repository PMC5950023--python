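# 30-year base-case configuration emulating the contemporary NHS AAA screening
# programme (NAAASP): 65-y-old men, prevalence ~1.6%, EVAR available,
# population-norm utility weights, costs and QALYs discounted at 3.5%/y.
# All values are documented approximations; see per-parameter notes.
name: naaasp-basecase
notes:
  provenance: >
    Synthetic fixture. Values approximate the contemporary NAAASP setting:
    AAA prevalence ~1.6% at 65, surveillance per the current programme,
    growth/rupture rates in the range reported by surveillance meta-analyses,
    ~60% of elective repairs by EVAR, modern elective mortality (open ~4%,
    EVAR ~1.5%), national-statistics non-AAA mortality (~1.2%/y at 65),
    ~1%/visit true loss from surveillance (recall systems re-book most DNAs).
  baseline_diameter: lognormal chosen to give P(D>=3.0cm)~1.6% and
    P(2.5<=D<3.0)~2.5% (sub-aneurysmal share relevant to scenario 2).
  utilities: male population-norm EQ-5D approximations by age band.
  costs: 2010s GBP approximations; ultrasound at the NHS outpatient
    reference cost of a surveillance visit (scan plus clinic time).
  rupture_hazard: log-linear in diameter, ~3.5%/y at 5.5 cm, steepness per
    surveillance meta-analyses (rate roughly doubling per ~0.27 cm).
global_fixed:
  invitation_age: 65
  time_horizon_years: 30
  censoring: {kind: horizon}
  discount_rate_costs: 0.035
  discount_rate_effects: 0.035
  wait_discovery_to_consultation_days: 71
  wait_consultation_to_surgery_days: 59
  ct_offset_cm: 0.24
  ultrasound_sd_cm: 0.20
  ct_sd_cm: 0.20
  baseline_diameter: {family: lognormal, mu: 0.134, sigma: 0.45}
  zero_growth_cutoff_cm: 2.0
  growth_bands:
    - {lower_cm: 2.0, mean: 0.020, sd: 0.010}
    - {lower_cm: 3.0, mean: 0.055, sd: 0.025}
  rupture_hazard: {intercept: -3.35, slope: 2.6, reference_diameter_cm: 5.5}
  life_table: {kind: gompertz, a: 2.4e-5, b: 0.095, start_age: 65, max_age: 150}
  utilities:
    - {from_age: 65, weight: 0.78}
    - {from_age: 75, weight: 0.75}
    - {from_age: 85, weight: 0.71}
  costs:
    invitation: 1.70
    ultrasound_scan: 50.0
    consultation: 306.0
    elective_open: 9500.0
    elective_evar: 12500.0
    emergency_open: 17000.0
    emergency_evar: 16000.0
  oversampling: {target_stratum_fraction: 0.5, stratum_threshold_cm: 2.0}
  incidental_detection_rate_per_year: 0.05
  policy: current
global_uncertain:
  attendance: {family: beta, alpha: 750, beta: 250, probability: true}
  p_dropout_per_visit: {family: beta, alpha: 1, beta: 99, probability: true}
  p_contraindicated: {family: beta, alpha: 12, beta: 88, probability: true}
  p_death_emergency: {family: beta, alpha: 37, beta: 63, probability: true}
  p_death_elective_open: {family: beta, alpha: 42, beta: 958, probability: true}
  p_death_elective_evar: {family: beta, alpha: 16, beta: 984, probability: true}
  prob_emergency_surgery_given_rupture: {family: beta, alpha: 50, beta: 50, probability: true}
  evar_proportion: {family: beta, alpha: 60, beta: 40, probability: true}
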