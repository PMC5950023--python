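# 4-year validation configuration emulating the MASS trial era (men aged 65,
# screened 2000s UK). All values are documented approximations assembled from
# public MASS-era sources; see per-parameter notes.
name: mass-validation
notes:
  provenance: >
    Synthetic fixture. Values approximate the MASS 4-y follow-up era: AAA
    prevalence ~4.9%, no EVAR, elective open mortality ~6%, attendance ~80%,
    life-years valued without utility weighting, costs discounted at 6%/y and
    life-years at 1.5%/y, censoring Uniform(3, 5.25) y shared within a pair.
  baseline_diameter: lognormal chosen to give P(D>=3.0cm)~4.9% and a tail with
    P(D>=5.5cm)~0.3%, matching the MASS size-category ordering.
  life_table: Gompertz approximating MASS-era non-AAA mortality (~2.3%/y at 65).
  costs: 2000s GBP approximations (invitation, ultrasound, CT consultation,
    open elective/emergency repair). EVAR unused (evar_proportion 0).
  rupture_hazard: log-linear in diameter, ~5%/y at 5.5 cm, steepness per
    surveillance meta-analyses (rate roughly doubling per ~0.27 cm).
global_fixed:
  invitation_age: 65
  time_horizon_years: 5.25
  censoring: {kind: uniform, low: 3.0, high: 5.25}
  discount_rate_costs: 0.06
  discount_rate_effects: 0.015
  wait_discovery_to_consultation_days: 71
  wait_consultation_to_surgery_days: 59
  ct_offset_cm: 0.24
  ultrasound_sd_cm: 0.20
  ct_sd_cm: 0.20
  baseline_diameter: {family: lognormal, mu: 0.1826, sigma: 0.5535}
  zero_growth_cutoff_cm: 2.0
  growth_bands:
    - {lower_cm: 2.0, mean: 0.020, sd: 0.010}
    - {lower_cm: 3.0, mean: 0.055, sd: 0.025}
  rupture_hazard: {intercept: -3.0, slope: 2.6, reference_diameter_cm: 5.5}
  life_table: {kind: gompertz, a: 6.5e-5, b: 0.09, start_age: 65, max_age: 150}
  utilities:
    - {from_age: 65, weight: 1.0}
  costs:
    invitation: 1.60
    ultrasound_scan: 25.0
    consultation: 250.0
    elective_open: 6909.0
    elective_evar: 6909.0
    emergency_open: 11176.0
    emergency_evar: 11176.0
  oversampling: {target_stratum_fraction: 0.5, stratum_threshold_cm: 2.0}
  incidental_detection_rate_per_year: 0.05
  evar_proportion: 0.0
  policy: current
global_uncertain:
  attendance: {family: beta, alpha: 800, beta: 200, probability: true}
  p_dropout_per_visit: {family: beta, alpha: 7, beta: 93, probability: true}
  p_contraindicated: {family: beta, alpha: 12, beta: 88, probability: true}
  p_death_emergency: {family: beta, alpha: 37, beta: 63, probability: true}
  p_death_elective_open: {family: beta, alpha: 60, beta: 940, probability: true}
  p_death_elective_evar: {family: beta, alpha: 60, beta: 940, probability: true}
  prob_emergency_surgery_given_rupture: {family: beta, alpha: 45, beta: 55, probability: true}
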