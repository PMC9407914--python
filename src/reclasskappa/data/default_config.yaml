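# Default synthetic-cohort configuration (version 1).
#
# Emulates a population CVD-screening cohort: n = 3971 subjects, outcome
# prevalence 1765/3971 = 0.4444, categorical covariates with fixed marginal
# frequencies, a strong binary risk score, a protective education gradient,
# and six candidate markers drawn independently of the outcome.
#
# `logodds` are CONDITIONAL effects on the logistic linear predictor.  They
# were calibrated once by Monte-Carlo integration so that the UNIVARIABLE
# (marginal) odds ratios under covariate independence approximate the
# intended targets (e.g. score high vs low: marginal OR ~ 22.7 from a
# conditional log-odds of 3.417 — conditional effects exceed marginal ones
# because logistic models are non-collapsible).
n: 3971
target_prevalence: 0.44447242508184337
covariates:
  - name: bmi
    role: base
    categories: [standard, underweight, overweight, obesity]
    freqs: [0.235, 0.005, 0.448, 0.312]
    logodds: [0.0, 0.791, 0.615, 1.031]
  - name: residence
    role: base
    categories: [urban, rural]
    freqs: [0.623, 0.377]
    logodds: [0.0, -0.097]
  - name: marital
    role: base
    categories: [relationship, single]
    freqs: [0.712, 0.288]
    logodds: [0.0, -0.164]
  - name: income
    role: base
    categories: [average, low, high]
    freqs: [0.561, 0.260, 0.179]
    logodds: [0.0, -0.407, -0.550]
  - name: activity
    role: base
    categories: [active, passive, mixed]
    freqs: [0.226, 0.336, 0.438]
    logodds: [0.0, 0.403, -0.047]
  - name: education
    role: marker
    categories: [basic, professional, medium, higher]
    freqs: [0.209, 0.268, 0.355, 0.168]
    logodds: [0.0, -0.779, -1.284, -1.449]
  - name: score
    role: marker
    categories: [low, high]
    freqs: [0.352, 0.648]
    logodds: [0.0, 3.417]
random_markers:
  - name: uniform
    dist: uniform
    params: {low: 0.0, high: 100.0}
  - name: normal
    dist: normal
    params: {mean: 0.0, sd: 1.0}
  - name: poisson
    dist: poisson
    params: {lam: 4.0}
  - name: exponential
    dist: exponential
    params: {rate: 1.0}
  - name: bernoulli_01
    dist: bernoulli
    params: {p: 0.1}
  - name: bernoulli_05
    dist: bernoulli
    params: {p: 0.5}
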