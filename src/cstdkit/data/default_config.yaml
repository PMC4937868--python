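# Packaged defaults: a female reference life history and the reference
# two-chemical simulation scenario (ban 1970, intake doubling/halving time
# 7 years, 30-year-old mothers sampled 1940-2080).
growth:
  anchor_ages: [0, 1, 5, 10, 15, 20]
  body_weight_kg: [3.5, 10.0, 20.0, 35.0, 55.0, 60.0]
  lipid_fraction: [0.25, 0.20, 0.18, 0.22, 0.27, 0.30]
schedule:
  age_at_childbirth: 30.0
  breastfeeding_duration: 0.5
  milk_lipid_output: 25.0   # g lipid/day (~700 g milk/day at 3.5% lipid)
chemical:
  t_half_elim: 3.0          # years
  absorbed_fraction: 1.0
scenario:
  ban_year: 1970
  t_double_in: 7.0          # years
  t_half_in: 7.0            # years
  peak_intake: 1.0          # ng/kg bw/day at the ban year
body:                       # static model / half-life tool constants
  body_weight: 60.0
  lipid_fraction: 0.30
features:
  in_utero: true
  breastfeeding: true
  growth: true
noise:
  sigma_log: 0.2
  n_per_year: 50
  seed: 0
simulation:
  target_age: 30.0
  start: 1940
  stop: 2080
  every: 2.0                   # sampling-year spacing
  step: 0.019230769230769232   # integrator step, 1/52 year
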