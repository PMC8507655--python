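# Full-pipeline configuration for a demonstration run.
# Every stage tolerance is surfaced here; omitted keys fall back to the
# defaults documented in docs/methods.md.
seed: 1

simulate:
  n_tracts_x: 15
  n_tracts_y: 12
  tract_side: 1000.0        # planar units
  n_systems: 90
  tracts_per_system_range: [1, 2]
  population_range: [1200, 8000]
  subgroup_alpha: 2.0
  subgroup_beta: 2.0
  effect_size: 3.0          # log-mean concentration shift per unit subgroup fraction
  tests_per_system_range: [4, 12]
  population_noise_sd: 0.1

risk:
  window: ["2014-01-01", "2019-12-31"]

attribute:
  mode: counts              # counts | percent
  sliver_eps: 1.0e-9

filter:
  population_floor: 500

trend:
  subgroups: [pct_subgroup]
  by_size: false
  alternative: increasing   # increasing | decreasing | two-sided
  method: auto              # auto | asymptotic | exact | permutation
  n_permutations: 100000
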