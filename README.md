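# waterdisparity

Community-level screening of drinking-water quality against neighbourhood
demographics. The package asks, for a set of community water systems
(CWS): *does cumulative cancer risk from drinking-water contaminants
increase with the share of a demographic subgroup in the population
served?* It is aimed at environmental-health and environmental-justice
analysts who have (or want to prototype against) three inputs: contaminant
monitoring records keyed by public water system ID (PWSID), service-area
boundary polygons, and census-tract demographic data.

## The statistic and the pipeline

For each system, each contaminant's long-term concentration C_i is the
arithmetic mean of all monitoring results in the study window, with
non-detects counted as zero. Cumulative cancer risk is the hazard-style
sum over carcinogenic contaminants

```
rho = Σ_i C_i / B_i ,        R = rho × 10⁻⁶ ,
```

where B_i is the benchmark concentration corresponding to 10⁻⁶ lifetime
cancer risk (user-supplied configuration; `examples/benchmarks.yaml` is
illustrative). When both the HAA5 and HAA9 haloacetic-acid group means
exist for a system, only HAA9 enters the sum (HAA9 contains the HAA5
species).

Tract demographics are apportioned to each service area by areal
interpolation under a uniform-density assumption — counts weighted by
the fraction of each tract's area the system covers — giving each system
a subgroup percentage. After excluding wholesale systems (reported
population zero), systems serving ≤ 500 people, and systems whose
tract-assigned population disagrees with the reported population by more
than ±50%, systems are split into terciles T1 < T2 < T3 by subgroup
percentage. Per tercile the package reports n, total population, and
median lifetime risk, and tests for a monotone trend with the
Jonckheere–Terpstra statistic (exact, asymptotic, or permutation
p-values). A synthetic-data generator with a tunable
demographic–contamination link (`effect_size`, a log-scale concentration
shift per unit subgroup fraction) provides a full test universe; see
`docs/methods.md` for the model and its limitations.

## Worked example

Run the whole pipeline — simulate, risk, attribution, cohort filter,
trend — from one config:

```
$ waterdisparity run-all --config examples/pipeline.yaml --out demo --seed 1
{"simulate": {"tracts": 180, "systems": 90, "test_records": 3670},
 "risk": {"systems_in": 90, "systems_with_risk": 90},
 "attribute": {"systems_in": 90, "systems_attributed": 90},
 "filter": {"matched": 90, "risk_only": 0, "gis_only": 0, "excluded": 0, "included": 90},
 "trend": {"systems_in": 90, "reports": 1}}
```

`demo/terciles.csv` then holds the tercile summary:

```
subgroup,size_class,tercile,n_systems,pct_min,pct_max,total_population,median_lifetime_risk
subgroup,all,T1,30,2.01496833621,42.9768358797,155099,0.000976267760484
subgroup,all,T2,30,43.565300286,63.306674021,157840,0.00206881965024
subgroup,all,T3,30,63.5429262394,92.667542707,142900,0.0041790675351
```

and `demo/trend_tests.csv` the trend test:

```
subgroup,size_class,J,z,p_value,method,sidedness,skip_reason
subgroup,all,2529,8.73333333333,1.23637489639e-18,asymptotic,increasing,
```

Reading this: the 90 simulated systems split into three terciles of 30
by subgroup percentage (boundaries in `pct_min`/`pct_max`). Median
lifetime cancer risk rises from 9.8 × 10⁻⁴ in the lowest-subgroup
tercile to 4.2 × 10⁻³ in the highest — the config injects a strong
positive association (`effect_size: 3.0`) — and the one-sided
Jonckheere–Terpstra test finds the increasing trend overwhelmingly
significant (J = 2529 against a null mean of 1350; p ≈ 10⁻¹⁸). With
`effect_size: 0.0` the same pipeline produces flat medians and uniform
p-values. `demo/manifest.json` records the config hash, seed, per-file
SHA-256 digests and per-stage record counts; rerunning with the same
config and seed reproduces every output byte for byte.

Each stage is also exposed as a subcommand (`simulate`, `risk`,
`attribute`, `filter`, `trend`) and as a plain library API
(`waterdisparity.risk_table`, `assign_demographics`, `build_cohort`,
`run_disparity`, `jonckheere_terpstra`, ...).

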