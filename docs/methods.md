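# Methods

## The analysis in brief

`waterdisparity` implements a community-level screening analysis of
drinking-water quality against neighbourhood demographics. The unit of
analysis is the community water system (CWS), identified by its PWSID.
The pipeline has five stages:

1. **Synthetic data generation** — a study universe of census tracts,
   service-area polygons, and contaminant monitoring records.
2. **Water quality** — per-system long-term mean concentrations and a
   cumulative cancer-risk statistic.
3. **Areal attribution** — apportioning tract demographics to service
   areas by polygon overlap.
4. **Cohort filtering** — PWSID matching, wholesale/population/agreement
   exclusions, size classification.
5. **Disparity analysis** — tercile summaries and a Jonckheere–Terpstra
   (JT) trend test of risk against demographic composition.

## Cumulative cancer risk

For each system, each contaminant's long-term concentration C_i is the
arithmetic mean of all monitoring results in the study window (default
2014-01-01 through 2019-12-31, inclusive), with **non-detects counted as
zero**. Records are converted to the benchmark's unit first; mass units
(ng/L, µg/L, mg/L) interconvert, activity (pCi/L) is a separate
dimension and mixing the two for one contaminant is an error.

The risk statistic is the hazard-style sum

    rho = Σ_i C_i / B_i ,      lifetime risk R = rho × 10⁻⁶ ,

where B_i is the concentration at 10⁻⁶ lifetime cancer risk. rho is
linear in concentrations and monotone in the contaminant set; both
properties are enforced by tests. Benchmarks are **user-supplied
configuration** (`examples/benchmarks.yaml` is illustrative only, not a
vetted health-guideline table).

Two special rules:

* grouped disinfection byproducts (THM4, HAA5, HAA9) are single
  parameters with group benchmarks; because HAA9 contains the HAA5
  species, a system with both means contributes only the HAA9 term
  (configurable via `group_rules.supersedes`);
* results reported as a combined nitrate+nitrite value feed the nitrate
  stream via the alias map.

A contaminant with no in-window samples is *absent* from the profile,
never imputed as zero; occurrence summaries count "systems with data"
and "systems with detections" separately for the same reason.

## Areal attribution

Attribution assumes population is uniformly distributed within each
tract. For system s and tract t,

    frac_t = area(t ∩ s) / area(t)

and assigned counts are Σ_t frac_t × count_t. Subgroup percentages are
derived from apportioned counts (count mode, the default); this is the
only mode that conserves population when systems tile the tract grid,
which the tests verify at 10⁻⁶ relative tolerance. A percent mode — the
area-fraction-weighted mean of tract percentages — is retained behind a
flag for sensitivity analysis, since apportioning a percentage variable
directly is a defensible alternative reading of the method.

Numerical choices: overlaps below ε = 10⁻⁹ of tract area are dropped as
floating-point slivers; fractions are clipped at 1; invalid or empty
geometries are rejected by name rather than auto-repaired, because
repair silently changes areas. Geometries must already be planar and
equal-area; the package validates but does not reproject.

## Cohort rules

Inner join of risk and attribution tables on PWSID (duplicates are an
error), then three exclusions applied in a fixed order so the ledger is
deterministic:

1. **wholesale** — reported served population of zero (the system sells
   finished water to other systems);
2. **population floor** — reported population ≤ 500, where tract-level
   attribution is known to be unreliable;
3. **agreement** — tract-assigned population outside ±50% of the
   reported population (pass iff 0.5 ≤ assigned/reported ≤ 1.5, bounds
   inclusive).

Size classes by reported population: very small ≤500, small 501–3300,
medium 3301–10,000, large 10,001–100,000, very large >100,000. The
small class starts at 501 so that it aligns with the >500 inclusion
floor. Ledger counts plus included count always equal the matched count.

## Terciles and the trend test

Within each analysis stratum (a subgroup overall, or subgroup × size
class), systems are sorted by subgroup percentage (ties broken by PWSID
for determinism) and split into three groups whose sizes differ by at
most one; remainders go to the lowest tercile(s) first. Reported
per-tercile: n, min/max percentage (the boundaries), total reported
population, and the median lifetime risk (midpoint convention for even
counts).

The JT statistic is J = Σ_{k<l} U_kl with U_kl the Mann–Whitney count
#{x<y} + ½#{x=y} over the ordered pair of groups. Null moments:
E₀[J] = (n² − Σn_k²)/4 and the Hollander–Wolfe tie-corrected variance,
which reduces to [n²(2n+3) − Σn_k²(2n_k+3)]/72 without ties (checked in
tests). p-values by three methods: normal approximation without
continuity correction (default for n > 10), exact enumeration of all
equally likely assignments of the pooled values to groups (n ≤ 10), or
seeded Monte-Carlo permutation (default 10⁵ draws). If all pooled values
are identical the statistic is degenerate and p = 1. Sidedness is
configurable (`increasing`, `decreasing`, `two-sided`; default
two-sided) and recorded in every report, since a one-sided "risk
increases with subgroup share" alternative is often what a screening
analysis wants but the choice must be explicit.

Strata with fewer than 6 systems get their tercile summary but no trend
test (three terciles of ≤2 carry no usable ordering). No multiplicity
adjustment is applied across strata; the number of tests run is visible
in the output so users can adjust externally.

## Synthetic data model

The generator emulates the *structure* of the real inputs:

* **Tracts**: an n_x × n_y grid of square cells (default 15×12, side
  1000 planar units). Population per tract ~ Uniform{1200..8000},
  matching typical census-tract sizes; subgroup fraction ~
  Beta(α, β) (default α = β = 2, a broad unimodal spread).
* **Systems**: contiguous runs of 1–3 cells within a grid row; with
  probability 0.5 one end cell is halved so overlap fractions strictly
  between 0 and 1 occur. Systems never overlap. The "regulator-reported"
  population is the true covered population times (1 + N(0, 0.1)),
  rounded, floored at zero.
* **Monitoring records**: per system × contaminant, k ~ Uniform{4..12}
  samples with dates uniform over the window and concentrations
  LogNormal(μ_c + β·f, σ_c), where f is the system's true subgroup
  fraction from exact areal attribution and β (`effect_size`) is the
  injected association. Draws below the detection limit become
  non-detect rows. Lognormal concentrations are the standard model for
  non-negative, right-skewed environmental data. A per-contaminant
  `availability` probability emulates partial monitoring coverage (the
  default HAA9 stream is available for ~30% of systems, mirroring how
  unregulated-contaminant monitoring covers mostly larger systems).
* The default contaminant set (THM4, HAA5, HAA9, arsenic, nitrate,
  radium) is shaped to produce cumulative risks of order 10⁻⁴–10⁻³ per
  lifetime, the magnitude typical of multi-contaminant hazard sums for
  US systems; the parameters are illustrative.

All three stages draw from independent child streams of one seed; a
fixed seed gives bit-identical outputs, which the pipeline's manifest
(config hash + per-file SHA-256 digests + per-stage record counts)
makes auditable.

`simulate_cohort` is a distribution-level shortcut used for statistical
calibration: it draws subgroup fractions directly from the Beta prior
and monitoring results from the same lognormal/censoring model, skipping
polygon construction (which is deterministic given f and so does not
change the joint null law of fraction and risk). This is what makes a
10,000-replicate type-I-error measurement run in well under a minute.

**What the generator does not emulate**: real geography (tract shapes,
nesting, projection artifacts), spatial autocorrelation of contamination,
multiple subgroups with correlated spatial structure, time trends within
the window, laboratory-specific reporting limits, or systems spanning
multiple grid rows. Passing tests therefore demonstrate correctness of
the *machinery* and calibration of the *test* under a clean data model,
not that any particular real-world disparity exists.

## Verification problem sizes

The test suite measures: type-I error over 10,000 null cohorts of 300
systems (band 0.05 ± 0.01 at α = 0.05, one-sided asymptotic); power
monotonicity over β ∈ {0, 0.25, 0.5, 1} at 300 replicates each; and
trend recovery over 200 full end-to-end runs of 90 systems with β = 3
(≥95% of runs must give median(T3) > median(T1) and one-sided p < 0.05).
With σ ≈ 0.6 on the dominant contaminants and subgroup fractions
spanning ~0.1–0.9, β = 3 shifts expected log concentration by ~4σ across
the range, i.e. a strong but not degenerate association. JT correctness
is checked against a brute-force enumeration oracle on all-small
configurations (total n ≤ 9, values in {1..4}).

## Known limitations

* Non-detect = 0 is the only censoring rule offered; half-detection-limit
  or survival-analysis imputations would change results and are out of
  scope by design.
* The exact JT method is limited to n ≤ 10 pooled observations; beyond
  that the permutation method is the high-fidelity option.
* Count-mode attribution conserves population but inherits the
  uniform-density assumption; dasymetric refinement is not implemented.
* The pipeline analyzes one synthetic subgroup by default; multiple
  subgroups are supported in the trend stage but the generator draws
  only one.
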