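# Methods

## Design

The scientific question is one of generalizability: does an insured
sub-population, observed through claims, show the same multiplicative
association between heatwave days and acute-care encounters as the
full population it is embedded in, observed through a separate,
non-linkable discharge dataset?  Because individuals cannot be matched
across the two sources, the comparison is made at the level of daily
stratum counts, with the case-crossover design absorbing all
time-invariant confounding within (county, year, month, day-of-week)
cells and the remaining short-term confounders (relative humidity,
holidays) modeled explicitly.

## Exposure

A county's heatwave threshold is the year-round percentile (default
97.5) of its daily maximum temperatures over a multi-year baseline
period, computed with the type-7 linear-interpolation quantile rule
(index h = 1 + (n−1)q/100 on the sorted sample).  The convention
matters — thresholds sit in the far tail — so it is fixed, and recorded
in the threshold table's metadata.  A heatwave day is any day inside a
maximal run of ≥ `min_run` (default 2) consecutive days with tmax
strictly above the threshold ("exceeded" is read as strict; a tie does
not count, configurable).  Isolated exceedance days feed the
`exceed_simple` sensitivity exposure; within-spell position
(`hw_first` vs `hw_later`) supports first-day/later-day sensitivity
models.  Missing calendar days break runs; temperatures are never
imputed.

## Encounters

Claim lines chain transitively: a claim within 1 calendar day of the
previous claim in the open encounter joins it, so a run of claims on
consecutive days is one encounter dated by its first claim.  (An
alternative reading — anchoring the 1-day window to the first claim —
would split long runs; transitive chaining is what "grouped by first
claim date" implies for runs, and the choice is documented here
because it is not forced.)  Mixed ED/inpatient encounters are
inpatient.  When chained claims disagree on cause, the earliest
claim's cause wins, ties broken lexicographically.

## Person-time and standardization

Reference person-time is the annual census count held constant within
the year; insured person-time is the monthly enrollee count assigned
to each day of its month.  Census 5-year age bands are collapsed to
the seven adult analysis bands, with 40% of the 15–19 band (2 of 5
single years) moved into 18–24 — deterministically by default, or as a
binomial draw.

Standardization weights are year-specific ratios of shares:
w(s, y) = ref_share(s, y) / ins_share(s, y), so re-weighted insured
stratum shares equal reference shares exactly (verified to 1e-9 in
tests).  Weighted counts are real-valued; the quasi-likelihood score
equations accept them unchanged.  Demographic comparison tables
average annual percentage shares across years and then take ratios
(ratioing averaged counts instead changes results only in the third
decimal for stable populations); rounding to 2 decimals happens only
at presentation.

## Conditional quasi-Poisson model

With stratum intercepts α_s, the Poisson model
E(N_ts) = exp(α_s + x_ts'β) conditioned on the stratum totals
n_s = Σ_t N_ts yields the multinomial log likelihood

    ℓ(β) = Σ_s [ Σ_t N_ts x_ts'β − n_s log Σ_t exp(x_ts'β) ],

whose maximizer equals the profile MLE of the dummy-intercept model.
The fit uses Newton–Raphson from β = 0 with step-halving; the Hessian
is the exact information (canonical link), so convergence is quadratic
and stable.  Convergence is declared at max|score| < 1e-8 or relative
ℓ change < 1e-10; an ill-conditioned information matrix receives a
1e-10 ridge with a warning.

Dispersion is Pearson χ² over df = n_obs − n_strata − p, counting the
eliminated stratum intercepts — the same convention as an
unconditional fit with explicit dummies, which the test suite pins by
comparing β, SEs and φ against an independent stratum-dummy GLM to
1e-6.  The covariance is φ × (inverse information); Wald CIs use
z = 1.96.  A saturated fit (df = 0) has no dispersion estimate; φ is
reported as NaN and the covariance left unscaled.

Columns constant within every stratum carry no conditional
information.  If such a column is the exposure of interest the fit
raises a non-identifiability error; otherwise the column is dropped
with a warning, leaving the remaining estimates untouched (conditional
likelihood is invariant to stratum-constant covariates).

Empty strata (total count zero) are removed before fitting — they
contribute a constant to ℓ — and tallied.  Weekdays use the ISO
convention (Monday = 1).  Main-analysis counts are aggregated over
age and sex within county-day, because the stratum key carries only
county and time; adding age-sex to the stratum key is a config option
for sensitivity analyses.

## rIRR comparison

Pooling the two datasets with dataset-labelled strata and interacting
every covariate with the dataset dummy d (0 = reference, 1 = insured)
gives exp(β₄) as the ratio of heatwave IRRs.  No d main effect enters:
no stratum mixes datasets, so it would be stratum-constant.  Because
the design is fully interacted and the strata are disjoint, the
combined point estimates factorize into the two separate fits (tested
to 1e-6); the combined fit's contribution is a joint covariance under
a pooled dispersion, giving a direct Wald CI and test for the ratio.
Both pooled and per-dataset dispersions are reported, since they can
differ.

Two common alternatives are implemented as foils: the coefficient
difference with independent SEs (invalid when the datasets share
exposure series and members), and the non-overlapping-CI rule (known
to be conservative).  `run_comparison_experiment` measures type-I
error, power and CI coverage of all three over replicated synthetic
studies; under the null the interaction Wald test rejects at ≈ 5% and
the CI-overlap rule at ≈ 3%, with rIRR CI coverage ≈ 95%.

## Synthetic generator

The generator's defaults are the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| climate mean tmax / amplitude | 26 / 9 °C | mid-latitude seasonal cycle with hot summers |
| AR(1) ρ / innovation sd | 0.7 / 3 °C | multi-day persistence yields realistic 2–5-day heat spells; ~4% of warm-season days flagged, near observed heatwave-day fractions for such definitions |
| RH mean / sd / corr with tmax anomaly | 55% / 15% / −0.4 | hot days tend to be dry |
| baseline encounter rate | 8e-4 per person-day | order of all-cause ED rates per million person-days in large discharge datasets |
| insured rate multiplier | 0.4 | insured members utilize acute care at lower rates |
| coverage | 3.4%, skewed younger | a commercial-claims cohort is a small, younger slice of a state population |
| heatwave log-IRR | log 1.1 (reference), log 1.2 (insured) | small effects typical of all-cause heat associations, distinct across datasets so the rIRR is informative |
| RH / holiday log-RR | +0.005 per % / −0.10 | mild confounding signals |
| overdispersion ν | 1.3 | quasi-Poisson dispersions for such models are typically reported below 1.5; 1.3 is a deliberate choice, not an observed value |

Counts are gamma-mixed Poisson with the gamma shape μ/(ν−1) and scale
ν−1, so Var/E = ν *exactly at every mean* — variance proportional to
the mean, the quasi-Poisson variance function, rather than the
quadratic negative-binomial one.  This also means sums of independent
cells keep Var = νμ, so the Monte Carlo experiments may draw counts at
the aggregated county-day level without changing what the model sees
(the `collapse_person_time` option, on by default in experiments).

Holidays default to eight fixed dates per year; real federal holidays
float, but a fixed list keeps the covariate well-defined and is
supplied explicitly in configs.  One root seed spawns independent
streams per component (climate, population, counts) so components can
be regenerated independently; identical seeds give byte-identical
tables.

What the generator does **not** emulate: spatial correlation between
counties, migration and mortality (person-time is closed), lagged
temperature effects, seasonal trends in baseline rates, and any
code-list semantics behind cause labels.  Passing tests therefore
demonstrate correctness of the estimators under the stated generating
model, not robustness to these real-data features.

## Monte Carlo experiment sizes

Recovery and coverage use 200 replicates of 20 counties × 2 warm
seasons at county populations of ~3×10⁵ (insured coverage 3.4%); null
calibration uses 500 replicates of the same design with equal true
IRRs.  These sizes give Monte Carlo standard errors of ~0.01 on
rejection rates and ~0.015 on coverage, small enough to detect
meaningful miscalibration while keeping a full run in minutes on one
CPU.

## Known limitations

- Wald inference throughout; no profile or bootstrap CIs, and no exact
  conditional inference for sparse strata.
- The standardization formula (year-specific ratio of shares) is one
  defensible reading of direct re-weighting; the formula is recorded
  in the weights table metadata.
- The naive-independence foil shares no members across synthetic
  datasets beyond the common exposure series, so the experiments
  demonstrate the comparison machinery rather than the worst-case
  correlation bias of the naive method.
- `exceed_simple` and first-day/later-day variants are implemented and
  tested mechanically, but no synthetic scenario drives a difference
  between them.
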