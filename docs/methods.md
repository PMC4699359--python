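# Methods

## The clock model

DNAM-age prediction is a linear score over CpG beta values mapped through a
calibrated age transform, logarithmic during development and linear in
adulthood with a knee at `adult_age` (default 20 years):

    F(a) = log(a+1) − log(adult_age+1)       for a ≤ adult_age
    F(a) = (a − adult_age)/(adult_age+1)     for a > adult_age

`F` is continuous and monotone on (−1, ∞); its inverse maps the linear
score `intercept + Σ wᵢ βᵢ` back to years. Coefficients are an input table
(`io.read_clock`); the package never embeds a published coefficient set.
Missing clock probes are dropped from the score and counted; NaN betas at
present probes are imputed per `missing_policy` — cohort-mean by default
(standard practice for this predictor family), `zero` and `error` as
alternatives. Because published clocks are usually applied to betas before
batch correction, the prediction stage accepts a different matrix from the
downstream testing stages.

Δ-age is DNAM-age minus chronological age, exactly. The Grubbs outlier
test reports `G = max|xᵢ − x̄|/s` against the classical t-based critical
value; the p-value is the matching `2n·P(T_{n−2} > t(G))` upper bound.

## Stress association

"Generalized linear regression" of Δ-age on stress is implemented as
Gaussian-identity OLS — the outcome is continuous and effects are reported
on its scale (years per stress unit). Formulas go through statsmodels, so
categorical covariates (sex, batch labels) expand to indicator contrasts
and interactions are ordinary product terms; incomplete cases are dropped
listwise. Rank-deficient designs are rejected up front with the collinear
columns named (pivoted QR). Batch terms enter as covariates rather than by
pre-correcting the outcome.

Stratification rules are total and deterministic: median splits send ties
to the low stratum; abuse strata use CTQ subscale cutoffs (sexual ≥ 8 OR
physical ≥ 10 → moderate/extreme). Fisher's z comparison of two
correlations reports |z| since the comparison is direction-free. Both
pooled and Welch two-sample t variants are provided because stratum
comparisons in the literature rarely state which was used.

## Paired glucocorticoid-response testing

With exactly two time points per subject, subject effects are absorbed by
differencing: `dᵢ = postᵢ − baselineᵢ`. The per-feature test compares
`d ~ 1 + covariates` against `d ~ 0 + covariates` with a Gaussian
likelihood ratio, `LRT = n·ln(RSS_red/RSS_full)` referred to χ²₁; the
full-model intercept is the covariate-adjusted mean paired difference and
gives the direction. Covariates are centered after indicator expansion, so
the intercept-free reduced model does not depend on covariate origin and
the statistic is invariant under affine covariate rescaling. Two
degenerate cases are distinguished: `d ≡ 0` is a clean null (LRT 0, p 1),
while a perfect non-trivial fit (RSS_full = 0 with signal) is flagged
`degenerate` with p set to 0 and a warning. Methylation tests run on beta
values by default; an M-value transform is available upstream of the call.
BH-FDR uses the standard step-up construction (via statsmodels; an
independent hand-rolled oracle backs it in the test suite).

Expression probes are pre-filtered by array detection p-values (detected
at p < 0.05 in ≥ 50 % of samples), the convention for expression arrays;
methylation QC uses p ≤ 0.01 in ≥ 75 % of samples. Both thresholds are
parameters.

## Interval enrichment

Overlap is point-in-interval on the CpG coordinate with BED half-open
semantics; the manifest's 1-based positions are converted to 0-based in a
single function. Padding supports ±1 kb / ±10 kb proximity summaries. The
permutation null draws sets of the query's size uniformly without
replacement from a background probe list — deliberately unmatched on CpG
density or chromatin state, mirroring the uniform-draw procedure this
statistic is usually reported with; matched nulls would be an extension,
not the baseline. The add-one estimator `p = (1+k)/(n_perm+1)` keeps p
strictly positive, so "p < 10⁻³ at 1,000 draws" appears as 1/1001.
`nested_background_compare` evaluates one set against an inner (training,
"21K") and outer (full-array, "450K") background at once and additionally
projects the inner background's overlap rate onto a query-sized set
against the outer null, enabling the three-way comparison (set vs outer,
set vs inner, inner vs outer) through one interface.

TSS linkage connects each query CpG to all genes whose TSS lies within
`max_dist` (default 1,500 bp, chosen to cover the 1–1,423 bp range typical
of clock-CpG gene annotation); distance statistics are over absolute
linked distances. Fisher's exact test uses the "probabilities ≤ observed
table" two-sided convention with the conditional MLE odds ratio;
over-representation analysis is an upper-tail hypergeometric per gene set
(sets with < 5 universe members skipped, default) with BH-FDR across
tested sets.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
conditions every statistical check runs under.

* **Cohort**: n = 400; ages uniform 18–77 years; ~70 % female; stress
  scores Poisson with mean 10 (right-skewed integers, range ≈ 0–20, like
  summed life-event questionnaires); cell fractions Dirichlet; 4 batches.
* **Clock structure**: probe baseline means in (0.3, 0.7), loadings
  ±(0.02, 0.08) beta per transformed-age unit; weights invert the loadings
  exactly, so noiseless Δ-age is identically 0. Construction fails if the
  implied betas would leave [0, 1] over the age range.
* **Stress effect**: acceleration enters the latent transformed age as
  `γ·stress/(adult_age+1)` with γ = 0.3 years/unit by default, so γ reads
  directly as years of Δ-age per stress unit above the knee. For the few
  samples below the knee the log branch compresses the effect slightly.
* **Noise**: beta noise SD 0.05 (array-scale), giving r(DNAM-age, age)
  ≈ 0.97–0.99 at n = 400 and Δ-age residual SD of ~3 years. Betas are
  clipped to [0, 1]; clip events are counted in the ground truth (defaults
  keep clipping ≈ 0.1 %; > 10 % warns, > 50 % errors) because clipping
  biases recovery at extreme ages.
* **DEX pairs**: 124 subjects; 110/353 ≈ 31 % of probes affected; down
  with probability 0.89; shift 0.10 beta against 0.01 re-measurement noise
  (a 10× effect).
* **Peaks**: per-probe membership 24 % (query) vs 13.8 % (background) —
  the 85-of-353 observed vs 48.8-of-353 expected regime — with peak
  lengths ~N(746, 371) bp around each selected CpG. Manifest probes are
  spaced 5 kb apart so placements rarely collide; actual membership is
  recomputed and recorded, and > 5 % collisions abort.
* **Expression**: 49 % of linked genes silent (below detection), 80 % of
  the rest regulated, 58 %/42 % up/down, unit shift against 0.3 noise.

What the generator does **not** emulate: probe-type chemistry and
normalization artifacts, spatial autocorrelation of methylation along the
genome, LD between SNPs and probes, matched CpG-density/chromatin
structure of real peak sets, and the empirical null behaviour of real
cohort confounding. Passing tests therefore demonstrate that the
estimators are correct and calibrated under the stated model, not that
real-cohort confounding is handled beyond the covariates modeled.

Two knock-on artifacts are worth knowing. Clipping at the beta bounds can
induce tiny systematic paired differences for probes sitting near 0 or 1
(occasionally one extra differential call at n = 124 pairs). And because
planted DEX shifts land on clock probes with arbitrary sign relative to
the clock weights, synthetic post-DEX DNAM-age *does* shift, unlike the
null result typically seen in real data — the pipeline reports the paired
t-test but the suite does not assert a null there.

## Seeds and problem sizes

All generators accept a seed or `numpy` Generator; the pipeline derives
per-stage child seeds from one global seed via `SeedSequence.spawn`, so
toggling a stage does not shift another stage's randomness. Seeded runs
are bit-reproducible.

Statistical suites run at sizes where each check is decisive yet quick:
coverage of the planted stress effect over 300 simulated cohorts of
n = 400 (Monte-Carlo SE on the coverage estimate ≈ 1.2 points against a
95 %-nominal vs 93 %-required margin); null calibration over 500
permutations; enrichment detection over 40 independent peak realizations
of a 353-of-20,000 design at 1,000 draws each; FDR control over 200 null
simulations of 50 features × 60 pairs. Exact tests are verified against
combinatorial enumeration on margins ≤ 30.

## Known limitations

* The paired LRT assumes Gaussian differences; no empirical-Bayes variance
  moderation or mixed models (out of scope).
* Uniform permutation backgrounds ignore CpG-density matching.
* The personal-vs-network partition of life-event items is a required
  configuration input — there is no canonical default.
* File-driven pipeline mode covers clock + association + enrichment;
  paired-DEX and expression stages currently run from the simulator (their
  library functions accept arbitrary user matrices directly).
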