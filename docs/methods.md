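# Methods

This note records the statistical models, defaults and design choices
behind `spheremark`, and what the synthetic benchmarks do and do not
establish about real data.

## Data model

The pipeline starts at the protein-level quantification matrix (proteins ×
samples) with typed sample metadata; upstream spectral processing (search,
FDR filtering, peptide-to-protein rollup) is out of scope.  Two designs
are supported: the tumor-evolution design with ordered culture states
ADH < SPH1 < SPH3 over several cell lines, and the two-group CTRL/KD
knockdown design.  Values are either linear intensities (non-negative;
zero is a valid intensity, distinct from missing) or log2 abundances,
tracked by an explicit scale flag.  Missing cells denote
non-identification and are never conflated with zeros.

## Selection cascade

Fold changes are condition-mean differences on the log2 scale over
non-missing replicates, so the additivity fc(S3−Adh) = fc(S1−Adh) +
fc(S3−S1) holds exactly.  The cascade is applied in a fixed order: gate →
artifact exclusion → selection criteria; exclusion wins, so a protein with
a large endpoint change that fits the artifact pattern is still discarded.
All thresholds are inclusive (≥) and configurable
(`SelectionThresholds`): gate 0.5, per-step 0.5, artifact window 0.5,
endpoint 1.5, all in log2 units.

Two readings of the "constant drift" criterion fit its verbal definition:
each step clearing 0.5, or only the cumulative change clearing 0.5 with
sign-consistent steps.  The per-step reading is the default (it implies
the monotone ordering S3 ≥ S1 ≥ Adh at threshold strength); the cumulative
reading is available via `criterion1_cumulative=True`.  Artifact exclusion
is direction-agnostic by default — "altered in both sphere passages" does
not constrain sign — with a strict same-sign mode
(`artifact_requires_same_sign=True`).  A selected protein's direction is
the sign of its endpoint change fc(S3−Adh); for constant-drift selections
all three fold changes share that sign, so the choice is unambiguous
there.

The cross-line intersection requires selection in *every* line with one
consistent direction; proteins absent from any line's contrast table
(dropped for lack of observed replicates) are excluded rather than
imputed.

Normalisation caveat: per-sample total normalisation shifts each sample's
log2 values by a sample-specific constant.  When planted effects are
asymmetric the condition totals differ, so normalisation slightly perturbs
fold changes; the exact-recovery benchmarks therefore run the cascade on
the unnormalised log2 matrix, while the CLI normalises real linear-scale
data before transforming (appropriate when loading differences dominate).

## Preprocessing

* `normalize_total` rescales each sample so its non-missing total equals
  the grand mean of sample totals (the target is a package choice; any
  common target gives the same relative factors).  It is idempotent.
* `log2_transform` uses pseudocount 0 by default and converts zeros to
  missing with a counted warning, since zero intensity means
  non-identification in isobaric data.
* `filter_min_present` keeps proteins observed in ≥ k (default 2)
  replicates of *every* condition (cell line × culture state).
* `impute_em` fits a multivariate normal over samples, treating proteins
  as i.i.d. observations — the orientation that is estimable when proteins
  vastly outnumber samples — and replaces missing cells with their
  conditional expectations.  Rows are grouped by missingness pattern; the
  observed-data log-likelihood is monitored and is non-decreasing.
  Convergence: relative log-likelihood change < 1e-6 (default), cap 100
  iterations (best iterate returned with a warning).  Singular covariances
  receive an automatic ridge of 1e-6 × mean diagonal (escalated ×10 on
  repeated failure), noted in the report.  The procedure is deterministic
  and never alters observed cells.

Pipeline order for the differential-expression branch is fixed:
log-transform → presence filter → imputation → moderated t.

## Moderated t

Two-group pooled-variance linear model only (the knockdown design is a
triplicate two-group comparison); general design matrices are out of
scope.  The prior (d₀, s₀²) is estimated by moment-matching log s²:
with e = log s² − ψ(d/2) + log(d/2), set ψ′(d₀/2) = var(e) − ψ′(d/2) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).  The trigamma inverse is solved
by damped Newton iteration to |Δ|/y < 1e-8.  When the spread of log s²
does not exceed its sampling floor, the prior is degenerate (d₀ = ∞) and
s₀² is taken as the geometric mean of the observed s², so that identical
per-protein variances reduce the moderated t exactly to the ordinary
pooled t.  Plain estimation is used (no robustification against variance
outliers, no abundance trend).  Zero-variance proteins are floored to the
smallest positive s² × 1e-3 with a note, to avoid infinite statistics
while flagging the artifact.  p-values are two-sided from t(d₀ + d)
(normal when d₀ = ∞); FDR is Benjamini–Hochberg.

Known limitation: single imputation understates residual variance for
proteins with imputed cells, and left-censored missingness biases group
means; the downstream FDR is therefore mildly anti-conservative for
proteins with missing data.  The benchmarks quantify this (false-call
counts in the acceptance run); multiple imputation or censored-likelihood
models are out of scope.

## Enrichment

The preranked enrichment score follows the standard weighted
Kolmogorov–Smirnov construction with weight exponent p ∈ {0, 1}
(default 1).  The extremum of the running sum is taken at the first
position whose magnitude ties the maximum within 1e-12, so exact ± ties
resolve positionally rather than by accumulated rounding.  The null is
gene permutation: `n_perm` (default 1,000) random same-size draws from the
ranked universe, shared across sets of equal size.  p-values use the +1
continuity correction and are sign-stratified, as is the NES
normalisation.  Phenotype permutation is deliberately not offered: the
module consumes a preranked list, and with triplicate groups a phenotype
null would be degenerate.  Ranking metrics: moderated t (default), signed
−log10 p, or log2FC; ties break lexicographically.  Sets are restricted
to the ranked universe and filtered to sizes [5, 500] by default.

## Clinical module

IHC scoring multiplies extent (0: 0%, 1: <50%, 2: >50% stained cells) by
intensity (0/1/2); the attainable scores are {0, 1, 2, 4} and map to
negative (0), low (1–2), high (4).  Chi-square association uses the
Pearson statistic with optional Yates correction (2×2 only); a zero
expected count is an error, while expected counts below 5 set a warning
flag rather than failing, since the choice of when the correction or an
exact test is "appropriate" is left to the analyst.  Kaplan–Meier curves
and the log-rank test are computed with `lifelines` (deaths precede
censorings at tied times; log-rank df = groups − 1).  Survival time is
stored as a real number of months.  Tumor volume is the caliper formula
(D·d²)/6 × 3.14 with D ≥ d > 0.

## Synthetic data

The generator emulates the statistical structure the cascade and the
differential-expression model assume — not the mass-spectrometric process.
Log2 abundances are baseline (N(20, 2²) per protein, shared across
samples) + planted cumulative effects + i.i.d. Gaussian replicate noise;
matrices are exported on the linear scale (2^x).  Class defaults: 90%
null, 4% monotone-up, 2% monotone-down, 2% artifact, 1% jump-up, 1%
jump-down, apportioned by largest-remainder rounding (deterministic, sums
exactly).  Effect defaults are stand-ins — no empirical effect-size
distributions are available for real CSC markers — chosen to sit clearly
inside the behavioural classes: monotone steps from ±[0.6, 2.0], artifact
shifts from ±[0.6, 2.0] with residual inter-passage drift of the same sign
in [0, 0.3] (well inside the 0.5 exclusion window, avoiding threshold
flakiness), jump totals from ±[1.6, 3.0] with the early step in [0, 0.3].
`shared_fraction` (default 1.0) controls how many non-null proteins are
planted in all cell lines versus exactly one.

Knockdown studies plant signed shifts from ±[1.0, 2.5] (configurable) in
the KD group.  Missingness is left-censored: missing probability is
logistic in log2 abundance with steepness `censor_steepness` (default 1.0
per log2 unit), the intercept bisected so the expected overall rate equals
`missing_rate`; steepness 0 degrades to missing-completely-at-random.

What passing benchmarks show: the cascade's decision logic is exactly the
stated rule set (oracle equivalence), recovers planted structure perfectly
at zero noise, and degrades gracefully at realistic replicate noise; the
moderated-t chain matches the published formulas and controls false calls
on null data.  What they do not show: robustness to correlated replicate
noise, batch/plex effects, peptide-level artifacts, or real effect-size
distributions — none of which the generator models (only a global
sample-total offset is representable).

## Benchmark problem sizes

The shipped benchmarks use 500–1,000 proteins, 3 replicates and 20
simulation seeds per stochastic claim, with 200–500 permutations for
enrichment nulls — sizes at which every reported quantity is stable to
well within its acceptance margin while the whole suite runs in seconds.
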