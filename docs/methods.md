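# Methods

This note records the model, the generator's stated world, and every
numerical or design choice a maintainer would need to reproduce or extend
the package.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Outcome definition and trajectory taxonomy

Cognitive decline: MoCA drop ≥ 3 points from baseline to year 2 and/or
year 4, evaluated only on present follow-ups; subjects with both follow-ups
missing are unlabelable and excluded (counted in
`df.attrs["n_unlabelable"]`).  On integer MoCA scores "≥ 3 points" and
"more than 2 points" are the same predicate; the suite asserts this
identity on the full (baseline, y2, y4) ∈ [0,30]³ grid.

Trajectories partition complete-follow-up subjects by the two drops
d2 = b − y2, d4 = b − y4:

| category       | rule                 |
|----------------|----------------------|
| stable         | d2 ≤ 2 and d4 ≤ 2    |
| early_decline  | d2 > 2 and d4 > 2    |
| late_decline   | d2 ≤ 2 and d4 > 2    |
| fluctuation    | d2 > 2 and d4 ≤ 2    |

A fluctuator *is* a decliner under the and/or label (the year-2 drop meets
the threshold); only stable subjects are non-decliners.  The boundary case
of recovery to exactly −2 by year 4 counts as recovered (fluctuation, not
early decline).  MoCA z-score bins: above 0 → above average, (−1, 0] →
below average, ≤ −1 → abnormal.  Normative z-scoring itself is pluggable:
the published norms are external data, so the package accepts any
z = (raw − m(age, edu))/s function and the synthetic module ships a linear
toy norm only.

## Binarization conventions

- Comparators are strict exactly as the cutoff descriptions phrase them
  ("higher than 5" → > 5; "lower than 31" → < 31); equality at the cutoff
  is absent.
- A missing source value binarizes to absent (missing values are treated
  as absent symptoms).  A derived score with any missing constituent item
  is itself missing — partial sums would silently shift cutoff semantics.
- Sex-specific cutoffs (UPSIT < 31 female / < 30 male) resolve from the
  record's sex.
- Ordinal "equals-or-exceeds level k" thresholds are stored as
  greater-than on k − 1, keeping one comparator algebra.
- Two unverifiable wordings are resolved once and flagged: "moderate or
  severe" on 0–4 MDS-UPDRS items is score ≥ 3 (the anchor labels call 3
  moderate and 4 severe), and the STAI "very much so"/"almost always"
  cutoffs use the maximum response category (4).

Derived scores: lateralized rigidity (2 items/side), akinesia (5
items/side), tremor (4 items/side) with unilateral means; PIGD score =
mean of the five axial items, phenotype tremor score = mean of lip/jaw +
four-limb rest tremor and postural + kinetic tremor of both arms (9
items); tremor/PIGD ratio ≤ 1.0 → PIGD phenotype, ≥ 1.5 → tremor-dominant,
in between → indeterminate, 0/0 → indeterminate and x/0 → tremor-dominant
by documented convention.  MoCA v1.0 domain sums use the standard per-item
maxima (visuospatial/executive 5, naming 3, attention 6, language 3,
abstraction 2, delayed recall 5, orientation 6).

## Diagnostic statistics and qualification

LR+ = sens/(1−spec), LR− = (1−sens)/spec from the 2×2
presence-by-outcome table.  No zero-cell continuity correction by default:
a feature with no false positives has LR+ = ∞, carried through the
pipeline (a Haldane–Anscombe +0.5 option exists for likelihood work,
default off, never applied to proportions).  A never-present feature has
LR+ = NaN and is rejected.  Roles: risk iff LR+ > 2 with presence
proportion > 0.01; protective iff LR− < 0.5 with proportion < 0.99; both
iff both; otherwise rejected.  The prevalence guards act on the
*proportion* scale: the source material defines an "odds" of presence but
selects a protective factor present in 82% of subjects (odds 4.47), which
only a proportion-scale upper guard admits.  LRs are reported at 2
decimals in output tables, full precision internally.  No family-wise
error control anywhere — rejecting true predictors (type II error) is the
costlier mistake in this screening design.

Group comparisons are normality-gated: Shapiro–Wilk on both groups (p >
0.05 both → two-sample t test, otherwise Wilcoxon rank-sum, implemented as
the two-sided Mann–Whitney U); discrete variables skip the gate and use
the rank test, as do constant or < 3-subject groups where Shapiro is
undefined.  Every report records which test ran and why.  Categorical
associations use Fisher's exact test (two-sided); the suite checks it
against a hypergeometric-enumeration oracle.

Cutoff search (`optimize_cutoff`): candidates are the distinct observed
values; presence is value > c (positive hypothesis sign) or value < c
(negative).  Among candidates with presence odds > 0.01 the LR+-maximizing
cutoff wins; the search is accepted only when the Spearman correlation
between candidate cutoff and induced LR+ has the hypothesized sign with
|ρ| ≥ 0.7.  The source material states the consistency check but neither
the objective nor the floor; LR+ maximization sits behind a strategy
switch and the floor is a parameter.

## The combiner and model reduction

Posterior: odds o = π/(1−π) from the age-of-onset bracket prior
(whole-dataset prior when age is missing or the bracket is empty),
multiplied by LR+ for each *present* risk feature and LR− for each
*absent* protective feature.  A feature whose negative side did not
qualify contributes nothing when absent — this exactly reproduces the
published four-question model (its members' LR− of 0.94, 0.97, 0.56 all
fail the < 0.5 rule) and is what lets a user neutralize stroke by
answering "no".  ∞ · present → posterior exactly 1; prior 0 with infinite
evidence raises an indeterminate-evidence error rather than guessing.
Priors use the [30,40), [40,45) … [70,75), [75,100) bracket grid,
half-open on the right, configurable; pooling across cohorts sums decliner
and total counts per bracket.

LRTS elimination: the likelihood functional is the Bernoulli
log-likelihood of observed outcomes under model posteriors (probabilities
clipped to [1e−12, 1−1e−12]); the source does not define one, and this is
the only likelihood available to a classifier of this form — it is
isolated behind `model_log_likelihood` so alternatives can be swapped in.
Per pass the single least-significant feature is removed if its LRTS falls
below χ²₀.₉₅(1) = 3.841 (α configurable), repeating until all survivors
are significant.  The source contains one sentence inverting this
convention ("a model excluding the tested feature was preferred … when the
LRTS exceeded the 95% quantile") that contradicts its own neighboring
sentence; the conventional reading — retain significant features — is
implemented.  Per-feature LRs are held fixed during elimination by default
(naïve Bayes LRs are marginal quantities, independent of which other
features remain); a re-estimation mode exists.  Feature selection runs
with the whole-dataset prior so the age structure cannot leak into it; the
final model carries the bracket priors.

Redundancy: for same-hypothesis pairs with Jaccard index strictly > 0.5
(both-absent pairs have J = 0 by convention), the member with the smaller
single-feature LRTS contribution is dropped; ties break on smaller
|log LR+|, then the lexicographically later name.  Different hypothesis
groups are never merged.

## Evaluation

ROC sweeps all distinct posterior cutoffs; AUC is the trapezoidal area,
which equals the tie-corrected Mann–Whitney statistic — ties weighted ½, a
material choice because a handful of binary features produces heavily tied
posteriors.  Cross-validation is repeated random subsampling: simple
(unstratified) uniform splits, training size ⌊0.8·n⌋, 300 repetitions by
default; priors and LRs refit on each training split with the feature set
held fixed; test splits missing an outcome class are redrawn and the
redraw count reported.  The reported spread is the across-repetition sd
(the across-subject alternative is not implemented).  Decision metrics use
the inclusive ≥ 50% cutoff.  No bootstrap CIs and no probability
re-calibration.

## The synthetic world

Defaults are the published summary statistics, chosen once:

- Age-of-onset brackets: combined-cohort counts/priors (n = 228, 58
  decliners; bracket priors 0.33, 0.29, 0.10, 0.11, 0.20, 0.23, 0.40,
  0.32, 0.64); sampling weights proportional to bracket n; age uniform
  within its bracket (finer structure is unidentifiable from the tables).
- Features, class-conditionally independent given outcome (the naïve
  Bayes assumption, which makes the enumeration oracle exact): stroke
  sens 3/49, spec 1; fainting sens 2/49, spec 135/137; dream vocalization
  sens 27/49, spec 109/137 — integer reconstructions of the published
  LR/proportion rows.  Columns are named after the clinical source
  variables so the packaged model scores generated cohorts directly.
- Trajectory mix among decliners: early 0.37 / late 0.33 / fluctuation
  0.30 (the training cohort's early and late shares; the remainder is
  fluctuation).  Non-decliners are stable.  These shares are narrative,
  not calibrated — the source gives no distributional detail for
  fluctuation.
- MoCA baseline ~ Normal(27.2, 2.1), rounded, clipped to [0, 30] (pooled
  baseline mean/sd of the two outcome groups); decline drops are
  3 + Geometric(0.5) − 1 points, stable-pattern noise uniform on
  {−2,…,+2}.  Only the ≥ 3-point threshold semantics matter downstream.
  Baselines of decline-pattern subjects are floored at 3 so the assigned
  drop is always realizable — this keeps label recovery exact and is
  immaterial at realistic MoCA means.
- Missingness: MCAR on item columns at rate 0.02 (the study reports at
  most 4 missing values per variable in 186 subjects); never on age of
  onset unless configured.  MCAR masking scales both class-conditional
  presence rates by (1 − rate), so implied LRs are unchanged while the
  implied presence proportion shrinks — the oracle accounts for this.
- A pairwise-dependence hook (feature B copies feature A with probability
  p) exists only to exercise the Jaccard filter; the analytic oracles
  assume independence and ignore it.

What a green test does and does not establish: the generator reproduces
the *binarized* statistical structure the pipeline assumes — it does not
simulate item-level psychometrics, correlated questionnaire batteries,
informative missingness, or cohort effects, so recovery tests validate
the estimation machinery, not the clinical claims.  The published
headline AUCs require the access-controlled cohorts and are not
reproduced; the exact generative AUC of the four-question model under the
stated world is computed by the enumeration oracle and compared with
Monte-Carlo estimates in the suite.

## Numerical and degenerate-input conventions

- Posterior clipping only inside the likelihood (ε = 1e−12); posteriors
  themselves are exact, including exact 0 and 1.
- `optimize_cutoff` with < 2 distinct values, or no candidate clearing the
  odds bound, returns a rejected result rather than raising.
- Elimination down to zero features returns a valid prior-only model.
- Empty brackets fall back to the overall prior at lookup time.
- CV raises when the cohort cannot form a two-class test split at all, and
  redraws (bounded, counted) when a particular split is degenerate.
- Serialization: model JSON round-trips infinities (JSON `Infinity`
  literal, as Python's `json` reads and writes them); cohort CSVs encode
  booleans as 0/1 and missing values as empty cells, so absent ≠ zero and
  write→read is an identity the suite asserts.

## Known limitations

- The LRTS for a feature inside a multi-feature model uses plug-in
  marginal LR estimates, not a joint conditional MLE; its null
  distribution is χ²(1) only asymptotically (measured slightly
  conservative at n = 1000 in the calibration suite).
- The cutoff-search acceptance rule (|ρ| ≥ 0.7) is a heuristic guard
  against cutoff overfitting, not a calibrated test.
- No MCI/dementia clinical criteria, no genetic/CSF/imaging biomarkers,
  no model updating from interim follow-ups, no probability
  re-calibration.
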