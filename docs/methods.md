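# Methods

This note documents the models, numerical choices and open design decisions
behind `svhbench`, and what the synthetic-data tests do and do not
demonstrate about real radiographic scoring data.

## The score data model

The Sharp–van der Heijde scheme is encoded as an explicit registry of 86
scored locations: per side, 15 hand/wrist and 6 foot joint-space-narrowing
(JSN) areas capped at 4, 16 hand/wrist erosion areas capped at 5, and 6
foot erosion joints capped at 10 (the two sides of each foot joint are
scored together, which is why the cap doubles and why the foot contributes
6 erosion locations per side rather than 12). Caps sum to 448. Only the
cardinalities and caps are load-bearing for any metric; the individual
area names (MCP1–5, PIP2–5, CMC3–5, carpal composites, MTP1–5, IP1, and the
16-site erosion enumeration) follow the standard SvH lists and act purely
as registry configuration and CSV column names.

The CSV template is our own documented dialect (`{LH|RH|LF|RF}_{name}__{J|E}`
columns plus `Patient_ID`, `Overall_narrowing`, `Overall_erosion`,
`Overall_Tol`): the original challenge's exact template is not public, so
ours is an explicit convention, not a reconstruction. Ground-truth files
must contain integers and their stored sub-totals are cross-checked
exactly; submission files are real-valued and their `Overall_Tol` column is
treated as an independent patient-level prediction (used by subchallenge 1),
so it is deliberately *not* checked against the sum of the joint columns —
teams may estimate overall damage separately from per-joint damage.
Reading uses pandas with `float_precision="round_trip"` so write→read is
bit-exact.

## The patient-weighted log-RMSE

The implemented form is

    wRMSE = sqrt( Σ w_i d_i² / Σ w_i ),   d_i = ln(1+y_i) − ln(1+s_i)

with the sum running over the subchallenge's comparison units (sc1: one
term per patient on overall totals; sc2/sc3: one term per JSN/erosion
location) and w_i the weight of the term's patient. Normalising by Σw makes
the metric a weighted mean of squared residuals, invariant under rescaling
all weights — verified by a duplication property test. The log is natural:
the published bin thresholds (1.1 ≈ ln 3, 1.95 ≈ ln 7, 3 ≈ ln 20, 4 ≈ ln 55,
5 ≈ ln 148) admit no other base.

Weights come from an 8-bin partition of the *ground-truth* overall total
(never the prediction, so all teams share identical weights): ranges 0, 1,
2–3, 4–7, 8–20, 21–55, 56–148, >148; threshold = ln(upper limit) except
bins 0 and 1 (thresholds 0 and 1) and the open bin (threshold 6); weight =
2^threshold. Real-valued totals are bucketed by the integer range containing
their floor, making bin assignment total on the non-negative reals.

Two readings of the weighting scheme were possible: pure per-term weighting,
or resampling patients into severity-balanced subsets. We implement pure
weighting — the deterministic reading that makes the metric a simple
weighted mean — and pool per-joint terms directly rather than averaging
within patient first, consistent with treating each joint score as a
comparison unit. Both choices are isolated in one function
(`patient_rmse_components`) should a variant ever be needed.

## Bootstrap Bayes factors

The resampling unit is the radiographic set (one patient row), drawn with
replacement at full cohort size; the same resample is shared by all teams
within an iteration, pairing the comparison. Because a patient's weight
depends only on their own truth total, the metric on a resample equals
`sqrt(A[idx].sum()/W[idx].sum())` with per-patient aggregates
A_p = w_p Σ_j d_pj², W_p = w_p n_j — the bootstrap is exact, not an
approximation, and fast enough for B=1000 at hundreds of patients in
milliseconds. Resample indices are logged for audit; (seed, B, cohort)
fully determine the matrix.

The Bayes factor versus a reference submission counts strict per-iteration
wins: K = ref wins / challenger wins. Exact metric ties within an iteration
are excluded from both counts, which keeps K → 1/K under swapping the pair;
an all-tie column (a team against itself or a bit-identical clone) is
reported as K = 1. K > 3 classifies the challenger worse, 1/K > 3 better,
anything else a statistical tie — the published rule states only the
"greater than 3" win side; the symmetric better side is the natural
completion and K = 3 exactly is a tie. Reference bootstrap-scoring
implementations may resolve within-iteration ties differently; our
exclusion rule is a documented choice.

The secondary comparison is a paired t-test of each team's bootstrap metric
vector against the reference's with Benjamini–Hochberg correction across
teams; a zero-variance difference vector is untestable and reported as
p = q = 1 with a degenerate flag.

Leaderboards sort by ascending metric with lexicographic team-id
tie-breaks, so rankings are deterministic.

## Ensembles

Cumulative top-k ensembles average the members' *raw* predicted scores per
(patient, joint) and per patient total; the metric's log transform applies
afterwards. Patient-level totals are means of the members' own totals, not
recomputed from ensembled joints, mirroring the independent-total reading
above. All k share one set of bootstrap resamples within a series run so
the Bayes-factor comparisons against the top individual are variance-paired.
With independent log-scale errors of equal SD σ the ensemble's log-residual
SD contracts like σ/√k up to a small log-normal convexity factor
(≈ √(1+σ²/2) for moderate σ); the tests verify the contraction within 10%
and also construct the orthogonal-member effect: four strongly
error-correlated leaders plus one individually worse but independent team,
whose inclusion dilutes the shared error component and improves the
ensemble.

## Synthetic data

The generator emulates the qualitative statistics of real RA cohorts, not
any particular printed table: a damage-free fraction (`zero_inflation`,
default 0.10 — damage-free patients exist in every RA cohort and anchor
weight bin 0), right-skewed totals with medians around 10 and a tail past
200 but far below the 448 ceiling, and per-joint zero inflation even in
damaged patients. Mechanism: latent severity S = scale·exp(σ·z) (log-normal,
defaults scale 1, σ 1.4), per-location gamma susceptibility g with variance
`joint_dispersion` (default 0.5), damage probability p = S·g/(S·g + h) with
half-max severity h = 44, and score ~ Binomial(cap, p). The defaults were
chosen once to land the median total near 10 with an IQR of roughly 2–25
and were not tuned to any test.

Simulated teams perturb the truth on the log scale — the metric's own
scale — so `error_sd` is directly the weighted RMSE an unbiased independent
team converges to; bias is likewise applied on the log scale. Correlated
teams mix an independent normal field with a cohort-level shared field:
ε = σ(c·z_shared + √(1−c²)·z_indep) + bias, giving error correlation c₁c₂
between two teams with the same shared seed. Patient totals receive their
own error draw rather than the sum of noisy joints, keeping σ interpretable
on every subchallenge. Predictions are clipped to [0, cap] per location and
[0, 448] for totals, which keeps submissions legal but truncates the error
distribution near the boundaries — calibration tests therefore use cohorts
kept away from the clip limits (severity scale 10, σ 0.5, no zero
inflation). Reader pairs apply the same log-scale perturbation per reader,
then round and clip to caps, yielding valid integer sheets for the
inter-reader CV (mean over patients of pair SD/mean, ddof=1, zero-mean
pairs excluded and counted).

What passing these tests does *not* show: real model errors are not
log-normal, not homoscedastic across severity, and correlate with anatomy
(wrists harder than MCPs); real cohorts have joint-to-joint dependence
beyond a single severity factor. The harness validates the *evaluation
machinery* under controlled error structure, not any claim about real
algorithm performance.

## Cross-cohort validation

When a second cohort (with its own submissions from the same teams) is
supplied, per-team metrics are computed on both and compared by the
concordance index over team pairs (1 same ordering, 0.5 random, 0
inverted; implemented via the survival-analysis concordance routine, whose
tie convention — ties in the first list non-comparable, ties only in the
second counted half — we adopt and test against explicit pair enumeration),
plus a Spearman correlation of the two metric lists.

## Outlier review

The published evaluation flagged visually discordant joints by expert
review; as a deterministic stand-in the harness flags |y − s| ≥ cutoff on
the raw score scale (default 3 score units, fully parameterised) and
reports rates as percentages rounded to one decimal.

## Numerical and operational choices

- All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive named child seeds from the run seed via CRC32-salted
  `SeedSequence`, recorded in the manifest, so reruns of an identical
  configuration are bit-identical (tested at the byte level).
- Spearman on a constant vector returns NaN rather than raising; the
  pairwise correlation matrix propagates NaN for constant teams.
- Malformed submission CSVs are skipped with a logged diagnostic during a
  pipeline run (a rolling-leaderboard operational model), but raise when
  read directly.
- Default problem sizes in the test suite (cohorts of 10–500, bootstrap
  B ≤ 1000, 20-replicate simulations) keep the whole suite under a minute
  while leaving the statistical assertions well-powered.

## Known limitations

- The harness scores sheets, not images: no DICOM, detection or
  segmentation.
- The per-patient severity factor is the only source of joint dependence in
  synthetic truth; spatial patterns of RA damage are not modelled.
- The inter-reader CV construction (per-pair CV averaged over patients) is
  one reasonable convention; published CV values for real reader pairs may
  use a different estimator.
- Ensembling is the arithmetic mean only; no weighted or stacked variants.
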