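# Methods

## Data model and formats

A *fragment* is a contiguous stretch of sequence with per-residue chemical
shifts for up to six nuclei — C (carbonyl), Cα, Cβ, HN, Hα, N — and a binary
label (`hairpin` / `not_hairpin`). Fragments travel in a TSV dialect with one
row per residue and fixed column order
(`protein_id, fragment_id, class, pos, aa, cs_C, cs_CA, cs_CB, cs_HN, cs_HA, cs_N`);
missing shifts are `NA` or empty, floats are written in shortest round-trip
form so write∘read is the identity. The canonical nucleus order above indexes
every vector and covariance in the package; nothing depends on dictionary
ordering. Nonstandard residues are carried as `X` with a warning; they only
matter for composition features, where they are excluded from both numerator
and denominator so the 20 fractions always sum to exactly 1.

Validation is advisory, not blocking: the default policy flags fragment
lengths outside 7–38 (hairpin) / 8–40 (not-hairpin) — the ranges typical of
curated hairpin/beta-link data — and per-nucleus coverage below 1.0. The
ranges describe data, not the method, so violations are reported and the
caller decides.

## Features

The primary feature is the per-nucleus average shift over the fragment,
giving a six-dimensional vector per fragment. With missing assignments the
mean is taken over present residues, gated by a `min_coverage` fraction
(default 1.0, i.e. strict completeness; fragments failing it are dropped and
listed, never silently imputed). Averaging is permutation-invariant and
commutes with additive shifts, both property-tested. Subset features (any of
the six nuclei, in canonical order) implement leave-one-nucleus-out ablation
through the same code path. The 20-dimensional amino-acid composition is
provided as a deliberately weaker comparison feature.

No secondary-shift referencing or random-coil correction is applied: input
values are taken as given.

## The discriminant

Each class v is modelled as Gaussian with mean μ_v and covariance Σ_v
estimated with the maximum-likelihood divisor p_v (class count); an
`unbiased` flag switches to p_v − 1 for sensitivity analysis (the two differ
by a factor p/(p−1), which barely moves decisions at the sample sizes here).
The score is η_v = ln p_v − δ_v/2 − ½ln|Σ_v| with δ_v the squared Mahalanobis
distance, computed via Cholesky solve — the inverse covariance is never
formed, and ln|Σ| comes from the factor diagonal. Using raw counts in ln p_v
rather than normalized priors shifts both scores by the same constant, so
predictions are unchanged; this is documented, not configurable.

Numerical choices:

- **Ridge.** Default ε = 0 for shift features (a 6×6 covariance from ≥ 50
  samples per class is comfortably positive definite). Composition features
  live on a simplex, so their covariance is rank-deficient by construction;
  the CLI defaults to ε = 1e-6 there. A singular covariance at ε = 0 raises
  an error advising a ridge rather than silently regularising.
- **Ties.** |η_hairpin − η_not| < 1e-12 predicts hairpin (the positive
  class); deterministic and favours sensitivity.
- **Serialization.** Models round-trip through JSON with full float
  precision; loading a file with an unknown version fails loudly.

## The error-allowed-scope correction

For a misclassified sample, R = (η_corr − η_wro)/η_corr with η_corr the
score of the *true* class; the sample is re-counted as correct when
R < r_max (default 0.2). The formula is implemented verbatim, which has two
consequences worth knowing. First, it needs the true label, so it is strictly
an evaluation-time device — `predict` on unlabeled data never applies it.
Second, its sign depends on the sign of η_corr: when η_corr > 0, any
misclassification gives R < 0 and is corrected at any non-negative threshold,
so in a strongly positive-η regime corrected metrics saturate; when
η_corr < 0 (far-from-mean samples), R is positive and the threshold bites.
Samples with η_corr = 0 are logged as undefined and left uncorrected. Because
the correction can only turn errors into successes, corrected accuracy is
non-decreasing in r_max — an invariant the tests assert. The correction is
applied per fold before averaging (pooled application is available via the
pooled confusion counts, which are always reported alongside).

Because corrected accuracies can saturate into ties, the nucleus-importance
ranking uses **uncorrected** fold-averaged accuracy by default (ascending:
the nucleus whose removal hurts most ranks first; ties break by MCC, then
canonical order); a `corrected=True` flag gives the corrected-metric ranking.

## Screening and evaluation statistics

Per-nucleus screening is the two-group special case of one-way ANOVA:
F = MS_between/MS_within with df (1, n−2), identical to the squared
pooled-variance t statistic (asserted to 1e-10 against an independent t
oracle). Degrees of freedom are printed in all outputs. P-P plots use
i/(n+1) plotting positions against a normal fitted by moments (ddof = 1);
the maximum diagonal deviation summarises departure from normality.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/n as percentages,
and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) on [−1, 1] — the
standard square-root form; a variant without the radical is sometimes seen in
print but is not self-consistent with values like 0.85, so it is not offered.
Metrics with an empty marginal are reported as undefined, never as silent
zeros. Accuracy equals the class-size-weighted mean of Sn and Sp, asserted as
an identity on random confusion tables.

## Cross-validation and comparison

Folds are stratified by default (75 negatives across 3 folds is fragile
unstratified) and deterministic given a seed; per-class fold sizes differ by
at most one. Reports carry per-fold, fold-averaged and pooled metrics, raw
and corrected — averaging and pooling genuinely differ with uneven folds, so
both are always present and labeled. Ablation reuses one fold assignment
across the full six-nuclei run and all six omission runs, drawn from the
fragments that pass full six-nuclei coverage, so the seven reports are
comparable row for row. External classifiers (e.g. scikit-learn SVM/RF) plug
in through a fit/predict array protocol and are evaluated on the same folds;
they have no η scores, hence no R correction, and a failing classifier is
recorded without aborting the comparison.

## Synthetic data and the Bayes oracle

The generator samples, per fragment: a length uniform in the class range
(defaults 7–38 hairpin, 8–40 not-hairpin), a six-dimensional fragment-level
center from the class Gaussian, then per-residue shifts as center plus
independent per-nucleus noise, with optional independent missingness and
uniform residue letters. Sampling at residue level (not the averages
directly) exercises the whole I/O → features → classifier pipeline. The
fragment-average vector is then class-conditionally Gaussian with covariance
Σ_class + diag(noise²)/l, marginalised over length — exactly the family the
discriminant assumes, so the Monte-Carlo Bayes-error oracle (exact posterior
under the generating mixture, priors proportional to class sizes) is a valid
bound for accuracy claims.

Defaults, chosen once for realism of magnitudes: class means
(176, 56, 40, 8.3, 4.3, 119) ppm with fragment-level SDs
(1.5, 1.5, 2.0, 0.3, 0.25, 2.5) ppm, diagonal covariance shared between
classes, per-residue noise SD at 0.5× the fragment-level SD, missingness 0.
`default_config(separation)` offsets the second class mean along
√diag(Σ)/√6, making the fragment-level Mahalanobis separation exactly the
requested value; `single_nucleus_config` puts all separation on one nucleus
for ablation probes. The study condition used by the acceptance script is
157/75 fragments at separation 3.0 — clearly separable but imperfect
(Bayes error ≈ 6%), which is the regime where correction, ablation and
screening all show non-trivial behaviour.

What the generator does **not** emulate: residue-type-dependent shift
distributions, secondary-shift physics, referencing errors, and block (e.g.
whole-nucleus) missingness. Passing tests therefore demonstrate correctness
of the statistical machinery under its own assumptions, not performance on
deposited experimental shifts — on real data the Gaussian and independence
assumptions hold only approximately, and the P-P diagnostic exists precisely
to check the first of these.

## Null-behaviour checks

Chance-level behaviour is asserted on aggregate statistics: with identical
class distributions, the mean over 10 seeds of the |fold-averaged MCC| must
stay below 0.15. A per-seed bound at that level would sit ~2 SE from zero
for a 200-fragment CV and fail by chance in a material fraction of runs, so
the aggregate form is used; it has ~11 SE of slack under the null and still
fails under any real leakage.

## Known limitations

- The R correction's evaluation-time semantics mean reported corrected
  metrics are not attainable by a deployed predictor; raw metrics are the
  honest forecast, and both are always printed.
- Covariances are estimated without shrinkage beyond the diagonal ridge;
  with < ~5 samples per feature per class, expect optimistic determinants
  (a warning fires when p_v < dimension).
- Only two classes are supported; the discriminant generalises to more but
  the correction coefficient as defined does not.
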