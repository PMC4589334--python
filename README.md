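# cshairpin

Beta-hairpin motif prediction from NMR chemical shifts with a two-class
quadratic discriminant.

## The problem

A beta-hairpin is a supersecondary motif of two antiparallel beta strands
joined by a tight turn; telling hairpin fragments apart from other beta-linked
fragments is a useful step in recognising protein folds before a structure is
solved. Backbone chemical shifts (C, Cα, Cβ, HN, Hα, N) are cheap, early NMR
observables that are sensitive to local structure, which makes them a natural
feature for this classification. This package is for structural
bioinformaticians who have per-residue shift assignments for labeled sequence
fragments (or want to simulate them) and want a transparent, fully inspectable
classifier rather than a black box.

## The method

A fragment of length *l* is reduced to the six-dimensional vector of
per-nucleus averages

    t_m = (1/l) Σ_j CS_mj ,   m ∈ {C, Cα, Cβ, HN, Hα, N}

Each class *v* (hairpin, not-hairpin) is fitted with a Gaussian: mean μ_v,
covariance Σ_v (maximum-likelihood divisor p_v, the class sample count). A
query vector *R* is scored per class with

    η_v = ln p_v − δ_v/2 − ½ ln|Σ_v| ,   δ_v = (R−μ_v)ᵀ Σ_v⁻¹ (R−μ_v)

and assigned to the class with the larger η (equivalent to the Bayes rule
with priors proportional to class counts). At evaluation time a misclassified
sample can be re-counted as correct when the "error-allowed-scope"
coefficient R = (η_corr − η_wro)/η_corr is below a threshold (default 0.2,
with η_corr the score of the true class). Performance is reported as
sensitivity, specificity, accuracy and Matthews correlation from three-fold
stratified cross-validation; per-nucleus one-way ANOVA screens features, and
leave-one-nucleus-out ablation ranks nucleus importance.

Because curated shift/motif datasets are not redistributable, the package
includes a synthetic fragment generator whose class structure matches the
classifier's assumptions (fragment-level Gaussian centers plus per-residue
noise), together with a Monte-Carlo Bayes-error oracle that bounds the
accuracy any classifier can reach on that generator.

## Worked example

```python
import cshairpin as ch

cfg = ch.default_config(3.0, n_hairpin=157, n_not=75, seed=1)
data, _ = ch.generate_dataset(cfg)
rep = ch.cross_validate(data, k=3, seed=1, r_max=0.2)
m = rep.averaged_raw
print(f"Sn {m.sn:.1f}%  Sp {m.sp:.1f}%  Acc {m.acc:.1f}%  MCC {m.mcc:.3f}")
c = rep.averaged_corrected
print(f"with R<0.2 correction: Acc {c.acc:.1f}%  MCC {c.mcc:.3f}")
err, se = ch.bayes_error_mc(cfg, n_mc=20000, seed=2)
print(f"Bayes error of the generator: {100*err:.1f}% (+/- {100*se:.2f}%)")
```

prints

```
Sn 96.8%  Sp 90.7%  Acc 94.8%  MCC 0.882
with R<0.2 correction: Acc 96.6%  MCC 0.922
Bayes error of the generator: 6.2% (+/- 0.17%)
```

Reading: on 157 hairpin / 75 not-hairpin synthetic fragments whose class
means sit 3 pooled SDs apart, three-fold cross-validation recovers 94.8% of
the ~93.8% accuracy the generator's Bayes bound allows (the small excess is
within sampling error of a 232-fragment test), and the error-allowed-scope
correction re-counts a handful of near-miss misclassifications. The same
pipeline runs on real data: convert the shift table to the TSV dialect
documented in `cshairpin.io` and call `read_fragment_table`.

The same runs are available from the shell:

```sh
cshairpin simulate --separation 3 --n-hairpin 157 --n-not 75 --seed 1 --out frags.tsv
cshairpin crossval frags.tsv --features cs6 --k 3 --r-max 0.2 --seed 1 --out cv.json
cshairpin ablate frags.tsv --seed 1 --out ablation.json
```

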