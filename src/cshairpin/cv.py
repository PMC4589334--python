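"""Cross-validation, leave-one-nucleus-out ablation and classifier comparison.

The evaluation protocol is stratified k-fold (default k=3) cross-validation:
fit the quadratic discriminant on k-1 parts, predict the held-out part, apply
the error-allowed-scope correction (R < r_max, default 0.2) to misclassified
samples, and report per-fold, fold-averaged and pooled metrics, both with and
without the correction.

Ablation refits on every five-nucleus subset using identical fold assignments
so accuracy drops are attributable to the omitted nucleus alone; the nucleus
whose omission hurts most ranks as most important.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ContractError, CsHairpinError, InfeasibleFoldsError
from .features import FeatureMatrix, FeatureSpec, build_feature_matrix
from .io import NUCLEI, Dataset, Label
from .qda import QdaModel, apply_r_correction, fit, predict_matrix
from .stats import ConfusionCounts, MetricsReport, confusion, metrics


@dataclass
class FoldAssignment:
    k: int
    seed: int
    stratified: bool
    fold_of: dict[str, int]  # fragment_id -> fold index in [0, k)

    def members(self, fold: int) -> list[str]:
        return [fid for fid, f in self.fold_of.items() if f == fold]


def make_folds(
    data: Dataset, k: int = 3, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Deterministically partition fragments into k folds.

    Stratified assignment shuffles each class separately and deals ids
    round-robin, so per-class fold sizes differ by at most one.
    """
    if k < 2:
        raise ContractError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    if stratified:
        for label in (Label.HAIRPIN, Label.NOT_HAIRPIN):
            ids = [f.fragment_id for f in data if f.label is label]
            if len(ids) < k:
                raise InfeasibleFoldsError(
                    f"class {label.value} has {len(ids)} fragments < k={k}"
                )
            order = rng.permutation(len(ids))
            for rank, idx in enumerate(order):
                fold_of[ids[idx]] = rank % k
    else:
        ids = [f.fragment_id for f in data]
        if len(ids) < k:
            raise InfeasibleFoldsError(f"{len(ids)} fragments < k={k}")
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            fold_of[ids[idx]] = rank % k
    return FoldAssignment(k, seed, stratified, fold_of)


@dataclass
class FoldResult:
    fold: int
    confusion_raw: ConfusionCounts
    confusion_corrected: ConfusionCounts
    metrics_raw: MetricsReport
    metrics_corrected: MetricsReport
    n_corrected: int
    n_undefined_r: int


def _mean_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of per-fold metrics, skipping undefined entries."""
    out = {}
    undefined = []
    for name in ("sn", "sp", "acc", "mcc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            out[name] = float(np.mean(vals))
        else:
            out[name] = None
            undefined.append(name)
    return MetricsReport(out["sn"], out["sp"], out["acc"], out["mcc"], tuple(undefined))


@dataclass
class CvReport:
    settings: dict
    folds: list[FoldResult]
    averaged_raw: MetricsReport
    averaged_corrected: MetricsReport
    pooled_raw: ConfusionCounts
    pooled_corrected: ConfusionCounts
    pooled_metrics_raw: MetricsReport
    pooled_metrics_corrected: MetricsReport
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        def cc(c: ConfusionCounts) -> dict:
            return {"tp": c.tp, "fn": c.fn, "fp": c.fp, "tn": c.tn}

        return {
            "settings": self.settings,
            "folds": [
                {
                    "fold": f.fold,
                    "confusion_raw": cc(f.confusion_raw),
                    "confusion_corrected": cc(f.confusion_corrected),
                    "metrics_raw": f.metrics_raw.to_dict(),
                    "metrics_corrected": f.metrics_corrected.to_dict(),
                    "n_corrected": f.n_corrected,
                    "n_undefined_r": f.n_undefined_r,
                }
                for f in self.folds
            ],
            "averaged_raw": self.averaged_raw.to_dict(),
            "averaged_corrected": self.averaged_corrected.to_dict(),
            "pooled_raw": cc(self.pooled_raw),
            "pooled_corrected": cc(self.pooled_corrected),
            "pooled_metrics_raw": self.pooled_metrics_raw.to_dict(),
            "pooled_metrics_corrected": self.pooled_metrics_corrected.to_dict(),
            "dropped": [list(d) for d in self.dropped],
        }


def cross_validate(
    data: Dataset,
    spec: FeatureSpec | None = None,
    k: int = 3,
    seed: int = 0,
    r_max: float = 0.2,
    epsilon: float = 0.0,
    stratified: bool = True,
    folds: FoldAssignment | None = None,
) -> CvReport:
    """k-fold cross-validation of the quadratic discriminant.

    Fragments dropped by the feature builder (insufficient coverage) are
    excluded before folding and listed in the report.  Passing ``folds``
    reuses an existing assignment (ablation comparability); it must cover
    every retained fragment.
    """
    spec = spec or FeatureSpec()
    X = build_feature_matrix(data, spec)
    if folds is None:
        retained = data.subset(X.fragment_ids)
        folds = make_folds(retained, k=k, seed=seed, stratified=stratified)
    missing = [fid for fid in X.fragment_ids if fid not in folds.fold_of]
    if missing:
        raise ContractError(f"fold assignment missing fragments: {missing[:5]}")

    fold_results: list[FoldResult] = []
    pooled_raw = ConfusionCounts(0, 0, 0, 0)
    pooled_cor = ConfusionCounts(0, 0, 0, 0)
    for f in range(folds.k):
        test_idx = [
            i for i, fid in enumerate(X.fragment_ids) if folds.fold_of[fid] == f
        ]
        train_idx = [
            i for i, fid in enumerate(X.fragment_ids) if folds.fold_of[fid] != f
        ]
        if not test_idx:
            raise InfeasibleFoldsError(f"fold {f} is empty")
        try:
            model = fit(X.select(train_idx), epsilon=epsilon)
        except CsHairpinError as e:
            raise type(e)(f"fold {f}: {e}") from e
        test = X.select(test_idx)
        truth = list(test.labels)
        preds = predict_matrix(model, test)
        corrected, log = apply_r_correction(preds, truth, r_max=r_max)
        c_raw = confusion(preds, truth)
        c_cor = confusion(corrected, truth)
        pooled_raw = pooled_raw + c_raw
        pooled_cor = pooled_cor + c_cor
        fold_results.append(
            FoldResult(
                f,
                c_raw,
                c_cor,
                metrics(c_raw),
                metrics(c_cor),
                len(log.corrected),
                len(log.undefined),
            )
        )
    settings = {
        "feature_kind": spec.kind.value,
        "nuclei": list(spec.nuclei) if spec.kind.value != "aac20" else None,
        "min_coverage": spec.min_coverage,
        "k": folds.k,
        "seed": folds.seed,
        "stratified": folds.stratified,
        "r_max": r_max,
        "epsilon": epsilon,
        "n_fragments": len(X),
    }
    return CvReport(
        settings,
        fold_results,
        _mean_metrics([fr.metrics_raw for fr in fold_results]),
        _mean_metrics([fr.metrics_corrected for fr in fold_results]),
        pooled_raw,
        pooled_cor,
        metrics(pooled_raw),
        metrics(pooled_cor),
        X.dropped,
    )


@dataclass
class AblationResult:
    full: CvReport
    omitted: dict[str, CvReport]  # omitted nucleus -> report on the other five


def ablate_nuclei(
    data: Dataset,
    k: int = 3,
    seed: int = 0,
    r_max: float = 0.2,
    epsilon: float = 0.0,
    min_coverage: float = 1.0,
) -> AblationResult:
    """Full six-nuclei CV plus six leave-one-nucleus-out CVs on shared folds.

    Folds are drawn once from the fragments retained by the full six-nuclei
    spec and reused everywhere, so the seven reports are directly comparable.
    """
    base = FeatureSpec(min_coverage=min_coverage)
    X = build_feature_matrix(data, base)
    retained = data.subset(X.fragment_ids)
    folds = make_folds(retained, k=k, seed=seed, stratified=True)
    full = cross_validate(
        retained, base, k=k, seed=seed, r_max=r_max, epsilon=epsilon, folds=folds
    )
    omitted = {}
    for m in NUCLEI:
        spec = FeatureSpec.cs_omit(m, min_coverage=min_coverage)
        omitted[m] = cross_validate(
            retained, spec, k=k, seed=seed, r_max=r_max, epsilon=epsilon, folds=folds
        )
    return AblationResult(full, omitted)


def rank_nuclei(ablation: AblationResult, corrected: bool = False) -> list[str]:
    """Order nuclei most- to least-important by leave-one-out accuracy drop.

    A nucleus whose omission gives the lowest fold-averaged accuracy ranks
    first; ties break by lowest averaged MCC, then canonical nucleus order.
    Uncorrected metrics are the default ranking signal: with positive eta
    scores the error-allowed-scope correction recovers every misclassification,
    collapsing corrected accuracies into uninformative ties.
    """

    def key(m: str):
        rep = ablation.omitted[m].averaged_corrected if corrected else (
            ablation.omitted[m].averaged_raw
        )
        acc = rep.acc if rep.acc is not None else float("inf")
        mcc = rep.mcc if rep.mcc is not None else float("inf")
        return (acc, mcc, NUCLEI.index(m))

    return sorted(NUCLEI, key=key)


# ---------------------------------------------------------------------------
# Pluggable classifier comparison


@dataclass
class ComparisonRow:
    name: str
    averaged: MetricsReport | None
    pooled: MetricsReport | None
    error: str | None = None


def compare_classifiers(
    data: Dataset,
    spec: FeatureSpec | None = None,
    k: int = 3,
    seed: int = 0,
    classifiers: Mapping[str, object] | None = None,
    epsilon: float = 0.0,
) -> list[ComparisonRow]:
    """Benchmark external classifiers against the internal QDA on shared folds.

    External classifiers follow the fit(X, y)/predict(X) array protocol
    (y is 1 for hairpin).  The internal discriminant is always the first row;
    external metrics are uncorrected (no eta scores, so no R correction).
    A failing classifier is recorded and the rest proceed.
    """
    spec = spec or FeatureSpec()
    X = build_feature_matrix(data, spec)
    retained = data.subset(X.fragment_ids)
    folds = make_folds(retained, k=k, seed=seed, stratified=True)

    rows: list[ComparisonRow] = []
    qda_rep = cross_validate(
        retained, spec, k=k, seed=seed, r_max=0.2, epsilon=epsilon, folds=folds
    )
    rows.append(ComparisonRow("QDA", qda_rep.averaged_raw, qda_rep.pooled_metrics_raw))

    y = np.array([lab is Label.HAIRPIN for lab in X.labels], dtype=int)
    for name, clf in (classifiers or {}).items():
        try:
            per_fold: list[MetricsReport] = []
            pooled = ConfusionCounts(0, 0, 0, 0)
            for f in range(folds.k):
                test = np.array(
                    [folds.fold_of[fid] == f for fid in X.fragment_ids]
                )
                clf.fit(X.X[~test], y[~test])
                pred = np.asarray(clf.predict(X.X[test])).astype(int)
                truth = y[test]
                tp = int(np.sum((pred == 1) & (truth == 1)))
                fn = int(np.sum((pred == 0) & (truth == 1)))
                fp = int(np.sum((pred == 1) & (truth == 0)))
                tn = int(np.sum((pred == 0) & (truth == 0)))
                c = ConfusionCounts(tp, fn, fp, tn)
                pooled = pooled + c
                per_fold.append(metrics(c))
            rows.append(
                ComparisonRow(name, _mean_metrics(per_fold), metrics(pooled))
            )
        except Exception as e:  # noqa: BLE001 - isolate classifier failures
            rows.append(ComparisonRow(name, None, None, error=str(e)))
    return rows
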