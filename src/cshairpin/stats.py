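"""Feature screening and evaluation statistics.

Contains the two-group one-way ANOVA used to screen each nucleus' averaged
shift for class separation (for two groups the F statistic equals the squared
pooled-variance t), normal P-P plot points for eyeballing the Gaussian
assumption behind the discriminant, and the four confusion-matrix metrics:
sensitivity, specificity, overall accuracy (as percentages) and Matthews
correlation coefficient on [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ContractError, DegenerateInputError, MissingClassError
from .features import FeatureMatrix
from .io import Label
from .qda import PredictionResult


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    ms_b: float  # between-group mean square
    ms_w: float  # within-group mean square
    f_value: float
    df: tuple[int, int]
    p_value: float


def anova_two_group(
    a: Sequence[float], b: Sequence[float], feature: str = ""
) -> AnovaResult:
    """One-way ANOVA for exactly two groups.

    F = MS_between / MS_within with df (1, n_a + n_b - 2); the p-value is the
    upper tail of the F distribution.  Zero within-group variance with a
    between-group difference yields F = inf, p = 0; zero variance everywhere
    is a degenerate input.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("each group needs at least 2 values")
    na, nb = len(x), len(y)
    grand = (x.sum() + y.sum()) / (na + nb)
    ss_b = na * (x.mean() - grand) ** 2 + nb * (y.mean() - grand) ** 2
    ss_w = float(((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
    df_b, df_w = 1, na + nb - 2
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0:
        if ms_b == 0:
            raise DegenerateInputError("both groups are constant and equal")
        return AnovaResult(feature, ms_b, 0.0, math.inf, (df_b, df_w), 0.0)
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(feature, ms_b, ms_w, f, (df_b, df_w), p)


def anova_by_nucleus(X: FeatureMatrix) -> list[AnovaResult]:
    """Screen every feature column for hairpin vs not-hairpin separation,
    returning one :class:`AnovaResult` per feature in matrix column order."""
    h = X.rows_for(Label.HAIRPIN)
    n = X.rows_for(Label.NOT_HAIRPIN)
    if h.shape[0] < 2 or n.shape[0] < 2:
        raise MissingClassError("both classes need at least 2 fragments")
    return [
        anova_two_group(h[:, j], n[:, j], feature=name)
        for j, name in enumerate(X.names)
    ]


@dataclass(frozen=True)
class PpResult:
    """P-P plot points: empirical vs fitted-normal cumulative probabilities."""

    points: list[tuple[float, float]]
    max_abs_deviation: float


def pp_plot_points(values: Sequence[float]) -> PpResult:
    """Normal P-P plot points with i/(n+1) plotting positions.

    The theoretical probabilities come from a normal with the sample mean and
    sample SD (ddof=1).  If the data are normal the points hug the diagonal;
    ``max_abs_deviation`` summarises the worst departure.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 3:
        raise ContractError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance; P-P plot undefined")
    emp = np.arange(1, n + 1) / (n + 1)
    theo = sps.norm.cdf(x, loc=x.mean(), scale=sd)
    dev = float(np.max(np.abs(emp - theo)))
    return PpResult(list(zip(emp.tolist(), theo.tolist())), dev)


# ---------------------------------------------------------------------------
# Confusion counts and metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


def confusion(
    preds: Sequence[PredictionResult], truth: Sequence[Label]
) -> ConfusionCounts:
    """Tally TP/FN/FP/TN; a prediction flagged ``corrected`` counts as
    correct for its true class regardless of the predicted label."""
    if len(preds) != len(truth):
        raise ContractError(f"{len(preds)} predictions vs {len(truth)} labels")
    tp = fn = fp = tn = 0
    for pr, t in zip(preds, truth):
        correct = pr.corrected or pr.predicted is t
        if t is Label.HAIRPIN:
            tp += correct
            fn += not correct
        else:
            tn += correct
            fp += not correct
    return ConfusionCounts(tp, fn, fp, tn)


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc as percentages, MCC on [-1, 1]; metrics whose marginal is
    empty are None and listed in ``undefined`` (never silently zero)."""

    sn: float | None
    sp: float | None
    acc: float | None
    mcc: float | None
    undefined: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "sn_pct": self.sn,
            "sp_pct": self.sp,
            "acc_pct": self.acc,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy (percent) and Matthews correlation.

    MCC uses the standard square-root denominator
    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)) on [-1, 1].
    """
    undefined: list[str] = []
    sn = sp = acc = mcc = None
    if c.tp + c.fn > 0:
        sn = 100.0 * c.tp / (c.tp + c.fn)
    else:
        undefined.append("sn")
    if c.tn + c.fp > 0:
        sp = 100.0 * c.tn / (c.tn + c.fp)
    else:
        undefined.append("sp")
    if c.total > 0:
        acc = 100.0 * (c.tp + c.tn) / c.total
    else:
        undefined.append("acc")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        undefined.append("mcc")
    return MetricsReport(sn, sp, acc, mcc, tuple(undefined))
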