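"""Two-class quadratic discriminant analysis on fragment feature vectors.

Each class v (hairpin / not-hairpin) is modelled by a Gaussian with mean
mu_v, covariance Sigma_v (maximum-likelihood form: divisor p_v, the class
sample count) and a per-class score

    eta_v = ln(p_v) - delta_v / 2 - ln|Sigma_v| / 2

where delta_v is the squared Mahalanobis distance of the query vector from
mu_v.  The predicted class maximises eta_v, which is equivalent to the Bayes
rule with priors proportional to the raw class counts (the two differ only by
a constant common to both classes).  The score difference

    xi = eta_hairpin - eta_not_hairpin

is the log-posterior-odds discriminant.

The "error-allowed-scope" coefficient

    R = (eta_corr - eta_wro) / eta_corr

(eta of the true class vs eta of the wrongly predicted class) re-counts a
misclassified sample as correct at evaluation time when R < r_max.  It needs
the true label, so it is strictly an evaluation-time device; prediction on
unlabeled data never applies it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import (
    ContractError,
    FormatError,
    MissingClassError,
    SingularCovarianceError,
    UndefinedRError,
)
from .features import FeatureMatrix, FeatureVector
from .io import Label

MODEL_FORMAT_VERSION = 1

#: Score differences below this magnitude are treated as ties (-> HAIRPIN).
TIE_TOLERANCE = 1e-12


@dataclass
class ClassModel:
    """Fitted Gaussian for one class: count, mean, covariance, log|Sigma|."""

    label: Label
    p: int
    mu: np.ndarray
    sigma: np.ndarray  # includes the ridge epsilon on the diagonal
    log_det: float
    epsilon: float = 0.0
    _chol: tuple | None = field(default=None, repr=False, compare=False)

    def _factor(self) -> tuple:
        if self._chol is None:
            self._chol = cho_factor(self.sigma, lower=True)
        return self._chol

    @property
    def dim(self) -> int:
        return self.mu.shape[0]


def _as_vector(x: FeatureVector | np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    if isinstance(x, FeatureVector):
        if tuple(x.names) != tuple(names):
            raise ContractError(
                f"feature names {list(x.names)} do not match model {list(names)}"
            )
        return x.values
    v = np.asarray(x, dtype=float)
    if v.shape != (len(names),):
        raise ContractError(f"expected a vector of length {len(names)}, got {v.shape}")
    return v


def mahalanobis_sq(cm: ClassModel, x: FeatureVector | np.ndarray) -> float:
    """Squared Mahalanobis distance (x - mu)' Sigma^-1 (x - mu).

    Computed through a Cholesky solve; the covariance inverse is never formed.
    """
    v = np.asarray(x.values if isinstance(x, FeatureVector) else x, dtype=float)
    if v.shape != (cm.dim,):
        raise ContractError(f"dimension mismatch: model {cm.dim}, vector {v.shape}")
    d = v - cm.mu
    return float(d @ cho_solve(cm._factor(), d))


def eta(cm: ClassModel, x: FeatureVector | np.ndarray) -> float:
    """Per-class discriminant score ln(p) - delta/2 - ln|Sigma|/2."""
    return math.log(cm.p) - mahalanobis_sq(cm, x) / 2.0 - cm.log_det / 2.0


@dataclass
class QdaModel:
    feature_names: tuple[str, ...]
    classes: dict[Label, ClassModel]
    epsilon: float
    n_train: int
    unbiased: bool = False

    def class_model(self, label: Label) -> ClassModel:
        return self.classes[label]


@dataclass(frozen=True)
class PredictionResult:
    fragment_id: str
    eta: dict[Label, float]
    predicted: Label
    xi: float  # eta[HAIRPIN] - eta[NOT_HAIRPIN]
    corrected: bool = False
    r_value: float | None = None


def fit(
    X: FeatureMatrix, epsilon: float = 0.0, unbiased: bool = False
) -> QdaModel:
    """Fit per-class Gaussians.

    The covariance divisor is the class sample count p_v (maximum likelihood);
    ``unbiased=True`` switches to p_v - 1 for sensitivity analysis.  A ridge
    ``epsilon`` is added to the diagonal before factorisation — needed for
    rank-deficient covariances such as compositional (simplex) features.
    """
    if epsilon < 0:
        raise ContractError("epsilon must be >= 0")
    classes: dict[Label, ClassModel] = {}
    d = len(X.names)
    for label in (Label.HAIRPIN, Label.NOT_HAIRPIN):
        rows = X.rows_for(label)
        p = rows.shape[0]
        if p < 2:
            raise MissingClassError(
                f"class {label.value} has {p} samples; need at least 2"
            )
        mu = rows.mean(axis=0)
        centered = rows - mu
        divisor = p - 1 if unbiased else p
        sigma = (centered.T @ centered) / divisor
        sigma = (sigma + sigma.T) / 2.0  # enforce exact symmetry
        sigma = sigma + epsilon * np.eye(d)
        try:
            chol = cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError:
            if epsilon == 0:
                raise SingularCovarianceError(
                    f"class {label.value}: covariance is singular; "
                    "pass a small ridge epsilon (e.g. 1e-6)"
                ) from None
            raise SingularCovarianceError(
                f"class {label.value}: covariance singular even at epsilon={epsilon}"
            ) from None
        log_det = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        if p < d:
            warnings.warn(
                f"class {label.value}: {p} samples < {d} features; "
                "covariance estimate is rank-deficient without a ridge",
                stacklevel=2,
            )
        classes[label] = ClassModel(label, p, mu, sigma, log_det, epsilon, chol)
    return QdaModel(tuple(X.names), classes, epsilon, len(X), unbiased)


def predict(model: QdaModel, x: FeatureVector | np.ndarray) -> PredictionResult:
    """Classify one feature vector by the larger eta; ties go to HAIRPIN."""
    v = _as_vector(x, model.feature_names)
    etas = {lab: eta(cm, v) for lab, cm in model.classes.items()}
    xi = etas[Label.HAIRPIN] - etas[Label.NOT_HAIRPIN]
    if xi > 0 or abs(xi) < TIE_TOLERANCE:
        pred = Label.HAIRPIN
    else:
        pred = Label.NOT_HAIRPIN
    fid = x.fragment_id if isinstance(x, FeatureVector) else ""
    return PredictionResult(fid, etas, pred, xi)


def predict_matrix(model: QdaModel, X: FeatureMatrix) -> list[PredictionResult]:
    if tuple(X.names) != model.feature_names:
        raise ContractError(
            f"feature names {list(X.names)} do not match model "
            f"{list(model.feature_names)}"
        )
    out = []
    for i in range(len(X)):
        r = predict(model, X.X[i])
        out.append(replace(r, fragment_id=X.fragment_ids[i]))
    return out


def r_coefficient(eta_corr: float, eta_wro: float) -> float:
    """Error-allowed-scope coefficient R = (eta_corr - eta_wro) / eta_corr."""
    if eta_corr == 0:
        raise UndefinedRError("eta of the true class is zero; R undefined")
    return (eta_corr - eta_wro) / eta_corr


@dataclass
class CorrectionLog:
    r_max: float
    corrected: list[tuple[str, float]] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)


def apply_r_correction(
    preds: Sequence[PredictionResult],
    truth: Sequence[Label],
    r_max: float = 0.2,
) -> tuple[list[PredictionResult], CorrectionLog]:
    """Mark misclassified samples with R < r_max as corrected.

    For a misclassified sample, eta_corr is the eta of the true class and
    eta_wro the eta of the (wrong) predicted class.  Correct samples pass
    through untouched; samples with eta_corr == 0 are logged as undefined and
    left uncorrected.  Requires true labels — evaluation-time only.
    """
    if len(preds) != len(truth):
        raise ContractError(
            f"{len(preds)} predictions vs {len(truth)} truth labels"
        )
    log = CorrectionLog(r_max)
    out: list[PredictionResult] = []
    for pr, true_label in zip(preds, truth):
        if pr.predicted is true_label:
            out.append(pr)
            continue
        try:
            r = r_coefficient(pr.eta[true_label], pr.eta[pr.predicted])
        except UndefinedRError:
            log.undefined.append(pr.fragment_id)
            out.append(pr)
            continue
        if r < r_max:
            out.append(replace(pr, corrected=True, r_value=r))
            log.corrected.append((pr.fragment_id, r))
        else:
            out.append(replace(pr, r_value=r))
    return out, log


# ---------------------------------------------------------------------------
# Serialization


def _model_dict(model: QdaModel) -> dict:
    return {
        "version": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "epsilon": model.epsilon,
        "n_train": model.n_train,
        "unbiased": model.unbiased,
        "classes": [
            {
                "label": cm.label.value,
                "p": cm.p,
                "mu": cm.mu.tolist(),
                "sigma": cm.sigma.flatten().tolist(),  # row-major
                "log_det": cm.log_det,
                "epsilon": cm.epsilon,
            }
            for cm in model.classes.values()
        ],
    }


def save_model(model: QdaModel, sink: str | Path | IO[str]) -> None:
    """Serialize a fitted model as JSON (floats at full precision)."""
    text = json.dumps(_model_dict(model), indent=2, sort_keys=True)
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def load_model(source: str | Path | IO[str]) -> QdaModel:
    """Inverse of :func:`save_model`; load∘save is the identity."""
    try:
        if isinstance(source, (str, Path)):
            obj = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            obj = json.load(source)
    except json.JSONDecodeError as e:
        raise FormatError(f"not a valid model file: {e}") from None
    if not isinstance(obj, dict) or obj.get("version") != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"unsupported model file version {obj.get('version')!r}"
            if isinstance(obj, dict)
            else "not a valid model file"
        )
    names = tuple(obj["feature_names"])
    d = len(names)
    classes: dict[Label, ClassModel] = {}
    for c in obj["classes"]:
        label = Label(c["label"])
        classes[label] = ClassModel(
            label,
            int(c["p"]),
            np.array(c["mu"], dtype=float),
            np.array(c["sigma"], dtype=float).reshape(d, d),
            float(c["log_det"]),
            float(c["epsilon"]),
        )
    if set(classes) != {Label.HAIRPIN, Label.NOT_HAIRPIN}:
        raise FormatError("model file must contain both classes")
    return QdaModel(
        names, classes, float(obj["epsilon"]), int(obj["n_train"]),
        bool(obj.get("unbiased", False)),
    )
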