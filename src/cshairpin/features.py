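"""Feature construction: fragment-averaged chemical shifts and amino-acid
composition.

The primary feature is the six-dimensional vector of per-nucleus averages

    t_m = (1/l) * sum_j CS_mj        m in {C, CA, CB, HN, HA, N}

over the l residues of a fragment.  When some residues lack an assignment for
nucleus m, the mean is taken over the residues where m is present, provided
the coverage fraction is at least ``min_coverage`` (default 1.0, i.e. strict
completeness).  The alternative feature is the 20-dimensional amino-acid
composition (residue frequencies), used only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, EmptyFeatureMatrixError, InsufficientDataError
from .io import NUCLEI, STANDARD_AA, Dataset, Fragment, Label


class FeatureKind(str, Enum):
    CS6 = "cs6"
    CS_SUBSET = "cs_subset"
    AAC20 = "aac20"


@dataclass(frozen=True)
class FeatureSpec:
    """What to compute per fragment: which feature family, which nuclei."""

    kind: FeatureKind = FeatureKind.CS6
    nuclei: tuple[str, ...] = NUCLEI
    min_coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.kind in (FeatureKind.CS6, FeatureKind.CS_SUBSET):
            if not self.nuclei:
                raise ContractError("nuclei subset must be non-empty")
            bad = [m for m in self.nuclei if m not in NUCLEI]
            if bad:
                raise ContractError(f"unknown nuclei {bad}")
        if not (0 < self.min_coverage <= 1):
            raise ContractError("min_coverage must be in (0, 1]")

    @staticmethod
    def cs_omit(nucleus: str, min_coverage: float = 1.0) -> "FeatureSpec":
        """Leave-one-nucleus-out spec in canonical order."""
        if nucleus not in NUCLEI:
            raise ContractError(f"unknown nucleus {nucleus!r}")
        rest = tuple(m for m in NUCLEI if m != nucleus)
        return FeatureSpec(FeatureKind.CS_SUBSET, rest, min_coverage)

    @property
    def feature_names(self) -> tuple[str, ...]:
        if self.kind is FeatureKind.AAC20:
            return tuple(STANDARD_AA)
        return tuple(self.nuclei)


@dataclass(frozen=True)
class FeatureVector:
    fragment_id: str
    label: Label
    kind: FeatureKind
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.names),):
            raise ContractError("values length must match names")
        if not np.all(np.isfinite(v)):
            raise ContractError("feature values must be finite")


@dataclass
class FeatureMatrix:
    """Row-per-fragment feature matrix with labels and provenance."""

    names: tuple[str, ...]
    X: np.ndarray
    labels: list[Label]
    fragment_ids: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, d = self.X.shape
        if d != len(self.names) or n != len(self.labels) or n != len(self.fragment_ids):
            raise ContractError("inconsistent feature matrix dimensions")
        if not np.all(np.isfinite(self.X)):
            raise ContractError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    def rows_for(self, label: Label) -> np.ndarray:
        mask = np.array([lab is label for lab in self.labels])
        return self.X[mask]

    def select(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.names,
            self.X[idx],
            [self.labels[i] for i in idx],
            [self.fragment_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.names))
        df.insert(0, "label", [lab.value for lab in self.labels])
        df.insert(0, "fragment_id", self.fragment_ids)
        return df

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)


def average_shifts(
    frag: Fragment,
    nuclei: Sequence[str] = NUCLEI,
    min_coverage: float = 1.0,
) -> FeatureVector:
    """Average each requested nucleus' shifts over the fragment.

    Raises :class:`InsufficientDataError` naming the first nucleus whose
    coverage (fraction of residues with an assigned shift) falls below
    ``min_coverage``.
    """
    if not nuclei:
        raise ContractError("nuclei must be non-empty")
    if not (0 < min_coverage <= 1):
        raise ContractError("min_coverage must be in (0, 1]")
    values = []
    for m in nuclei:
        if m not in NUCLEI:
            raise ContractError(f"unknown nucleus {m!r}")
        present = [r.shifts[m] for r in frag.rows if r.shifts.get(m) is not None]
        cov = len(present) / len(frag)
        if cov < min_coverage:
            raise InsufficientDataError(
                f"fragment {frag.fragment_id!r}: nucleus {m} coverage "
                f"{cov:.3f} < {min_coverage}"
            )
        values.append(float(np.mean(present)))
    kind = FeatureKind.CS6 if tuple(nuclei) == NUCLEI else FeatureKind.CS_SUBSET
    return FeatureVector(frag.fragment_id, frag.label, kind, tuple(nuclei), np.array(values))


def aac_composition(frag: Fragment) -> FeatureVector:
    """20-dimensional amino-acid composition; 'X' residues are ignored
    entirely (excluded from numerator and denominator) so the fractions
    always sum to exactly 1 over the standard alphabet."""
    counts = {aa: 0 for aa in STANDARD_AA}
    n = 0
    for r in frag.rows:
        if r.residue in counts:
            counts[r.residue] += 1
            n += 1
    if n == 0:
        raise InsufficientDataError(
            f"fragment {frag.fragment_id!r} has no standard residues"
        )
    values = np.array([counts[aa] / n for aa in STANDARD_AA])
    return FeatureVector(
        frag.fragment_id, frag.label, FeatureKind.AAC20, tuple(STANDARD_AA), values
    )


def build_feature_matrix(data: Dataset, spec: FeatureSpec) -> FeatureMatrix:
    """Batch fragments into a :class:`FeatureMatrix`.

    Fragments that fail the coverage requirement are dropped and listed in
    ``matrix.dropped`` with the reason; row order follows dataset order.
    """
    if len(data) == 0:
        raise EmptyFeatureMatrixError("dataset is empty")
    rows, labels, ids, dropped = [], [], [], []
    for frag in data:
        try:
            if spec.kind is FeatureKind.AAC20:
                fv = aac_composition(frag)
            else:
                fv = average_shifts(frag, spec.nuclei, spec.min_coverage)
        except InsufficientDataError as e:
            dropped.append((frag.fragment_id, str(e)))
            continue
        rows.append(fv.values)
        labels.append(frag.label)
        ids.append(frag.fragment_id)
    if not rows:
        raise EmptyFeatureMatrixError(
            f"all {len(data)} fragments dropped: first reason: {dropped[0][1]}"
        )
    return FeatureMatrix(spec.feature_names, np.vstack(rows), labels, ids, dropped)
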