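"""Reading, writing and validating labeled chemical-shift fragment tables.

The on-disk format is a TSV dialect with one row per residue:

    protein_id  fragment_id  class  pos  aa  cs_C  cs_CA  cs_CB  cs_HN  cs_HA  cs_N

``class`` is ``hairpin`` or ``not_hairpin``; ``pos`` is 1-based within the
fragment; shift columns hold ppm values, with ``NA`` or an empty cell meaning
the shift is unassigned.  Nuclei are always handled in the canonical order
C, CA, CB, HN, HA, N (carbonyl carbon, alpha/beta carbons, amide proton,
alpha proton, amide nitrogen).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .exceptions import DuplicateRowError, FormatError, ParseError

#: Canonical nucleus order used for every vector and covariance index.
NUCLEI: tuple[str, ...] = ("C", "CA", "CB", "HN", "HA", "N")

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

COLUMNS: tuple[str, ...] = (
    "protein_id",
    "fragment_id",
    "class",
    "pos",
    "aa",
    *(f"cs_{m}" for m in NUCLEI),
)


class Label(str, Enum):
    """Fragment class: beta-hairpin (positive) vs not-beta-hairpin (negative)."""

    HAIRPIN = "hairpin"
    NOT_HAIRPIN = "not_hairpin"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ResidueShiftRow:
    """Per-residue record: one amino acid and its six (possibly missing) shifts."""

    protein_id: str
    fragment_id: str
    position: int
    residue: str
    shifts: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        if self.residue not in STANDARD_AA and self.residue != "X":
            raise FormatError(
                f"residue {self.residue!r} is not a standard one-letter code or 'X'"
            )
        for m, v in self.shifts.items():
            if m not in NUCLEI:
                raise FormatError(f"unknown nucleus {m!r}")
            if v is not None and not (v == v and abs(v) != float("inf")):
                raise FormatError(f"non-finite shift for {m}: {v!r}")


@dataclass
class Fragment:
    """A contiguous labeled sequence fragment with per-residue shifts."""

    fragment_id: str
    protein_id: str
    label: Label
    rows: list[ResidueShiftRow]

    def __post_init__(self) -> None:
        positions = [r.position for r in self.rows]
        if positions != list(range(1, len(positions) + 1)):
            raise FormatError(
                f"fragment {self.fragment_id!r}: positions must be contiguous "
                f"1..{len(positions)}, got {positions}"
            )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sequence(self) -> str:
        return "".join(r.residue for r in self.rows)

    def coverage(self, nucleus: str) -> float:
        """Fraction of residues with an assigned shift for ``nucleus``."""
        if not self.rows:
            return 0.0
        present = sum(1 for r in self.rows if r.shifts.get(nucleus) is not None)
        return present / len(self.rows)


@dataclass
class Dataset:
    """An ordered collection of fragments with unique ids."""

    fragments: list[Fragment]

    def __post_init__(self) -> None:
        ids = [f.fragment_id for f in self.fragments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate fragment ids: {dupes}")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def counts(self) -> dict[Label, int]:
        out = {Label.HAIRPIN: 0, Label.NOT_HAIRPIN: 0}
        for f in self.fragments:
            out[f.label] += 1
        return out

    def subset(self, fragment_ids: Iterable[str]) -> "Dataset":
        wanted = set(fragment_ids)
        return Dataset([f for f in self.fragments if f.fragment_id in wanted])


# ---------------------------------------------------------------------------
# Reading / writing


def _fmt(v: float | None) -> str:
    if v is None:
        return "NA"
    return repr(float(v))


def read_fragment_table(source: str | Path | IO[str]) -> Dataset:
    """Parse a CS fragment TSV into a :class:`Dataset`.

    Rows are grouped by ``fragment_id`` in order of first appearance and
    sorted by position within each fragment.  ``NA`` and empty shift cells
    become missing values.

    Raises
    ------
    FormatError
        Missing/misordered header columns, non-contiguous positions, or a
        fragment whose label/protein changes between rows.
    ParseError
        A non-numeric shift or position cell (message carries the line number).
    DuplicateRowError
        Two rows share (fragment_id, position).
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    got = tuple(df.columns)
    for col in COLUMNS:
        if col not in got:
            raise FormatError(f"missing required column {col!r}")
    if got[: len(COLUMNS)] != COLUMNS:
        raise FormatError(
            f"columns must appear in order {list(COLUMNS)}, got {list(got)}"
        )

    records: dict[str, dict] = {}
    seen: set[tuple[str, int]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # 1-based, after the header
        fid = row.fragment_id
        try:
            pos = int(getattr(row, "pos"))
        except ValueError:
            raise ParseError(
                f"line {line}: non-integer pos {getattr(row, 'pos')!r}"
            ) from None
        key = (fid, pos)
        if key in seen:
            raise DuplicateRowError(
                f"line {line}: duplicate row for fragment {fid!r} position {pos}"
            )
        seen.add(key)
        # 'class' is a reserved word, so itertuples renames it; fetch by index
        cls = row[COLUMNS.index("class")]
        try:
            label = Label(cls)
        except ValueError:
            raise ParseError(
                f"line {line}: class must be 'hairpin' or 'not_hairpin', got {cls!r}"
            ) from None
        aa = row.aa
        if aa == "X":
            warnings.warn(
                f"line {line}: nonstandard residue 'X' in fragment {fid!r}",
                stacklevel=2,
            )
        shifts: dict[str, float | None] = {}
        for m in NUCLEI:
            cell = row[COLUMNS.index(f"cs_{m}")].strip()
            if cell in ("", "NA"):
                shifts[m] = None
                continue
            try:
                shifts[m] = float(cell)
            except ValueError:
                raise ParseError(
                    f"line {line}: non-numeric shift cs_{m}={cell!r}"
                ) from None
        try:
            rsr = ResidueShiftRow(row.protein_id, fid, pos, aa, shifts)
        except FormatError as e:
            raise ParseError(f"line {line}: {e}") from None
        rec = records.setdefault(
            fid, {"protein_id": row.protein_id, "label": label, "rows": []}
        )
        if rec["label"] is not label:
            raise FormatError(f"fragment {fid!r} has inconsistent class labels")
        if rec["protein_id"] != row.protein_id:
            raise FormatError(f"fragment {fid!r} has inconsistent protein ids")
        rec["rows"].append(rsr)

    fragments = []
    for fid, rec in records.items():
        rows = sorted(rec["rows"], key=lambda r: r.position)
        fragments.append(Fragment(fid, rec["protein_id"], rec["label"], rows))
    return Dataset(fragments)


def write_fragment_table(data: Dataset, sink: str | Path | IO[str]) -> None:
    """Write a :class:`Dataset` in the CS fragment TSV dialect.

    Column order is fixed, missing shifts become ``NA`` and floats are written
    with ``repr`` (shortest round-trip form), so write∘read is the identity.
    """
    lines = ["\t".join(COLUMNS)]
    for frag in data.fragments:
        for r in frag.rows:
            cells = [
                frag.protein_id,
                frag.fragment_id,
                frag.label.value,
                str(r.position),
                r.residue,
                *(_fmt(r.shifts.get(m)) for m in NUCLEI),
            ]
            lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def dumps_fragment_table(data: Dataset) -> str:
    """Return the TSV dialect as a string (convenience wrapper)."""
    buf = _io.StringIO()
    write_fragment_table(data, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationPolicy:
    """Length bounds per class plus a minimum per-nucleus coverage fraction.

    Defaults reflect the benchmark dataset this method was developed on:
    hairpin fragments of 7-38 residues, not-hairpin of 8-40, and full shift
    coverage.  They describe typical data, not hard requirements of the
    method, so violations are reported rather than raised.
    """

    length_bounds: Mapping[Label, tuple[int, int]] = field(
        default_factory=lambda: {
            Label.HAIRPIN: (7, 38),
            Label.NOT_HAIRPIN: (8, 40),
        }
    )
    min_coverage: float = 1.0


@dataclass(frozen=True)
class ValidationIssue:
    fragment_id: str
    kind: str  # "length" | "coverage"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]
    #: fragment_id -> nucleus -> coverage fraction
    coverage: dict[str, dict[str, float]]

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "issues": [
                {"fragment_id": i.fragment_id, "kind": i.kind, "message": i.message}
                for i in self.issues
            ],
            "coverage": self.coverage,
        }


def validate_dataset(
    data: Dataset, policy: ValidationPolicy | None = None
) -> ValidationReport:
    """Check fragments against a :class:`ValidationPolicy`.

    Pure: never mutates or drops data.  The report lists, per fragment,
    length-range violations and per-nucleus coverage below the policy minimum.
    """
    policy = policy or ValidationPolicy()
    issues: list[ValidationIssue] = []
    coverage: dict[str, dict[str, float]] = {}
    for frag in data.fragments:
        lo, hi = policy.length_bounds[frag.label]
        if not (lo <= len(frag) <= hi):
            issues.append(
                ValidationIssue(
                    frag.fragment_id,
                    "length",
                    f"length {len(frag)} outside [{lo}, {hi}] for class "
                    f"{frag.label.value}",
                )
            )
        cov = {m: frag.coverage(m) for m in NUCLEI}
        coverage[frag.fragment_id] = cov
        for m, c in cov.items():
            if c < policy.min_coverage:
                issues.append(
                    ValidationIssue(
                        frag.fragment_id,
                        "coverage",
                        f"nucleus {m} covered at {c:.3f} < {policy.min_coverage}",
                    )
                )
    return ValidationReport(issues, coverage)
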