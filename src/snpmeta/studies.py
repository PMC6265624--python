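"""Reading, validating and writing per-study genotype-count tables.

The unit of data is one case-control study of a single SNP, summarised as
two genotype-count triples (effect-allele homozygote, heterozygote,
reference-allele homozygote) for cases and controls.  The effect ("R")
allele is, by convention, the allele of the first-listed homozygote column
of the input table; all downstream contrasts are oriented accordingly.

Published count tables occasionally contain internal inconsistencies
(genotype cells that do not sum to the reported study total, typically
typesetting errors).  :func:`validate_study` implements an explicit,
documented reconciliation rule so that such rows are either repaired
unambiguously or flagged, never silently accepted.
"""

from __future__ import annotations

import enum
import importlib.resources
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Ethnicity",
    "ControlSource",
    "GenotypeCounts",
    "StudyRecord",
    "StudyParseError",
    "StudyValidationError",
    "parse_studies",
    "validate_study",
    "validate_studies",
    "write_studies",
    "load_table1",
    "COLUMNS",
]

#: Canonical column order of the study table format.
COLUMNS = [
    "study_id", "author", "year", "snp", "ethnicity", "source",
    "case_rr", "case_rw", "case_ww",
    "control_rr", "control_rw", "control_ww",
    "case_total", "control_total", "reported_hwe_p",
]

_REQUIRED = COLUMNS[:12]
_COUNT_COLS = COLUMNS[6:12]


class StudyParseError(ValueError):
    """Raised when the input table cannot be parsed into study records."""


class StudyValidationError(ValueError):
    """Raised when a study record violates the count-consistency contract."""


class Ethnicity(str, enum.Enum):
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"
    OTHER = "other"


class ControlSource(str, enum.Enum):
    """Origin of the control group: population-, hospital- or family-based."""

    PB = "PB"
    HB = "HB"
    FB = "FB"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts ordered by effect-allele dosage.

    Attributes
    ----------
    rr : int
        Effect-allele homozygotes (two copies).
    rw : int
        Heterozygotes (one copy).
    ww : int
        Reference-allele homozygotes (no copies).
    """

    rr: int
    rw: int
    ww: int

    def __post_init__(self) -> None:
        for name in ("rr", "rw", "ww"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"genotype count {name}={v!r} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.rr + self.rw + self.ww

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.rr, self.rw, self.ww)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study of one SNP, as a row of the study table."""

    study_id: str
    author: str
    year: int
    snp: str
    ethnicity: Ethnicity
    source: ControlSource
    case_counts: GenotypeCounts
    control_counts: GenotypeCounts
    reported_case_total: int | None = None
    reported_control_total: int | None = None
    reported_hwe_p: float | None = None
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.year <= 1900:
            raise ValueError(f"implausible publication year {self.year}")
        if self.case_counts.total <= 0 or self.control_counts.total <= 0:
            raise ValueError(f"study {self.study_id}: empty case or control group")


def _norm_enum(cls, token: str, row_id: str):
    for member in cls:
        if member.value.lower() == str(token).strip().lower():
            return member
    raise StudyValidationError(
        f"row {row_id!r}: unknown {cls.__name__} token {token!r} "
        f"(expected one of {[m.value for m in cls]})"
    )


def _parse_hwe_p(token) -> float | None:
    """Reported HWE p-values may be censored ('<0.01'); those carry no
    exact value for cross-checking and are stored as missing."""
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip()
    if not s or s.upper() == "NA":
        return None
    if s.startswith("<") or s.startswith(">"):
        return None
    return float(s)


def parse_studies(source, *, sep: str | None = None) -> list[StudyRecord]:
    """Parse a delimited study table into a list of :class:`StudyRecord`.

    Parameters
    ----------
    source : path, file-like or str
        TSV or CSV text with a header row naming the canonical columns.
    sep : str, optional
        Field delimiter; sniffed from the header line when omitted.

    The genotype columns are ordered effect-homozygote, heterozygote,
    reference-homozygote; metadata enums are matched case-insensitively.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if sep is None:
        if hasattr(source, "read"):
            head = source.readline()
            source.seek(0)
        else:
            with open(source) as fh:
                head = fh.readline()
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise StudyParseError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    for _, row in df.iterrows():
        rid = str(row["study_id"]).strip()
        counts = {}
        for col in _COUNT_COLS + ["case_total", "control_total"]:
            raw = row.get(col)
            if col in ("case_total", "control_total") and (
                raw is None or pd.isna(raw) or str(raw).strip() in ("", "NA")
            ):
                counts[col] = None
                continue
            try:
                counts[col] = int(str(raw).strip())
            except (TypeError, ValueError):
                raise StudyParseError(
                    f"row {rid!r}: non-integer value {raw!r} in column {col!r}"
                ) from None
        records.append(
            StudyRecord(
                study_id=rid,
                author=str(row["author"]).strip(),
                year=int(str(row["year"]).strip()),
                snp=str(row["snp"]).strip(),
                ethnicity=_norm_enum(Ethnicity, row["ethnicity"], rid),
                source=_norm_enum(ControlSource, row["source"], rid),
                case_counts=GenotypeCounts(counts["case_rr"], counts["case_rw"], counts["case_ww"]),
                control_counts=GenotypeCounts(
                    counts["control_rr"], counts["control_rw"], counts["control_ww"]
                ),
                reported_case_total=counts["case_total"],
                reported_control_total=counts["control_total"],
                reported_hwe_p=_parse_hwe_p(row.get("reported_hwe_p")),
            )
        )
    return records


#: Absolute cell-sum/total discrepancy tolerated (with a warning) when no
#: unambiguous single-cell repair exists.
KEEP_AND_WARN_BAND = 5


def _reconcile_arm(
    counts: GenotypeCounts, total: int | None, arm: str, study_id: str, policy: str
) -> tuple[GenotypeCounts, list[str]]:
    if total is None or counts.total == total:
        return counts, []
    diff = total - counts.total
    if policy == "strict":
        raise StudyValidationError(
            f"study {study_id}: {arm} genotype cells sum to {counts.total}, "
            f"reported total is {total}"
        )
    # Candidate repair for cell i replaces it with total - (sum of the other
    # two); that candidate is cell_i + diff, admissible only if nonnegative.
    # A repair is accepted only when exactly one cell admits one -- i.e. the
    # erroneous cell is unambiguous.
    cells = counts.as_tuple()
    admissible = [i for i, c in enumerate(cells) if c + diff >= 0]
    if len(admissible) == 1:
        i = admissible[0]
        fixed = list(cells)
        old = fixed[i]
        fixed[i] = old + diff
        name = ("rr", "rw", "ww")[i]
        warning = (
            f"{arm} {name} cell reconciled from {old} to {fixed[i]} "
            f"to match reported total {total}"
        )
        return GenotypeCounts(*fixed), [warning]
    if abs(diff) <= KEEP_AND_WARN_BAND:
        warning = (
            f"{arm} cells sum to {counts.total} but reported total is {total} "
            f"(off by {-diff:+d}); no unambiguous single-cell fix, counts kept as printed"
        )
        return counts, [warning]
    raise StudyValidationError(
        f"study {study_id}: {arm} cells sum to {counts.total} vs reported total "
        f"{total}; two or more cells would need changing"
    )


def validate_study(record: StudyRecord, policy: str = "reconcile") -> StudyRecord:
    """Check (and under ``policy='reconcile'`` repair) cell-sum consistency.

    strict
        Any disagreement between the genotype cells and the reported arm
        total is an error.
    reconcile
        When exactly one cell can be replaced by ``total - (sum of the other
        two)`` without going negative, that replacement is applied and
        recorded as a warning on the returned record.  A small residual
        discrepancy (|cells - total| <= 5) with no unambiguous fix keeps the
        printed cells and warns.  Anything else is an error.
    """
    if policy not in ("strict", "reconcile"):
        raise ValueError(f"unknown validation policy {policy!r}")
    case, w1 = _reconcile_arm(
        record.case_counts, record.reported_case_total, "case", record.study_id, policy
    )
    control, w2 = _reconcile_arm(
        record.control_counts, record.reported_control_total, "control", record.study_id, policy
    )
    warnings = tuple(w1 + w2)
    if not warnings and case is record.case_counts and control is record.control_counts:
        return record
    return replace(record, case_counts=case, control_counts=control, warnings=warnings)


def validate_studies(records: Iterable[StudyRecord], policy: str = "reconcile") -> list[StudyRecord]:
    return [validate_study(r, policy) for r in records]


def write_studies(records: Sequence[StudyRecord], path, *, sep: str = "\t") -> None:
    """Write records in the canonical column order (round-trips with
    :func:`parse_studies`)."""
    rows = []
    for r in records:
        rows.append({
            "study_id": r.study_id, "author": r.author, "year": r.year, "snp": r.snp,
            "ethnicity": r.ethnicity.value, "source": r.source.value,
            "case_rr": r.case_counts.rr, "case_rw": r.case_counts.rw, "case_ww": r.case_counts.ww,
            "control_rr": r.control_counts.rr, "control_rw": r.control_counts.rw,
            "control_ww": r.control_counts.ww,
            "case_total": r.reported_case_total, "control_total": r.reported_control_total,
            "reported_hwe_p": r.reported_hwe_p,
        })
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def load_table1(validated: bool = True) -> list[StudyRecord]:
    """Load the packaged 12-study KLK3/prostate-cancer fixture table.

    The fixture ships the counts as printed (including one known
    typesetting error in the Stegeman case heterozygote row); with
    ``validated=True`` (default) the reconcile policy is applied, which
    repairs that cell from its row total.
    """
    ref = importlib.resources.files("snpmeta").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as path:
        records = parse_studies(Path(path))
    if validated:
        records = validate_studies(records, policy="reconcile")
    return records


def by_snp(records: Iterable[StudyRecord], snp: str) -> list[StudyRecord]:
    """All records for one SNP, in input order."""
    return [r for r in records if r.snp == snp]
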