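"""Domain types and IO for multi-study case-control genotype tables.

A *study table* holds one row per study x SNP with the six genotype counts
(case 11/12/22, control 11/12/22) plus the metadata used for subgrouping
(source of controls, genotyping method) and Newcastle-Ottawa quality
components.  The package ships the Fas/FasL preeclampsia dataset
(9 studies for Fas -670 A/G, 3 for FasL 124 A/G, 2 for FasL -844 C/T and
1 for Fas -1377 G/A; 834 cases and 1072 controls for Fas -670) as a
versioned fixture, loadable with :func:`load_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "Dataset",
    "COLUMNS",
    "GENOTYPE_METHODS",
    "SOURCES_OF_CONTROLS",
    "read_study_table",
    "write_study_table",
    "total_sample_sizes",
    "load_fixture",
]

GENOTYPE_METHODS = ("PCR-RFLP", "PCR")
SOURCES_OF_CONTROLS = ("HB", "PB")

#: Fixed column order of the CSV/TSV dialect.
COLUMNS = [
    "study_id", "author", "year", "nationality", "gene", "snp",
    "allele1", "allele2", "method", "soc", "ethnicity",
    "case_11", "case_12", "case_22", "ctrl_11", "ctrl_12", "ctrl_22",
    "nos_sel", "nos_comp", "nos_exp",
]

_COUNT_COLS = ["case_11", "case_12", "case_22", "ctrl_11", "ctrl_12", "ctrl_22"]

FIXTURE_NAME = "fas_fasl_preeclampsia.csv"


@dataclass(frozen=True, order=True)
class GenotypeCounts:
    """Genotype counts (11 / 12 / 22) for one arm of one study.

    Genotype 11 is homozygous for the reference allele, 22 homozygous for
    the risk allele tested, 12 heterozygous.
    """

    n11: int
    n12: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n22"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.total < 1:
            raise ValidationError("an arm must contain at least one subject")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n22

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n11, self.n12, self.n22)


@dataclass(frozen=True)
class StudyRecord:
    """One study x SNP row: metadata plus case and control genotype counts."""

    study_id: str
    author: str
    year: int
    nationality: str
    gene: str
    snp: str
    allele1: str
    allele2: str
    method: str
    soc: str
    ethnicity: str
    case_counts: GenotypeCounts
    control_counts: GenotypeCounts
    nos_selection: int
    nos_comparability: int
    nos_exposure: int

    def __post_init__(self) -> None:
        if self.soc not in SOURCES_OF_CONTROLS:
            raise ValidationError(
                f"{self.study_id}: unknown source of controls {self.soc!r}; "
                f"expected one of {SOURCES_OF_CONTROLS}")
        if self.method not in GENOTYPE_METHODS:
            raise ValidationError(
                f"{self.study_id}: unknown genotyping method {self.method!r}; "
                f"expected one of {GENOTYPE_METHODS}")
        if self.allele1 == self.allele2:
            raise ValidationError(f"{self.study_id}: allele1 equals allele2")
        for name, hi in (("nos_selection", 4), ("nos_comparability", 2),
                         ("nos_exposure", 3)):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise ValidationError(
                    f"{self.study_id}: {name}={v} outside [0, {hi}]")

    @property
    def nos_total(self) -> int:
        """Total Newcastle-Ottawa quality score (0-9 stars)."""
        return self.nos_selection + self.nos_comparability + self.nos_exposure

    @property
    def n_cases(self) -> int:
        return self.case_counts.total

    @property
    def n_controls(self) -> int:
        return self.control_counts.total


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of study records, one per study x SNP."""

    records: tuple[StudyRecord, ...]

    def __init__(self, records: Iterable[StudyRecord]) -> None:
        object.__setattr__(self, "records", tuple(records))
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.snp, rec.study_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate study_id {rec.study_id!r} for SNP {rec.snp!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def snps(self) -> list[str]:
        """SNP labels in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.snp not in out:
                out.append(rec.snp)
        return out

    def for_snp(self, snp: str) -> "Dataset":
        return Dataset(r for r in self.records if r.snp == snp)

    def filter(self, **fields) -> "Dataset":
        """Subset on exact metadata matches, e.g. ``filter(soc="HB")``."""
        recs = self.records
        for name, value in fields.items():
            recs = tuple(r for r in recs if getattr(r, name) == value)
        return Dataset(recs)


def _record_from_row(row: pd.Series) -> StudyRecord:
    case = GenotypeCounts(int(row["case_11"]), int(row["case_12"]),
                          int(row["case_22"]))
    ctrl = GenotypeCounts(int(row["ctrl_11"]), int(row["ctrl_12"]),
                          int(row["ctrl_22"]))
    return StudyRecord(
        study_id=str(row["study_id"]),
        author=str(row["author"]),
        year=int(row["year"]),
        nationality=str(row["nationality"]),
        gene=str(row["gene"]),
        snp=str(row["snp"]),
        allele1=str(row["allele1"]),
        allele2=str(row["allele2"]),
        method=str(row["method"]),
        soc=str(row["soc"]),
        ethnicity=str(row["ethnicity"]),
        case_counts=case,
        control_counts=ctrl,
        nos_selection=int(row["nos_sel"]),
        nos_comparability=int(row["nos_comp"]),
        nos_exposure=int(row["nos_exp"]),
    )


def read_study_table(path, dialect: str = "csv") -> Dataset:
    """Read and validate a study table.

    Parameters
    ----------
    path : path-like or file-like
        Source of the table; UTF-8, one header row.
    dialect : {"csv", "tsv"}
        Field separator.

    Raises
    ------
    SchemaError
        If required columns are missing.
    ValidationError
        If any row fails validation; the error lists the offending
        1-based data row numbers.
    """
    if dialect not in ("csv", "tsv"):
        raise SchemaError(f"unknown dialect {dialect!r}; expected csv or tsv")
    sep = "," if dialect == "csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError("file is empty (no header row)")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    problems: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 1
        try:
            for col in _COUNT_COLS + ["year", "nos_sel", "nos_comp", "nos_exp"]:
                try:
                    int(row[col])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"column {col!r} is not an integer: {row[col]!r}")
            records.append(_record_from_row(row))
        except ValidationError as exc:
            problems.append((rownum, str(exc)))
    if problems:
        detail = "; ".join(f"row {n}: {msg}" for n, msg in problems)
        raise ValidationError(f"invalid study table: {detail}", rows=problems)
    return Dataset(records)


def write_study_table(ds: Dataset, path, dialect: str = "csv") -> None:
    """Write a dataset in the same dialect :func:`read_study_table` accepts."""
    if dialect not in ("csv", "tsv"):
        raise SchemaError(f"unknown dialect {dialect!r}; expected csv or tsv")
    sep = "," if dialect == "csv" else "\t"
    rows = []
    for r in ds:
        rows.append({
            "study_id": r.study_id, "author": r.author, "year": r.year,
            "nationality": r.nationality, "gene": r.gene, "snp": r.snp,
            "allele1": r.allele1, "allele2": r.allele2, "method": r.method,
            "soc": r.soc, "ethnicity": r.ethnicity,
            "case_11": r.case_counts.n11, "case_12": r.case_counts.n12,
            "case_22": r.case_counts.n22, "ctrl_11": r.control_counts.n11,
            "ctrl_12": r.control_counts.n12, "ctrl_22": r.control_counts.n22,
            "nos_sel": r.nos_selection, "nos_comp": r.nos_comparability,
            "nos_exp": r.nos_exposure,
        })
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep=sep, index=False)


def total_sample_sizes(ds: Dataset) -> tuple[int, int]:
    """Sum case and control genotype totals over all records.

    Each record contributes its own arms; a control arm shared by two case
    series (stored as two records) is counted once per record, matching how
    multi-arm citations enter the meta-analysis.
    """
    cases = sum(r.n_cases for r in ds)
    controls = sum(r.n_controls for r in ds)
    return cases, controls


def load_fixture() -> Dataset:
    """Load the packaged Fas/FasL preeclampsia genotype-count dataset."""
    ref = resources.files("genemeta").joinpath("data", FIXTURE_NAME)
    with ref.open("r", encoding="utf-8") as fh:
        return read_study_table(fh, dialect="csv")
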