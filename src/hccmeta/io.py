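"""Study-record data model and flat-file I/O.

One :class:`StudyRecord` holds the genotype (or carrier) counts of a single
case-control study for a single variant, plus the metadata a field synopsis
tracks (gene, dbSNP ID, ethnicity, control source, virus type).  A
:class:`StudyTable` is the ordered collection of records the pipeline
consumes.  The on-disk format is a single CSV dialect: comma-separated,
UTF-8, header row, counts as plain integers.

Genotype count columns are keyed off the *effect allele* of the declared
contrast ("A vs a"): ``n_eff_hom`` is two copies of the effect allele,
``n_het`` one copy, ``n_other_hom`` zero.  This removes the strand and
minor/major-allele orientation ambiguity that plagues literature-extracted
tables, where the minor allele can flip between ethnicities.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

ETHNICITIES = frozenset({"Caucasian", "Asian", "African", "mixed"})
CONTROL_SOURCES = frozenset({"hospital", "population", "family", "unknown"})
VIRUS_TYPES = frozenset({"HBV", "HCV", "mixed", "none", "unknown"})
VARIANT_SCHEMES = frozenset({"genotype", "carrier"})

#: CSV column order.  Genotype-scheme rows fill the ``*_eff_hom/_het/_other_hom``
#: columns; carrier-scheme rows fill ``*_present/_null``; the others stay empty.
CSV_COLUMNS = [
    "study_id", "pubmed_id", "first_author", "year",
    "gene", "rsid", "effect_allele", "other_allele",
    "ethnicity", "control_source", "virus_type", "variant_scheme",
    "case_n_eff_hom", "case_n_het", "case_n_other_hom",
    "control_n_eff_hom", "control_n_het", "control_n_other_hom",
    "case_n_present", "case_n_null",
    "control_n_present", "control_n_null",
]


class StudyTableFormatError(ValueError):
    """The file does not conform to the study-table CSV schema."""


class RecordValidationError(ValueError):
    """A row violates the StudyRecord invariants."""


@dataclass(frozen=True)
class StudyRecord:
    """Genotype counts and metadata of one study for one variant.

    ``case_counts``/``control_counts`` are ``(n_eff_hom, n_het, n_other_hom)``
    for ``variant_scheme='genotype'`` and ``(n_present, n_null)`` for
    ``variant_scheme='carrier'`` (present/null variants such as GSTM1/GSTT1
    deletions).
    """

    study_id: str
    gene: str
    rsid: str
    case_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    pubmed_id: str = ""
    first_author: str = ""
    year: int = 0
    effect_allele: str = "A"
    other_allele: str = "a"
    ethnicity: str = "mixed"
    control_source: str = "unknown"
    virus_type: str = "unknown"
    variant_scheme: str = "genotype"

    def __post_init__(self) -> None:
        object.__setattr__(self, "case_counts", tuple(int(c) for c in self.case_counts))
        object.__setattr__(self, "control_counts", tuple(int(c) for c in self.control_counts))

    def validate(self) -> None:
        """Raise :class:`RecordValidationError` on any invariant violation."""
        if self.ethnicity not in ETHNICITIES:
            raise RecordValidationError(
                f"{self.study_id}: unknown ethnicity {self.ethnicity!r}")
        if self.control_source not in CONTROL_SOURCES:
            raise RecordValidationError(
                f"{self.study_id}: unknown control_source {self.control_source!r}")
        if self.virus_type not in VIRUS_TYPES:
            raise RecordValidationError(
                f"{self.study_id}: unknown virus_type {self.virus_type!r}")
        if self.variant_scheme not in VARIANT_SCHEMES:
            raise RecordValidationError(
                f"{self.study_id}: unknown variant_scheme {self.variant_scheme!r}")
        width = 3 if self.variant_scheme == "genotype" else 2
        for arm, counts in (("case", self.case_counts), ("control", self.control_counts)):
            if len(counts) != width:
                raise RecordValidationError(
                    f"{self.study_id}: {arm} counts must have {width} entries "
                    f"for scheme={self.variant_scheme}, got {len(counts)}")
            if any(c < 0 for c in counts):
                raise RecordValidationError(
                    f"{self.study_id}: negative {arm} count {counts}")
            if sum(counts) < 1:
                raise RecordValidationError(
                    f"{self.study_id}: {arm} total must be >= 1")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    @property
    def source_id(self) -> str:
        """Publication identifier used for the independent-sources rule."""
        return self.pubmed_id or self.study_id


@dataclass
class StudyTable:
    """Ordered collection of validated StudyRecords."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""
    n_dropped: int = 0  # rows dropped by a non-strict read

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.study_id in seen:
                raise RecordValidationError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, rsid: str | None = None, scheme: str | None = None,
               ethnicity: str | None = None, virus_type: str | None = None) -> "StudyTable":
        recs = self.records
        if rsid is not None:
            recs = [r for r in recs if r.rsid == rsid]
        if scheme is not None:
            recs = [r for r in recs if r.variant_scheme == scheme]
        if ethnicity is not None:
            recs = [r for r in recs if r.ethnicity == ethnicity]
        if virus_type is not None:
            recs = [r for r in recs if r.virus_type == virus_type]
        return StudyTable(records=list(recs), provenance=self.provenance)

    def rsids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.rsid not in out:
                out.append(rec.rsid)
        return out


def _record_to_row(rec: StudyRecord) -> dict[str, str]:
    row = {
        "study_id": rec.study_id, "pubmed_id": rec.pubmed_id,
        "first_author": rec.first_author, "year": str(rec.year),
        "gene": rec.gene, "rsid": rec.rsid,
        "effect_allele": rec.effect_allele, "other_allele": rec.other_allele,
        "ethnicity": rec.ethnicity, "control_source": rec.control_source,
        "virus_type": rec.virus_type, "variant_scheme": rec.variant_scheme,
    }
    for col in CSV_COLUMNS[12:]:
        row[col] = ""
    if rec.variant_scheme == "genotype":
        for col, v in zip(("case_n_eff_hom", "case_n_het", "case_n_other_hom"), rec.case_counts):
            row[col] = str(v)
        for col, v in zip(("control_n_eff_hom", "control_n_het", "control_n_other_hom"),
                          rec.control_counts):
            row[col] = str(v)
    else:
        for col, v in zip(("case_n_present", "case_n_null"), rec.case_counts):
            row[col] = str(v)
        for col, v in zip(("control_n_present", "control_n_null"), rec.control_counts):
            row[col] = str(v)
    return row


def _parse_counts(row: dict[str, str], scheme: str, arm: str, rownum: int) -> tuple[int, ...]:
    if scheme == "genotype":
        cols = (f"{arm}_n_eff_hom", f"{arm}_n_het", f"{arm}_n_other_hom")
    else:
        cols = (f"{arm}_n_present", f"{arm}_n_null")
    out = []
    for col in cols:
        raw = (row.get(col) or "").strip()
        try:
            val = int(raw)
        except ValueError:
            raise RecordValidationError(
                f"row {rownum}: non-integer count {raw!r} in column {col}") from None
        out.append(val)
    return tuple(out)


def _row_to_record(row: dict[str, str], rownum: int) -> StudyRecord:
    scheme = (row.get("variant_scheme") or "genotype").strip()
    if scheme not in VARIANT_SCHEMES:
        raise RecordValidationError(f"row {rownum}: unknown variant_scheme {scheme!r}")
    try:
        year = int(row.get("year") or 0)
    except ValueError:
        raise RecordValidationError(f"row {rownum}: non-integer year {row['year']!r}") from None
    rec = StudyRecord(
        study_id=row["study_id"].strip(),
        pubmed_id=(row.get("pubmed_id") or "").strip(),
        first_author=(row.get("first_author") or "").strip(),
        year=year,
        gene=row["gene"].strip(),
        rsid=row["rsid"].strip(),
        effect_allele=(row.get("effect_allele") or "A").strip(),
        other_allele=(row.get("other_allele") or "a").strip(),
        ethnicity=(row.get("ethnicity") or "mixed").strip(),
        # missing metadata defaults to "unknown"; counts are never imputed
        control_source=(row.get("control_source") or "unknown").strip() or "unknown",
        virus_type=(row.get("virus_type") or "unknown").strip() or "unknown",
        variant_scheme=scheme,
        case_counts=_parse_counts(row, scheme, "case", rownum),
        control_counts=_parse_counts(row, scheme, "control", rownum),
    )
    try:
        rec.validate()
    except RecordValidationError as exc:
        raise RecordValidationError(f"row {rownum}: {exc}") from None
    return rec


REQUIRED_COLUMNS = ["study_id", "gene", "rsid"]


def read_study_table(path, strict: bool = True) -> StudyTable:
    """Read a study table from the canonical CSV dialect.

    With ``strict`` off, rows failing validation are dropped, logged, and
    tallied in the returned table's ``n_dropped`` instead of aborting.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise StudyTableFormatError(f"missing required column {col!r}")
        records: list[StudyRecord] = []
        dropped = 0
        for rownum, row in enumerate(reader, start=2):
            try:
                records.append(_row_to_record(row, rownum))
            except RecordValidationError:
                if strict:
                    raise
                dropped += 1
                logger.warning("dropping invalid row %d of %s", rownum, path)
    table = StudyTable(records=records, provenance=str(path), n_dropped=dropped)
    table.validate()
    return table


def write_study_table(table: StudyTable, path) -> None:
    """Write ``table`` as CSV; ``read_study_table`` round-trips it exactly."""
    table.validate()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in table.records:
            writer.writerow(_record_to_row(rec))


# ---------------------------------------------------------------------------
# synopsis output

SYNOPSIS_COLUMNS = [
    "gene", "rsid", "comparison", "frequency", "subgroup", "model",
    "n_studies", "n_cases", "n_controls",
    "OR(95%CI)", "P", "Ph/I2", "grade", "evidence",
]


def format_or_ci(or_pooled: float, ci_low: float, ci_high: float) -> str:
    """Render the synopsis OR(95%CI) field, e.g. ``1.34(1.17-1.54)``."""
    return f"{or_pooled:.2f}({ci_low:.2f}-{ci_high:.2f})"


def format_p(p: float) -> str:
    """Three-decimal p with floor display: values below 0.0005 print as 0."""
    if p < 0.0005:
        return "0"
    return f"{p:.3f}"


def _synopsis_row(result, vgrade) -> list[str]:
    comparison = getattr(result, "comparison", "")
    freq = getattr(result, "effect_allele_freq", None)
    return [
        getattr(result, "gene", ""),
        result.variant,
        comparison,
        "" if freq is None else f"{freq:.2f}",
        result.subgroup,
        result.model if isinstance(result.model, str) else result.model.value,
        str(result.k),
        str(result.n_cases),
        str(result.n_controls),
        format_or_ci(result.or_pooled, result.ci_low, result.ci_high),
        format_p(result.p),
        f"{format_p(result.p_het)}/{result.i2:.1f}%",
        vgrade.letters if vgrade is not None else "",
        vgrade.composite.capitalize() if vgrade is not None else "",
    ]


def write_synopsis(results: Iterable[tuple], path, format: str = "csv") -> None:
    """Write graded meta-analysis results as a synopsis table.

    ``results`` is an iterable of ``(MetaAnalysisResults, VeniceGrade)``
    pairs (the grade may be None).  ``format`` is ``csv`` or ``markdown``.
    """
    if format not in {"csv", "markdown"}:
        raise ValueError(f"unknown synopsis format {format!r}")
    rows = [_synopsis_row(res, vg) for res, vg in results]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if format == "csv":
            writer = csv.writer(fh)
            writer.writerow(SYNOPSIS_COLUMNS)
            writer.writerows(rows)
        else:
            fh.write("| " + " | ".join(SYNOPSIS_COLUMNS) + " |\n")
            fh.write("|" + "|".join("---" for _ in SYNOPSIS_COLUMNS) + "|\n")
            for row in rows:
                fh.write("| " + " | ".join(row) + " |\n")
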