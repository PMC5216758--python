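"""Genetic-model contrasts: collapse genotype counts to 2x2 tables.

For a biallelic variant with effect allele A and other allele a, the three
standard case-control contrasts are

* additive (= allele) model: A alleles vs a alleles (unit: alleles, so each
  subject contributes two observations),
* dominant model: carriers (AA + Aa) vs non-carriers (aa),
* recessive model: homozygotes AA vs all others (Aa + aa),

plus the carrier model for present/null variants (e.g. GSTM1/GSTT1 whole-gene
deletions) where genotype resolution does not exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from hccmeta.io import StudyRecord


class GeneticModel(str, Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    CARRIER = "carrier"

    @property
    def scheme(self) -> str:
        """Variant scheme this model applies to."""
        return "carrier" if self is GeneticModel.CARRIER else "genotype"


class ModelApplicabilityError(ValueError):
    """Genetic model applied to a record of the wrong variant scheme."""


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 case/control x exposed/unexposed count table.

    ``unit`` is ``"alleles"`` for the additive contrast (totals are twice the
    subject totals) and ``"subjects"`` otherwise.
    """

    case_exposed: float
    case_unexposed: float
    control_exposed: float
    control_unexposed: float
    unit: str = "subjects"

    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_exposed, self.case_unexposed,
                self.control_exposed, self.control_unexposed)

    @property
    def total(self) -> float:
        return sum(self.cells())


def _collapse(counts: tuple[int, ...], model: GeneticModel) -> tuple[int, int]:
    if model is GeneticModel.CARRIER:
        present, null = counts
        return present, null
    n_hom, n_het, n_other = counts
    if model is GeneticModel.ADDITIVE:
        return 2 * n_hom + n_het, 2 * n_other + n_het
    if model is GeneticModel.DOMINANT:
        return n_hom + n_het, n_other
    return n_hom, n_het + n_other  # recessive


def build_contrast(record: StudyRecord, model: GeneticModel | str) -> ContrastTable:
    """Collapse a study's counts into the 2x2 contrast of ``model``."""
    model = GeneticModel(model)
    if model.scheme != record.variant_scheme:
        raise ModelApplicabilityError(
            f"{model.value} model is not applicable to "
            f"scheme={record.variant_scheme} record {record.study_id}")
    case_e, case_u = _collapse(record.case_counts, model)
    ctrl_e, ctrl_u = _collapse(record.control_counts, model)
    unit = "alleles" if model is GeneticModel.ADDITIVE else "subjects"
    return ContrastTable(case_e, case_u, ctrl_e, ctrl_u, unit=unit)


def effect_allele_frequency(records: Iterable[StudyRecord],
                            arm: str = "controls") -> float:
    """Pooled effect-allele frequency over ``records`` in the chosen arm.

    ``arm`` is one of ``cases``, ``controls``, ``pooled``.  All records must
    be genotype-scheme (allele counts are undefined for carrier variants).
    """
    if arm not in {"cases", "controls", "pooled"}:
        raise ValueError(f"unknown arm {arm!r}")
    alleles = 0
    total = 0
    seen = False
    for rec in records:
        seen = True
        if rec.variant_scheme != "genotype":
            raise ModelApplicabilityError(
                f"allele frequency undefined for carrier record {rec.study_id}")
        arms = []
        if arm in {"cases", "pooled"}:
            arms.append(rec.case_counts)
        if arm in {"controls", "pooled"}:
            arms.append(rec.control_counts)
        for n_hom, n_het, n_other in arms:
            alleles += 2 * n_hom + n_het
            total += 2 * (n_hom + n_het + n_other)
    if not seen or total == 0:
        raise ValueError("no genotype data to compute an allele frequency from")
    return alleles / total
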