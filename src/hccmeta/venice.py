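"""Venice-criteria grading of cumulative epidemiological evidence.

Each significant meta-analysis is graded A/B/C on three axes:

* amount of evidence — total copies of the tested allele among cases and
  controls combined: A over 1,000, B 100-1,000 (inclusive), C under 100;
* replication — model-specific I-squared: A < 25%, B 25-50% (inclusive),
  C > 50%;
* protection from bias — C when the summary OR magnitude
  (max(OR, 1/OR)) is below 1.15 or publication bias is evident
  (Egger p < 0.05 or a hard flag); A when the magnitude is at least 1.15
  with no evidence of bias (Egger p >= 0.10, no flags); B in between.

The composite is strong when all three letters are A, weak when any letter
is C, moderate otherwise.  Judgment-based bias indicators that cannot be
automated (genotyping error, population stratification, phenotype
misclassification) enter as optional manual flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RARE_VARIANT_FREQ = 0.01


@dataclass(frozen=True)
class VeniceGrade:
    amount: str
    replication: str
    bias: str
    composite: str
    rationale: str = ""

    @property
    def letters(self) -> str:
        return self.amount + self.replication + self.bias


def grade_amount(effect_allele_count_total: int,
                 frequency: float | None = None) -> tuple[str, str]:
    """Letter for amount of evidence, with a rare-variant caveat note.

    ``effect_allele_count_total`` is the total number of copies of the
    tested allele among cases and controls combined.
    """
    n = effect_allele_count_total
    if n < 0:
        raise ValueError("allele count must be non-negative")
    letter = "A" if n > 1000 else ("B" if n >= 100 else "C")
    note = ""
    if frequency is not None and frequency < RARE_VARIANT_FREQ:
        note = (f"rare variant (frequency {frequency:.3%} < 1%): "
                "an A grade may be unobtainable")
    return letter, note


def grade_replication(i2: float) -> str:
    """Letter for extent of replication from the heterogeneity I-squared."""
    if not 0 <= i2 <= 100:
        raise ValueError(f"I^2 must be in [0, 100], got {i2}")
    if i2 < 25:
        return "A"
    if i2 <= 50:
        return "B"
    return "C"


def grade_bias(or_pooled: float,
               egger_p: float | None = None,
               hard_bias_flags: list[str] | None = None,
               soft_bias_flags: list[str] | None = None,
               prospective_replication: bool = False) -> tuple[str, str]:
    """Letter for protection from bias, with the triggering rules noted.

    ``hard_bias_flags`` mark evident bias (forces C); ``soft_bias_flags``
    mark possible bias (caps at B).  ``prospective_replication`` exempts an
    OR-magnitude below 1.15 from the automatic C when there is no evidence
    of publication bias.
    """
    if or_pooled <= 0:
        raise ValueError("OR must be positive")
    hard = list(hard_bias_flags or [])
    soft = list(soft_bias_flags or [])
    magnitude = max(or_pooled, 1.0 / or_pooled)
    reasons = []
    small = magnitude < 1.15
    if small and prospective_replication and (egger_p is None or egger_p >= 0.05) and not hard:
        small = False
        reasons.append("OR magnitude < 1.15 exempted by prospective replication")
    if small:
        reasons.append(f"summary OR magnitude {magnitude:.3f} < 1.15")
    if egger_p is not None and egger_p < 0.05:
        reasons.append(f"Egger p {egger_p:.3g} < 0.05: publication bias evident")
    if hard:
        reasons.append("bias evident: " + ", ".join(hard))
    if small or (egger_p is not None and egger_p < 0.05) or hard:
        return "C", "; ".join(reasons)
    if (egger_p is not None and egger_p < 0.10) or soft:
        if egger_p is not None and egger_p < 0.10:
            reasons.append(f"Egger p {egger_p:.3g} in [0.05, 0.10): bias possible")
        if soft:
            reasons.append("bias possible: " + ", ".join(soft))
        return "B", "; ".join(reasons)
    reasons.append("no observable bias")
    return "A", "; ".join(reasons)


def composite(amount: str, replication: str, bias: str) -> str:
    """Strong iff AAA; weak iff any C; moderate otherwise."""
    letters = (amount, replication, bias)
    for letter in letters:
        if letter not in {"A", "B", "C"}:
            raise ValueError(f"invalid grade letter {letter!r}")
    if letters == ("A", "A", "A"):
        return "strong"
    if "C" in letters:
        return "weak"
    return "moderate"


def grade(meta, bias_result=None, allele_count: int | None = None,
          hard_bias_flags: list[str] | None = None,
          soft_bias_flags: list[str] | None = None,
          prospective_replication: bool = False) -> VeniceGrade:
    """Assemble the full Venice grade for a fitted meta-analysis.

    ``meta`` is a :class:`~hccmeta.meta.MetaAnalysisResults`.  When
    ``allele_count`` is not given it is estimated as
    ``2 * (n_cases + n_controls) * pooled effect-allele frequency``.
    """
    freq = meta.effect_allele_freq
    if allele_count is None:
        if freq is None:
            raise ValueError("allele_count required for carrier-scheme results")
        allele_count = round(2 * (meta.n_cases + meta.n_controls) * freq)
    a_letter, a_note = grade_amount(allele_count, frequency=freq)
    r_letter = grade_replication(meta.i2)
    egger_p = bias_result.egger_p if bias_result is not None else None
    b_letter, b_note = grade_bias(
        meta.or_pooled, egger_p=egger_p,
        hard_bias_flags=hard_bias_flags, soft_bias_flags=soft_bias_flags,
        prospective_replication=prospective_replication)
    rationale_parts = [
        f"amount={a_letter} ({allele_count} effect-allele copies)",
        f"replication={r_letter} (I^2={meta.i2:.1f}%)",
        f"bias={b_letter} ({b_note})",
    ]
    if a_note:
        rationale_parts.insert(1, a_note)
    comp = composite(a_letter, r_letter, b_letter)
    return VeniceGrade(amount=a_letter, replication=r_letter, bias=b_letter,
                       composite=comp, rationale="; ".join(rationale_parts))
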