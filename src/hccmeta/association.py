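"""Per-study effect estimation and Hardy-Weinberg testing.

The per-study effect is the log odds ratio of the 2x2 contrast with its
large-sample (Woolf) standard error.  Tables with a zero cell receive the
Haldane-Anscombe continuity correction (+0.5 to every cell).  Controls are
screened for deviation from Hardy-Weinberg equilibrium with the asymptotic
1-df Pearson chi-square; HWE deviation in controls is a standard proxy for
genotyping error or population stratification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from hccmeta.genetic_models import ContrastTable

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero even after continuity correction."""


@dataclass(frozen=True)
class StudyEffect:
    """Log odds ratio and standard error of one study's contrast."""

    log_or: float
    se: float
    corrected: bool = False
    study_id: str = ""

    @property
    def var(self) -> float:
        return self.se ** 2

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    violated: bool
    degenerate: bool = False


def study_odds_ratio(table: ContrastTable, study_id: str = "") -> StudyEffect:
    """Log OR and Woolf SE of a 2x2 contrast, continuity-corrected on zeros.

    The correction adds 0.5 to all four cells iff any raw cell is zero
    (Haldane-Anscombe); ``corrected`` records whether it fired.
    """
    a, b, c, d = table.cells()
    corrected = False
    if min(a, b, c, d) == 0:
        # an all-zero margin stays zero after +0.5 only in the empty-row sense;
        # a fully empty arm or exposure column is not estimable
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            raise DegenerateTableError(
                f"study {study_id or '<anon>'}: zero margin in 2x2 table {table.cells()}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return StudyEffect(log_or=log_or, se=se, corrected=corrected, study_id=study_id)


def hwe_test(control_counts: tuple[int, int, int], alpha: float = 0.05) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    ``control_counts`` are ``(n_AA, n_Aa, n_aa)`` with A the effect allele.
    Expected counts are ``n * (p^2, 2pq, q^2)`` at the observed allele
    frequency ``p``.  Monomorphic controls (p = 0 or 1) satisfy HWE
    trivially and are flagged degenerate.
    """
    n_hom, n_het, n_other = control_counts
    n = n_hom + n_het + n_other
    if n < 1:
        raise ValueError("need at least one control genotype")
    p = (2 * n_hom + n_het) / (2 * n)
    q = 1 - p
    if p == 0.0 or p == 1.0:
        logger.debug("monomorphic controls (p=%g): HWE trivially satisfied", p)
        return HweResult(chi2=0.0, p=1.0, violated=False, degenerate=True)
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(control_counts, expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=pval, violated=pval < alpha)
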