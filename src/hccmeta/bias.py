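"""Publication-bias tests and sensitivity analyses.

Egger's test regresses the standardized effect (log OR / SE) on precision
(1/SE); a nonzero intercept indicates small-study (funnel) asymmetry.
Begg's test is the Kendall rank correlation between variance-stabilized
deviates from the fixed-effect pool and the per-study variances.  Both are
low-powered at small study counts, so results with k < 10 carry a
``low_power`` flag.

Sensitivity analyses re-pool after consecutively omitting each study
(leave-one-out) or after excluding studies whose control genotypes deviate
from Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from hccmeta.association import StudyEffect, hwe_test
from hccmeta.genetic_models import GeneticModel
from hccmeta.io import StudyTable
from hccmeta.meta import (
    EligibilityError,
    MetaAnalysis,
    MetaAnalysisResults,
    pool_fixed,
    pool_random,
)

#: variance floor for Begg's standardized deviates (var_i - var_pooled can
#: round to <= 0 for the most precise study)
_VAR_EPS = 1e-12

LOW_POWER_K = 10


@dataclass(frozen=True)
class BiasResult:
    egger_intercept: float
    egger_se: float
    egger_p: float
    begg_tau: float
    begg_p: float
    k: int

    @property
    def low_power(self) -> bool:
        return self.k < LOW_POWER_K


@dataclass
class SensitivityResult:
    baseline: MetaAnalysisResults
    leave_one_out: list[MetaAnalysisResults] = field(default_factory=list)
    hwe_excluded: MetaAnalysisResults | None = None
    excluded_ids: list[str] = field(default_factory=list)
    robust: bool = True
    notes: str = ""


def _check_k(effects: Sequence[StudyEffect], what: str) -> None:
    if len(effects) < 3:
        raise EligibilityError(
            f"{what} needs at least 3 studies, got {len(effects)}",
            n_sources=len(effects))


def egger_test(effects: Iterable[StudyEffect]) -> tuple[float, float, float]:
    """Egger regression: intercept, its SE, and two-sided p (t, k-2 df).

    Classic formulation: OLS of the standard normal deviate theta_i/se_i on
    precision 1/se_i; the slope estimates the effect, the intercept the
    asymmetry.
    """
    effects = list(effects)
    _check_k(effects, "Egger test")
    snd = np.array([e.log_or / e.se for e in effects])
    prec = np.array([1.0 / e.se for e in effects])
    if np.ptp(prec) == 0 and np.ptp(snd) == 0:
        raise ValueError("degenerate Egger regression: no variation in inputs")
    res = stats.linregress(prec, snd)
    k = len(effects)
    t = res.intercept / res.intercept_stderr
    p = float(2.0 * stats.t.sf(abs(t), df=k - 2))
    return float(res.intercept), float(res.intercept_stderr), p


def begg_test(effects: Iterable[StudyEffect]) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation: Kendall tau and two-sided p.

    Deviates are standardized as (theta_i - theta_fixed) /
    sqrt(var_i - var_fixed_pooled), the radicand floored at a small epsilon;
    p uses the tie-corrected normal approximation.
    """
    effects = list(effects)
    _check_k(effects, "Begg test")
    pooled, pooled_se = pool_fixed(effects)
    var_pooled = pooled_se ** 2
    theta = np.array([e.log_or for e in effects])
    var = np.array([e.var for e in effects])
    deviates = (theta - pooled) / np.sqrt(np.maximum(var - var_pooled, _VAR_EPS))
    tau, p = stats.kendalltau(deviates, var)
    return float(tau), float(p)


def funnel_data(effects: Iterable[StudyEffect]) -> tuple[list[tuple[float, float]], float]:
    """Plot-ready (log OR, SE) points plus the random-effects reference line."""
    effects = list(effects)
    if not effects:
        raise ValueError("no effects")
    points = [(e.log_or, e.se) for e in effects]
    if len(effects) >= 2:
        ref, _, _ = pool_random(effects)
    else:
        ref = effects[0].log_or
    return points, ref


def leave_one_out(model: MetaAnalysis, alpha: float = 0.05) -> SensitivityResult:
    """Re-pool after omitting each study in turn.

    ``robust`` is True when no single omission flips significance at
    ``alpha``.  With a k=3 baseline the omission re-pools run at k=2 and are
    flagged sub-threshold in ``notes``.
    """
    baseline = model.fit()
    results: list[MetaAnalysisResults] = []
    notes = []
    if model.k == 3:
        notes.append("omission results have k=2, below the synopsis threshold")
    for eff in model.effects:
        results.append(model.drop(eff.study_id).fit())
    base_sig = baseline.p < alpha
    robust = all((r.p < alpha) == base_sig for r in results)
    return SensitivityResult(
        baseline=baseline, leave_one_out=results, robust=robust,
        notes="; ".join(notes))


def hwe_sensitivity(table: StudyTable, rsid: str,
                    model: GeneticModel | str = GeneticModel.ADDITIVE,
                    subgroup: str | None = None,
                    alpha: float = 0.05,
                    min_sources: int = 3) -> SensitivityResult:
    """Re-pool after excluding studies whose controls violate HWE.

    ``hwe_excluded`` is None when no study is excluded; when fewer than two
    studies survive the exclusion the re-pool is reported non-computable in
    ``notes``.
    """
    model = GeneticModel(model)
    if model.scheme != "genotype":
        raise ValueError("HWE sensitivity requires genotype-scheme records")
    meta = MetaAnalysis.from_table(table, rsid, model=model, subgroup=subgroup,
                                   min_sources=min_sources)
    baseline = meta.fit()
    sub = table.subset(rsid=rsid, scheme="genotype", ethnicity=subgroup)
    excluded = [r.study_id for r in sub.records
                if hwe_test(r.control_counts, alpha=alpha).violated]
    if not excluded:
        return SensitivityResult(baseline=baseline, excluded_ids=[])
    surviving = MetaAnalysis(
        effects=[e for e in meta.effects if e.study_id not in excluded],
        variant=meta.variant, model=meta.model, subgroup=meta.subgroup,
        gene=meta.gene, comparison=meta.comparison,
        source_ids=[s for s, e in zip(meta.source_ids, meta.effects)
                    if e.study_id not in excluded],
    )
    if surviving.k < 2:
        return SensitivityResult(
            baseline=baseline, excluded_ids=excluded,
            notes=f"only {surviving.k} studies pass HWE; re-pool not computable")
    return SensitivityResult(
        baseline=baseline, hwe_excluded=surviving.fit(), excluded_ids=excluded)
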