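"""Inverse-variance meta-analysis: fixed effects, DerSimonian-Laird random
effects, and heterogeneity statistics.

Model/results layout
--------------------
:class:`MetaAnalysis` is the model object: a set of per-study log odds
ratios with standard errors, built either directly or from a
:class:`~hccmeta.io.StudyTable` via :meth:`MetaAnalysis.from_table`.
``fit()`` returns a :class:`MetaAnalysisResults` carrying the pooled OR,
its 95% CI and two-sided p, Cochran's Q with its p-value, I-squared,
the DerSimonian-Laird tau-squared, and study/subject counts, with
``summary()``, bias tests and sensitivity analyses as methods.

Estimators
----------
With fixed-effect weights :math:`w_i = 1/se_i^2`,

.. math::

    \\hat\\theta_F = \\frac{\\sum w_i \\theta_i}{\\sum w_i}, \\qquad
    Q = \\sum w_i (\\theta_i - \\hat\\theta_F)^2, \\qquad
    \\hat\\tau^2 = \\max\\!\\left(0,
        \\frac{Q - (k-1)}{\\sum w_i - \\sum w_i^2 / \\sum w_i}\\right),

and the random-effects pool re-weights with
:math:`w_i^* = 1/(se_i^2 + \\hat\\tau^2)`.
:math:`I^2 = \\max(0, (Q - df)/Q) \\cdot 100` summarises the fraction of
total variation attributable to between-study heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from hccmeta.association import StudyEffect, study_odds_ratio
from hccmeta.genetic_models import (
    GeneticModel,
    build_contrast,
    effect_allele_frequency,
)
from hccmeta.io import StudyTable

Z_95 = 1.96  # normal quantile used for 95% CIs, matching printed CI arithmetic


class EligibilityError(ValueError):
    """Too few independent sources for a synopsis-grade meta-analysis."""

    def __init__(self, message: str, n_sources: int = 0):
        super().__init__(message)
        self.n_sources = n_sources


def _as_effects(effects: Iterable[StudyEffect]) -> list[StudyEffect]:
    out = list(effects)
    if len(out) < 2:
        raise EligibilityError(
            f"need at least 2 effects to pool, got {len(out)}", n_sources=len(out))
    return out


def pool_fixed(effects: Iterable[StudyEffect]) -> tuple[float, float]:
    """Inverse-variance fixed-effect pooled log-OR and its SE."""
    effects = _as_effects(effects)
    w = np.array([1.0 / e.var for e in effects])
    theta = np.array([e.log_or for e in effects])
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return pooled, se


def cochran_q(effects: Iterable[StudyEffect]) -> tuple[float, int, float]:
    """Cochran's Q, its df (k-1), and the heterogeneity p-value."""
    effects = _as_effects(effects)
    pooled, _ = pool_fixed(effects)
    w = np.array([1.0 / e.var for e in effects])
    theta = np.array([e.log_or for e in effects])
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(effects) - 1
    p_het = float(stats.chi2.sf(q, df=df))
    return q, df, p_het


def i_squared(q: float, df: int) -> float:
    """I-squared heterogeneity percentage, truncated at 0."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def dl_tau2(effects: Iterable[StudyEffect]) -> float:
    """DerSimonian-Laird moment estimator of between-study variance."""
    effects = _as_effects(effects)
    q, df, _ = cochran_q(effects)
    w = np.array([1.0 / e.var for e in effects])
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def pool_random(effects: Iterable[StudyEffect],
                tau2: float | None = None) -> tuple[float, float, float]:
    """Random-effects pooled log-OR, SE and two-sided normal p.

    ``tau2`` defaults to the DerSimonian-Laird estimate; passing 0 reduces
    exactly to the fixed-effect pool.
    """
    effects = _as_effects(effects)
    if tau2 is None:
        tau2 = dl_tau2(effects)
    w = np.array([1.0 / (e.var + tau2) for e in effects])
    theta = np.array([e.log_or for e in effects])
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return pooled, se, p


def classify_heterogeneity(i2: float) -> str:
    """Mild (<25), moderate (25-50 inclusive) or large (>50) heterogeneity."""
    if not 0 <= i2 <= 100:
        raise ValueError(f"I^2 must be in [0, 100], got {i2}")
    if i2 < 25:
        return "mild"
    if i2 <= 50:
        return "moderate"
    return "large"


def count_sources(effects_or_records) -> int:
    """Number of independent sources (distinct publications).

    Two cohorts inside one publication count once toward eligibility but
    both contribute effects.
    """
    ids = set()
    for item in effects_or_records:
        sid = getattr(item, "source_id", None) or getattr(item, "study_id", "")
        ids.add(sid)
    return len(ids)


@dataclass
class MetaAnalysis:
    """A meta-analysis model over per-study effects.

    Parameters
    ----------
    effects
        Per-study :class:`~hccmeta.association.StudyEffect` objects.
    variant, model, subgroup, gene, comparison
        Labels carried through to the results.
    source_ids
        Publication identifiers aligned with ``effects``; used for the
        independent-sources eligibility rule (defaults to study ids).
    """

    effects: list[StudyEffect]
    variant: str = ""
    model: GeneticModel | str = GeneticModel.ADDITIVE
    subgroup: str = "all"
    gene: str = ""
    comparison: str = ""
    n_cases: int = 0
    n_controls: int = 0
    effect_allele_freq: float | None = None
    source_ids: list[str] = field(default_factory=list)
    min_sources: int = 3

    def __post_init__(self) -> None:
        self.effects = list(self.effects)
        if not self.source_ids:
            self.source_ids = [e.study_id for e in self.effects]
        if isinstance(self.model, str):
            self.model = GeneticModel(self.model)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_table(cls, table: StudyTable, rsid: str,
                   model: GeneticModel | str = GeneticModel.ADDITIVE,
                   subgroup: str | None = None,
                   min_sources: int = 3) -> "MetaAnalysis":
        """Build the model for one variant x genetic model x subgroup.

        ``subgroup`` filters on ethnicity (``None`` = all ancestries).
        Raises :class:`EligibilityError` when fewer than ``min_sources``
        independent publications remain after filtering.
        """
        model = GeneticModel(model)
        sub = table.subset(rsid=rsid, scheme=model.scheme, ethnicity=subgroup)
        records = sub.records
        n_src = count_sources(records)
        if n_src < min_sources:
            raise EligibilityError(
                f"{rsid} [{model.value}, {subgroup or 'all'}]: "
                f"{n_src} independent sources < {min_sources}", n_sources=n_src)
        effects = [study_odds_ratio(build_contrast(r, model), study_id=r.study_id)
                   for r in records]
        freq = None
        if model.scheme == "genotype":
            freq = effect_allele_frequency(records, arm="controls")
        first = records[0]
        return cls(
            effects=effects,
            variant=rsid,
            model=model,
            subgroup=subgroup or "all",
            gene=first.gene,
            comparison=f"{first.effect_allele} vs {first.other_allele}",
            n_cases=sum(r.n_cases for r in records),
            n_controls=sum(r.n_controls for r in records),
            effect_allele_freq=freq,
            source_ids=[r.source_id for r in records],
            min_sources=min_sources,
        )

    # -- properties ---------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def n_sources(self) -> int:
        return len(set(self.source_ids))

    def drop(self, study_id: str) -> "MetaAnalysis":
        """A new model with one study removed (for leave-one-out)."""
        keep = [i for i, e in enumerate(self.effects) if e.study_id != study_id]
        if len(keep) == self.k:
            raise KeyError(f"no study {study_id!r} in this meta-analysis")
        return MetaAnalysis(
            effects=[self.effects[i] for i in keep],
            variant=self.variant, model=self.model, subgroup=self.subgroup,
            gene=self.gene, comparison=self.comparison,
            n_cases=self.n_cases, n_controls=self.n_controls,
            effect_allele_freq=self.effect_allele_freq,
            source_ids=[self.source_ids[i] for i in keep],
            min_sources=self.min_sources,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "random") -> "MetaAnalysisResults":
        """Pool the effects; ``method`` is ``random`` (primary) or ``fixed``."""
        if method not in {"random", "fixed"}:
            raise ValueError(f"unknown pooling method {method!r}")
        q, df, p_het = cochran_q(self.effects)
        i2 = i_squared(q, df)
        tau2 = dl_tau2(self.effects)
        if method == "fixed":
            pooled, se = pool_fixed(self.effects)
            p = float(2.0 * stats.norm.sf(abs(pooled / se)))
        else:
            pooled, se, p = pool_random(self.effects, tau2=tau2)
        fixed_pooled, fixed_se = pool_fixed(self.effects)
        return MetaAnalysisResults(
            model_obj=self,
            variant=self.variant, model=self.model, subgroup=self.subgroup,
            gene=self.gene, comparison=self.comparison,
            effect_allele_freq=self.effect_allele_freq,
            k=self.k, n_sources=self.n_sources,
            n_cases=self.n_cases, n_controls=self.n_controls,
            log_or=pooled, se=se,
            or_pooled=math.exp(pooled),
            ci_low=math.exp(pooled - Z_95 * se),
            ci_high=math.exp(pooled + Z_95 * se),
            p=p, q=q, q_df=df, p_het=p_het, i2=i2, tau2=tau2,
            method=method, het_class=classify_heterogeneity(i2),
            fixed_log_or=fixed_pooled, fixed_se=fixed_se,
        )


@dataclass
class MetaAnalysisResults:
    """Fitted pooled estimate with heterogeneity diagnostics.

    All estimates are on the odds-ratio scale except ``log_or``/``se``;
    ``p`` is the two-sided normal p of the pooled effect and ``p_het`` the
    chi-square p of Cochran's Q (the synopsis "Ph").
    """

    model_obj: MetaAnalysis
    variant: str
    model: GeneticModel
    subgroup: str
    gene: str
    comparison: str
    effect_allele_freq: float | None
    k: int
    n_sources: int
    n_cases: int
    n_controls: int
    log_or: float
    se: float
    or_pooled: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    q_df: int
    p_het: float
    i2: float
    tau2: float
    method: str
    het_class: str
    fixed_log_or: float
    fixed_se: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    # bias/sensitivity methods delegate to hccmeta.bias so that module
    # remains the tested functional surface
    def egger(self):
        from hccmeta.bias import egger_test
        return egger_test(self.model_obj.effects)

    def begg(self):
        from hccmeta.bias import begg_test
        return begg_test(self.model_obj.effects)

    def funnel_data(self):
        from hccmeta.bias import funnel_data
        return funnel_data(self.model_obj.effects)

    def leave_one_out(self):
        from hccmeta.bias import leave_one_out
        return leave_one_out(self.model_obj)

    def plot_funnel(self, ax=None):
        """Begg-style funnel plot: per-study log OR against SE."""
        import matplotlib.pyplot as plt

        points, ref = self.funnel_data()
        if ax is None:
            _, ax = plt.subplots()
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        ax.scatter(xs, ys)
        ax.axvline(ref, linestyle="--", color="grey")
        ax.set_xlabel("log odds ratio")
        ax.set_ylabel("standard error")
        ax.invert_yaxis()
        ax.set_title(f"{self.variant} ({self.model.value}, {self.subgroup})")
        return ax

    def summary(self) -> str:
        """Human-readable fit summary in the statsmodels style."""
        lines = [
            "Meta-analysis results",
            "=" * 58,
            f"variant: {self.variant} ({self.gene}, {self.comparison})",
            f"model: {self.model.value}   subgroup: {self.subgroup}   "
            f"method: {self.method}-effects",
            f"studies: {self.k} (sources: {self.n_sources})   "
            f"cases: {self.n_cases}   controls: {self.n_controls}",
            "-" * 58,
            f"OR = {self.or_pooled:.3f}  95% CI ({self.ci_low:.3f}, "
            f"{self.ci_high:.3f})  p = {self.p:.4g}",
            f"Q = {self.q:.3f} (df {self.q_df}, Ph = {self.p_het:.4g})   "
            f"I^2 = {self.i2:.1f}% ({self.het_class})   tau^2 = {self.tau2:.4f}",
            "=" * 58,
        ]
        return "\n".join(lines)


def meta_analyze(table: StudyTable, rsid: str,
                 model: GeneticModel | str = GeneticModel.ADDITIVE,
                 subgroup: str | None = None,
                 min_sources: int = 3,
                 method: str = "random") -> MetaAnalysisResults:
    """One-call meta-analysis: build the model from ``table`` and fit it."""
    return MetaAnalysis.from_table(
        table, rsid, model=model, subgroup=subgroup, min_sources=min_sources,
    ).fit(method=method)
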