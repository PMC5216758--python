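"""Synopsis orchestration: eligibility filtering, per-variant/model/subgroup
meta-analysis, bias and sensitivity analyses, and Venice grading.

The presentation rule follows field-synopsis practice: every nominally
significant association is presented; a non-significant one is presented
only when it rests on at least ``null_presentation_min`` independent
datasets (this guards against false-negative claims from thin data).
Per-variant failures are logged and skipped, never fatal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import yaml

from hccmeta.bias import BiasResult, SensitivityResult, begg_test, egger_test, \
    hwe_sensitivity, leave_one_out
from hccmeta.genetic_models import GeneticModel
from hccmeta.io import StudyTable, write_synopsis
from hccmeta.meta import EligibilityError, MetaAnalysis, MetaAnalysisResults, \
    count_sources
from hccmeta.venice import VeniceGrade, grade

logger = logging.getLogger(__name__)

GENOTYPE_MODELS = (GeneticModel.ADDITIVE, GeneticModel.DOMINANT,
                   GeneticModel.RECESSIVE)


@dataclass
class PipelineConfig:
    """All knobs of the synopsis run; defaults mirror standard practice
    (three independent sources for eligibility, six for presenting null
    results, nominal 0.05 significance, HWE screening at 0.05)."""

    models: tuple = ("additive", "dominant", "recessive", "carrier")
    subgroup_dims: tuple = ("ethnicity",)
    min_sources: int = 3
    null_presentation_min: int = 6
    hwe_alpha: float = 0.05
    meta_alpha: float = 0.05
    egger_alpha: float = 0.05
    continuity: bool = True
    multiple_testing: str | None = None  # None | "bonferroni" | "fdr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_sources < 2:
            raise ValueError("min_sources must be >= 2")
        for name in ("hwe_alpha", "meta_alpha", "egger_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("models", "subgroup_dims"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SynopsisEntry:
    """One variant x model x subgroup result with its companion analyses."""

    result: MetaAnalysisResults
    bias: BiasResult | None
    sensitivity: SensitivityResult | None
    hwe: SensitivityResult | None
    venice: VeniceGrade | None
    presented: bool
    significant: bool
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        r = self.result
        out = {
            "gene": r.gene, "rsid": r.variant, "comparison": r.comparison,
            "model": r.model.value, "subgroup": r.subgroup,
            "k": r.k, "n_sources": r.n_sources,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
            "or": r.or_pooled, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p": r.p, "q": r.q, "p_het": r.p_het, "i2": r.i2, "tau2": r.tau2,
            "het_class": r.het_class, "method": r.method,
            "effect_allele_freq": r.effect_allele_freq,
            "significant": self.significant, "presented": self.presented,
        }
        if self.p_adjusted is not None:
            out["p_adjusted"] = self.p_adjusted
        if self.bias is not None:
            out.update({
                "egger_intercept": self.bias.egger_intercept,
                "egger_p": self.bias.egger_p,
                "begg_tau": self.bias.begg_tau, "begg_p": self.bias.begg_p,
                "bias_low_power": self.bias.low_power,
            })
        if self.sensitivity is not None:
            out["loo_robust"] = self.sensitivity.robust
        if self.hwe is not None:
            out["hwe_excluded_ids"] = list(self.hwe.excluded_ids)
        if self.venice is not None:
            out.update({"grade": self.venice.letters,
                        "evidence": self.venice.composite,
                        "grade_rationale": self.venice.rationale})
        return out


@dataclass
class SynopsisReport:
    entries: list[SynopsisEntry] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    def presented(self) -> list[SynopsisEntry]:
        return [e for e in self.entries if e.presented]

    def write(self, synopsis_path, dump_path=None, format: str = "csv") -> None:
        write_synopsis([(e.result, e.venice) for e in self.presented()],
                       synopsis_path, format=format)
        if dump_path is not None:
            with open(dump_path, "w", encoding="utf-8") as fh:
                json.dump({"entries": [e.to_dict() for e in self.entries],
                           "skipped": self.skipped},
                          fh, indent=1, sort_keys=True)


def _applicable_models(scheme: str, config: PipelineConfig) -> list[GeneticModel]:
    wanted = [GeneticModel(m) for m in config.models]
    if scheme == "carrier":
        return [m for m in wanted if m is GeneticModel.CARRIER]
    return [m for m in wanted if m is not GeneticModel.CARRIER]


def _subgroups(table: StudyTable, rsid: str, scheme: str,
               config: PipelineConfig) -> list[tuple[str, str | None]]:
    """('all', None) plus each ethnicity level with >= min_sources sources."""
    out: list[tuple[str, str | None]] = [("all", None)]
    if "ethnicity" in config.subgroup_dims:
        sub = table.subset(rsid=rsid, scheme=scheme)
        levels = sorted({r.ethnicity for r in sub.records})
        for eth in levels:
            n_src = count_sources(sub.subset(ethnicity=eth).records)
            if n_src >= config.min_sources:
                out.append((eth, eth))
    return out


def _analyze_one(table: StudyTable, rsid: str, model: GeneticModel,
                 label: str, eth: str | None,
                 config: PipelineConfig) -> SynopsisEntry:
    meta = MetaAnalysis.from_table(table, rsid, model=model, subgroup=eth,
                                   min_sources=config.min_sources)
    result = meta.fit(method="random")
    bias = None
    if meta.k >= 3:
        try:
            intercept, se, egger_p = egger_test(meta.effects)
            tau, begg_p = begg_test(meta.effects)
            bias = BiasResult(egger_intercept=intercept, egger_se=se,
                              egger_p=egger_p, begg_tau=tau, begg_p=begg_p,
                              k=meta.k)
        except ValueError as exc:
            logger.info("bias tests failed for %s/%s/%s: %s",
                        rsid, model.value, label, exc)
    sensitivity = leave_one_out(meta, alpha=config.meta_alpha)
    hwe = None
    if model.scheme == "genotype":
        hwe = hwe_sensitivity(table, rsid, model=model, subgroup=eth,
                              alpha=config.hwe_alpha,
                              min_sources=config.min_sources)
    significant = result.p < config.meta_alpha
    presented = significant or result.n_sources >= config.null_presentation_min
    venice = None
    if significant:
        venice = grade(result, bias_result=bias)
    return SynopsisEntry(result=result, bias=bias, sensitivity=sensitivity,
                         hwe=hwe, venice=venice, presented=presented,
                         significant=significant)


def run_synopsis(table: StudyTable, config: PipelineConfig | None = None) -> SynopsisReport:
    """Run the full synopsis over every variant x model x subgroup."""
    config = config or PipelineConfig()
    report = SynopsisReport()
    if len(table) == 0:
        logger.warning("empty study table: empty report")
        return report
    for rsid in table.rsids():
        schemes = sorted({r.variant_scheme for r in table.subset(rsid=rsid).records})
        for scheme in schemes:
            for model in _applicable_models(scheme, config):
                for label, eth in _subgroups(table, rsid, scheme, config):
                    try:
                        report.entries.append(
                            _analyze_one(table, rsid, model, label, eth, config))
                    except EligibilityError as exc:
                        report.skipped.append(
                            {"rsid": rsid, "model": model.value,
                             "subgroup": label, "reason": str(exc),
                             "n_sources": exc.n_sources})
                        logger.info("skipping %s/%s/%s: %s",
                                    rsid, model.value, label, exc)
                    except ValueError as exc:
                        report.skipped.append(
                            {"rsid": rsid, "model": model.value,
                             "subgroup": label, "reason": str(exc)})
                        logger.warning("failed %s/%s/%s: %s",
                                       rsid, model.value, label, exc)
    _adjust_pvalues(report, config)
    return report


def _adjust_pvalues(report: SynopsisReport, config: PipelineConfig) -> None:
    """Optional multiple-testing adjustment across all computed analyses;
    nominal p remains the significance/presentation criterion."""
    if config.multiple_testing is None or not report.entries:
        return
    pvals = [e.result.p for e in report.entries]
    if config.multiple_testing == "bonferroni":
        adjusted = [min(1.0, p * len(pvals)) for p in pvals]
    elif config.multiple_testing == "fdr":
        from scipy.stats import false_discovery_control
        adjusted = list(false_discovery_control(pvals, method="bh"))
    else:
        raise ValueError(
            f"unknown multiple_testing method {config.multiple_testing!r}")
    for entry, adj in zip(report.entries, adjusted):
        entry.p_adjusted = float(adj)
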