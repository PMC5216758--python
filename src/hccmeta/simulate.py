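"""Synthetic multi-study case-control genotype data.

The generator emulates the statistical structure a candidate-gene
meta-analysis assumes: control genotypes in Hardy-Weinberg equilibrium at a
control effect-allele frequency p0, a per-allele (multiplicative) odds model
in cases so the additive-contrast OR equals exp(theta) exactly, Normal
between-study variation of the study-level log OR (tau2), and an optional
significance-threshold censoring mechanism for publication bias (studies
with an additive-contrast p at or above ``censor_alpha`` are suppressed with
probability ``censor_prob``).

Case genotype law: with HWE control proportions (p0^2, 2 p0 q0, q0^2) and
study log OR theta_s, the case probability of carrying g copies of the
effect allele is proportional to the control proportion times
exp(theta_s * g); under this law the population allelic odds ratio is
exactly exp(theta_s).

Reproducibility: one global seed; per-study streams are derived by
deterministic seed-sequence spawning so changing k never reshuffles
earlier studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from hccmeta.genetic_models import GeneticModel, build_contrast
from hccmeta.association import study_odds_ratio
from hccmeta.io import StudyRecord, StudyTable


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-study generator.

    ``n_cases``/``n_controls`` may be a fixed integer or an inclusive
    ``(low, high)`` range sampled uniformly per study.  ``p0`` may be a
    fixed frequency or ``("beta", a, b)`` for Beta-distributed per-study
    control frequencies.
    """

    k: int = 10
    n_cases: int | tuple[int, int] = 1000
    n_controls: int | tuple[int, int] = 1000
    p0: float | tuple = 0.3
    theta: float = 0.0
    tau2: float = 0.0
    ethnicities: dict[str, float] = field(
        default_factory=lambda: {"Asian": 0.6, "Caucasian": 0.25,
                                 "African": 0.1, "mixed": 0.05})
    censor_prob: float = 0.0
    censor_alpha: float = 0.05
    gene: str = "GENE1"
    rsid: str = "rs0000001"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0 <= self.censor_prob <= 1:
            raise ValueError("censor_prob must be in [0, 1]")
        if isinstance(self.p0, (int, float)) and not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")


def _draw_size(spec, rng) -> int:
    if isinstance(spec, tuple):
        low, high = spec
        return int(rng.integers(low, high + 1))
    return int(spec)


def _draw_p0(spec, rng) -> float:
    if isinstance(spec, tuple) and spec and spec[0] == "beta":
        _, a, b = spec
        p = float(rng.beta(a, b))
        # keep strictly polymorphic
        return min(max(p, 1e-4), 1 - 1e-4)
    return float(spec)


def case_genotype_probs(p0: float, study_theta: float) -> np.ndarray:
    """Case genotype law ``(P(g=2), P(g=1), P(g=0))`` under the per-allele
    odds model; g counts copies of the effect allele."""
    q0 = 1.0 - p0
    hwe = np.array([p0 * p0, 2 * p0 * q0, q0 * q0])
    weights = hwe * np.exp(study_theta * np.array([2.0, 1.0, 0.0]))
    return weights / weights.sum()


def simulate_study(config: SimulationConfig, study_theta: float,
                   rng: np.random.Generator,
                   study_index: int = 0) -> StudyRecord:
    """Draw one case-control study at study-level log OR ``study_theta``."""
    config.validate()
    n_cases = _draw_size(config.n_cases, rng)
    n_controls = _draw_size(config.n_controls, rng)
    p0 = _draw_p0(config.p0, rng)
    q0 = 1.0 - p0
    ctrl = rng.multinomial(n_controls, [p0 * p0, 2 * p0 * q0, q0 * q0])
    case = rng.multinomial(n_cases, case_genotype_probs(p0, study_theta))
    eths = list(config.ethnicities)
    probs = np.array([config.ethnicities[e] for e in eths], dtype=float)
    eth = eths[rng.choice(len(eths), p=probs / probs.sum())]
    return StudyRecord(
        study_id=f"{config.rsid}_s{study_index:03d}",
        pubmed_id=f"{90000000 + study_index}",
        first_author=f"Author{study_index:03d}",
        year=2005 + study_index % 10,
        gene=config.gene, rsid=config.rsid,
        effect_allele="A", other_allele="a",
        ethnicity=eth,
        case_counts=tuple(int(x) for x in case),
        control_counts=tuple(int(x) for x in ctrl),
    )


def simulate_dataset(config: SimulationConfig) -> StudyTable:
    """Draw ``config.k`` studies with between-study heterogeneity and
    optional publication-bias censoring.

    Study-level log ORs are Normal(theta, tau2).  Deterministic under a
    fixed seed; per-study substreams are spawned from the global seed, so
    study i is identical whatever ``k`` is.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.k + 1)
    censor_rng = np.random.default_rng(children[-1])
    records = []
    n_censored = 0
    for i in range(config.k):
        rng = np.random.default_rng(children[i])
        theta_i = config.theta + math.sqrt(config.tau2) * rng.standard_normal()
        rec = simulate_study(config, theta_i, rng, study_index=i)
        if config.censor_prob > 0:
            try:
                eff = study_odds_ratio(build_contrast(rec, GeneticModel.ADDITIVE),
                                       study_id=rec.study_id)
                from scipy import stats
                p = 2 * stats.norm.sf(abs(eff.log_or / eff.se))
            except ValueError:
                p = 1.0
            if p >= config.censor_alpha and censor_rng.random() < config.censor_prob:
                n_censored += 1
                continue
        records.append(rec)
    if not records:
        import logging
        logging.getLogger(__name__).warning(
            "all %d simulated studies were censored", config.k)
    table = StudyTable(records=records,
                       provenance=f"simulated (seed={config.seed})")
    table.n_dropped = n_censored
    return table


def simulate_variants(configs: Sequence[SimulationConfig]) -> StudyTable:
    """Concatenate independent per-variant simulations into one table."""
    records = []
    for cfg in configs:
        records.extend(simulate_dataset(cfg).records)
    return StudyTable(records=records, provenance="simulated multi-variant")
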