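"""Fixed/random-effects pooling, heterogeneity, and the Model/Results API."""

import json
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hccmeta.association import StudyEffect
from hccmeta.io import StudyTable
from hccmeta.meta import (
    EligibilityError,
    MetaAnalysis,
    classify_heterogeneity,
    cochran_q,
    dl_tau2,
    i_squared,
    meta_analyze,
    pool_fixed,
    pool_random,
)
from hccmeta.simulate import SimulationConfig, simulate_dataset

from conftest import make_record

EFFECTS = st.lists(
    st.builds(StudyEffect,
              log_or=st.floats(-2, 2, allow_nan=False),
              se=st.floats(0.05, 1.0, allow_nan=False)),
    min_size=2, max_size=12)


class TestFixedPool:
    def test_two_identical_effects(self):
        pooled, se = pool_fixed([StudyEffect(0.2, 0.2), StudyEffect(0.2, 0.2)])
        assert pooled == pytest.approx(0.2)
        assert se == pytest.approx(0.2 / math.sqrt(2))

    def test_worked_inverse_variance_average(self, worked_effects):
        pooled, se = pool_fixed(worked_effects)
        assert pooled == pytest.approx(0.2, rel=1e-9)
        assert se == pytest.approx(0.2 / math.sqrt(3), rel=1e-9)

    def test_precise_study_dominates(self):
        pooled, _ = pool_fixed([StudyEffect(1.0, 1e-4), StudyEffect(-1.0, 10.0)])
        assert pooled == pytest.approx(1.0, abs=1e-6)

    def test_single_effect_rejected(self):
        with pytest.raises(EligibilityError):
            pool_fixed([StudyEffect(0.2, 0.2)])


class TestHeterogeneity:
    def test_identical_effects_have_zero_q(self):
        q, df, p = cochran_q([StudyEffect(0.3, 0.1)] * 4)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 3 and p == pytest.approx(1.0)

    def test_worked_q_and_p(self, worked_effects):
        q, df, p = cochran_q(worked_effects)
        assert q == pytest.approx(2.0, rel=1e-9)
        assert df == 2
        assert p == pytest.approx(math.exp(-1.0), rel=1e-9)  # chi2(2) sf

    @given(effects=EFFECTS, shift=st.floats(-3, 3, allow_nan=False))
    def test_q_invariant_under_constant_shift(self, effects, shift):
        q0, _, _ = cochran_q(effects)
        shifted = [StudyEffect(e.log_or + shift, e.se) for e in effects]
        q1, _, _ = cochran_q(shifted)
        assert q1 == pytest.approx(q0, rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("q, df, expect", [
        (10, 5, 50.0), (2, 2, 0.0), (3, 6, 0.0), (0, 4, 0.0),
    ])
    def test_i_squared_with_truncation(self, q, df, expect):
        assert i_squared(q, df) == pytest.approx(expect)

    def test_dl_tau2_truncates_and_worked_value(self, worked_effects):
        assert dl_tau2(worked_effects) == 0.0  # Q = df
        effects = [StudyEffect(0.0, 0.1), StudyEffect(1.0, 0.1)]
        # Q = 50, df = 1, denom = 200 - 2e4/200 = 100
        assert dl_tau2(effects) == pytest.approx(0.49, rel=1e-9)

    @pytest.mark.parametrize("i2, label", [
        (0.0, "mild"), (24.99, "mild"), (25.0, "moderate"), (47.9, "moderate"),
        (50.0, "moderate"), (50.01, "large"), (59.2, "large"),
    ])
    def test_heterogeneity_classes(self, i2, label):
        assert classify_heterogeneity(i2) == label


class TestRandomPool:
    @given(effects=EFFECTS)
    def test_tau2_zero_reduces_to_fixed(self, effects):
        pooled_f, se_f = pool_fixed(effects)
        pooled_r, se_r, _ = pool_random(effects, tau2=0.0)
        assert pooled_r == pytest.approx(pooled_f, rel=1e-12, abs=1e-12)
        assert se_r == pytest.approx(se_f, rel=1e-12)

    def test_worked_random_pool(self, worked_effects):
        # tau2 = 0 here, so the random pool is the fixed pool
        pooled, se, _ = pool_random(worked_effects)
        assert math.exp(pooled) == pytest.approx(math.exp(0.2), rel=1e-9)
        assert se == pytest.approx(math.sqrt(0.04 / 3), rel=1e-9)

    def test_all_null_effects(self):
        pooled, _, p = pool_random([StudyEffect(0.0, 0.2)] * 3)
        assert math.exp(pooled) == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    @given(effects=EFFECTS)
    def test_ci_contains_point_estimate(self, effects):
        ma = MetaAnalysis(effects=effects)
        res = ma.fit()
        assert res.ci_low <= res.or_pooled <= res.ci_high


def test_ci_width_shrinks_with_k():
    widths = []
    for k in (5, 20, 80):
        cfg = SimulationConfig(k=k, n_cases=500, n_controls=500,
                               theta=0.2, seed=9)
        res = meta_analyze(simulate_dataset(cfg), "rs0000001")
        widths.append(math.log(res.ci_high) - math.log(res.ci_low))
    assert widths[0] > widths[1] > widths[2]


class TestEligibility:
    def test_parameter_recovery_three_large_studies(self):
        cfg = SimulationConfig(k=3, n_cases=5000, n_controls=5000,
                               theta=0.3, seed=5)
        res = meta_analyze(simulate_dataset(cfg), "rs0000001")
        assert abs(res.log_or - 0.3) < 3 * res.se

    def test_two_studies_are_ineligible(self):
        table = StudyTable(records=[make_record(study_id=f"s{i}")
                                    for i in range(2)])
        with pytest.raises(EligibilityError) as exc:
            meta_analyze(table, "rs1")
        assert exc.value.n_sources == 2

    def test_shared_pubmed_id_counts_once_for_eligibility(self):
        # three cohorts, two publications: ineligible, but both cohorts of
        # the shared publication would contribute effects when eligible
        recs = [make_record(study_id="a", pubmed_id="p1"),
                make_record(study_id="b", pubmed_id="p1"),
                make_record(study_id="c", pubmed_id="p2")]
        with pytest.raises(EligibilityError) as exc:
            meta_analyze(StudyTable(records=recs), "rs1")
        assert exc.value.n_sources == 2
        recs.append(make_record(study_id="d", pubmed_id="p3"))
        res = meta_analyze(StudyTable(records=recs), "rs1")
        assert res.k == 4 and res.n_sources == 3


def test_summary_mentions_the_key_numbers(sim_table):
    res = meta_analyze(sim_table, "rs0000001")
    text = res.summary()
    assert f"{res.or_pooled:.3f}" in text
    assert "I^2" in text and "tau^2" in text


def test_dl_pooling_matches_metafor():
    """Independent oracle: R metafor's rma(method='DL') on five effects."""
    yi = [0.25, -0.1, 0.4, 0.05, 0.6]
    vi = [0.04, 0.09, 0.02, 0.06, 0.12]
    script = (
        "suppressMessages(library(metafor));"
        f"r <- rma(yi=c({','.join(map(str, yi))}), vi=c({','.join(map(str, vi))}),"
        " method='DL');"
        "cat(jsonlite::toJSON(list(b=as.numeric(r$b), se=r$se, tau2=r$tau2,"
        " QE=r$QE, I2=r$I2), digits=12))"
    )
    try:
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120, check=True)
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        pytest.fail(f"metafor oracle unavailable: {exc}")
    ref = json.loads(out.stdout)
    effects = [StudyEffect(y, math.sqrt(v)) for y, v in zip(yi, vi)]
    tau2 = dl_tau2(effects)
    pooled, se, _ = pool_random(effects)
    q, df, _ = cochran_q(effects)
    assert pooled == pytest.approx(ref["b"][0], rel=1e-8)
    assert se == pytest.approx(ref["se"][0], rel=1e-8)
    assert tau2 == pytest.approx(ref["tau2"][0], rel=1e-8)
    assert q == pytest.approx(ref["QE"][0], rel=1e-8)
    assert i_squared(q, df) == pytest.approx(ref["I2"][0], rel=1e-6)
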