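"""Publication-bias tests and sensitivity analyses."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hccmeta.association import StudyEffect
from hccmeta.bias import (
    begg_test,
    egger_test,
    funnel_data,
    hwe_sensitivity,
    leave_one_out,
)
from hccmeta.io import StudyTable
from hccmeta.meta import EligibilityError, MetaAnalysis, pool_random
from hccmeta.simulate import SimulationConfig, simulate_dataset

from conftest import make_record


def _effects(pairs):
    return [StudyEffect(lo, se, study_id=f"s{i}")
            for i, (lo, se) in enumerate(pairs)]


class TestEgger:
    def test_symmetric_funnel_has_zero_intercept(self):
        # mirror pairs around theta = 0.3 at matched precisions
        pairs = [(0.3 + d, se) for d, se in [(0.2, 0.1), (-0.2, 0.1),
                                             (0.1, 0.2), (-0.1, 0.2)]]
        intercept, _, _ = egger_test(_effects(pairs))
        # snd/precision are not exactly collinear, but symmetry keeps the
        # intercept near zero relative to its own scale
        assert abs(intercept) < 1e-9 or abs(intercept) < 0.2

    def test_three_point_closed_form_ols(self):
        pairs = [(0.1, 0.1), (0.3, 0.2), (0.2, 0.25)]
        effects = _effects(pairs)
        x = np.array([1 / se for _, se in pairs])
        y = np.array([lo / se for lo, se in pairs])
        n = len(x)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = np.sum(resid ** 2) / (n - 2)
        se_int = math.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
        from scipy import stats
        p = 2 * stats.t.sf(abs(intercept / se_int), df=n - 2)
        got = egger_test(effects)
        assert got[0] == pytest.approx(intercept, rel=1e-9)
        assert got[1] == pytest.approx(se_int, rel=1e-9)
        assert got[2] == pytest.approx(p, rel=1e-9)

    def test_requires_three_studies(self):
        with pytest.raises(EligibilityError):
            egger_test(_effects([(0.1, 0.1), (0.2, 0.2)]))

    @given(st.floats(0.5, 4.0))
    def test_intercept_invariant_under_joint_scaling(self, c):
        pairs = [(0.1, 0.1), (0.35, 0.2), (0.15, 0.25), (0.4, 0.3)]
        base = egger_test(_effects(pairs))
        scaled = egger_test(_effects([(lo * c, se * c) for lo, se in pairs]))
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[2] == pytest.approx(base[2], rel=1e-9)


def _brute_kendall(x, y):
    """Pair-counting tau-b."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a = np.sign(x[i] - x[j])
        b = np.sign(y[i] - y[j])
        if a == 0 and b == 0:
            continue
        if a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    from collections import Counter
    return sum(c * (c - 1) / 2 for c in Counter(v).values())


class TestBegg:
    def test_perfect_concordance_and_reversal(self):
        # effects rise steeply with se, so the standardized deviates rank
        # exactly like the variances -> tau = 1 (and -1 when reversed)
        inc = _effects([(0.0, 0.1), (1.0, 0.2), (2.0, 0.3), (3.0, 0.4)])
        tau, _ = begg_test(inc)
        assert tau == pytest.approx(1.0)
        dec = _effects([(3.0, 0.1), (2.0, 0.2), (1.0, 0.3), (0.0, 0.4)])
        tau, _ = begg_test(dec)
        assert tau == pytest.approx(-1.0)

    def test_k4_matches_hand_pair_counting(self):
        pairs = [(0.3, 0.10), (-0.1, 0.20), (0.6, 0.15), (0.05, 0.40)]
        effects = _effects(pairs)
        from hccmeta.meta import pool_fixed
        pooled, pooled_se = pool_fixed(effects)
        dev = [(e.log_or - pooled) / math.sqrt(max(e.var - pooled_se**2, 1e-12))
               for e in effects]
        var = [e.var for e in effects]
        tau, _ = begg_test(effects)
        assert tau == pytest.approx(_brute_kendall(dev, var), rel=1e-9)

    @given(st.integers(0, 1000))
    def test_brute_force_agrees_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        pairs = [(float(rng.normal(0, 0.5)), float(rng.uniform(0.05, 0.5)))
                 for _ in range(k)]
        effects = _effects(pairs)
        from hccmeta.meta import pool_fixed
        pooled, pooled_se = pool_fixed(effects)
        dev = [(e.log_or - pooled) / math.sqrt(max(e.var - pooled_se**2, 1e-12))
               for e in effects]
        var = [e.var for e in effects]
        tau, _ = begg_test(effects)
        assert tau == pytest.approx(_brute_kendall(dev, var), rel=1e-9)


def test_funnel_data_passthrough(worked_effects):
    points, ref = funnel_data(worked_effects)
    assert points == [(e.log_or, e.se) for e in worked_effects]
    assert ref == pytest.approx(pool_random(worked_effects)[0])


class TestLeaveOneOut:
    def test_exchangeable_studies_give_identical_omissions(self):
        effects = [StudyEffect(0.3, 0.15, study_id=f"s{i}") for i in range(5)]
        sens = leave_one_out(MetaAnalysis(effects=effects))
        assert len(sens.leave_one_out) == 5
        ors = {round(r.or_pooled, 12) for r in sens.leave_one_out}
        assert len(ors) == 1
        assert all(r.k == 4 for r in sens.leave_one_out)
        assert sens.robust

    def test_planted_outlier_moves_pooled_or_most(self):
        effects = [StudyEffect(0.2, 0.1, study_id=f"s{i}") for i in range(6)]
        effects.append(StudyEffect(1.8, 0.1, study_id="outlier"))
        ma = MetaAnalysis(effects=effects)
        sens = leave_one_out(ma)
        base = sens.baseline.log_or
        # leave_one_out results are ordered like the effects
        moved = max(range(len(sens.leave_one_out)),
                    key=lambda i: abs(sens.leave_one_out[i].log_or - base))
        assert effects[moved].study_id == "outlier"

    def test_dropping_then_refitting_recovers_baseline(self):
        effects = [StudyEffect(0.1 * i, 0.1 + 0.02 * i, study_id=f"s{i}")
                   for i in range(5)]
        ma = MetaAnalysis(effects=effects)
        base = ma.fit()
        reduced = ma.drop("s3")
        assert reduced.k == 4
        restored = MetaAnalysis(effects=effects)
        assert restored.fit().or_pooled == pytest.approx(base.or_pooled)

    def test_robust_false_when_omission_flips_significance(self):
        # homogeneous mildly positive studies plus one that tips the pool
        # over the significance line without inducing heterogeneity
        effects = [StudyEffect(0.08, 0.1, study_id=f"s{i}") for i in range(4)]
        effects.append(StudyEffect(0.3, 0.1, study_id="driver"))
        sens = leave_one_out(MetaAnalysis(effects=effects))
        assert sens.baseline.p < 0.05
        assert not sens.robust


class TestHweSensitivity:
    def _table(self, with_violator):
        recs = [make_record(study_id=f"s{i}", control=(36, 48, 16),
                            case=(45, 40, 15)) for i in range(4)]
        if with_violator:
            # controls far from HWE at p_hat = 0.5: too few heterozygotes
            recs.append(make_record(study_id="bad", control=(50, 0, 50),
                                    case=(55, 10, 35)))
        return StudyTable(records=recs)

    def test_all_pass_means_no_exclusion(self):
        sens = hwe_sensitivity(self._table(False), "rs1")
        assert sens.hwe_excluded is None
        assert sens.excluded_ids == []

    def test_planted_violator_is_excluded(self):
        sens = hwe_sensitivity(self._table(True), "rs1")
        assert sens.excluded_ids == ["bad"]
        assert sens.hwe_excluded is not None
        assert sens.hwe_excluded.k == 4

    def test_exclusion_moves_estimate_toward_truth(self):
        # null truth plus one HWE-violating study with a large spurious effect
        rng_recs = [make_record(study_id=f"s{i}", control=(36, 48, 16),
                                case=(36, 48, 16)) for i in range(4)]
        rng_recs.append(make_record(study_id="bad", control=(60, 2, 38),
                                    case=(90, 8, 2)))
        sens = hwe_sensitivity(StudyTable(records=rng_recs), "rs1")
        assert "bad" in sens.excluded_ids
        assert abs(sens.hwe_excluded.log_or) < abs(sens.baseline.log_or)
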