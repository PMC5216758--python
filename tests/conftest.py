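import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hccmeta.association import StudyEffect
from hccmeta.io import StudyRecord, StudyTable
from hccmeta.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def worked_effects():
    """Three effects (0.2, 0.0, 0.4), all variance 0.04: the worked chain
    with fixed pool 0.2, Q = 2 (df 2), tau2 = 0."""
    return [
        StudyEffect(log_or=0.2, se=0.2, study_id="s1"),
        StudyEffect(log_or=0.0, se=0.2, study_id="s2"),
        StudyEffect(log_or=0.4, se=0.2, study_id="s3"),
    ]


def make_record(study_id="s1", rsid="rs1", case=(10, 20, 30),
                control=(25, 50, 25), **kw):
    defaults = dict(gene="GENE1", pubmed_id=f"pm_{study_id}",
                    ethnicity="Asian", year=2010)
    defaults.update(kw)
    return StudyRecord(study_id=study_id, rsid=rsid, case_counts=case,
                       control_counts=control, **defaults)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def sim_table():
    """Deterministic 10-study dataset with a real effect (theta = 0.3)."""
    cfg = SimulationConfig(k=10, n_cases=1000, n_controls=1000,
                           p0=0.3, theta=0.3, seed=1)
    return simulate_dataset(cfg)
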