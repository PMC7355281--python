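import numpy as np
import pytest

from twinconcord import (AnalysisConfig, Cohort, TwinPair,
                         make_reclassification_fixture)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def fixture_cohort(config) -> Cohort:
    return make_reclassification_fixture(config)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Three hand-written pairs spanning the concordance categories."""
    return Cohort(label="toy", pairs=[
        TwinPair(pair_id="a", score_t1=90.0, score_t2=50.0, age=8.0,
                 raw_t1=118.18, raw_t2=45.45),
        TwinPair(pair_id="b", score_t1=80.0, score_t2=70.0, age=10.0),
        TwinPair(pair_id="c", score_t1=64.0, score_t2=66.0, age=12.0),
    ])


def pair(t1: float, t2: float, pair_id: str = "p", **kwargs) -> TwinPair:
    return TwinPair(pair_id=pair_id, score_t1=t1, score_t2=t2, **kwargs)


def scores(cohort: Cohort, attr1: str = "raw_t1", attr2: str = "raw_t2"):
    a = np.array([getattr(p, attr1) for p in cohort], dtype=float)
    b = np.array([getattr(p, attr2) for p in cohort], dtype=float)
    return a, b
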