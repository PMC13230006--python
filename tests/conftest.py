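import pytest

from retention_grammar import build_catalog, build_feature_matrix
from retention_grammar.synthetic_data import EffectConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """Small synthetic study exercising every planted structure."""
    cfg = EffectConfig(n_ci=60, n_ri=8, seed=7)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_catalog(tiny_study):
    return build_catalog(tiny_study.transcripts, tiny_study.genome)


@pytest.fixture(scope="session")
def tiny_features(tiny_study, tiny_catalog):
    return build_feature_matrix(
        tiny_catalog,
        tiny_study.genome,
        repeats=tiny_study.repeats,
        pwm_groups=tiny_study.pwm_groups,
    )
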