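import logging

import pytest
from hypothesis import HealthCheck, settings

from cnscreen import pipeline, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

logging.getLogger("cnscreen").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_experiment():
    """A deterministic scaled-down screen with planted effects."""
    return synthetic.simulate_experiment(synthetic.small_config(), seed=11)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline artifacts for the scaled-down screen."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = pipeline.PipelineConfig(synthetic=synthetic.small_config(), seed=11)
    return pipeline.run_pipeline(cfg, out)
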