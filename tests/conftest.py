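import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import embedclass as ec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_config() -> ec.FixtureConfig:
    """Desk-scale fixture: 13 well-separated classes, 60 reference tiles each."""
    return ec.FixtureConfig(tiles_per_class_range=(60, 60), seed=3)


@pytest.fixture(scope="session")
def reference(fixture_config):
    frame = ec.make_reference_set(fixture_config)
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    X = frame[fcols].to_numpy(dtype=float)
    y = frame["label"].to_numpy()
    return frame, X, y


@pytest.fixture(scope="session")
def pipeline_config() -> ec.PipelineConfig:
    return ec.PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def tsne_map(reference) -> ec.ReferenceMap:
    frame, X, y = reference
    return ec.build_map(X, y, tile_ids=frame["tile_id"].to_numpy(), params=ec.EmbedParams(seed=0))
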