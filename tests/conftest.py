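import numpy as np
import pytest

from eggmimic import (
    EggPatternParams,
    PopulationConfig,
    detect_features,
    generate_egg_image,
    generate_population,
)


@pytest.fixture(scope="session")
def default_population():
    """Population table at the study's per-period sample sizes."""
    return generate_population(PopulationConfig(seed=42))


@pytest.fixture(scope="session")
def blob_egg():
    """An egg with well-separated high-contrast blobs plus ground truth."""
    params = EggPatternParams(
        n_markings=20,
        marking_size_mean=1.0,
        marking_size_cv=0.2,
        marking_elongation=1.3,
        spatial_clustering=0.0,
        min_separation_mm=2.5,
        placement_margin=0.8,
    )
    egg, truth = generate_egg_image(params, seed=2, egg_id="blob_egg")
    return egg, truth


@pytest.fixture(scope="session")
def blob_features(blob_egg):
    egg, _ = blob_egg
    return detect_features(egg)
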