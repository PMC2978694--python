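import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_code():
    from lacicode.synthetic import PlantedCode

    return PlantedCode.simple({"KA": "TA", "YQ": "TG"})


@pytest.fixture
def planted_class(small_code):
    """One 8-member recognition class with a site planted in every region."""
    from lacicode.synthetic import generate_family, generate_regions

    records, class_map = generate_family(1, 8, small_code, seed=7)
    regions, truth = generate_regions(
        class_map, small_code, site_rate=1.0, region_len=150, seed=11
    )
    return records, class_map, regions, truth
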