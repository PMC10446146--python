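import pytest
from hypothesis import HealthCheck, settings

from nanorelease import FilterSample, SurfaceSpec

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def surface() -> SurfaceSpec:
    """Three coated honeycombs of 90 cm2 each (0.027 m2 photoactive)."""
    return SurfaceSpec(n_units=3, area_per_unit_m2=0.009)


@pytest.fixture(scope="session")
def open_circuit_sample() -> FilterSample:
    """96 h open-circuit campaign, 303.7 m3 sampled, Ti below the 1 ng LOQ."""
    return FilterSample(
        label="Test 2A", ti_mass_ng=None, loq_ng=1.0,
        sampled_volume_m3=303.7, duration_h=96.0,
    )


@pytest.fixture(scope="session")
def recirculating_sample() -> FilterSample:
    """72 h sealed-circuit campaign, 229.6 m3 sampled, Ti below the LOQ."""
    return FilterSample(
        label="Test 2B", ti_mass_ng=None, loq_ng=1.0,
        sampled_volume_m3=229.6, duration_h=72.0,
    )
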