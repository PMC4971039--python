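import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "cuspec",
    derandomize=True,
    max_examples=50,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cuspec")


@pytest.fixture
def table2_spectrum():
    """Noise-free synthetic spectrum with the five reported Cu complexes,
    plus its ground-truth manifest."""
    from cuspec.synthetic_data import SpectrumRecipe, gen_spectrum

    return gen_spectrum(SpectrumRecipe(seed=11))


@pytest.fixture
def noisy_table2_spectrum():
    """Same five complexes under 10x uniform chemical noise."""
    from cuspec.synthetic_data import SpectrumRecipe, gen_spectrum

    return gen_spectrum(SpectrumRecipe(seed=11, noise_peaks=50))
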