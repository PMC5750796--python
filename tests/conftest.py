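import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ewhk import GeneratorConfig, SpectraDataset, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_ds() -> SpectraDataset:
    """Hand-built 4-sample dataset on a short axis, for I/O and plumbing."""
    rng = np.random.default_rng(7)
    wn = np.arange(1000.0, 1021.0, 2.0)
    return SpectraDataset(
        wavenumbers=wn,
        absorbance=rng.uniform(0.1, 1.0, size=(4, wn.size)),
        labels=np.array(["cancer", "cancer", "colitis", "colitis"], dtype=object),
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
    )


@pytest.fixture(scope="session")
def synth_ds() -> SpectraDataset:
    """Default synthetic two-class dataset (44 spectra per class)."""
    return generate(GeneratorConfig(seed=11, n_per_class=44))
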