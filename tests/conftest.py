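import numpy as np
import pytest

from gcalpha.effects import GenotypeRegion, orient_and_maf


@pytest.fixture
def rng():
    return np.random.default_rng(20130815)


def make_region(dosage, positions=None, oriented=True):
    """Build a GenotypeRegion from a plain dosage matrix."""
    dosage = np.asarray(dosage, dtype=float)
    n, k = dosage.shape
    region = GenotypeRegion(
        samples=[f"S{i}" for i in range(n)],
        variant_ids=[f"v{j}" for j in range(k)],
        positions=np.arange(1, k + 1) if positions is None else np.asarray(positions),
        dosage=dosage,
    )
    return orient_and_maf(region) if oriented else region


@pytest.fixture
def region_factory():
    return make_region


@pytest.fixture
def random_rare_region(rng):
    """A 400-sample, 12-variant rare-dosage region with no missing calls."""
    f = rng.uniform(0.01, 0.08, size=12)
    dose = rng.binomial(2, f, size=(400, 12)).astype(float)
    # ensure polymorphic columns
    dose[0, dose.sum(axis=0) == 0] = 1.0
    return make_region(dose)
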