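import numpy as np
import pytest

from planeval import CohortSpec, CumulativeDVH, DifferentialDVH, EffectModel, NoiseModel


@pytest.fixture
def uniform_dvh():
    """Near-step curve: the whole structure receives (almost exactly) 78 Gy."""
    return CumulativeDVH("PTV", 80.0, [0.0, 78.0, 78.0 + 1e-6], [1.0, 1.0, 0.0])


@pytest.fixture
def linear_dvh():
    """Linear falloff from full coverage at 70 Gy to none at 80 Gy."""
    return CumulativeDVH("PTV", 80.0, [0.0, 70.0, 80.0], [1.0, 1.0, 0.0])


@pytest.fixture
def two_level_ddvh():
    return DifferentialDVH("x", [60.0, 80.0], [0.5, 0.5])


def random_cumulative(rng, n_max=30, dmax=90.0):
    """Random valid monotone cumulative DVH (shared property-test helper)."""
    n = int(rng.integers(3, n_max))
    dose = np.concatenate([[0.0], np.sort(rng.uniform(0.01, dmax, n))])
    frac = np.concatenate([[1.0], np.sort(rng.uniform(0.0, 1.0, n))[::-1]])
    if rng.random() < 0.5:
        frac[-1] = 0.0
    return CumulativeDVH("rand", float(rng.uniform(1, 500)), dose, frac)


@pytest.fixture
def small_spec():
    return CohortSpec(n_patients=3, seed=42)


@pytest.fixture
def frozen_spec():
    """Deterministic generator: zero noise, default effects."""
    return CohortSpec(n_patients=3, seed=42, noise=NoiseModel().zeroed())


@pytest.fixture
def null_spec():
    """No effects, no noise: every variant equals the patient base plan."""
    return CohortSpec(
        n_patients=2, seed=42, effects=EffectModel().zeroed(), noise=NoiseModel().zeroed()
    )
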