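from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from preaction import (
    SynthConfig,
    build_reference_set,
    generate_expert_punches,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_refset():
    """Three simulated experts, five clean punches each."""
    return build_reference_set(generate_expert_punches(3, 5, seed=1))


@pytest.fixture(scope="session")
def noiseless_refset():
    """Templates averaged from noise-free punches: self-match cost floors
    are exactly zero, so identity properties hold exactly."""
    cfg = SynthConfig(noise_sd=0.0)
    return build_reference_set(generate_expert_punches(3, 5, seed=1, base_cfg=cfg))


@pytest.fixture(scope="session")
def full_refset():
    """Five simulated experts, thirty clean punches each."""
    return build_reference_set(generate_expert_punches(5, 30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_trace(x, y=None, z=None, rate=100.0, unit="raw"):
    """Build an AccelTrace from per-axis lists (missing axes are zero)."""
    from preaction import AccelTrace

    x = np.asarray(x, dtype=np.float64)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=np.float64)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=np.float64)
    return AccelTrace(np.column_stack([x, y, z]), rate, unit=unit)
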