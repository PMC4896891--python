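"""Shared fixtures for the rckinetics test suite."""

import numpy as np
import pytest

from rckinetics import RateSet, preset_rates


@pytest.fixture(scope="session")
def ox_02() -> RateSet:
    """Oxidation preset at 0.2 mW/cm^2."""
    return preset_rates("oxidation", 0.2)


@pytest.fixture(scope="session")
def ox_2() -> RateSet:
    return preset_rates("oxidation", 2.0)


@pytest.fixture(scope="session")
def red_02() -> RateSet:
    """Reduction (dark) preset following 0.2 mW/cm^2 illumination."""
    return preset_rates("reduction", 0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rateset(rng: np.random.Generator, k_lo: float = 1e-3,
                   k_hi: float = 10.0, dark: bool = False) -> RateSet:
    """Log-uniform random rate set, optionally with the dark constraint."""
    from rckinetics import LIGHT_DRIVEN, RATE_NAMES
    names = [n for n in RATE_NAMES if not (dark and n in LIGHT_DRIVEN)]
    draw = {n: float(np.exp(rng.uniform(np.log(k_lo), np.log(k_hi))))
            for n in names}
    return RateSet(**draw)
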