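"""Shared fixtures and the independent brute-force pulse oracle.

The oracle re-states the three published peak criteria in plain Python,
with no code shared with the package's detector, so agreement between the
two is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lhpulse import DetectionParams, LHProfile, SimParams, simulate_profile

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


def oracle_detect(
    values,
    rise: float = 0.20,
    fall: float = 0.10,
    min_amplitude: float = 0.320,
    lookback: int = 2,
    lookahead: int = 2,
    nadir_window: int = 3,
) -> list[int]:
    """Brute-force application of the three peak criteria at every index.

    A peak at i must (a) be an interior local maximum (leftmost of a
    plateau), (b) exceed at least one of the previous `lookback` values by
    more than `rise`, (c) be followed within `lookahead` samples by a value
    more than `fall` below it, and (d) sit at least `min_amplitude` above
    the lowest of the `nadir_window` preceding values.
    """
    values = [float(v) for v in values]
    n = len(values)
    peaks = []
    for i in range(1, n - 1):
        if not (values[i] > values[i - 1] and values[i] >= values[i + 1]):
            continue
        prev = values[max(0, i - lookback) : i]
        if not any(values[i] > (1.0 + rise) * p for p in prev):
            continue
        nxt = values[i + 1 : i + 1 + lookahead]
        if not any(v < (1.0 - fall) * values[i] for v in nxt):
            continue
        nadir = min(values[max(0, i - nadir_window) : i])
        if not values[i] - nadir >= min_amplitude:
            continue
        peaks.append(i)
    return peaks


def make_profile(values, dt: float = 5.0, **kwargs) -> LHProfile:
    values = np.asarray(values, dtype=float)
    return LHProfile(
        animal_id=kwargs.pop("animal_id", "test"),
        times=np.arange(len(values)) * dt,
        values=values,
        **kwargs,
    )


@pytest.fixture
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def simulated_profiles() -> list:
    """A small bag of seeded profiles across secretion regimes."""
    out = []
    for seed, (ipi, mu) in enumerate([(60.0, 0.0), (20.0, 0.7), (30.0, 0.3)]):
        params = SimParams(mean_ipi=ipi, bolus_mu=mu, seed=seed)
        out.append(simulate_profile(params, animal_id=f"sim{seed}").profile)
    return out
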