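"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def slab_series_profile(y: np.ndarray, t: float, length: float,
                        diffusivity: float, n_terms: int = 400) -> np.ndarray:
    """Eigenfunction-series solution of the 1-D diffusion slab.

    c(y, 0) = 0, c(0, t) = 0, c(L, t) = 1:
        c = y/L + (2/pi) sum_n ((-1)^n / n) sin(n pi y / L) exp(-n^2 pi^2 D t / L^2)
    Independent closed-form oracle for the finite-volume transport solver.
    """
    c = y / length
    n = np.arange(1, n_terms + 1)[:, None]
    decay = np.exp(-(n**2) * np.pi**2 * diffusivity * t / length**2)
    c = c + (2 / np.pi) * np.sum(
        ((-1.0) ** n / n) * np.sin(n * np.pi * y[None, :] / length) * decay, axis=0
    )
    return c


def slab_series_formation_time(times: np.ndarray, y: np.ndarray, length: float,
                               diffusivity: float, tolerance: float) -> float:
    """First time in ``times`` at which the series profile is everywhere
    within ``tolerance`` (of the unit contrast) of the steady linear profile."""
    steady = y / length
    for t in times:
        dev = np.abs(slab_series_profile(y, t, length, diffusivity) - steady).max()
        if dev <= tolerance:
            return float(t)
    return float("nan")


def circ_dist(a: float, b: float) -> float:
    """Distance between two directions on the circle, degrees in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240715)
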