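"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lpmp import GridSpec, LorentzianComponent, Reconstruction


def assert_monotone_residuals(rec: Reconstruction) -> None:
    """Residual norms must be non-increasing (orthogonal projection property).

    A tiny additive slack covers floating-point rounding of exactly flat
    steps; the sequence itself is produced by joint least squares over
    growing column sets, so any genuine increase is a solver bug.
    """
    norms = np.asarray(rec.residual_norms)
    assert norms.ndim == 1 and norms.size >= 1
    slack = 1e-10 * max(norms[0], 1.0)
    assert np.all(np.diff(norms) <= slack), f"residuals increased: {norms}"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(N=16, gamma_unit=1.0, J=6)


def six_peak_fixture() -> tuple[GridSpec, list[LorentzianComponent]]:
    """Well-separated on-grid peaks recoverable exactly from 120 of 257 samples.

    Narrow widths keep the greedy width search unambiguous: wide Lorentzian
    tails otherwise bias the per-iteration width argmin (see the methods
    note); the descending amplitudes let the pursuit peel peaks strongest
    first.
    """
    grid = GridSpec(N=128, gamma_unit=1.0, J=20)
    centers = [-110, -68, -25, 18, 60, 103]
    widths = [1, 1, 0, 1, 1, 0]
    amps = [16.0, 8.0, 4.0, 2.0, 1.0, 0.5]
    peaks = [
        LorentzianComponent(c, j, complex(a)) for c, j, a in zip(centers, widths, amps)
    ]
    return grid, peaks
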