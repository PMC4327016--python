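"""Discrete transforms and the Lorentzian atom dictionary.

A free induction decay (FID) sampled on a uniform grid of ``M = 2N + 1``
points is modelled as a superposition of exponentially damped complex
oscillations.  Working in the natural grid units (time unit ``1/Omega``,
frequency unit ``Delta Omega = Omega / M``), the on-grid oscillation with
frequency index ``l`` contributes ``exp(2*pi*1j*k*l/M)`` at time index ``k``,
and a damping of ``j`` line-width units multiplies it by
``exp(-2*pi*k*j*gamma_unit/M)``.

Two square transforms tie the domains together:

* the *synthesis* matrix ``S`` (frequency -> time), kernel
  ``exp(+2*pi*1j*k*l/M)``;
* the *analysis* matrix ``T = S^{-1}`` (time -> frequency), kernel
  ``exp(-2*pi*1j*k*l/M) / M``.

A Lorentzian atom ``L_l^j`` is the analysis transform of the damped
oscillation ``C^j S_l`` — a discrete complex Lorentzian peaked at frequency
index ``l`` with half-width ``j`` line-width units.  Atoms with ``j = 0`` are
exactly the standard basis vectors of the frequency domain.

Frequency vectors ("spectra") are plain complex ndarrays of length ``M``
indexed by ``l = -N ... N`` (array position ``l + N``); time vectors are
complex ndarrays indexed by ``k = 0 ... 2N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "LorentzianComponent",
    "build_fourier_matrix",
    "fourier_inverse",
    "synthesis_matrix",
    "analysis_matrix",
    "build_damping_matrix",
    "damping_diagonal",
    "lorentzian_atom",
    "atom_bank",
    "atom_peak_height",
    "atom_time_signal",
    "peaks_to_spectrum",
    "spectrum_to_time",
    "time_to_spectrum",
]


@dataclass(frozen=True)
class GridSpec:
    """Frequency/time grid and dictionary parameters.

    Parameters
    ----------
    N : int
        Grid half-size.  The full grid has ``2 N + 1`` points: time indices
        ``k in [0, 2N]`` and frequency indices ``l in [-N, N]``.
    gamma_unit : float, default 1.0
        The width unit ``Gamma`` expressed as a fraction of one grid
        frequency step ``Delta Omega``.  With the default, the width index
        ``j`` of an atom is measured directly in grid line-width units.
    J : int, default 20
        Largest admissible width index; atoms carry ``j in [0, J]``.
    """

    N: int
    gamma_unit: float = 1.0
    J: int = 20

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")
        # J = 0 is allowed: the dictionary then degenerates to the impulse
        # basis and LPMP coincides with plain OMP.
        if int(self.J) != self.J or self.J < 0:
            raise ValueError(f"J must be an integer >= 0, got {self.J!r}")
        if not self.gamma_unit > 0:
            raise ValueError(f"gamma_unit must be > 0, got {self.gamma_unit!r}")

    @property
    def size(self) -> int:
        """Number of grid points ``M = 2 N + 1``."""
        return 2 * self.N + 1

    @property
    def frequencies(self) -> np.ndarray:
        """Signed frequency indices ``[-N, ..., N]``."""
        return np.arange(-self.N, self.N + 1)

    @property
    def times(self) -> np.ndarray:
        """Time indices ``[0, ..., 2N]``."""
        return np.arange(self.size)

    def column(self, center: int) -> int:
        """Array position of frequency index ``center`` (validates range)."""
        if int(center) != center or not -self.N <= center <= self.N:
            raise ValueError(
                f"frequency index {center!r} outside grid [-{self.N}, {self.N}]"
            )
        return int(center) + self.N

    def validate_width(self, j: int) -> int:
        if int(j) != j or not 0 <= j <= self.J:
            raise ValueError(f"width index {j!r} outside [0, {self.J}]")
        return int(j)


@dataclass(frozen=True)
class LorentzianComponent:
    """One matched peak: center index ``l``, width index ``j``, amplitude ``b``."""

    center: int
    width_index: int
    amplitude: complex

    def validate(self, grid: GridSpec) -> "LorentzianComponent":
        grid.column(self.center)
        grid.validate_width(self.width_index)
        return self


def build_fourier_matrix(grid: GridSpec) -> np.ndarray:
    """The Fourier matrix ``F`` with ``F[k, l] = exp(-2*pi*1j*k*l/M)``.

    Rows are time indices ``k in [0, 2N]``; columns are frequency indices in
    the signed order ``l = -N ... N``.  ``F`` is ``M``-unitary:
    ``F @ fourier_inverse(grid) == I`` with the inverse ``(1/M) F*``.
    """
    k = grid.times[:, None]
    l = grid.frequencies[None, :]
    return np.exp(-2j * np.pi * k * l / grid.size)


def fourier_inverse(grid: GridSpec) -> np.ndarray:
    """``F^{-1} = (1/M) F*`` for the matrix of :func:`build_fourier_matrix`."""
    return build_fourier_matrix(grid).conj().T / grid.size


@lru_cache(maxsize=None)
def synthesis_matrix(grid: GridSpec) -> np.ndarray:
    """Frequency -> time transform ``S`` with ``S[k, l] = exp(+2*pi*1j*k*l/M)``.

    Applied to the impulse at ``l`` it yields the pure on-grid oscillation
    ``exp(2*pi*1j*k*l/M)``, matching the continuous FID model evaluated at
    ``t_k = k/Omega``.
    """
    k = grid.times[:, None]
    l = grid.frequencies[None, :]
    return np.exp(2j * np.pi * k * l / grid.size)


@lru_cache(maxsize=None)
def analysis_matrix(grid: GridSpec) -> np.ndarray:
    """Time -> frequency transform ``T = S^{-1}``, kernel ``exp(-2*pi*1j*k*l/M)/M``."""
    return synthesis_matrix(grid).conj().T / grid.size


def damping_diagonal(grid: GridSpec, power: int) -> np.ndarray:
    """Diagonal of ``C^j``: ``exp(-2*pi*k*j*gamma_unit/M)`` for ``k in [0, 2N]``."""
    j = grid.validate_width(power)
    return np.exp(-2.0 * np.pi * grid.times * j * grid.gamma_unit / grid.size)


def build_damping_matrix(grid: GridSpec, power: int) -> np.ndarray:
    """The damping matrix ``C^j`` as a dense diagonal matrix."""
    return np.diag(damping_diagonal(grid, power)).astype(complex)


@lru_cache(maxsize=None)
def atom_bank(grid: GridSpec, j: int) -> np.ndarray:
    """All atoms of width index ``j`` as columns of an ``M x M`` matrix.

    Column at array position ``l + N`` is the atom ``L_l^j``.  Banks are
    cached per ``(grid, j)`` on first use; memory is ``M**2`` complex entries
    per width, a deliberate desk-scale trade of memory for speed.
    """
    grid.validate_width(j)
    if j == 0:
        # C^0 = I and T S = I analytically: impulse atoms are exact
        bank = np.eye(grid.size, dtype=complex)
        bank.setflags(write=False)
        return bank
    S = synthesis_matrix(grid)
    damped = damping_diagonal(grid, j)[:, None] * S
    bank = analysis_matrix(grid) @ damped
    bank.setflags(write=False)
    return bank


def lorentzian_atom(grid: GridSpec, l: int, j: int) -> np.ndarray:
    """The frequency-domain Lorentzian atom ``L_l^j`` (length ``M``).

    ``j = 0`` atoms are exactly standard basis vectors; for ``j >= 1`` the
    atom is a discrete complex Lorentzian whose maximum modulus sits at
    index ``l``.
    """
    return atom_bank(grid, j)[:, grid.column(l)]


def atom_peak_height(grid: GridSpec, j: int) -> float:
    """Modulus of an atom ``L_l^j`` at its own center ``l``.

    Closed form of the geometric series ``(1/M) sum_k rho^k`` with
    ``rho = exp(-2*pi*j*gamma_unit/M)``; equals 1 for ``j = 0``.
    """
    j = grid.validate_width(j)
    if j == 0:
        return 1.0
    rho = np.exp(-2.0 * np.pi * j * grid.gamma_unit / grid.size)
    return float((1.0 - rho**grid.size) / (1.0 - rho) / grid.size)


def atom_time_signal(
    grid: GridSpec, l: int, j: int, indices: np.ndarray | None = None
) -> np.ndarray:
    """Time signal of atom ``(l, j)``: ``exp(-2*pi*k*j*gamma_unit/M) * exp(2*pi*1j*k*l/M)``.

    This is the closed form of ``spectrum_to_time(grid, lorentzian_atom(...))``.
    ``indices`` restricts evaluation to a subset of time indices (a sampling
    schedule); by default the full grid is used.
    """
    grid.column(l)
    j = grid.validate_width(j)
    k = grid.times if indices is None else np.asarray(indices)
    rate = (2j * np.pi * l - 2.0 * np.pi * j * grid.gamma_unit) / grid.size
    return np.exp(rate * k)


def peaks_to_spectrum(
    grid: GridSpec, peaks: Iterable[LorentzianComponent] | Sequence[LorentzianComponent]
) -> np.ndarray:
    """Superpose atoms: ``f_hat = sum_p b_p * L_{l_p}^{j_p}``."""
    out = np.zeros(grid.size, dtype=complex)
    for peak in peaks:
        peak.validate(grid)
        out += complex(peak.amplitude) * lorentzian_atom(grid, peak.center, peak.width_index)
    return out


def spectrum_to_time(grid: GridSpec, spectrum: np.ndarray) -> np.ndarray:
    """Apply the synthesis transform ``S`` to a frequency-domain vector."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape != (grid.size,):
        raise ValueError(
            f"spectrum length {spectrum.shape} does not match grid size {grid.size}"
        )
    return synthesis_matrix(grid) @ spectrum


def time_to_spectrum(grid: GridSpec, signal: np.ndarray) -> np.ndarray:
    """Apply the analysis transform ``T = S^{-1}`` to a time-domain vector."""
    signal = np.asarray(signal)
    if signal.shape != (grid.size,):
        raise ValueError(
            f"signal length {signal.shape} does not match grid size {grid.size}"
        )
    return analysis_matrix(grid) @ signal
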