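"""Greedy sparse solvers: OMP and Lorentzian peak matching pursuit (LPMP).

Both solvers explain a non-uniformly sampled FID ``y`` (values at a subset
``K`` of the time grid) greedily, one dictionary element per iteration,
refitting all amplitudes jointly by least squares after every selection.

* :func:`omp_reconstruct` uses the plain Fourier dictionary — its atoms are
  frequency impulses, i.e. the columns of the restricted synthesis matrix.
* :func:`lpmp_reconstruct` matches one *Lorentzian peak* per iteration: the
  center is picked by the same matched-filter argmax as OMP, then the width
  index ``j in [0, J]`` is searched exhaustively, refitting all amplitudes
  jointly for each candidate width.  A committed width is never revisited;
  amplitudes of earlier peaks may change on every later iteration.

Stopping is governed by a :class:`StoppingRule` (absolute residual
threshold, relative improvement factor ``alpha``, or noise amplitude
``sigma``), always backed by an iteration cap of at most ``m`` matched
peaks — beyond that the joint least-squares system cannot be
overdetermined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .dictionary import (
    GridSpec,
    LorentzianComponent,
    lorentzian_atom,
    atom_peak_height,
    peaks_to_spectrum,
    synthesis_matrix,
)

__all__ = [
    "Schedule",
    "Measurement",
    "Mask",
    "StoppingRule",
    "Reconstruction",
    "SingularSystemError",
    "CenterExhaustedError",
    "measurement_operator",
    "select_center",
    "fit_coefficients",
    "select_width",
    "omp_reconstruct",
    "lpmp_reconstruct",
    "should_continue",
]

#: Condition-number threshold beyond which a least-squares system is
#: declared singular and the solver stops cleanly.
CONDITION_LIMIT = 1e12

#: Residuals at or below this fraction of ``||y||`` are treated as exact
#: zeros: every stopping rule terminates there, whatever its kind.
ZERO_RESIDUAL_RTOL = 1e-12


class SingularSystemError(np.linalg.LinAlgError):
    """Raised when the joint least-squares system is (numerically) rank deficient."""


class CenterExhaustedError(RuntimeError):
    """Raised when no admissible peak center remains to select."""


@dataclass(frozen=True)
class Schedule:
    """Sampling schedule ``K``: distinct time-grid indices in ``[0, 2N]``.

    Order is preserved as given (generated schedules are ascending);
    duplicates or out-of-range indices are rejected.
    """

    indices: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("schedule must contain at least one index")
        if np.unique(idx).size != idx.size:
            raise ValueError("schedule contains duplicate indices")
        if idx.min() < 0 or idx.max() >= self.grid.size:
            raise ValueError(
                f"schedule indices must lie in [0, {self.grid.size - 1}]"
            )
        idx.setflags(write=False)
        object.__setattr__(self, "indices", idx)

    @property
    def m(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class Measurement:
    """Observed complex samples ``y_i = f(t_{k_i})`` paired with their schedule."""

    y: np.ndarray
    schedule: Schedule

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=complex)
        if y.shape != (self.schedule.m,):
            raise ValueError(
                f"measurement length {y.shape} does not match schedule length "
                f"{self.schedule.m}"
            )
        y.setflags(write=False)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class Mask:
    """Admissible peak centers: a nonempty subset of ``[-N, N]``."""

    allowed: np.ndarray

    def __post_init__(self) -> None:
        allowed = np.unique(np.asarray(self.allowed, dtype=int))
        if allowed.size == 0:
            raise ValueError("mask must contain at least one admissible center")
        allowed.setflags(write=False)
        object.__setattr__(self, "allowed", allowed)

    def validate(self, grid: GridSpec) -> "Mask":
        if self.allowed.min() < -grid.N or self.allowed.max() > grid.N:
            raise ValueError(
                f"mask indices must lie within [-{grid.N}, {grid.N}]"
            )
        return self

    @classmethod
    def full(cls, grid: GridSpec) -> "Mask":
        return cls(grid.frequencies)

    @classmethod
    def around_centers(
        cls, grid: GridSpec, centers: Iterable[float], halfwidth: int = 5
    ) -> "Mask":
        """Union of windows of ``+-halfwidth`` grid points around each center.

        Centers may be off-grid reals; each is rounded to the nearest grid
        index first.  Windows are clipped to the grid.
        """
        allowed: set[int] = set()
        for c in centers:
            c0 = int(round(c))
            lo = max(-grid.N, c0 - halfwidth)
            hi = min(grid.N, c0 + halfwidth)
            allowed.update(range(lo, hi + 1))
        return cls(np.array(sorted(allowed)))


@dataclass(frozen=True)
class StoppingRule:
    """Stopping criterion for the greedy loop.

    Exactly one of the three kinds is active:

    ``epsilon``
        stop as soon as ``||y - A f_hat||_2 < epsilon``;
    ``relative``
        continue only while the newest iteration shrank the residual to at
        most ``alpha`` times the previous one (first iteration always runs);
    ``noise``
        stop once the newest matched peak's spectral height (modulus of its
        amplitude times the atom's center value) falls to at most ``sigma``.

    ``max_iter`` is always enforced in addition and is silently capped at the
    number of measurements ``m`` (and the grid size) at solve time.
    """

    kind: Literal["epsilon", "relative", "noise"]
    epsilon: Optional[float] = None
    alpha: Optional[float] = None
    sigma: Optional[float] = None
    max_iter: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "epsilon":
            if self.epsilon is None or self.epsilon < 0:
                raise ValueError("epsilon rule requires epsilon >= 0")
        elif self.kind == "relative":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("relative rule requires alpha in [0, 1]")
        elif self.kind == "noise":
            if self.sigma is None or self.sigma < 0:
                raise ValueError("noise rule requires sigma >= 0")
        else:
            raise ValueError(f"unknown stopping rule kind {self.kind!r}")
        if self.max_iter is not None and self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")

    @classmethod
    def epsilon_rule(cls, epsilon: float, max_iter: int | None = None) -> "StoppingRule":
        return cls(kind="epsilon", epsilon=epsilon, max_iter=max_iter)

    @classmethod
    def relative_rule(cls, alpha: float = 0.98, max_iter: int | None = None) -> "StoppingRule":
        return cls(kind="relative", alpha=alpha, max_iter=max_iter)

    @classmethod
    def noise_rule(cls, sigma: float, max_iter: int | None = None) -> "StoppingRule":
        return cls(kind="noise", sigma=sigma, max_iter=max_iter)

    def effective_max_iter(self, m: int, grid_size: int) -> int:
        cap = min(m, grid_size)
        if self.max_iter is not None:
            cap = min(cap, self.max_iter)
        return cap


@dataclass
class Reconstruction:
    """Result of a greedy reconstruction.

    Attributes
    ----------
    peaks : list of LorentzianComponent
        One per completed iteration, in selection order, with the final
        jointly refitted amplitudes.  OMP peaks carry ``width_index = 0``.
    spectrum : ndarray
        Dense frequency-domain estimate (length ``2N + 1``).
    residual_norms : ndarray
        ``||y - A f_hat||_2`` after each completed iteration, preceded by the
        initial ``||y||_2``; non-increasing.
    stop_reason : str
        One of ``threshold``, ``relative``, ``noise``, ``max_iter``,
        ``singular``, ``exhausted``.
    """

    peaks: list[LorentzianComponent]
    spectrum: np.ndarray
    residual_norms: np.ndarray
    stop_reason: str
    grid: GridSpec

    @property
    def n_iterations(self) -> int:
        return len(self.peaks)

    @property
    def support(self) -> list[int]:
        """Selected centers in selection order."""
        return [p.center for p in self.peaks]


def measurement_operator(schedule: Schedule) -> np.ndarray:
    """Rows of the frequency->time (synthesis) transform selected by ``K``.

    The resulting ``m x (2N+1)`` operator ``A`` maps a frequency-domain
    vector to its predicted time samples on the schedule:
    ``A @ lorentzian_atom(grid, l, j)`` equals the atom's damped oscillation
    restricted to the sampled indices.
    """
    return synthesis_matrix(schedule.grid)[schedule.indices, :]


def select_center(
    A: np.ndarray, residual: np.ndarray, allowed: np.ndarray | Mask
) -> int:
    """Matched-filter selection: the admissible ``l`` maximizing ``|(A* r)_l|``.

    Ties are broken toward the smallest frequency index.  ``allowed`` holds
    the admissible signed indices (a mask already excluding used centers).
    """
    if isinstance(allowed, Mask):
        allowed = allowed.allowed
    allowed = np.asarray(allowed, dtype=int)
    if allowed.size == 0:
        raise CenterExhaustedError("no admissible peak centers remain")
    M = A.shape[1]
    N = (M - 1) // 2
    corr = A.conj().T @ residual
    vals = np.abs(corr[allowed + N])
    # allowed is ascending, argmax returns the first maximum -> smallest index
    return int(allowed[int(np.argmax(vals))])


def _lstsq_checked(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with a rank/condition guard.

    Returns the coefficient vector and the residual 2-norm; raises
    :class:`SingularSystemError` when the column set is numerically rank
    deficient (condition number above ``CONDITION_LIMIT``).
    """
    if B.shape[1] > B.shape[0]:
        raise SingularSystemError(
            f"{B.shape[1]} columns exceed {B.shape[0]} measurements"
        )
    coeffs, _, rank, sv = np.linalg.lstsq(B, y, rcond=None)
    if rank < B.shape[1] or sv[-1] == 0 or sv[0] / sv[-1] > CONDITION_LIMIT:
        raise SingularSystemError("least-squares column set is rank deficient")
    residual = y - B @ coeffs
    return coeffs, float(np.linalg.norm(residual))


def fit_coefficients(
    A: np.ndarray, atoms: Sequence[np.ndarray], y: np.ndarray
) -> np.ndarray:
    """Jointly fit complex amplitudes of ``atoms`` to ``y`` by least squares.

    Columns of the design matrix are ``A @ atom`` for each frequency-domain
    atom; the solution is unique whenever the columns are independent.
    """
    if len(atoms) == 0:
        return np.zeros(0, dtype=complex)
    B = np.column_stack([A @ np.asarray(a, dtype=complex) for a in atoms])
    coeffs, _ = _lstsq_checked(B, y)
    return coeffs


def select_width(
    A: np.ndarray,
    fixed: Sequence[LorentzianComponent],
    center: int,
    grid: GridSpec,
    y: np.ndarray,
) -> tuple[int, np.ndarray]:
    """Exhaustive width search for a new peak at ``center``.

    For every candidate ``j in [0, J]`` the amplitudes of all peaks — the
    committed ``fixed`` ones plus the candidate — are refitted jointly and
    the residual norm evaluated; the ``j`` with the smallest residual wins,
    ties going to the smallest ``j``.  Returns ``(j, coefficients)`` with the
    candidate's coefficient last.  A singular candidate system (the matrix
    inversion at the heart of the refit has broken down) propagates as
    :class:`SingularSystemError`; the caller stops cleanly.
    """
    fixed_cols = [
        A @ lorentzian_atom(grid, p.center, p.width_index) for p in fixed
    ]
    best: tuple[float, int, np.ndarray] | None = None
    for j in range(grid.J + 1):
        cols = fixed_cols + [A @ lorentzian_atom(grid, center, j)]
        coeffs, resid = _lstsq_checked(np.column_stack(cols), y)
        if best is None or resid < best[0]:
            best = (resid, j, coeffs)
    assert best is not None
    return best[1], best[2]


def _stop_reason(
    residual_norms: Sequence[float],
    rule: StoppingRule,
    max_iter: int,
    last_peak_height: float | None,
) -> Optional[str]:
    """Reason to stop before the next iteration, or None to continue."""
    norms = list(residual_norms)
    completed = len(norms) - 1
    # machine-zero guard: nothing left to explain under any rule
    if norms[-1] <= ZERO_RESIDUAL_RTOL * norms[0]:
        return "threshold"
    if rule.kind == "epsilon" and norms[-1] < rule.epsilon:
        return "threshold"
    if rule.kind == "relative" and completed >= 1:
        if norms[-1] > rule.alpha * norms[-2]:
            return "relative"
    if rule.kind == "noise" and last_peak_height is not None:
        if last_peak_height <= rule.sigma:
            return "noise"
    if completed >= max_iter:
        return "max_iter"
    return None


def should_continue(
    residual_norms: Sequence[float],
    rule: StoppingRule,
    *,
    m: int | None = None,
    grid_size: int | None = None,
    last_peak_height: float | None = None,
) -> bool:
    """Whether the greedy loop should run another iteration.

    ``residual_norms`` starts with the initial ``||y||_2``.  The epsilon rule
    continues while the last norm is at least ``epsilon``; the relative rule
    continues while the last completed iteration improved the residual by at
    least the factor ``alpha`` (the first iteration always runs); the noise
    rule stops once the newest peak's spectral height is at most ``sigma``.
    ``max_iter`` (capped at ``m``) is always enforced.
    """
    if len(residual_norms) == 0:
        raise ValueError("residual_norms must contain the initial ||y||")
    cap_m = m if m is not None else len(residual_norms)  # completed + margin
    cap_g = grid_size if grid_size is not None else cap_m
    max_iter = rule.effective_max_iter(cap_m, cap_g) if m is not None else (
        rule.max_iter if rule.max_iter is not None else math.inf
    )
    return _stop_reason(residual_norms, rule, max_iter, last_peak_height) is None


def omp_reconstruct(
    A: np.ndarray, y: np.ndarray, rule: StoppingRule
) -> Reconstruction:
    """Orthogonal matching pursuit over the restricted Fourier dictionary.

    One frequency impulse is selected per iteration by the matched-filter
    argmax (already-selected columns excluded), after which all coefficients
    are refitted jointly.  Returns a :class:`Reconstruction` whose spectrum
    is the sparse coefficient vector on the frequency grid and whose peaks
    carry ``width_index = 0``.
    """
    y = np.asarray(y, dtype=complex)
    m, M = A.shape
    N = (M - 1) // 2
    grid = GridSpec(N=N) if N >= 1 else None
    max_iter = rule.effective_max_iter(m, M)

    norms: list[float] = [float(np.linalg.norm(y))]
    support: list[int] = []
    coeffs = np.zeros(0, dtype=complex)
    residual = y.copy()
    last_height: float | None = None

    while True:
        reason = _stop_reason(norms, rule, max_iter, last_height)
        if reason is not None:
            break
        remaining = np.setdiff1d(np.arange(-N, N + 1), support)
        if remaining.size == 0:
            reason = "exhausted"
            break
        l = select_center(A, residual, remaining)
        cols = A[:, [s + N for s in support] + [l + N]]
        try:
            new_coeffs, resid_norm = _lstsq_checked(cols, y)
        except SingularSystemError:
            reason = "singular"
            break
        support.append(l)
        coeffs = new_coeffs
        residual = y - cols @ coeffs
        norms.append(resid_norm)
        last_height = float(abs(coeffs[-1]))

    spectrum = np.zeros(M, dtype=complex)
    for l, b in zip(support, coeffs):
        spectrum[l + N] = b
    peaks = [
        LorentzianComponent(center=l, width_index=0, amplitude=complex(b))
        for l, b in zip(support, coeffs)
    ]
    return Reconstruction(
        peaks=peaks,
        spectrum=spectrum,
        residual_norms=np.asarray(norms),
        stop_reason=reason,
        grid=grid if grid is not None else GridSpec(N=max(N, 1)),
    )


def lpmp_reconstruct(
    measurement: Measurement,
    grid: GridSpec,
    rule: StoppingRule,
    mask: Mask | None = None,
) -> Reconstruction:
    """Lorentzian peak matching pursuit, optionally restricted by a mask.

    Each iteration (i) picks the admissible center maximizing the
    matched-filter correlation with the current residual, excluding centers
    already matched, (ii) searches the width index ``j in [0, J]``
    exhaustively with a joint least-squares refit of all amplitudes per
    candidate, and (iii) commits the best width — widths never change in
    later iterations, amplitudes always may.  With ``mask=None`` the full
    frequency grid is admissible; a full mask reproduces the unmasked run
    exactly (identical code path).
    """
    y = measurement.y
    schedule = measurement.schedule
    if schedule.grid != grid:
        raise ValueError("measurement schedule was built on a different grid")
    if mask is not None:
        mask.validate(grid)
    admissible = (mask.allowed if mask is not None else grid.frequencies)

    A = measurement_operator(schedule)
    max_iter = rule.effective_max_iter(schedule.m, grid.size)

    norms: list[float] = [float(np.linalg.norm(y))]
    peaks: list[LorentzianComponent] = []
    coeffs = np.zeros(0, dtype=complex)
    residual = y.copy()
    last_height: float | None = None

    while True:
        reason = _stop_reason(norms, rule, max_iter, last_height)
        if reason is not None:
            break
        used = [p.center for p in peaks]
        remaining = np.setdiff1d(admissible, used)
        if remaining.size == 0:
            reason = "exhausted"
            break
        l = select_center(A, residual, remaining)
        try:
            j, new_coeffs = select_width(A, peaks, l, grid, y)
        except SingularSystemError:
            reason = "singular"
            break
        peaks = [
            LorentzianComponent(p.center, p.width_index, complex(b))
            for p, b in zip(peaks, new_coeffs[:-1])
        ]
        peaks.append(LorentzianComponent(l, j, complex(new_coeffs[-1])))
        coeffs = new_coeffs
        cols = np.column_stack(
            [A @ lorentzian_atom(grid, p.center, p.width_index) for p in peaks]
        )
        residual = y - cols @ coeffs
        norms.append(float(np.linalg.norm(residual)))
        last_height = float(abs(coeffs[-1])) * atom_peak_height(grid, j)

    spectrum = peaks_to_spectrum(grid, peaks)
    return Reconstruction(
        peaks=peaks,
        spectrum=spectrum,
        residual_norms=np.asarray(norms),
        stop_reason=reason,
        grid=grid,
    )
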