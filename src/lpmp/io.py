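"""Plain-text readers and writers for signals, spectra, peaks, schedules, masks.

All formats are tab-separated text with ``#``-prefixed header lines:

* time-signal / spectrum files: ``index  re  im`` — indices are 0-based time
  steps for time files and signed frequency indices for spectrum files;
* peak lists: ``center  width_index  amp_re  amp_im`` (integer grid peaks)
  or ``frequency  damping  amp_re  amp_im`` (continuous, off-grid peaks);
* schedules: one integer time-grid index per line (nuslist style), file
  order preserved, duplicates dropped with a warning;
* masks: one signed frequency index per line, or inclusive ranges ``a:b``;
* residual history: ``iteration  residual_norm``.

Values are written with 17 significant digits, so write -> read round trips
are lossless at double precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .dictionary import GridSpec, LorentzianComponent
from .simulate import ContinuousPeak, SimulationConfig
from .solvers import Mask, Measurement, Schedule

__all__ = [
    "FileFormatError",
    "read_signal",
    "write_signal",
    "read_spectrum",
    "write_spectrum",
    "read_measurement",
    "read_schedule",
    "write_schedule",
    "read_mask",
    "write_mask",
    "read_peaks",
    "write_peaks",
    "read_continuous_peaks",
    "write_continuous_peaks",
    "write_residuals",
    "read_sim_config",
    "write_sim_config",
]

logger = logging.getLogger(__name__)

_FMT = "%.17g"


class FileFormatError(ValueError):
    """A text input file does not match its format contract."""


def _data_lines(path: Path) -> list[tuple[int, list[str]]]:
    """Non-comment, non-blank lines of ``path`` as (1-based lineno, fields)."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            out.append((lineno, stripped.split()))
    return out


def _parse(path: Path, lineno: int, token: str, kind) -> float | int:
    try:
        return kind(token)
    except ValueError:
        raise FileFormatError(
            f"{path}:{lineno}: cannot parse {token!r} as {kind.__name__}"
        ) from None


def _read_indexed_complex(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    rows = _data_lines(path)
    if not rows:
        raise FileFormatError(f"{path}: no data rows found")
    indices, values = [], []
    for lineno, fields in rows:
        if len(fields) != 3:
            raise FileFormatError(
                f"{path}:{lineno}: expected 3 columns (index re im), got {len(fields)}"
            )
        idx = _parse(path, lineno, fields[0], int)
        re = _parse(path, lineno, fields[1], float)
        im = _parse(path, lineno, fields[2], float)
        indices.append(idx)
        values.append(complex(re, im))
    return np.asarray(indices, dtype=int), np.asarray(values, dtype=complex)


def _write_indexed_complex(path, indices, values, header: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        for idx, val in zip(indices, values):
            fh.write(f"{int(idx)}\t{_FMT % val.real}\t{_FMT % val.imag}\n")


def read_signal(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a time-signal file -> (time indices, complex values)."""
    indices, values = _read_indexed_complex(path)
    if indices.min() < 0:
        raise FileFormatError(f"{path}: time indices must be >= 0")
    return indices, values


def write_signal(path, values: np.ndarray, indices: np.ndarray | None = None) -> None:
    values = np.asarray(values, dtype=complex)
    if indices is None:
        indices = np.arange(values.size)
    _write_indexed_complex(path, indices, values, "time_index\tre\tim")


def read_spectrum(path, grid: GridSpec | None = None) -> np.ndarray:
    """Read a spectrum file -> dense complex vector ordered ``l = -N ... N``.

    The file must cover every frequency index of the grid exactly once; if
    ``grid`` is omitted it is inferred from the index range.
    """
    indices, values = _read_indexed_complex(path)
    if grid is None:
        N = int(np.max(np.abs(indices)))
        grid = GridSpec(N=max(N, 1))
    expected = grid.frequencies
    order = np.argsort(indices)
    if not np.array_equal(indices[order], expected):
        raise FileFormatError(
            f"{path}: spectrum must cover every index in [-{grid.N}, {grid.N}] exactly once"
        )
    return values[order]


def write_spectrum(path, grid: GridSpec, values: np.ndarray) -> None:
    values = np.asarray(values, dtype=complex)
    if values.shape != (grid.size,):
        raise ValueError("spectrum length does not match grid size")
    _write_indexed_complex(path, grid.frequencies, values, "frequency_index\tre\tim")


def read_measurement(path, grid: GridSpec) -> Measurement:
    """Read a sampled-signal file (subset of time rows) as a Measurement.

    Row indices are the sampled time-grid indices; file order is preserved.
    """
    indices, values = read_signal(path)
    schedule = Schedule(indices=indices, grid=grid)
    return Measurement(y=values, schedule=schedule)


def read_schedule(path, grid: GridSpec) -> Schedule:
    """Read a nuslist-style schedule; duplicates dropped with a warning."""
    path = Path(path)
    rows = _data_lines(path)
    if not rows:
        raise FileFormatError(f"{path}: no schedule entries found")
    seen: set[int] = set()
    indices: list[int] = []
    for lineno, fields in rows:
        if len(fields) != 1:
            raise FileFormatError(
                f"{path}:{lineno}: expected one index per line, got {len(fields)} fields"
            )
        k = _parse(path, lineno, fields[0], int)
        if not 0 <= k < grid.size:
            raise FileFormatError(
                f"{path}:{lineno}: index {k} outside time grid [0, {grid.size - 1}]"
            )
        if k in seen:
            logger.warning("%s:%d: duplicate schedule index %d dropped", path, lineno, k)
            continue
        seen.add(k)
        indices.append(k)
    return Schedule(indices=np.asarray(indices, dtype=int), grid=grid)


def write_schedule(path, schedule: Schedule) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# time_index\n")
        for k in schedule.indices:
            fh.write(f"{int(k)}\n")


def read_mask(path, grid: GridSpec) -> Mask:
    """Read a mask file: single indices or inclusive ranges ``a:b``."""
    path = Path(path)
    rows = _data_lines(path)
    if not rows:
        raise FileFormatError(f"{path}: no mask entries found")
    allowed: set[int] = set()
    for lineno, fields in rows:
        for token in fields:
            if ":" in token:
                parts = token.split(":")
                if len(parts) != 2:
                    raise FileFormatError(
                        f"{path}:{lineno}: malformed range {token!r}"
                    )
                a = _parse(path, lineno, parts[0], int)
                b = _parse(path, lineno, parts[1], int)
                if a > b:
                    raise FileFormatError(
                        f"{path}:{lineno}: empty range {token!r}"
                    )
                allowed.update(range(a, b + 1))
            else:
                allowed.add(_parse(path, lineno, token, int))
    mask = Mask(np.array(sorted(allowed)))
    try:
        mask.validate(grid)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from None
    return mask


def write_mask(path, mask: Mask) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# frequency_index (or a:b ranges)\n")
        for l in mask.allowed:
            fh.write(f"{int(l)}\n")


def read_peaks(path, grid: GridSpec) -> list[LorentzianComponent]:
    """Read an on-grid peak list ``center width_index amp_re amp_im``."""
    path = Path(path)
    rows = _data_lines(path)
    peaks = []
    for lineno, fields in rows:
        if len(fields) != 4:
            raise FileFormatError(
                f"{path}:{lineno}: expected 4 columns "
                f"(center width_index amp_re amp_im), got {len(fields)}"
            )
        center = _parse(path, lineno, fields[0], int)
        width = _parse(path, lineno, fields[1], int)
        amp = complex(
            _parse(path, lineno, fields[2], float),
            _parse(path, lineno, fields[3], float),
        )
        try:
            peak = LorentzianComponent(center, width, amp).validate(grid)
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: {exc}") from None
        peaks.append(peak)
    return peaks


def write_peaks(path, peaks: Sequence[LorentzianComponent]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# center\twidth_index\tamp_re\tamp_im\n")
        for p in peaks:
            fh.write(
                f"{int(p.center)}\t{int(p.width_index)}\t"
                f"{_FMT % p.amplitude.real}\t{_FMT % p.amplitude.imag}\n"
            )


def read_continuous_peaks(path) -> list[ContinuousPeak]:
    """Read an off-grid peak list ``frequency damping amp_re amp_im``."""
    path = Path(path)
    rows = _data_lines(path)
    if not rows:
        raise FileFormatError(f"{path}: no peaks found")
    peaks = []
    for lineno, fields in rows:
        if len(fields) != 4:
            raise FileFormatError(
                f"{path}:{lineno}: expected 4 columns "
                f"(frequency damping amp_re amp_im), got {len(fields)}"
            )
        freq = _parse(path, lineno, fields[0], float)
        damping = _parse(path, lineno, fields[1], float)
        amp = complex(
            _parse(path, lineno, fields[2], float),
            _parse(path, lineno, fields[3], float),
        )
        try:
            peaks.append(ContinuousPeak(freq, damping, amp))
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_continuous_peaks(path, peaks: Sequence[ContinuousPeak]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# frequency\tdamping\tamp_re\tamp_im\n")
        for p in peaks:
            fh.write(
                f"{_FMT % p.frequency}\t{_FMT % p.damping}\t"
                f"{_FMT % p.amplitude.real}\t{_FMT % p.amplitude.imag}\n"
            )


def write_residuals(path, residual_norms: np.ndarray) -> None:
    """Write the residual history; iteration 0 is the initial ``||y||``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# iteration\tresidual_norm\n")
        for i, r in enumerate(residual_norms):
            fh.write(f"{i}\t{_FMT % r}\n")


def write_sim_config(path, config: SimulationConfig) -> None:
    """Serialise a simulation scenario to JSON."""
    payload = {
        "grid": {
            "N": config.grid.N,
            "gamma_unit": config.grid.gamma_unit,
            "J": config.grid.J,
        },
        "peaks": [
            {
                "frequency": p.frequency,
                "damping": p.damping,
                "amplitude": [p.amplitude.real, p.amplitude.imag],
            }
            for p in config.peaks
        ],
        "noise_fraction": config.noise_fraction,
        "n_samples": config.n_samples,
        "n_schedules": config.n_schedules,
        "seed": config.seed,
        "noise_normalization": config.noise_normalization,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_sim_config(path) -> SimulationConfig:
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"{path}: invalid JSON ({exc})") from None
    try:
        grid = GridSpec(**payload["grid"])
        peaks = tuple(
            ContinuousPeak(
                frequency=p["frequency"],
                damping=p["damping"],
                amplitude=complex(*p["amplitude"]),
            )
            for p in payload["peaks"]
        )
        return SimulationConfig(
            grid=grid,
            peaks=peaks,
            noise_fraction=payload.get("noise_fraction", 0.05),
            n_samples=payload.get("n_samples", 120),
            n_schedules=payload.get("n_schedules", 50),
            seed=payload.get("seed", 0),
            noise_normalization=payload.get("noise_normalization", "max"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FileFormatError(f"{path}: malformed config ({exc})") from None
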