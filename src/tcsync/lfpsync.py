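"""Instantaneous phase and the phase-locking value (PLV).

The synchrony statistic between two LFP channels x and y is

    PLV = | (1/T) * sum_t exp( i * (phi_x(t) - phi_y(t)) ) |

where phi is the argument of the analytic signal ``x + i H(x)`` (H the
FFT-based Hilbert transform).  PLV is 1 for perfectly phase-coupled signals
(any constant phase offset), and concentrates near ``sqrt(pi) / (2 sqrt(T))``
for independent phases.

Phases are extracted once per analysis epoch and then sliced into windows;
the first and last 5% of the epoch's samples are excluded from windowing to
guard against Hilbert end effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .recio import RecordingError, WindowSet, split_windows

#: minimum samples for a phase estimate
MIN_PHASE_SAMPLES = 64
#: minimum samples for a PLV estimate (50 ms at 500 Hz)
MIN_PLV_SAMPLES = 25
#: fraction of epoch samples dropped at each end before windowing
EDGE_GUARD_FRACTION = 0.05


class PhaseError(RecordingError):
    """Phase extraction or PLV preconditions violated."""


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel, wrapped to (-pi, pi]."""

    phases: np.ndarray
    fs: float
    source_channel: int | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if not np.all(np.isfinite(self.phases)):
            raise PhaseError("phases must be finite")


@dataclass
class PLVMatrix:
    """Symmetric pairwise PLV matrix over channels for one window."""

    values: np.ndarray
    window: tuple[float, float] | None = None
    channels: list[int] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise PhaseError("PLV matrix must be square")
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise PhaseError("PLV values must lie in [0, 1]")
        self.values = v


def analytic_phase(x: np.ndarray, fs: float, source_channel: int | None = None) -> PhaseSeries:
    """Instantaneous phase via the analytic signal ``x + i H(x)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise PhaseError("analytic_phase expects a single channel")
    if x.size < MIN_PHASE_SAMPLES:
        raise PhaseError(f"segment of {x.size} samples too short (need >= {MIN_PHASE_SAMPLES})")
    if np.ptp(x) == 0:
        raise PhaseError("constant segment: phase undefined")
    phi = np.angle(_signal.hilbert(x))
    phi = np.where(phi <= -np.pi, phi + 2 * np.pi, phi)  # wrap to (-pi, pi]
    return PhaseSeries(phases=phi, fs=fs, source_channel=source_channel)


def _phase_array(p: PhaseSeries | np.ndarray) -> np.ndarray:
    return p.phases if isinstance(p, PhaseSeries) else np.asarray(p, dtype=np.float64)


def plv(x_phase: PhaseSeries | np.ndarray, y_phase: PhaseSeries | np.ndarray) -> float:
    """Phase-locking value of two equal-length phase series."""
    px, py = _phase_array(x_phase), _phase_array(y_phase)
    if px.shape != py.shape:
        raise PhaseError("phase series lengths differ")
    if px.size < MIN_PLV_SAMPLES:
        raise PhaseError(f"need at least {MIN_PLV_SAMPLES} samples for PLV")
    val = np.abs(np.mean(np.exp(1j * (px - py))))
    return float(min(val, 1.0))


def plv_matrix(
    phases: np.ndarray,
    window: tuple[float, float] | None = None,
    channels: list[int] | None = None,
) -> PLVMatrix:
    """Pairwise PLV over all channel pairs of one window.

    ``phases`` is channels x samples.  Computed as ``|Z Z^H| / T`` with
    ``Z = exp(i phases)``; the result is bit-exactly symmetric and the
    diagonal is set to exactly 1.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=np.float64))
    n_ch, T = phases.shape
    if n_ch < 2:
        raise PhaseError("need at least 2 channels")
    if T < MIN_PLV_SAMPLES:
        raise PhaseError(f"need at least {MIN_PLV_SAMPLES} samples for PLV")
    z = np.exp(1j * phases)
    M = np.abs(z @ z.conj().T) / T
    M = np.minimum(M, 1.0)
    # mirror the upper triangle so symmetry is bit-exact regardless of the
    # matmul backend's per-entry summation order
    upper = np.triu(M, k=1)
    M = upper + upper.T
    np.fill_diagonal(M, 1.0)
    return PLVMatrix(values=M, window=window, channels=channels)


def epoch_phases(lfp: np.ndarray, fs: float) -> np.ndarray:
    """Per-channel instantaneous phase of a band-limited epoch (channels x samples)."""
    lfp = np.atleast_2d(np.asarray(lfp, dtype=np.float64))
    return np.vstack(
        [analytic_phase(lfp[c], fs, source_channel=c).phases for c in range(lfp.shape[0])]
    )


def pairwise_plv(
    lfp: np.ndarray,
    fs: float,
    win_length: float = 0.5,
    overlap_fraction: float = 0.5,
    edge_guard: float = EDGE_GUARD_FRACTION,
) -> tuple[list[PLVMatrix], WindowSet]:
    """Windowed pairwise PLV matrices for a band-limited multichannel epoch.

    Phase is extracted once over the whole epoch; the first and last
    ``edge_guard`` fraction of samples are excluded before windowing.
    Returns one :class:`PLVMatrix` per window plus the window set (times
    relative to the epoch start).
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=np.float64))
    phases = epoch_phases(lfp, fs)
    n = phases.shape[1]
    guard = int(np.floor(edge_guard * n))
    usable = phases[:, guard : n - guard] if guard else phases
    span = usable.shape[1] / fs
    wins = split_windows(span, win_length, overlap_fraction)
    t_off = guard / fs
    mats = []
    abs_windows = []
    for (s, e) in wins:
        a, b = int(round(s * fs)), int(round(s * fs)) + int(round(win_length * fs))
        mats.append(
            plv_matrix(
                usable[:, a:b],
                window=(s + t_off, e + t_off),
                channels=list(range(lfp.shape[0])),
            )
        )
        abs_windows.append((s + t_off, e + t_off))
    return mats, WindowSet(
        length=win_length, overlap_fraction=overlap_fraction, windows=abs_windows
    )


def write_plv_stack(mats: list[PLVMatrix], path) -> None:
    """Serialize windowed PLV matrices: flat binary stack + JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not mats:
        raise PhaseError("nothing to write")
    arr = np.ascontiguousarray(
        np.stack([m.values for m in mats]).astype("<f8")
    )
    (path / "plv.bin").write_bytes(arr.tobytes())
    (path / "plv.json").write_text(
        json.dumps(
            {
                "shape": list(arr.shape),
                "dtype": "<f8",
                "windows": [list(m.window) if m.window else None for m in mats],
                "channels": mats[0].channels,
            }
        )
    )


def read_plv_stack(path) -> list[PLVMatrix]:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "plv.json").read_text())
    arr = np.frombuffer((path / "plv.bin").read_bytes(), dtype=meta["dtype"]).reshape(
        meta["shape"]
    )
    return [
        PLVMatrix(
            values=arr[k].copy(),
            window=tuple(meta["windows"][k]) if meta["windows"][k] else None,
            channels=meta["channels"],
        )
        for k in range(arr.shape[0])
    ]


def plv_matrix_csv(m: PLVMatrix) -> str:
    """Single-matrix CSV export for inspection."""
    lines = [",".join(str(c) for c in (m.channels or range(m.values.shape[0])))]
    for row in m.values:
        lines.append(",".join(f"{v:.17g}" for v in row))
    return "\n".join(lines)


def plv_at_windows(
    phases: np.ndarray,
    fs: float,
    windows: list[tuple[float, float]],
) -> list[PLVMatrix]:
    """PLV matrices at explicitly given windows (seconds, epoch-relative).

    Used for evoked epochs, whose placement follows the stimulus schedule
    rather than a regular tiling.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=np.float64))
    n = phases.shape[1]
    mats = []
    for (s, e) in windows:
        a = int(round(s * fs))
        b = int(round(e * fs))
        if a < 0 or b > n:
            raise PhaseError(f"window [{s}, {e}) outside the epoch")
        mats.append(
            plv_matrix(
                phases[:, a:b], window=(s, e), channels=list(range(phases.shape[0]))
            )
        )
    return mats
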