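"""Recording data model and I/O.

A *recording* couples a multichannel LFP matrix (microvolts, fixed sampling
rate) with sorted spike trains, an optional tactile stimulus schedule and
session metadata (animal group, experimental condition).  This module also
implements the signal-conditioning and segmentation conventions used by the
rest of the pipeline:

* zero-phase band-limiting of the LFP (default 1-120 Hz) so that
  downstream instantaneous-phase estimates are undistorted,
* anti-aliased decimation to the analysis rate (0.5 kHz),
* 1-ms binary binning of spike timestamps,
* fixed-length overlapping analysis windows (50-1000 ms),
* rest-epoch trimming (drop the first and last minute) and 500-ms
  post-stimulus evoked epochs.

All times are seconds as 64-bit floats with t = 0 at recording start, and
every epoch/window is half-open ``[start, end)``: an event exactly at ``end``
belongs to the next interval.

Recordings round-trip losslessly through a plain-text/flat-binary bundle on
disk (``lfp.bin`` + JSON sidecars + TSV event tables), so bundles are
language-neutral and diff-able.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

#: fixed spike-binning resolution, seconds
BIN_WIDTH_S = 0.001
#: default zero-phase analysis band, Hz
DEFAULT_BAND_HZ = (1.0, 120.0)
#: duration of an evoked epoch after each stimulus pulse onset, seconds
EVOKED_EPOCH_S = 0.5
#: seconds trimmed from each end of a rest recording
REST_TRIM_S = 60.0

GROUPS = ("CR", "CCI")
CONDITIONS = ("rest", "tactile", "reac_rest", "reac_tactile")
REGIONS = ("VPL", "S1")


class RecordingError(ValueError):
    """A recording or bundle violates a structural invariant."""


class BundleFormatError(RecordingError):
    """An on-disk bundle is malformed (missing file, shape mismatch...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrain:
    """One sorted unit's timestamps with provenance labels.

    ``qc_status`` is one of ``pending``, ``accepted``, ``rejected_rate``,
    ``rejected_isi`` and is filled in by :mod:`tcsync.spikes`.
    """

    unit_id: str
    channel: int
    region: str
    timestamps: np.ndarray
    qc_status: str = "pending"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.timestamps.ndim != 1:
            raise RecordingError(f"unit {self.unit_id}: timestamps must be 1-D")
        if self.timestamps.size:
            if np.any(~np.isfinite(self.timestamps)):
                raise RecordingError(f"unit {self.unit_id}: non-finite timestamp")
            if np.any(self.timestamps < 0):
                raise RecordingError(f"unit {self.unit_id}: negative timestamp")
            if np.any(np.diff(self.timestamps) <= 0):
                raise RecordingError(
                    f"unit {self.unit_id}: timestamps not strictly increasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)


@dataclass
class StimulusSchedule:
    """Couplet tactile stimulation: pairs of fast 5-ms pressure pulses.

    First pulses are spaced 0.5 s apart; each second pulse trails its first
    by a uniform 150-250 ms delay.
    """

    first_pulse_times: np.ndarray
    second_pulse_times: np.ndarray
    pulse_width: float = 0.005

    def __post_init__(self) -> None:
        self.first_pulse_times = np.asarray(self.first_pulse_times, dtype=np.float64)
        self.second_pulse_times = np.asarray(self.second_pulse_times, dtype=np.float64)
        if self.first_pulse_times.shape != self.second_pulse_times.shape:
            raise RecordingError("couplet pulse arrays must have equal length")
        delay = self.second_pulse_times - self.first_pulse_times
        if delay.size and (np.any(delay < 0.150 - 1e-12) or np.any(delay > 0.250 + 1e-12)):
            raise RecordingError("second-pulse delays must lie in [0.150, 0.250] s")

    @property
    def n_couplets(self) -> int:
        return int(self.first_pulse_times.size)

    def all_pulse_times(self) -> np.ndarray:
        """Every pulse onset (first and second), sorted ascending."""
        return np.sort(
            np.concatenate([self.first_pulse_times, self.second_pulse_times])
        )


@dataclass
class BinarySpikeSequence:
    """0/1 vector at 1-ms resolution; bin b covers [t0 + b ms, t0 + (b+1) ms)."""

    bins: np.ndarray
    bin_width: float = BIN_WIDTH_S
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.uint8)
        if self.bins.size and not np.all((self.bins == 0) | (self.bins == 1)):
            raise RecordingError("binary sequence values must be 0 or 1")


@dataclass
class WindowSet:
    """Fixed-length overlapping analysis windows, half-open in seconds."""

    length: float
    overlap_fraction: float
    windows: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def shifted(self, offset: float) -> "WindowSet":
        return WindowSet(
            length=self.length,
            overlap_fraction=self.overlap_fraction,
            windows=[(s + offset, e + offset) for s, e in self.windows],
        )


@dataclass
class Recording:
    """One session: LFP matrix + spike trains + stimulus schedule + metadata."""

    lfp: np.ndarray
    fs_lfp: float
    spike_trains: list[SpikeTrain]
    schedule: StimulusSchedule | None
    channel_meta: list[dict]
    session_meta: dict

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=np.float64)
        self.validate()

    @property
    def n_channels(self) -> int:
        return int(self.lfp.shape[0])

    @property
    def duration(self) -> float:
        return float(self.session_meta["duration"])

    def validate(self) -> None:
        if self.lfp.ndim != 2:
            raise RecordingError("lfp must be channels x samples")
        if not np.all(np.isfinite(self.lfp)):
            raise RecordingError("lfp contains non-finite samples")
        if not self.fs_lfp > 0:
            raise RecordingError("fs_lfp must be positive")
        if len(self.channel_meta) != self.lfp.shape[0]:
            raise RecordingError(
                f"channel_meta length {len(self.channel_meta)} != "
                f"channel count {self.lfp.shape[0]}"
            )
        dur = float(self.session_meta.get("duration", self.lfp.shape[1] / self.fs_lfp))
        for tr in self.spike_trains:
            if tr.timestamps.size and tr.timestamps[-1] >= dur:
                raise RecordingError(
                    f"unit {tr.unit_id}: timestamp beyond recording duration"
                )


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------


def bandlimit_lfp(
    lfp: np.ndarray,
    fs: float,
    low: float = DEFAULT_BAND_HZ[0],
    high: float = DEFAULT_BAND_HZ[1],
) -> np.ndarray:
    """Zero-phase band-pass (order-4 Butterworth, forward-backward).

    Forward-backward application cancels the filter's phase response, so
    instantaneous phases extracted downstream are not shifted.  ``low == 0``
    degrades to a pure low-pass.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=np.float64))
    if not (0 <= low < high):
        raise RecordingError("need 0 <= low < high")
    if high >= fs / 2:
        raise RecordingError(f"high edge {high} Hz at or beyond Nyquist {fs / 2} Hz")
    if low == 0:
        sos = _signal.butter(4, high, btype="lowpass", fs=fs, output="sos")
    else:
        sos = _signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, lfp, axis=-1)


def downsample_lfp(lfp: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased decimation to ``fs_out`` (integer factor required)."""
    lfp = np.asarray(lfp, dtype=np.float64)
    if fs_out > fs_in:
        raise RecordingError("cannot downsample to a higher rate")
    if fs_out == fs_in:
        return lfp.copy()
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise RecordingError(f"fs_in/fs_out = {ratio} is not an integer factor")
    out = _signal.resample_poly(lfp, up=1, down=q, axis=-1)
    n_out = int(math.floor(lfp.shape[-1] * fs_out / fs_in))
    return out[..., :n_out]


# ---------------------------------------------------------------------------
# binning / epoching / windowing
# ---------------------------------------------------------------------------


def bin_spikes(train: SpikeTrain, epoch: tuple[float, float]) -> BinarySpikeSequence:
    """Binarize a spike train over ``[start, end)`` at 1-ms resolution.

    A bin is 1 iff at least one timestamp falls in it; two timestamps in the
    same millisecond collapse to a single 1 (logged, since a well-sorted unit
    with a refractory period should never produce them).
    """
    start, end = float(epoch[0]), float(epoch[1])
    if end <= start:
        raise RecordingError("epoch must have positive length")
    n_bins = int(math.ceil((end - start) / BIN_WIDTH_S - 1e-9))
    bins = np.zeros(n_bins, dtype=np.uint8)
    t = train.timestamps
    t = t[(t >= start) & (t < end)]
    if t.size:
        idx = np.floor((t - start) / BIN_WIDTH_S).astype(np.int64)
        idx = idx[idx < n_bins]
        if np.unique(idx).size < idx.size:
            logger.warning(
                "unit %s: %d spike(s) collapsed into occupied 1-ms bins",
                train.unit_id,
                idx.size - np.unique(idx).size,
            )
        bins[idx] = 1
    return BinarySpikeSequence(bins=bins, t0=start)


def split_windows(
    epoch_length: float, win_length: float, overlap_fraction: float = 0.5
) -> WindowSet:
    """Tile an epoch with fixed-length overlapping windows.

    Window k starts at ``k * win_length * (1 - overlap_fraction)``; the last
    window lies fully inside the epoch.  Window starts are relative to the
    epoch start (shift with :meth:`WindowSet.shifted` for absolute times).
    """
    if not (0.050 - 1e-12 <= win_length <= 1.000 + 1e-12):
        raise RecordingError("window length must lie in [0.050, 1.000] s")
    if not (0 <= overlap_fraction < 1):
        raise RecordingError("overlap fraction must lie in [0, 1)")
    if win_length > epoch_length + 1e-12:
        raise RecordingError("window longer than epoch")
    step = win_length * (1.0 - overlap_fraction)
    n = int(math.floor((epoch_length - win_length) / step + 1e-9)) + 1
    windows = [(k * step, k * step + win_length) for k in range(n)]
    return WindowSet(length=win_length, overlap_fraction=overlap_fraction, windows=windows)


def trim_rest_epoch(rec: Recording) -> tuple[float, float]:
    """Rest analysis epoch: drop the first and last minute of the session."""
    dur = rec.duration
    if dur < 2 * REST_TRIM_S + REST_TRIM_S:  # need >= 180 s
        raise RecordingError(f"recording of {dur} s too short to trim 60 s per end")
    return (REST_TRIM_S, dur - REST_TRIM_S)


def extract_evoked_epochs(rec: Recording) -> list[tuple[float, float]]:
    """One 500-ms epoch per stimulus pulse onset (first and second pulses).

    Epochs from a couplet's two pulses overlap whenever the intra-couplet
    delay is below 500 ms; both are kept as-is.
    """
    if rec.schedule is None or rec.schedule.n_couplets == 0:
        raise RecordingError("recording has no stimulus schedule")
    onsets = rec.schedule.all_pulse_times()
    return [(float(t), float(t) + EVOKED_EPOCH_S) for t in onsets]


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

_SPIKE_HEADER = "unit_id\tchannel\tregion\ttime_s"
_STIM_HEADER = "couplet_idx\tpulse_idx\ttime_s"


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording bundle: flat binary LFP + JSON/TSV sidecars.

    Floats are serialized with 17 significant digits, so ``read_recording``
    reconstructs the recording bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    arr = np.ascontiguousarray(rec.lfp, dtype="<f8")
    (path / "lfp.bin").write_bytes(arr.tobytes())
    (path / "lfp.json").write_text(
        json.dumps(
            {
                "shape": list(arr.shape),
                "dtype": "<f8",
                "order": "C",
                "fs": rec.fs_lfp,
                "units": "uV",
            },
            indent=1,
        )
    )

    lines = [_SPIKE_HEADER]
    for tr in rec.spike_trains:
        for t in tr.timestamps:
            lines.append(f"{tr.unit_id}\t{tr.channel}\t{tr.region}\t{t:.17g}")
    (path / "spikes.tsv").write_text("\n".join(lines) + "\n")

    lines = [_STIM_HEADER]
    if rec.schedule is not None:
        for i in range(rec.schedule.n_couplets):
            lines.append(f"{i}\t0\t{rec.schedule.first_pulse_times[i]:.17g}")
            lines.append(f"{i}\t1\t{rec.schedule.second_pulse_times[i]:.17g}")
    (path / "stimuli.tsv").write_text("\n".join(lines) + "\n")

    meta = {
        "session": rec.session_meta,
        "channels": rec.channel_meta,
        "units": [
            {
                "unit_id": tr.unit_id,
                "channel": tr.channel,
                "region": tr.region,
                "qc_status": tr.qc_status,
            }
            for tr in rec.spike_trains
        ],
        "pulse_width": rec.schedule.pulse_width if rec.schedule is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a bundle written by :func:`write_recording` (validating it)."""
    path = Path(path)
    for name in ("lfp.bin", "lfp.json", "spikes.tsv", "stimuli.tsv", "meta.json"):
        if not (path / name).exists():
            raise BundleFormatError(f"bundle missing {name}")

    sidecar = json.loads((path / "lfp.json").read_text())
    shape = tuple(sidecar["shape"])
    raw = np.frombuffer((path / "lfp.bin").read_bytes(), dtype=sidecar["dtype"])
    if raw.size != int(np.prod(shape)):
        raise BundleFormatError(
            f"lfp.bin holds {raw.size} samples but sidecar declares shape {shape}"
        )
    lfp = raw.reshape(shape).astype(np.float64)

    meta = json.loads((path / "meta.json").read_text())

    spikes_by_unit: dict[str, list[float]] = {}
    with open(path / "spikes.tsv") as fh:
        header = fh.readline().rstrip("\n")
        if header != _SPIKE_HEADER:
            raise BundleFormatError("spikes.tsv has an unexpected header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise BundleFormatError(f"malformed spikes.tsv row: {line!r}")
            spikes_by_unit.setdefault(parts[0], []).append(float(parts[3]))

    trains = []
    for u in meta["units"]:
        trains.append(
            SpikeTrain(
                unit_id=u["unit_id"],
                channel=int(u["channel"]),
                region=u["region"],
                timestamps=np.asarray(spikes_by_unit.get(u["unit_id"], []), dtype=np.float64),
                qc_status=u.get("qc_status", "pending"),
            )
        )

    firsts: dict[int, float] = {}
    seconds: dict[int, float] = {}
    with open(path / "stimuli.tsv") as fh:
        header = fh.readline().rstrip("\n")
        if header != _STIM_HEADER:
            raise BundleFormatError("stimuli.tsv has an unexpected header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise BundleFormatError(f"malformed stimuli.tsv row: {line!r}")
            idx, pulse, t = int(parts[0]), int(parts[1]), float(parts[2])
            (firsts if pulse == 0 else seconds)[idx] = t
    schedule = None
    if firsts:
        if set(firsts) != set(seconds):
            raise BundleFormatError("stimuli.tsv couplets missing a pulse")
        order = sorted(firsts)
        schedule = StimulusSchedule(
            first_pulse_times=np.asarray([firsts[i] for i in order]),
            second_pulse_times=np.asarray([seconds[i] for i in order]),
            pulse_width=meta.get("pulse_width") or 0.005,
        )

    return Recording(
        lfp=lfp,
        fs_lfp=float(sidecar["fs"]),
        spike_trains=trains,
        schedule=schedule,
        channel_meta=meta["channels"],
        session_meta=meta["session"],
    )


def recordings_equal(a: Recording, b: Recording) -> bool:
    """Bit-exact equality of two recordings (round-trip contract)."""
    if a.fs_lfp != b.fs_lfp or a.lfp.shape != b.lfp.shape:
        return False
    if not np.array_equal(a.lfp, b.lfp):
        return False
    if len(a.spike_trains) != len(b.spike_trains):
        return False
    for ta, tb in zip(a.spike_trains, b.spike_trains):
        if (ta.unit_id, ta.channel, ta.region, ta.qc_status) != (
            tb.unit_id,
            tb.channel,
            tb.region,
            tb.qc_status,
        ):
            return False
        if not np.array_equal(ta.timestamps, tb.timestamps):
            return False
    if (a.schedule is None) != (b.schedule is None):
        return False
    if a.schedule is not None:
        if not np.array_equal(a.schedule.first_pulse_times, b.schedule.first_pulse_times):
            return False
        if not np.array_equal(
            a.schedule.second_pulse_times, b.schedule.second_pulse_times
        ):
            return False
    return a.channel_meta == b.channel_meta and a.session_meta == b.session_meta
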