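"""Synthetic thalamocortical recordings with known ground truth.

The generator emulates the statistical structure the analysis chain assumes:

* LFP sources are stochastic Kuramoto oscillators — one per electrode of two
  3x3 matrices (thalamic VPL and cortical S1) — integrated by Euler-Maruyama:

      dphi_i = omega_i dt + sum_j K_ij sin(phi_j - phi_i) dt + sigma dW_i

  The observed LFP is a cosine readout with additive Gaussian noise,
  ``x_i(t) = A_i cos(phi_i(t)) + eps_i(t)``.  Pairwise phase-locking is
  therefore controlled directly by the coupling matrix K, which makes
  parameter recovery through the analysis pipeline a well-posed test.

* Spike trains are inhomogeneous Poisson processes (thinning) with a 2-ms
  absolute refractory period.

* Tactile stimulation follows the couplet protocol: 5-ms pressure pulses,
  first pulses every 500 ms, second pulses trailing by U(150, 250) ms.

* Group/condition effects (control vs chronic-pain, rest / tactile /
  REAC-rest / REAC-tactile) are multiplicative presets on coupling and
  firing rates; REAC rate multipliers are 1.43 / 1.93 / 1.09 / 1.41 for
  CR-rest / CCI-rest / CR-tactile / CCI-tactile respectively.

One master seed spawns independent sub-streams (parameters, phase noise,
observation noise, spikes, schedule), so the same seed always yields a
bit-identical recording.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .recio import (
    CONDITIONS,
    EVOKED_EPOCH_S,
    GROUPS,
    Recording,
    SpikeTrain,
    StimulusSchedule,
)

#: absolute refractory period enforced on synthetic spike trains, seconds
REFRACTORY_S = 0.002

#: couplet first-pulse spacing, seconds
COUPLET_SPACING_S = 0.5
#: uniform range of the intra-couplet delay, seconds
COUPLET_DELAY_RANGE_S = (0.150, 0.250)
#: stimulus pulse width, seconds (metadata only)
PULSE_WIDTH_S = 0.005

_STREAMS = ("params", "phase", "obs", "spikes", "schedule")


class SynthError(ValueError):
    """Invalid synthesis configuration or arguments."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Free parameters of the generator.

    Array-valued fields left as ``None`` are resolved deterministically from
    ``seed`` in ``__post_init__``: natural frequencies uniform over
    ``natural_freq_range`` (default 10-14 Hz — a single analyzed rhythm
    band, so pairwise detuning stays comparable to the coupling and
    phase-locking lives in its sensitive mid-range), a block-structured
    coupling matrix (stronger within a region than between regions), and
    base firing rates U(8, 30) spikes/s (inside the 4-100 spikes/s
    unit-acceptance band).
    """

    n_channels_per_region: int = 9
    regions: tuple[str, ...] = ("VPL", "S1")
    duration: float = 600.0
    fs: float = 500.0
    natural_freqs: np.ndarray | None = None  # Hz per oscillator
    natural_freq_range: tuple[float, float] = (10.0, 14.0)  # Hz
    coupling: np.ndarray | None = None  # rad/s, symmetric, zero diagonal
    phase_noise_sd: float = 2.5  # rad / sqrt(s)
    amplitude: float = 50.0  # uV
    obs_noise_sd: float = 10.0  # uV
    base_rates: np.ndarray | None = None  # spikes/s per unit (1 unit/channel)
    base_rate_range: tuple[float, float] = (8.0, 30.0)  # spikes/s
    stim_rate_gain: float = 1.5  # rate gain inside evoked epochs
    evoked_coupling_gain: float = 1.0  # coupling gain inside evoked epochs
    within_coupling: float = 2.0  # rad/s, default block structure
    between_coupling: float = 1.0  # rad/s
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_channels
        rng = np.random.default_rng(self._stream_seed("params"))
        if self.natural_freqs is None:
            self.natural_freqs = rng.uniform(*self.natural_freq_range, size=n)
        else:
            rng.uniform(*self.natural_freq_range, size=n)  # keep stream alignment
        self.natural_freqs = np.asarray(self.natural_freqs, dtype=np.float64)
        if self.coupling is None:
            blocks = self.region_labels()
            same = np.equal.outer(blocks, blocks)
            K = np.where(same, self.within_coupling, self.between_coupling).astype(
                np.float64
            )
            np.fill_diagonal(K, 0.0)
            self.coupling = K
        else:
            self.coupling = np.asarray(self.coupling, dtype=np.float64)
        if self.base_rates is None:
            self.base_rates = rng.uniform(*self.base_rate_range, size=n)
        else:
            self.base_rates = np.asarray(self.base_rates, dtype=np.float64)
        self.validate()

    # -- derived ------------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.n_channels_per_region * len(self.regions)

    def region_labels(self) -> np.ndarray:
        """Region label per channel/oscillator, region blocks contiguous."""
        return np.asarray(
            [r for r in self.regions for _ in range(self.n_channels_per_region)]
        )

    def _stream_seed(self, name: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.seed), _STREAMS.index(name)])

    def stream_rng(self, name: str) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng(self._stream_seed(name))

    def validate(self) -> None:
        if self.duration <= 0:
            raise SynthError("duration must be positive")
        if self.n_channels_per_region < 1:
            raise SynthError("need at least one channel per region")
        for arr, name in (
            (self.natural_freqs, "natural_freqs"),
            (self.coupling, "coupling"),
            (self.base_rates, "base_rates"),
        ):
            if not np.all(np.isfinite(arr)):
                raise SynthError(f"{name} contains non-finite values")
        n = self.n_channels
        if self.natural_freqs.shape != (n,):
            raise SynthError("natural_freqs must have one entry per oscillator")
        if self.coupling.shape != (n, n):
            raise SynthError("coupling must be n x n")
        if not np.allclose(self.coupling, self.coupling.T):
            raise SynthError("coupling must be symmetric")
        if np.any(np.diag(self.coupling) != 0):
            raise SynthError("coupling diagonal must be zero")
        if np.any(self.coupling < 0):
            raise SynthError("coupling must be nonnegative")
        if not self.fs > 2 * float(np.max(self.natural_freqs)):
            raise SynthError("fs must exceed twice the fastest natural frequency")
        if np.any(self.base_rates < 0) or self.stim_rate_gain < 0:
            raise SynthError("rates and rate gains must be nonnegative")
        if self.phase_noise_sd < 0 or self.obs_noise_sd < 0:
            raise SynthError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class ConditionPreset:
    """Multiplicative group x condition effect: coupling, rate, evoked coupling."""

    group: str
    condition: str
    coupling_multiplier: float
    rate_multiplier: float
    evoked_coupling_multiplier: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SynthError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise SynthError(f"unknown condition {self.condition!r}")
        if min(
            self.coupling_multiplier,
            self.rate_multiplier,
            self.evoked_coupling_multiplier,
        ) <= 0:
            raise SynthError("preset multipliers must be positive")


@dataclass
class GroundTruth:
    """What the generator actually used — the recovery-test oracle."""

    coupling: np.ndarray
    block_labels: np.ndarray
    true_rates: np.ndarray


def default_preset_table() -> dict[tuple[str, str], ConditionPreset]:
    """Load the versioned preset table shipped with the package."""
    text = resources.files("tcsync.data").joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    table: dict[tuple[str, str], ConditionPreset] = {}
    for group, conds in raw["presets"].items():
        for condition, m in conds.items():
            table[(group, condition)] = ConditionPreset(
                group=group,
                condition=condition,
                coupling_multiplier=float(m["coupling"]),
                rate_multiplier=float(m["rate"]),
                evoked_coupling_multiplier=float(m["evoked_coupling"]),
            )
    missing = {(g, c) for g in GROUPS for c in CONDITIONS} - set(table)
    if missing:
        raise SynthError(f"preset table missing cells: {sorted(missing)}")
    return table


def apply_condition(config: SynthConfig, preset: ConditionPreset) -> SynthConfig:
    """New config with coupling/rates scaled by the preset.

    The evoked coupling gain is stored as the *ratio* of the evoked to the
    baseline coupling multiplier; it takes effect only inside evoked epochs.
    """
    if (preset.group, preset.condition) not in {
        (g, c) for g in GROUPS for c in CONDITIONS
    }:
        raise SynthError("preset outside the group x condition table")
    return dataclasses.replace(
        config,
        coupling=config.coupling * preset.coupling_multiplier,
        base_rates=config.base_rates * preset.rate_multiplier,
        evoked_coupling_gain=config.evoked_coupling_gain
        * preset.evoked_coupling_multiplier
        / preset.coupling_multiplier,
    )


# ---------------------------------------------------------------------------
# simulation primitives
# ---------------------------------------------------------------------------


def simulate_phases(
    config: SynthConfig,
    epoch: float | None = None,
    coupling_gain: np.ndarray | None = None,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Euler-Maruyama integration of the stochastic Kuramoto system.

    Parameters
    ----------
    epoch
        Length to simulate in seconds (default ``config.duration``).
    coupling_gain
        Optional per-sample scalar multiplying the whole coupling matrix
        (used to realize evoked synchrony boosts); length must equal the
        number of samples.
    dt
        Integration step; must not exceed ``1/fs``.  Defaults to ``1/fs``.

    Returns
    -------
    ndarray, shape (n_oscillators, n_samples)
        Unwrapped phase trajectories in radians.
    """
    config.validate()
    epoch = config.duration if epoch is None else float(epoch)
    if epoch <= 0:
        raise SynthError("epoch must be positive")
    if dt is None:
        dt = 1.0 / config.fs
    if dt > 1.0 / config.fs + 1e-12:
        raise SynthError("integration step must not exceed 1/fs")
    n_samples = int(round(epoch * config.fs))
    n = config.n_channels
    if coupling_gain is not None:
        coupling_gain = np.asarray(coupling_gain, dtype=np.float64)
        if coupling_gain.shape != (n_samples,):
            raise SynthError("coupling_gain must have one value per sample")
    if rng is None:
        rng = config.stream_rng("phase")

    omega = 2.0 * np.pi * config.natural_freqs
    K = config.coupling
    coupled = bool(np.any(K))
    sigma_dt = config.phase_noise_sd * np.sqrt(dt)

    phases = np.empty((n, n_samples), dtype=np.float64)
    phi = rng.uniform(-np.pi, np.pi, size=n)
    phases[:, 0] = phi
    if n_samples == 1:
        return phases
    if sigma_dt > 0:
        noise = sigma_dt * rng.standard_normal((n, n_samples - 1))
    else:
        noise = None
    drift0 = omega * dt
    for t in range(1, n_samples):
        step = drift0.copy()
        if coupled:
            pull = (K * np.sin(phi[np.newaxis, :] - phi[:, np.newaxis])).sum(axis=1)
            if coupling_gain is not None:
                pull *= coupling_gain[t - 1]
            step += pull * dt
        phi = phi + step
        if noise is not None:
            phi = phi + noise[:, t - 1]
        phases[:, t] = phi
    return phases


def synth_lfp(
    phases: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cosine readout with additive white observation noise (microvolts)."""
    phases = np.asarray(phases, dtype=np.float64)
    if not np.all(np.isfinite(phases)):
        raise SynthError("phases must be finite")
    if rng is None:
        rng = config.stream_rng("obs")
    amp = np.broadcast_to(
        np.atleast_1d(np.asarray(config.amplitude, dtype=np.float64)),
        (phases.shape[0],),
    )
    lfp = amp[:, None] * np.cos(phases)
    if config.obs_noise_sd > 0:
        lfp = lfp + config.obs_noise_sd * rng.standard_normal(phases.shape)
    return lfp


def synth_spikes(
    rate_profile: np.ndarray,
    duration: float,
    seed: int | np.random.Generator,
    refractory: float = REFRACTORY_S,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning, with refractory deletion.

    ``rate_profile`` gives the instantaneous rate (spikes/s) on a uniform
    grid over ``[0, duration)``.  After thinning, spikes closer than
    ``refractory`` to the previously kept spike are deleted.

    Returns sorted, strictly increasing timestamps in ``[0, duration)``.
    """
    rate = np.asarray(rate_profile, dtype=np.float64)
    if np.any(rate < 0) or not np.all(np.isfinite(rate)):
        raise SynthError("rate profile must be finite and nonnegative")
    if duration <= 0:
        raise SynthError("duration must be positive")
    rmax = float(rate.max(initial=0.0))
    if rmax == 0.0:
        return np.empty(0, dtype=np.float64)
    if rmax * refractory >= 1.0:
        raise SynthError("max rate x refractory >= 1: thinning invalid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_cand = rng.poisson(rmax * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum(
        (times / duration * rate.size).astype(np.int64), rate.size - 1
    )
    keep = rng.uniform(0.0, rmax, size=n_cand) < rate[idx]
    times = times[keep]

    if times.size and refractory > 0:
        kept = []
        last = -np.inf
        for t in times:
            if t - last >= refractory:
                kept.append(t)
                last = t
        times = np.asarray(kept, dtype=np.float64)
    return times


def synth_stimulus_schedule(
    duration: float, seed: int | np.random.Generator
) -> StimulusSchedule:
    """Couplet pulse schedule over ``[0, duration)``.

    First pulses every 500 ms starting at t = 0; each second pulse trails
    its first by a uniform 150-250 ms delay.
    """
    if duration < COUPLET_SPACING_S:
        raise SynthError("duration must be at least one couplet spacing (0.5 s)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(np.floor(duration / COUPLET_SPACING_S + 1e-9))
    first = COUPLET_SPACING_S * np.arange(n, dtype=np.float64)
    delays = rng.uniform(*COUPLET_DELAY_RANGE_S, size=n)
    return StimulusSchedule(
        first_pulse_times=first,
        second_pulse_times=first + delays,
        pulse_width=PULSE_WIDTH_S,
    )


# ---------------------------------------------------------------------------
# whole-recording assembly
# ---------------------------------------------------------------------------


def _evoked_gain_profile(
    schedule: StimulusSchedule | None,
    n_samples: int,
    fs: float,
    gain: float,
) -> np.ndarray | None:
    """Per-sample multiplier: ``gain`` inside evoked epochs, 1 elsewhere."""
    if schedule is None or gain == 1.0:
        return None
    g = np.ones(n_samples, dtype=np.float64)
    for onset in schedule.all_pulse_times():
        a = int(round(onset * fs))
        b = int(round((onset + EVOKED_EPOCH_S) * fs))
        g[a : min(b, n_samples)] = gain
    return g


def make_recording(
    config: SynthConfig,
    group: str = "CR",
    condition: str = "rest",
    preset_table: dict[tuple[str, str], ConditionPreset] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one full session for a group x condition cell.

    Applies the condition preset, simulates phases (with the evoked coupling
    boost inside stimulus epochs for tactile conditions), reads out the LFP,
    draws one Poisson unit per electrode (evoked rate gain applied the same
    way) and packages everything as a :class:`~tcsync.recio.Recording`.
    """
    if preset_table is None:
        preset_table = default_preset_table()
    preset = preset_table[(group, condition)]
    cfg = apply_condition(config, preset)

    n_samples = int(round(cfg.duration * cfg.fs))
    tactile = condition in ("tactile", "reac_tactile")
    schedule = (
        synth_stimulus_schedule(cfg.duration, cfg.stream_rng("schedule"))
        if tactile
        else None
    )

    gain = _evoked_gain_profile(schedule, n_samples, cfg.fs, cfg.evoked_coupling_gain)
    phases = simulate_phases(cfg, cfg.duration, coupling_gain=gain)
    lfp = synth_lfp(phases, cfg)

    regions = cfg.region_labels()
    spike_rng = cfg.stream_rng("spikes")
    rate_gain = _evoked_gain_profile(schedule, n_samples, cfg.fs, cfg.stim_rate_gain)
    trains = []
    for ch in range(cfg.n_channels):
        profile = np.full(n_samples, cfg.base_rates[ch])
        if rate_gain is not None:
            profile = profile * rate_gain
        ts = synth_spikes(profile, cfg.duration, spike_rng)
        ts = ts[ts < cfg.duration]
        trains.append(
            SpikeTrain(
                unit_id=f"u{ch:03d}",
                channel=ch,
                region=str(regions[ch]),
                timestamps=ts,
            )
        )

    side = int(np.ceil(np.sqrt(cfg.n_channels_per_region)))
    channel_meta = [
        {
            "channel": ch,
            "region": str(regions[ch]),
            "row": int((ch % cfg.n_channels_per_region) // side),
            "col": int((ch % cfg.n_channels_per_region) % side),
        }
        for ch in range(cfg.n_channels)
    ]
    rec = Recording(
        lfp=lfp,
        fs_lfp=cfg.fs,
        spike_trains=trains,
        schedule=schedule,
        channel_meta=channel_meta,
        session_meta={
            "group": group,
            "condition": condition,
            "duration": cfg.duration,
            "seed": cfg.seed,
        },
    )
    truth = GroundTruth(
        coupling=cfg.coupling.copy(),
        block_labels=regions,
        true_rates=cfg.base_rates.copy(),
    )
    return rec, truth
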