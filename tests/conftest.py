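import numpy as np
import pytest

from tcsync import recio, synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording():
    """2-channel, 1-s synthetic recording with a couplet schedule."""
    cfg = synthgen.SynthConfig(
        n_channels_per_region=1, duration=1.0, seed=7, obs_noise_sd=1.0
    )
    phases = synthgen.simulate_phases(cfg, 1.0)
    lfp = synthgen.synth_lfp(phases, cfg)
    schedule = synthgen.synth_stimulus_schedule(1.0, cfg.stream_rng("schedule"))
    trains = [
        recio.SpikeTrain("u000", 0, "VPL", np.array([0.1, 0.25, 0.6])),
        recio.SpikeTrain("u001", 1, "S1", np.array([0.05, 0.5, 0.95])),
    ]
    return recio.Recording(
        lfp=lfp,
        fs_lfp=cfg.fs,
        spike_trains=trains,
        schedule=schedule,
        channel_meta=[
            {"channel": 0, "region": "VPL", "row": 0, "col": 0},
            {"channel": 1, "region": "S1", "row": 0, "col": 0},
        ],
        session_meta={"group": "CR", "condition": "tactile", "duration": 1.0},
    )


def two_oscillator_config(K, seed, freq=12.0, noise=1.5, duration=30.0):
    """Two equal-frequency oscillators with symmetric coupling K (rad/s)."""
    return synthgen.SynthConfig(
        n_channels_per_region=1,
        regions=("VPL", "S1"),
        duration=duration,
        natural_freqs=np.array([freq, freq]),
        coupling=np.array([[0.0, K], [K, 0.0]]),
        phase_noise_sd=noise,
        obs_noise_sd=0.0,
        seed=seed,
    )
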