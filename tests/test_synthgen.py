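"""Generator contracts: Kuramoto limits, Poisson statistics, schedules, presets."""

import numpy as np
import pytest

from tcsync import lfpsync, recio, synthgen
from tcsync.synthgen import ConditionPreset, SynthConfig, SynthError

from conftest import two_oscillator_config


class TestSimulatePhases:
    def test_uncoupled_noiseless_is_linear_phase(self):
        cfg = SynthConfig(
            n_channels_per_region=2,
            duration=4.0,
            natural_freqs=np.array([10.0, 13.0, 17.0, 21.0]),
            coupling=np.zeros((4, 4)),
            phase_noise_sd=0.0,
            seed=3,
        )
        ph = synthgen.simulate_phases(cfg, 4.0)
        t = np.arange(ph.shape[1]) / cfg.fs
        expected = ph[:, [0]] + 2 * np.pi * cfg.natural_freqs[:, None] * t
        assert np.allclose(ph, expected, atol=1e-8)

    def test_strong_coupling_locks_to_plv_one(self):
        # sin(dphi) dynamics have a stable fixed point at dphi = 0 for equal
        # frequencies; with large K the signals become perfectly locked
        cfg = two_oscillator_config(K=50.0, seed=0, noise=0.0, duration=10.0)
        ph = synthgen.simulate_phases(cfg, 10.0)
        lfp = synthgen.synth_lfp(ph, cfg)
        p0 = lfpsync.analytic_phase(lfp[0], cfg.fs).phases
        p1 = lfpsync.analytic_phase(lfp[1], cfg.fs).phases
        mid = slice(500, -500)
        assert lfpsync.plv(p0[mid], p1[mid]) > 0.99

    def test_same_seed_identical(self):
        cfg = SynthConfig(n_channels_per_region=2, duration=2.0, seed=11)
        a = synthgen.simulate_phases(cfg, 2.0)
        b = synthgen.simulate_phases(cfg, 2.0)
        assert np.array_equal(a, b)

    def test_bad_step_rejected(self):
        cfg = SynthConfig(n_channels_per_region=1, duration=1.0, seed=0)
        with pytest.raises(SynthError):
            synthgen.simulate_phases(cfg, 1.0, dt=1.0)

    def test_output_shape(self):
        cfg = SynthConfig(n_channels_per_region=3, duration=2.0, seed=1)
        assert synthgen.simulate_phases(cfg, 2.0).shape == (6, 1000)


class TestSynthLfp:
    def test_noiseless_bounded_by_amplitude(self):
        cfg = SynthConfig(
            n_channels_per_region=1, duration=2.0, amplitude=1.0, obs_noise_sd=0.0, seed=2
        )
        ph = synthgen.simulate_phases(cfg, 2.0)
        assert np.max(np.abs(synthgen.synth_lfp(ph, cfg))) <= 1.0

    def test_phase_recovered_by_hilbert(self):
        cfg = two_oscillator_config(K=0.0, seed=5, noise=0.0, duration=10.0)
        ph = synthgen.simulate_phases(cfg, 10.0)
        lfp = synthgen.synth_lfp(ph, cfg)
        rec = lfpsync.analytic_phase(lfp[0], cfg.fs).phases
        wrapped = np.angle(np.exp(1j * ph[0]))
        mid = slice(len(rec) // 10, -len(rec) // 10)
        err = np.angle(np.exp(1j * (rec[mid] - wrapped[mid])))
        assert np.max(np.abs(err)) < 0.05

    def test_amplitude_scales_rms(self):
        cfg = SynthConfig(
            n_channels_per_region=1, duration=2.0, amplitude=1.0, obs_noise_sd=0.0, seed=2
        )
        ph = synthgen.simulate_phases(cfg, 2.0)
        x1 = synthgen.synth_lfp(ph, cfg)
        cfg2 = SynthConfig(
            n_channels_per_region=1, duration=2.0, amplitude=2.0, obs_noise_sd=0.0, seed=2
        )
        x2 = synthgen.synth_lfp(ph, cfg2)
        assert np.isclose(
            np.sqrt(np.mean(x2**2)), 2 * np.sqrt(np.mean(x1**2)), rtol=1e-12
        )


class TestSynthSpikes:
    def test_poisson_count_statistics(self):
        # pure Poisson check (refractory off): 20 spk/s for 100 s
        t = synthgen.synth_spikes(np.full(1000, 20.0), 100.0, seed=4, refractory=0.0)
        assert abs(t.size - 2000) <= 3 * np.sqrt(2000)
        assert np.all(np.diff(t) > 0) and t[0] >= 0 and t[-1] < 100.0

    def test_zero_rate_empty(self):
        assert synthgen.synth_spikes(np.zeros(100), 10.0, seed=0).size == 0

    def test_doubling_rate_doubles_counts(self):
        counts = {r: [] for r in (10.0, 20.0)}
        for s in range(100):
            for r in counts:
                counts[r].append(
                    synthgen.synth_spikes(np.full(50, r), 20.0, seed=s, refractory=0.0).size
                )
        ratio = np.mean(counts[20.0]) / np.mean(counts[10.0])
        assert abs(ratio - 2.0) < 0.1

    def test_refractory_enforced(self):
        t = synthgen.synth_spikes(np.full(100, 80.0), 50.0, seed=1)
        assert np.all(np.diff(t) >= synthgen.REFRACTORY_S - 1e-12)

    def test_invalid_thinning_rejected(self):
        with pytest.raises(SynthError):
            synthgen.synth_spikes(np.full(10, 600.0), 1.0, seed=0)


class TestStimulusSchedule:
    def test_couplet_counts_and_delays(self):
        sched = synthgen.synth_stimulus_schedule(10.0, seed=0)
        assert sched.n_couplets == 20
        assert sched.all_pulse_times().size == 40
        delays = sched.second_pulse_times - sched.first_pulse_times
        assert np.all((delays >= 0.150) & (delays <= 0.250))
        assert np.allclose(np.diff(sched.first_pulse_times), 0.5)

    def test_same_seed_identical(self):
        a = synthgen.synth_stimulus_schedule(30.0, seed=9)
        b = synthgen.synth_stimulus_schedule(30.0, seed=9)
        assert np.array_equal(a.second_pulse_times, b.second_pulse_times)

    def test_too_short_rejected(self):
        with pytest.raises(SynthError):
            synthgen.synth_stimulus_schedule(0.2, seed=0)


class TestPresets:
    def test_identity_preset_is_noop(self):
        cfg = SynthConfig(n_channels_per_region=2, duration=1.0, seed=0)
        out = synthgen.apply_condition(
            cfg, ConditionPreset("CR", "rest", 1.0, 1.0, 1.0)
        )
        assert np.array_equal(out.coupling, cfg.coupling)
        assert np.array_equal(out.base_rates, cfg.base_rates)
        assert out.evoked_coupling_gain == cfg.evoked_coupling_gain

    @pytest.mark.parametrize("group,mult", [("CR", 1.43), ("CCI", 1.93)])
    def test_reac_rest_rate_multipliers(self, group, mult):
        table = synthgen.default_preset_table()
        cfg = SynthConfig(n_channels_per_region=2, duration=1.0, seed=0)
        out = synthgen.apply_condition(cfg, table[(group, "reac_rest")])
        assert np.allclose(out.base_rates, cfg.base_rates * mult)

    def test_table_covers_all_cells(self):
        table = synthgen.default_preset_table()
        assert set(table) == {
            (g, c) for g in recio.GROUPS for c in recio.CONDITIONS
        }

    def test_invalid_preset_rejected(self):
        with pytest.raises(SynthError):
            ConditionPreset("XX", "rest", 1.0, 1.0, 1.0)
        with pytest.raises(SynthError):
            ConditionPreset("CR", "rest", 0.0, 1.0, 1.0)


class TestRecordingAssembly:
    def test_same_seed_bit_identical_recording(self):
        cfg = SynthConfig(n_channels_per_region=2, duration=5.0, seed=21)
        a, _ = synthgen.make_recording(cfg, "CR", "tactile")
        b, _ = synthgen.make_recording(cfg, "CR", "tactile")
        assert recio.recordings_equal(a, b)

    def test_ground_truth_matches_config(self):
        cfg = SynthConfig(n_channels_per_region=2, duration=2.0, seed=3)
        _, truth = synthgen.make_recording(cfg, "CCI", "rest")
        table = synthgen.default_preset_table()
        mult = table[("CCI", "rest")].coupling_multiplier
        assert np.allclose(truth.coupling, cfg.coupling * mult)
        assert truth.block_labels.shape == (4,)

    def test_rate_fidelity_constant_units(self):
        # realized rate within 5% of target over a long constant-rate train
        t = synthgen.synth_spikes(np.full(100, 20.0), 480.0, seed=8)
        assert abs(t.size / 480.0 - 20.0) / 20.0 < 0.05


def test_block_recovery_within_exceeds_between():
    """Block-diagonal coupling yields higher within- than between-block PLV."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = SynthConfig(
            n_channels_per_region=4,
            duration=30.0,
            within_coupling=6.0,
            between_coupling=0.2,
            seed=seed,
        )
        ph = synthgen.simulate_phases(cfg, 30.0)
        lfp = synthgen.synth_lfp(ph, cfg)
        mats, _ = lfpsync.pairwise_plv(lfp, cfg.fs)
        iu = np.triu_indices(cfg.n_channels, k=1)
        labels = cfg.region_labels()
        same = np.equal.outer(labels, labels)[iu]
        vals = np.stack([m.values[iu] for m in mats])
        if vals[:, same].mean() > vals[:, ~same].mean():
            hits += 1
    assert hits == n_seeds
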