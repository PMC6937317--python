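import numpy as np
import pytest
from scipy import signal as sps

from lfpbeta.beta import compute_channel_tfmap
from lfpbeta.simulate import (
    ConfigError,
    SimConfig,
    TrialTable,
    generate_learning_sequence,
    generate_session,
    inject_artifacts,
    _pink_noise,
)


class TestConfig:
    def test_defaults_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"fs": 150.0}, "fs"),
            ({"beta_freq": 30.0}, "beta_freq"),
            ({"trial_duration_range": (0.5, 2.5)}, "trial_duration_range"),
            ({"inter_trial_interval_min": 3.0}, "inter_trial_interval_min"),
            ({"burst_gain": -1.0}, "burst_gain"),
            ({"structures": ("OB", "OB")}, "unique"),
            ({"artifact_rate": 1.0, "fs": 400.0}, "500"),
            ({"coupled_pairs": {("OB", "XX"): (0.0, 0.0)}}, "XX"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, match):
        with pytest.raises(ConfigError, match=match):
            SimConfig(**kwargs).validate()

    def test_beta_above_nyquist_after_downsampling(self):
        # 17-28 Hz always below 100 Hz, but fs must keep it below fs/2
        with pytest.raises(ConfigError):
            SimConfig(fs=40.0).validate()

    def test_schedule_length_mismatch(self):
        with pytest.raises(ConfigError, match="length"):
            SimConfig(n_trials=10, burst_gain=tuple([1.0] * 5)).gain_schedule()


class TestGenerateSession:
    def test_determinism(self, quiet_config):
        r1, t1 = generate_session(quiet_config)
        r2, t2 = generate_session(quiet_config)
        for s in r1.structures:
            np.testing.assert_array_equal(r1.channels[s], r2.channels[s])
        assert r1.events.df.equals(r2.events.df)
        np.testing.assert_array_equal(t1.burst_peak_times, t2.burst_peak_times)

    def test_different_seed_differs(self, quiet_config):
        from dataclasses import replace

        r1, _ = generate_session(quiet_config)
        r2, _ = generate_session(replace(quiet_config, seed=12))
        assert not np.array_equal(r1.channels["OB"], r2.channels["OB"])

    def test_trial_structure(self, quiet_session):
        rec, _ = quiet_session
        ev = rec.events
        durations = ev.ends - ev.starts
        assert np.all(durations < 2.0)
        gaps = ev.starts[1:] - ev.ends[:-1]
        assert np.all(gaps >= 7.0)
        # balanced pseudo-random odors
        odors = ev.odors
        assert abs((odors == "A").sum() - (odors == "B").sum()) <= 2

    def test_zero_gain_no_beta_power_increase(self, quiet_session):
        rec, truth = quiet_session
        tfm = compute_channel_tfmap(rec.channels["OB"], rec.fs, "OB")
        series = tfm.amplitude.max(axis=1)
        in_win, out_win = [], []
        for i in range(len(rec.events)):
            end = rec.events.ends[i]
            in_win.append(series[tfm.sample_slice(end - 0.4, end + 0.1)].mean())
            out_win.append(series[tfm.sample_slice(end + 2.0, end + 2.5)].mean())
        # no burst injected: trial-end power equals off-trial power
        assert np.mean(in_win) == pytest.approx(np.mean(out_win), rel=0.1)

    def test_coupled_pair_cross_spectrum_phase(self, coupled_session):
        cfg, (rec, truth) = coupled_session
        ma = compute_channel_tfmap(rec.channels["OB"], rec.fs, "OB")
        mb = compute_channel_tfmap(rec.channels["AP"], rec.fs, "AP")
        j = int(np.argmin(np.abs(ma.freqs - cfg.beta_freq)))
        phases = []
        for tp in truth.burst_peak_times:
            i = ma.index_of_time(tp)
            phases.append(np.angle(ma.coeffs[i, j] * np.conj(mb.coeffs[i, j])))
        z = np.exp(1j * np.asarray(phases))
        assert np.angle(z.mean()) == pytest.approx(np.pi / 2, abs=0.1)
        assert 1.0 - np.abs(z.mean()) < 0.05  # near-zero circular variance

    def test_uncoupled_phases_uniform(self):
        # ground-truth phase differences for an uncoupled pair: Rayleigh
        # test should not reject uniformity in >= 90% of seeds
        rejections = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SimConfig(structures=("OB", "PP"), n_trials=30, fs=200.0,
                            burst_gain=1.0, respiration_amplitude=0.0, seed=seed)
            _, truth = generate_session(cfg)
            d = truth.burst_phases["OB"] - truth.burst_phases["PP"]
            r = np.abs(np.mean(np.exp(1j * d)))
            n = d.size
            p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * r) ** 2)) - (1 + 2 * n))
            if p < 0.05:
                rejections += 1
        assert rejections <= 0.1 * n_seeds

    def test_zero_jitter_constant_truth_phase_difference(self, coupled_session):
        _, (rec, truth) = coupled_session
        d = np.mod(truth.burst_phases["OB"] - truth.burst_phases["AP"], 2 * np.pi)
        np.testing.assert_allclose(d, np.pi / 2, atol=1e-12)

    def test_burst_gains_align_with_trials(self, coupled_session):
        cfg, (rec, truth) = coupled_session
        assert all(g.size == cfg.n_trials for g in truth.burst_gains.values())

    def test_spectral_slope_matches_configured_exponent(self):
        for alpha in (0.8, 1.0, 1.5):
            x = _pink_noise(2**17, alpha, np.random.default_rng(1))
            f, p = sps.welch(x, fs=1000.0, nperseg=4096)
            band = (f > 2) & (f < 100)
            slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
            assert slope == pytest.approx(-alpha, abs=0.2)


class TestInjectArtifacts:
    def test_zero_rate_identity(self, quiet_session, quiet_config):
        rec, truth = quiet_session
        out, truth2 = inject_artifacts(rec, quiet_config, truth)
        np.testing.assert_array_equal(out.channels["OB"], rec.channels["OB"])

    def test_bookkeeping_counts(self):
        cfg = SimConfig(structures=("OB",), n_trials=10, burst_gain=0.0,
                        artifact_rate=2.0, artifact_amplitude=20.0, seed=42)
        rec, truth = generate_session(cfg)
        ivs = truth.artifact_intervals["OB"]
        assert len(ivs) > 0
        assert all(0 <= a < b <= rec.duration for a, b in ivs)
        assert all(0.02 <= b - a <= 0.2 + 1e-9 for a, b in ivs)

    def test_energy_above_90hz(self):
        cfg = SimConfig(structures=("OB",), n_trials=10, burst_gain=0.0,
                        artifact_rate=4.0, artifact_amplitude=20.0, seed=42)
        rec, truth = generate_session(cfg)
        a, b = truth.artifact_intervals["OB"][0]
        seg = rec.channels["OB"][int(a * cfg.fs):int(b * cfg.fs)]
        f, p = sps.periodogram(seg, fs=cfg.fs)
        assert p[f >= 90].sum() > p[f < 90].sum()

    def test_low_fs_rejected(self, quiet_config):
        from dataclasses import replace

        cfg = replace(quiet_config, fs=400.0)
        rec, truth = generate_session(quiet_config)
        rec_low = type(rec)(channels=rec.channels, fs=400.0, events=rec.events)
        with pytest.raises(ConfigError):
            inject_artifacts(rec_low, cfg, truth)

    def test_bad_amplitude_rejected(self):
        with pytest.raises(ConfigError, match="artifact_amplitude"):
            SimConfig(artifact_rate=1.0, artifact_amplitude=0.0).validate()


class TestLearningSequence:
    def test_unknown_scenario(self):
        with pytest.raises(ConfigError, match="acquisition"):
            generate_learning_sequence(SimConfig(), "warp-drive")

    def test_acquisition_monotone_performance(self):
        cfg = SimConfig(structures=("OB",), n_trials=12, fs=200.0,
                        respiration_amplitude=0.0, seed=4)
        seq = generate_learning_sequence(cfg, "acquisition", n_sessions=6)
        perf = [truth.latent_performance.mean() for _, truth in seq]
        assert all(b >= a for a, b in zip(perf, perf[1:]))
        assert perf[0] == pytest.approx(0.5, abs=0.05)
        assert perf[-1] == pytest.approx(0.92, abs=0.05)

    def test_reversal_first_session_below_chance_with_high_gain(self):
        cfg = SimConfig(structures=("OB",), n_trials=40, fs=200.0,
                        respiration_amplitude=0.0, seed=4)
        seq = generate_learning_sequence(cfg, "reversal", n_sessions=5)
        rec, truth = seq[0]
        assert truth.latent_performance.mean() < 0.3
        assert rec.events.correct.mean() < 0.5
        assert truth.burst_gains["OB"].max() == pytest.approx(3.0)

    def test_recall_retains_acquisition_gains(self):
        cfg = SimConfig(structures=("OB",), n_trials=12, fs=200.0,
                        respiration_amplitude=0.0, seed=4)
        acq = generate_learning_sequence(cfg, "acquisition", n_sessions=4)
        rec = generate_learning_sequence(cfg, "recall", n_sessions=2)
        # recall gain profile equals the final acquisition profile (no decay)
        np.testing.assert_allclose(
            rec[0][1].burst_gains["OB"],
            acq[-1][1].burst_gains["OB"],
        )

    def test_within_session_gain_ramp(self):
        cfg = SimConfig(structures=("OB",), n_trials=30, fs=200.0,
                        respiration_amplitude=0.0, seed=4)
        seq = generate_learning_sequence(cfg, "acquisition", n_sessions=3)
        g = seq[-1][1].burst_gains["OB"]
        assert np.all(np.diff(g[:15]) > 0)
        np.testing.assert_allclose(g[15:], g[14], rtol=1e-12)


class TestTrialTable:
    def test_invariants_enforced(self):
        import pandas as pd

        df = pd.DataFrame({
            "trial": [0], "nose_poke_start": [2.0], "nose_poke_end": [1.0],
            "odor": ["A"], "side": ["L"], "correct": [True],
        })
        with pytest.raises(ValueError):
            TrialTable(df)

    def test_csv_roundtrip(self, tmp_path, quiet_session):
        rec, _ = quiet_session
        path = tmp_path / "events.csv"
        rec.events.to_csv(path)
        back = TrialTable.from_csv(path)
        assert back.df["odor"].tolist() == rec.events.df["odor"].tolist()
        np.testing.assert_allclose(back.starts, rec.events.starts, atol=1e-9)
        assert len(back.licks) == len(rec.events.licks)
        for a, b in zip(back.licks, rec.events.licks):
            assert len(a) == len(b)
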