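"""Generator tests: determinism, planted-effect fidelity, signal construction."""

import numpy as np
import pandas as pd
import pytest

from oscpls.bands import BandDefinition
from oscpls.config import config_from_dict
from oscpls.spectral import band_window_power, compute_tfr
from oscpls.synthetic import (
    coupling_loading,
    generate_power_dataset,
    generate_timecourses,
    generate_trials,
)


def small_config(**over):
    base = {"n_per_group": 6, "n_channels": 8, "n_trials": 40, "seed": 5}
    base.update(over)
    return config_from_dict(base)


class TestPowerDataset:
    def test_seeded_determinism_bit_identical(self):
        cfg = small_config()
        p1, b1, t1 = generate_power_dataset(cfg, 77)
        p2, b2, t2 = generate_power_dataset(cfg, 77)
        assert np.array_equal(p1.values, p2.values)
        pd.testing.assert_frame_equal(b1, b2)
        assert t1.subject_latent == t2.subject_latent
        p3, _, _ = generate_power_dataset(cfg, 78)
        assert not np.array_equal(p1.values, p3.values)

    def test_null_config_has_no_condition_effect(self):
        cfg = small_config(n_per_group=100)
        power, _, _ = generate_power_dataset(cfg, 1)
        a = power.condition("test")
        b = power.condition("first_study")
        diff = (a - b).mean(axis=0)  # channels x bands
        se = (a - b).std(axis=0, ddof=1) / np.sqrt(a.shape[0])
        t = diff / se
        # per-channel t statistics stay within Monte-Carlo error of zero
        assert np.all(np.abs(t) < 5.0)
        assert abs(t.mean()) < 0.5

    def test_planted_effect_size_recovered_at_large_n(self):
        # -1.5 SD test-phase decrease in 20 channels for the older group:
        # the two-sample effect size between groups at the test phase should
        # come back within +-0.3 of -1.5 at n = 200 per group
        channels = list(range(20))
        cfg = config_from_dict(
            {
                "n_per_group": 200,
                "n_channels": 24,
                "n_trials": 10,
                "seed": 9,
                "effects": [
                    {
                        "group": "older",
                        "channels": channels,
                        "bands": ["theta", "alpha", "beta"],
                        "phase": "test",
                        "magnitude_sd": -1.5,
                    }
                ],
            }
        )
        power, _, truth = generate_power_dataset(cfg, 9)
        groups = np.array([power.group_of[s] for s in power.subjects])
        test = power.condition("test")
        young, old = test[groups == "younger"], test[groups == "older"]
        sp = np.sqrt((young.var(axis=0, ddof=1) + old.var(axis=0, ddof=1)) / 2)
        d = (old.mean(axis=0) - young.mean(axis=0)) / sp
        planted = d[channels, :]
        assert np.all(np.abs(planted - (-1.5)) < 0.3)
        null = np.delete(d, channels, axis=0)
        assert np.all(np.abs(null) < 0.3)

    def test_effect_on_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            small_config(
                effects=[
                    {
                        "group": "older",
                        "channels": [99],
                        "bands": ["alpha"],
                        "phase": "test",
                        "magnitude_sd": 1.0,
                    }
                ]
            )

    def test_coupling_latent_correlates_with_contrast_at_target_r(self):
        r_target = 0.6
        cfg = config_from_dict(
            {
                "n_per_group": 400,
                "n_channels": 4,
                "n_trials": 10,
                "seed": 4,
                "coupling": [
                    {
                        "group": "older",
                        "channels": [0, 1],
                        "bands": ["alpha"],
                        "phase": "test",
                        "baseline_phase": "first_study",
                        "r": r_target,
                    }
                ],
            }
        )
        power, _, truth = generate_power_dataset(cfg, 4)
        groups = np.array([power.group_of[s] for s in power.subjects])
        contrast = power.contrast("test", "first_study")
        u = np.array([truth.subject_latent[s] for s in power.subjects])
        bi = power.bands.index("alpha")
        older = groups == "older"
        for ch in (0, 1):
            r_emp = np.corrcoef(contrast[older, ch, bi], u[older])[0, 1]
            assert r_emp == pytest.approx(r_target, abs=0.1)
        r_null = np.corrcoef(contrast[~older, 0, bi], u[~older])[0, 1]
        assert abs(r_null) < 0.15

    def test_coupling_loading_closed_form(self):
        beta = coupling_loading(0.6, 2.0)
        # corr = beta / sqrt(beta^2 + 2 sd^2) must equal r exactly
        assert beta / np.sqrt(beta**2 + 2 * 4.0) == pytest.approx(0.6, abs=1e-12)


class TestTrials:
    def test_accuracy_centred_on_configured_group_mean(self):
        cfg = small_config(n_per_group=150, n_trials=204)
        trials = generate_trials(cfg, 3)
        young = trials[trials["group"] == "younger"]
        acc = young.groupby("subject").apply(
            lambda s: 100 * (s["response"] == "correct").mean(), include_groups=False
        )
        assert acc.mean() == pytest.approx(82.5, abs=1.5)

    def test_fast_rt_fraction_controls_sub_second_trials(self):
        cfg = small_config(
            n_per_group=40,
            n_trials=204,
            behaviour={"fast_rt_fraction": 0.10},
        )
        trials = generate_trials(cfg, 8)
        old = trials[(trials["group"] == "older") & (trials["response"] == "correct")]
        frac_kept = (old["rt_ms"] > 1000.0).mean()
        # ~10% drawn below 1 s; the log-normal bulk for the older group sits
        # well above 1 s, so close to 90% of correct trials survive the filter
        assert 0.85 <= frac_kept <= 0.93


class TestTimecourses:
    def test_alpha_only_carrier_dominates_alpha_band(self):
        cfg = small_config(n_channels=1)
        gains = {
            "theta": {"default": 0.0},
            "beta": {"default": 0.0},
            "alpha": {"default": 1.0},
        }
        sig, fs, t0 = generate_timecourses(
            cfg, 2, fs=120.0, n_trials=30, background_gain=0.0, carrier_gains=gains
        )
        tfr = compute_tfr(sig, fs, window_points=64, n_windows=100, t_start=t0)
        alpha = band_window_power(tfr, BandDefinition("alpha", 9, 14), (0.0, 8.0))
        theta = band_window_power(tfr, BandDefinition("theta", 2, 7), (0.0, 8.0))
        assert alpha[0] / theta[0] > 10.0

    def test_zero_gain_zero_background_gives_silence(self):
        cfg = small_config(n_channels=2)
        gains = {b: {"default": 0.0} for b in ("theta", "alpha", "beta")}
        sig, _, _ = generate_timecourses(
            cfg, 1, fs=100.0, n_trials=3, background_gain=0.0, carrier_gains=gains
        )
        assert np.all(sig == 0.0)

    def test_band_above_nyquist_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="Nyquist"):
            generate_timecourses(cfg, 1, fs=50.0)  # beta reaches 30 Hz

    def test_planted_delay_alpha_gain_recovers_log_power_ratio(self):
        # alpha amplitude x0.5 during the delay window: band power should
        # drop to 0.25 of the pre-stimulus level (amplitude^2 -> power)
        cfg = small_config(n_channels=1)
        gains = {
            "theta": {"default": 0.0},
            "beta": {"default": 0.0},
            "alpha": {"default": 1.0, "delay": 0.5},
        }
        sig, fs, t0 = generate_timecourses(
            cfg, 6, fs=160.0, n_trials=500, background_gain=0.0, carrier_gains=gains
        )
        tfr = compute_tfr(sig, fs, window_points=64, n_windows=200, t_start=t0)
        band = BandDefinition("alpha", 9, 14)
        # measurement windows shrunk so 0.4 s segments sit fully inside the
        # gain regions (delay window is 9.75..10.5 s)
        p_delay = band_window_power(tfr, band, (10.0, 10.25))
        p_pre = band_window_power(tfr, band, (-0.5, -0.25))
        log_ratio = np.log(p_delay[0] / p_pre[0])
        assert log_ratio == pytest.approx(np.log(0.25), abs=0.1 * abs(np.log(0.25)))
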