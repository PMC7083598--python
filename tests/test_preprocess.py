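"""Conditioning-chain behavior: filters, channel/epoch rejection,
re-referencing and automated blink removal."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from salieeg.config import desk_config
from salieeg.preprocess import (condition_raw, epoch_and_reject,
                                joint_probability_reject, make_epochs,
                                pick_control_tones, reject_bad_channels,
                                remove_blinks, rereference_average)
from salieeg.simulate import gen_salience_curve, gen_tone_schedule, \
    simulate_session
from salieeg.tone_locking import locking_change
from salieeg.types import Recording
from tests.conftest import epochs_from_array


def _rec(data, fs=512.0, groups=None):
    labels = [f"E{k+1:03d}" for k in range(data.shape[0])]
    return Recording(data, fs, labels, groups or {})


class TestConditionRaw:
    def test_constant_channel_becomes_zero(self):
        rec = _rec(np.full((2, 5120), 7.3))
        out = condition_raw(rec)
        assert np.abs(out.data).max() < 1e-6

    def test_line_component_attenuated_at_least_20_db(self, rng):
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 60.0 * t) + 0.01 * rng.standard_normal(len(t))
        out = condition_raw(_rec(x[None, :]))
        # periodogram oracle before/after
        f_in, p_in = sps.periodogram(x, fs)
        f_out, p_out = sps.periodogram(out.data[0], out.fs)
        e_in = p_in[np.abs(f_in - 60) < 0.5].sum()
        e_out = p_out[np.abs(f_out - 60) < 0.5].sum()
        assert 10 * np.log10(e_in / e_out) >= 20.0

    def test_tone_rate_amplitude_preserved_within_5pct(self):
        fs = 512.0
        t = np.arange(int(40 * fs)) / fs
        x = np.sin(2 * np.pi * 2.6 * t)
        out = condition_raw(_rec(x[None, :]))
        # amplitude oracle: projection onto the 2.6 Hz quadrature pair,
        # away from the resampling edges
        tt = np.arange(out.n_samples) / out.fs
        core = slice(int(2 * out.fs), int(38 * out.fs))
        c = np.cos(2 * np.pi * 2.6 * tt[core])
        s = np.sin(2 * np.pi * 2.6 * tt[core])
        amp = 2 * np.hypot(out.data[0][core] @ c, out.data[0][core] @ s) \
            / len(tt[core])
        assert abs(amp - 1.0) < 0.05

    def test_downsamples_to_256(self):
        rec = _rec(np.zeros((1, 5120)), fs=512.0)
        assert condition_raw(rec).fs == 256.0

    def test_low_rate_input_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            condition_raw(_rec(np.zeros((1, 1000)), fs=128.0))


class TestBadChannels:
    def test_single_noisy_channel_removed(self, rng):
        data = rng.standard_normal((32, 2560))
        data[5] *= 10.0
        rec = _rec(data, fs=256.0)
        out, bad, flag = reject_bad_channels(rec)
        assert bad == ["E006"]
        assert not flag
        assert out.n_channels == 31

    def test_homogeneous_channels_kept(self, rng):
        # identical band energy in every channel: none can exceed +2.5 SD
        base = rng.standard_normal(2560)
        data = np.tile(base, (16, 1))
        _, bad, _ = reject_bad_channels(_rec(data, fs=256.0))
        assert bad == []

    def test_threshold_uses_band_energy_only(self, rng):
        data = rng.standard_normal((32, 2560))
        t = np.arange(2560) / 256.0
        data[3] += 50.0 * np.sin(2 * np.pi * 2.0 * t)   # huge 2 Hz drift
        _, bad, _ = reject_bad_channels(_rec(data, fs=256.0))
        assert "E004" not in bad


class TestRereference:
    def test_zero_mean_input_unchanged(self):
        data = np.array([[1.0, -2.0], [-1.0, 2.0]])
        out = rereference_average(_rec(data, fs=256.0))
        np.testing.assert_allclose(out.data, data)

    def test_per_sample_mean_is_zero(self, rng):
        out = rereference_average(_rec(rng.standard_normal((8, 100)), 256.0))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_idempotent(self, rng):
        rec = _rec(rng.standard_normal((8, 100)), 256.0)
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data)


class TestEpochRejection:
    def test_clean_gaussian_epochs_survive(self, rng):
        # a seeded clean pool; nothing is improbable enough to reject
        data = np.random.default_rng(0).standard_normal((15, 4, 2560))
        res = joint_probability_reject(epochs_from_array(data))
        assert res.n_rejected == 0

    def test_large_spike_rejected_by_local_criterion(self):
        data = np.random.default_rng(1).standard_normal((15, 4, 2560))
        data[7, 2, 1000:1015] += 500.0
        res = joint_probability_reject(epochs_from_array(data))
        assert 7 not in res.epochs.meta.index or res.n_rejected >= 1
        assert any(res.rejected_info["trial"] == 7)

    def test_control_epochs_never_contain_targets_or_events(self):
        cfg = desk_config(seed=4)
        _, events = gen_salience_curve(cfg, 0)
        sched = gen_tone_schedule(cfg, events, 0)
        half = 3.6
        rng = np.random.default_rng(0)
        for _ in range(1000):
            picks = pick_control_tones(sched, events, 3, half_width=half,
                                       rng=rng)
            for t0 in picks:
                assert np.abs(events["time"] - t0).min() > half
                if len(sched.target_times):
                    assert np.abs(sched.target_times - t0).min() > half

    def test_epochs_carry_all_three_conditions(self):
        cfg = desk_config(seed=2)
        s = simulate_session(cfg)
        rec = condition_raw(s.recording(0, 0))
        rec = rereference_average(rec)
        ep = epoch_and_reject(rec, s.schedules[0], s.scene_events(0), 0,
                              n_controls=4, control_halfwidth=3.6,
                              rng=np.random.default_rng(0))
        kinds = set(ep.meta["kind"])
        assert {"target", "salient"} <= kinds

    def test_edge_clipped_onsets_dropped(self):
        cfg = desk_config(seed=2)
        s = simulate_session(cfg)
        rec = condition_raw(s.recording(0, 0))
        ep = make_epochs(rec, s.schedules[0], s.scene_events(0), 0,
                         n_controls=0, rng=np.random.default_rng(0))
        on = ep.meta["onset_time"]
        assert (on >= 5.0).all() and (on <= rec.duration - 5.0).all()


class TestBlinkRemoval:
    @pytest.fixture(scope="class")
    def blinky(self):
        cfg = desk_config(seed=5, blink_rate=0.15)
        clean_cfg = desk_config(seed=5, blink_rate=0.15, blink_amp=0.0)
        s = simulate_session(cfg)
        s0 = simulate_session(clean_cfg)
        return s.recording(0, 0), s0.recording(0, 0)

    def test_frontal_blink_variance_reduced_80pct(self, blinky):
        rec, rec0 = blinky
        idx = rec.channel_index(rec.groups["frontal"])
        before = (rec.data[idx] - rec0.data[idx]).var()
        out = remove_blinks(rec)
        after = (out.data[idx] - rec0.data[idx]).var()
        assert after < 0.2 * before

    def test_no_blinks_leaves_channels_nearly_unchanged(self):
        cfg = desk_config(seed=6, blink_rate=1e-9)  # EOG present, no blinks
        rec = simulate_session(cfg).recording(0, 0)
        out = remove_blinks(rec)
        for k in range(rec.n_channels - 1):
            r = np.corrcoef(rec.data[k], out.data[k])[0, 1]
            assert r > 0.99

    def test_tone_locking_statistic_preserved_within_5pct(self):
        # after blink removal the statistic should match the blink-free
        # ground-truth recording (the pre-removal value is itself biased:
        # blink energy inflates the normalization band); pool every scene
        # so the concatenated segments give the ratio enough resolution
        from salieeg.types import Epochs
        cfg = desk_config(seed=5, blink_rate=0.15)
        cfg0 = desk_config(seed=5, blink_rate=0.15, blink_amp=0.0)
        s = simulate_session(cfg)
        s0 = simulate_session(cfg0)
        parts_clean, parts_removed = [], []
        for scene in range(cfg.n_scenes):
            removed = remove_blinks(s.recording(0, scene))
            clean = s0.recording(0, scene)
            kw = dict(n_controls=0, rng=np.random.default_rng(0))
            parts_removed.append(make_epochs(removed, s.schedules[scene],
                                             s.scene_events(scene), 0, **kw))
            parts_clean.append(make_epochs(clean, s0.schedules[scene],
                                           s0.scene_events(scene), 0, **kw))
        r_rm = locking_change(Epochs.concatenate(parts_removed)).query(
            "condition=='salient' and tier==''")
        r_cl = locking_change(Epochs.concatenate(parts_clean)).query(
            "condition=='salient' and tier==''")
        assert abs(r_rm["post"].iloc[0] - r_cl["post"].iloc[0]) \
            < 0.05 * r_cl["post"].iloc[0]

    def test_missing_eog_is_a_logged_noop(self, rng):
        rec = _rec(rng.standard_normal((4, 1000)), 256.0)
        out = remove_blinks(rec)
        np.testing.assert_array_equal(out.data, rec.data)
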