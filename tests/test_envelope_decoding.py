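"""Backward-model ridge decoder and sliding-window accuracy."""

import numpy as np
import pandas as pd
import pytest

from salieeg.envelope_decoding import (bandpass_eeg, evaluate_loso,
                                       extract_envelope, fit_decoder,
                                       lagged_design, n_lags_for,
                                       predict_envelope, sliding_correlation)


class TestExtractEnvelope:
    def test_dc_input_flagged_degenerate(self):
        env, flag = extract_envelope(np.ones(5120), 512.0, 64.0)
        assert flag
        assert not env.any()

    def test_4hz_modulator_recovered(self):
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        x = (1 + 0.8 * np.sin(2 * np.pi * 4 * t)) * np.sin(2 * np.pi * 100 * t)
        env, flag = extract_envelope(x, fs, 64.0)
        mod = np.sin(2 * np.pi * 4 * np.arange(len(env)) / 64.0)
        assert not flag
        assert np.corrcoef(env, mod)[0, 1] > 0.9

    def test_20hz_modulator_attenuated_by_8hz_lowpass(self):
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        x = (1 + 0.8 * np.sin(2 * np.pi * 20 * t)) * np.sin(2 * np.pi * 100 * t)
        env, _ = extract_envelope(x, fs, 64.0)
        mod = np.sin(2 * np.pi * 20 * np.arange(len(env)) / 64.0)
        assert abs(np.corrcoef(env, mod)[0, 1]) < 0.5

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="64"):
            extract_envelope(np.zeros(100), 32.0, 64.0)


class TestRidge:
    def test_zero_lambda_equals_least_squares(self, rng):
        eeg = rng.standard_normal((4, 2000))
        env = rng.standard_normal(2000)
        W = fit_decoder(eeg, env, fs=64.0, lam=0.0).W
        X = lagged_design(eeg, n_lags_for(64.0))
        W_ls, *_ = np.linalg.lstsq(X, env, rcond=None)
        assert np.linalg.norm(W - W_ls) / np.linalg.norm(W_ls) < 1e-8

    def test_solution_satisfies_normal_equations(self, rng):
        eeg = rng.standard_normal((3, 1500))
        env = rng.standard_normal(1500)
        lam = 10.0
        w = fit_decoder(eeg, env, fs=64.0, lam=lam)
        X = lagged_design(eeg, w.n_lags)
        resid = (X.T @ X + lam * np.eye(X.shape[1])) @ w.W - X.T @ env
        assert np.linalg.norm(resid) / np.linalg.norm(X.T @ env) < 1e-8

    def test_weight_norm_shrinks_monotonically_in_lambda(self, rng):
        eeg = rng.standard_normal((3, 1500))
        env = rng.standard_normal(1500)
        norms = [np.linalg.norm(fit_decoder(eeg, env, 64.0, lam=l).W)
                 for l in (0.0, 1e2, 1e4, 1e6, 2 ** 20)]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_collinear_channels_at_zero_lambda_error(self, rng):
        base = rng.standard_normal(1000)
        eeg = np.vstack([base, base, base])          # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_decoder(eeg, rng.standard_normal(1000), 64.0, lam=0.0)

    def test_delayed_copy_reconstructed(self, rng):
        fs = 64.0
        env = bandpass_eeg(rng.standard_normal(4000)[None, :], fs,
                           (2.0, 8.0))[0]
        lag = 5
        eeg = np.vstack([np.roll(env, lag) + 0.05 * rng.standard_normal(4000)
                         for _ in range(3)])
        w = fit_decoder(eeg, env, fs, lam=1.0)
        y = predict_envelope(w, eeg)
        assert np.corrcoef(y[100:-100], env[100:-100])[0, 1] > 0.95

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="length"):
            fit_decoder(rng.standard_normal((2, 100)),
                        rng.standard_normal(99), 64.0)


class TestSlidingCorrelation:
    def test_trace_length(self, rng):
        a, b = rng.standard_normal(500), rng.standard_normal(500)
        assert len(sliding_correlation(a, b, 64)) == 500 - 64 + 1

    def test_identical_signals_give_unit_correlation(self, rng):
        a = rng.standard_normal(300)
        r = sliding_correlation(a, a, 50)
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_matches_naive_window_loop(self, rng):
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        r = sliding_correlation(a, b, 40)
        for t in (0, 57, 160):
            ref = np.corrcoef(a[t:t + 40], b[t:t + 40])[0, 1]
            assert r[t] == pytest.approx(ref, abs=1e-10)


class TestLOSO:
    def _toy_scenes(self, rng, n_scenes=4, n=4000, fs=64.0, snr=1.0):
        eeg, envs = [], []
        for _ in range(n_scenes):
            env = bandpass_eeg(rng.standard_normal(n)[None, :], fs,
                               (2.0, 8.0))[0]
            x = np.vstack([np.roll(env, 3) + (1 / snr) *
                           rng.standard_normal(n) for _ in range(3)])
            eeg.append(x)
            envs.append(env)
        return eeg, envs

    def test_noise_only_accuracy_centered_at_zero(self, rng):
        eeg = [rng.standard_normal((3, 4000)) for _ in range(3)]
        envs = [rng.standard_normal(4000) for _ in range(3)]
        traces, _ = evaluate_loso(eeg, envs, pd.DataFrame({"scene": [],
                                                           "time": []}), 64.0)
        assert abs(np.mean([t.r.mean() for t in traces])) < 0.05

    def test_training_on_test_scene_inflates_accuracy(self, rng):
        eeg, envs = self._toy_scenes(rng, snr=0.5)
        traces, _ = evaluate_loso(eeg, envs, pd.DataFrame({"scene": [],
                                                           "time": []}), 64.0)
        loso_r = traces[0].r.mean()
        # leak: include scene 0 in its own training set by duplicating it
        eeg_leak = [eeg[0]] + eeg
        env_leak = [envs[0]] + envs
        traces_leak, _ = evaluate_loso(eeg_leak, env_leak,
                                       pd.DataFrame({"scene": [], "time": []}),
                                       64.0)
        assert traces_leak[1].r.mean() > loso_r

    def test_event_pairs_reported_per_tier(self, rng):
        eeg, envs = self._toy_scenes(rng)
        events = pd.DataFrame({"scene": [0, 1], "time": [20.0, 30.0],
                               "tier": ["high", "low"]})
        _, pairs = evaluate_loso(eeg, envs, events, 64.0)
        assert set(pairs["tier"]) == {"high", "low"}
        assert pairs[["pre", "post"]].abs().max().max() <= 1.0

    def test_single_scene_rejected(self, rng):
        with pytest.raises(ValueError, match="2 scenes"):
            evaluate_loso([rng.standard_normal((2, 1000))],
                          [rng.standard_normal(1000)],
                          pd.DataFrame({"scene": [], "time": []}), 64.0)
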