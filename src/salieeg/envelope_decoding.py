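"""Backward-model reconstruction of the ignored scene envelope.

A ridge decoder maps lagged multichannel EEG (2-8 Hz band, lags 0-250 ms)
onto the scene envelope, W = (X'X + lambda I)^-1 X'Y with lambda fixed at
2^20. Decoders are trained leave-one-scene-out and evaluated as the
correlation between reconstructed and true envelope in a 1 s sliding
window; the event-locked contrast compares the window just after each
salient event with the window just before it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, signal


log = logging.getLogger(__name__)

RIDGE_LAMBDA = float(2 ** 20)
MAX_LAG_S = 0.250
EEG_BAND = (2.0, 8.0)


@dataclass
class DecoderWeights:
    W: np.ndarray               # (n_channels * n_lags,)
    n_channels: int
    n_lags: int
    fs: float
    lam: float
    training_scenes: tuple[int, ...] = ()


def extract_envelope(audio: np.ndarray, fs: float, target_fs: float,
                     order: str = "hilbert_lowpass"
                     ) -> tuple[np.ndarray, bool]:
    """Envelope of an audio trace, resampled to the EEG rate and z-scored.

    The default 'hilbert_lowpass' takes the Hilbert magnitude first and
    band-limits it to 8 Hz after -- the order that actually recovers the
    modulator of a carrier above 8 Hz. 'lowpass_hilbert' applies the 8 Hz
    low-pass to the raw signal first; it is only meaningful for inputs
    whose energy already lies below 8 Hz (for broadband audio it removes
    the carrier along with everything else) and is provided for
    completeness. Returns (envelope, degenerate_flag); the flag marks a
    (near-)constant input whose z-score is undefined, in which case a zero
    trace is returned.
    """
    if fs < 64:
        raise ValueError("audio must be sampled at >= 64 Hz")
    x = np.asarray(audio, dtype=float)
    sos = signal.butter(4, 8.0, btype="low", fs=fs, output="sos")
    if order == "lowpass_hilbert":
        env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, x)))
    elif order == "hilbert_lowpass":
        env = signal.sosfiltfilt(sos, np.abs(signal.hilbert(x)))
    else:
        raise ValueError(f"unknown order {order!r}")
    if fs != target_fs:
        n_out = int(round(len(env) * target_fs / fs))
        env = signal.resample(env, n_out)
    sd = env.std()
    if sd < 1e-12 * (abs(env.mean()) + 1e-30) or sd == 0:
        log.warning("degenerate (constant) envelope; returning zeros")
        return np.zeros_like(env), True
    return (env - env.mean()) / sd, False


def bandpass_eeg(data: np.ndarray, fs: float,
                 band: tuple[float, float] = EEG_BAND) -> np.ndarray:
    sos = signal.butter(4, band, btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def n_lags_for(fs: float, max_lag_s: float = MAX_LAG_S) -> int:
    """Number of lag taps, 0..max_lag inclusive (65 at 256 Hz)."""
    return int(round(max_lag_s * fs)) + 1


def lagged_design(eeg: np.ndarray, n_lags: int) -> np.ndarray:
    """Design matrix with forward lags: row t holds eeg[:, t..t+n_lags-1].

    The stimulus at time t is reconstructed from EEG up to 250 ms later
    (the neural response lags the stimulus). Edges are zero-padded.
    """
    n_ch, n = eeg.shape
    X = np.zeros((n, n_ch * n_lags))
    for l in range(n_lags):
        X[: n - l, l::n_lags] = eeg[:, l:].T
    return X


def _normal_equations(eeg: np.ndarray, env: np.ndarray, n_lags: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    X = lagged_design(eeg, n_lags)
    return X.T @ X, X.T @ env


def fit_decoder(eeg: np.ndarray, envelope: np.ndarray, fs: float,
                lam: float = RIDGE_LAMBDA,
                max_lag_s: float = MAX_LAG_S) -> DecoderWeights:
    """Closed-form ridge solution on the lagged design.

    ``eeg`` (channels x samples) must already be band-passed to 2-8 Hz and
    have the same length as ``envelope``. With lam = 0 this is exact least
    squares and will fail on collinear channels (use lam > 0).
    """
    if eeg.shape[1] != len(envelope):
        raise ValueError("EEG and envelope lengths differ")
    n_lags = n_lags_for(fs, max_lag_s)
    xtx, xty = _normal_equations(eeg, np.asarray(envelope, float), n_lags)
    W = _solve_ridge(xtx, xty, lam)
    return DecoderWeights(W, eeg.shape[0], n_lags, fs, lam)


def _solve_ridge(xtx: np.ndarray, xty: np.ndarray, lam: float) -> np.ndarray:
    A = xtx + lam * np.eye(xtx.shape[0])
    try:
        c = linalg.cho_factor(A)
        return linalg.cho_solve(c, xty)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations (collinear channels); "
            "use a ridge parameter lambda > 0") from err


def predict_envelope(weights: DecoderWeights, eeg: np.ndarray) -> np.ndarray:
    X = lagged_design(eeg, weights.n_lags)
    return X @ weights.W


def sliding_correlation(a: np.ndarray, b: np.ndarray, win: int) -> np.ndarray:
    """Pearson r between a and b in every length-``win`` window (step 1).

    Output length is len(a) - win + 1; windows with zero variance yield 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < win:
        raise ValueError("inputs too short for the window")
    k = np.ones(win)
    sa = np.convolve(a, k, "valid")
    sb = np.convolve(b, k, "valid")
    saa = np.convolve(a * a, k, "valid")
    sbb = np.convolve(b * b, k, "valid")
    sab = np.convolve(a * b, k, "valid")
    cov = sab - sa * sb / win
    va = saa - sa ** 2 / win
    vb = sbb - sb ** 2 / win
    denom = np.sqrt(np.clip(va * vb, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


@dataclass
class AccuracyTrace:
    """Sliding-window reconstruction accuracy of one held-out scene."""

    scene: int
    r: np.ndarray        # value at index t = window [t, t + 1 s)
    fs: float


def evaluate_loso(eeg_per_scene: list[np.ndarray],
                  env_per_scene: list[np.ndarray],
                  events: pd.DataFrame, fs: float,
                  lam: float = RIDGE_LAMBDA, max_lag_s: float = MAX_LAG_S,
                  corr_win_s: float = 1.0,
                  pre: tuple[float, float] = (-1.0, 0.0),
                  post: tuple[float, float] = (0.0, 1.0),
                  already_bandpassed: bool = False,
                  ) -> tuple[list[AccuracyTrace], pd.DataFrame]:
    """Leave-one-scene-out reconstruction and event-locked accuracy pairs.

    For every scene a decoder is trained on all other scenes (normal
    equations are accumulated once and the held-out scene subtracted) and
    the sliding 1 s correlation trace computed. For each salient event the
    accuracies of the 1 s windows before and after the event time are
    paired. Returns the traces and a frame (scene, time, tier, pre, post).
    """
    n_scenes = len(eeg_per_scene)
    if n_scenes < 2:
        raise ValueError("leave-one-scene-out needs >= 2 scenes")
    win = int(round(corr_win_s * fs))
    n_lags = n_lags_for(fs, max_lag_s)
    eeg_bp = [e if already_bandpassed else bandpass_eeg(e, fs)
              for e in eeg_per_scene]
    for e, y in zip(eeg_bp, env_per_scene):
        if e.shape[1] < win + n_lags:
            raise ValueError("scene too short for the correlation window")
    parts = [_normal_equations(e, np.asarray(y, float), n_lags)
             for e, y in zip(eeg_bp, env_per_scene)]
    xtx_all = np.sum([p[0] for p in parts], axis=0)
    xty_all = np.sum([p[1] for p in parts], axis=0)

    traces, rows = [], []
    for s in range(n_scenes):
        W = _solve_ridge(xtx_all - parts[s][0], xty_all - parts[s][1], lam)
        weights = DecoderWeights(W, eeg_bp[s].shape[0], n_lags, fs, lam,
                                 tuple(i for i in range(n_scenes) if i != s))
        y_hat = predict_envelope(weights, eeg_bp[s])
        r = sliding_correlation(np.asarray(env_per_scene[s], float), y_hat, win)
        traces.append(AccuracyTrace(s, r, fs))
        ev = events[events["scene"] == s] if len(events) else events
        for _, row in ev.iterrows():
            i_pre = int(round((row["time"] + pre[0]) * fs))
            i_post = int(round((row["time"] + post[0]) * fs))
            if i_pre < 0 or i_post >= len(r):
                continue
            rows.append({"scene": s, "time": row["time"],
                         "tier": row.get("tier", ""),
                         "pre": float(r[i_pre]), "post": float(r[i_post])})
    return traces, pd.DataFrame(rows, columns=["scene", "time", "tier",
                                               "pre", "post"])
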