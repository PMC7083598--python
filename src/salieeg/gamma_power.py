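"""Event-related high-gamma (70-110 Hz) power.

Spectrograms use 2 s FFT windows (Hann taper, 200 ms step); power per
frequency and electrode is normalized by its mean across the whole event
window after trial averaging and expressed in dB. The change statistic is
the band power of the 2 s window spanning +1.5 to +3.5 s post-onset minus
the window spanning -2.5 to -0.5 s, in dB (the shared normalization
cancels in the difference).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Epochs

GAMMA_BAND = (70.0, 110.0)
POST_WINDOW = (1.5, 3.5)
PRE_WINDOW = (-2.5, -0.5)


def event_spectrogram(epochs: Epochs, win: float = 2.0, step: float = 0.2,
                      channels: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged, self-normalized spectrogram in dB.

    Returns (freqs, window_centers_s, spec) with spec shaped
    (n_channels, n_freqs, n_windows). Per frequency and electrode the
    trial-averaged power is divided by its mean over all windows before
    conversion to dB, so a stationary signal maps to ~0 dB everywhere and
    global amplitude scaling leaves the map unchanged.
    """
    n_win = int(round(win * epochs.fs))
    n_step = max(int(round(step * epochs.fs)), 1)
    n_samp = epochs.data.shape[2]
    if n_win > n_samp:
        raise ValueError("spectrogram window longer than the epoch")
    x = epochs.data if channels is None else epochs.data[:, channels, :]
    starts = np.arange(0, n_samp - n_win + 1, n_step)
    taper = np.hanning(n_win)
    freqs = np.fft.rfftfreq(n_win, 1.0 / epochs.fs)
    power = np.zeros((x.shape[1], len(freqs), len(starts)))
    for j, s0 in enumerate(starts):
        seg = x[:, :, s0: s0 + n_win] * taper[None, None, :]
        spec = np.abs(np.fft.rfft(seg, axis=2)) ** 2
        power[:, :, j] = spec.mean(axis=0)      # average across trials
    norm = power.mean(axis=2, keepdims=True)
    spec_db = 10.0 * np.log10(power / np.where(norm > 0, norm, 1.0) + 1e-20)
    centers = epochs.window[0] + (starts + n_win / 2) / epochs.fs
    return freqs, centers, spec_db


def _window_band_power(epochs: Epochs, interval: tuple[float, float],
                       band: tuple[float, float],
                       channels: np.ndarray) -> np.ndarray:
    """Trial-averaged band power of one exact 2 s window, per electrode."""
    lo = int(round((interval[0] - epochs.window[0]) * epochs.fs))
    hi = int(round((interval[1] - epochs.window[0]) * epochs.fs))
    if lo < 0 or hi > epochs.data.shape[2]:
        raise ValueError(f"window {interval} outside the epoch")
    seg = epochs.data[:, channels, lo:hi]
    taper = np.hanning(hi - lo)
    spec = np.abs(np.fft.rfft(seg * taper[None, None, :], axis=2)) ** 2
    freqs = np.fft.rfftfreq(hi - lo, 1.0 / epochs.fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    return spec[:, :, m].mean(axis=(0, 2))      # average trials and freqs


def gamma_change(epochs: Epochs, band: tuple[float, float] = GAMMA_BAND,
                 post: tuple[float, float] = POST_WINDOW,
                 pre: tuple[float, float] = PRE_WINDOW) -> pd.DataFrame:
    """High-gamma change (dB) per condition and salience tier.

    Change = 10 log10(P_post / P_pre) per electrode of the central+frontal
    union, averaged over electrodes; P is the trial-averaged band power of
    the respective 2 s window.
    """
    channels = epochs.group_union_index()
    rows = []
    pools: list[tuple[str, str, Epochs]] = [
        (kind, "", epochs.select(kind=kind)) for kind in Epochs.KINDS]
    sal = epochs.select(kind="salient")
    if sal.n_trials:
        for tier in ("high", "mid", "low"):
            pools.append(("salient", tier, sal.select(tier=tier)))
    for kind, tier, pool in pools:
        if pool.n_trials == 0:
            continue
        p_post = _window_band_power(pool, post, band, channels)
        p_pre = _window_band_power(pool, pre, band, channels)
        change = 10.0 * np.log10(p_post / p_pre)
        rows.append({"condition": kind, "tier": tier,
                     "n_trials": pool.n_trials,
                     "change_db": float(change.mean())})
    return pd.DataFrame(rows)


def gamma_by_subject(per_subject_epochs: dict[int, Epochs],
                     **kw) -> pd.DataFrame:
    frames = []
    for subject, ep in per_subject_epochs.items():
        df = gamma_change(ep, **kw)
        df.insert(0, "subject", subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def gamma_by_behavior_split(per_subject_epochs: dict[int, Epochs],
                            scene_errors: dict[int, float],
                            kind: str = "salient",
                            absolute: bool = False) -> pd.DataFrame:
    """Gamma change split by scene-level behavioral error.

    ``scene_errors`` maps scene -> signed error (detected minus actual
    targets). Epochs from scenes with error >= 0 form the 'positive'
    split and the rest the 'negative' split (with ``absolute`` the split
    is by error magnitude above/below the median instead).
    """
    err = dict(scene_errors)
    if absolute:
        mags = {s: abs(e) for s, e in err.items()}
        med = float(np.median(list(mags.values())))
        sign = {s: ("positive" if m > med else "negative")
                for s, m in mags.items()}
    else:
        sign = {s: ("positive" if e >= 0 else "negative") for s, e in err.items()}
    rows = []
    for subject, ep in per_subject_epochs.items():
        pool = ep.select(kind=kind)
        for split in ("positive", "negative"):
            scenes = [s for s, lab in sign.items() if lab == split]
            mask = pool.meta["scene"].isin(scenes).to_numpy()
            if not mask.any():
                continue
            sub = Epochs(pool.data[mask], pool.fs, pool.window,
                         pool.meta[mask].reset_index(drop=True),
                         pool.labels, pool.groups)
            channels = sub.group_union_index()
            p_post = _window_band_power(sub, POST_WINDOW, GAMMA_BAND, channels)
            p_pre = _window_band_power(sub, PRE_WINDOW, GAMMA_BAND, channels)
            rows.append({"subject": subject, "split": split, "kind": kind,
                         "n_trials": int(mask.sum()),
                         "change_db": float(np.mean(
                             10.0 * np.log10(p_post / p_pre)))})
    return pd.DataFrame(rows)
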