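"""Phase-locking to the attended tone rhythm.

The statistic is the spectral energy at the presentation rate (2.6 Hz)
normalized by the mean energy at surrounding frequencies (2.55-2.65 Hz,
excluding the rate bin), computed on six-tone (2.3 s) segments cut before
or after the onsets of interest, concatenated across trials, and
zero-padded to a fixed length of 260 six-tone windows so every condition
shares one frequency grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Epochs

F0 = 2.6
PAD_WINDOWS = 260
NEIGHBOR_BAND = (2.55, 2.65)


def six_tone_samples(fs: float, f0: float = F0) -> int:
    """Samples in one six-tone segment (591 at 256 Hz and 2.6 Hz)."""
    return int(round(6.0 / f0 * fs))


def segment_and_concatenate(epochs: Epochs, side: str, f0: float = F0,
                            channels: np.ndarray | None = None) -> np.ndarray:
    """Per electrode, six-tone segments cut pre or post onset and
    concatenated across trials in trial order.

    Returns an array (n_channels, n_trials * segment_samples).
    """
    if side not in ("pre", "post"):
        raise ValueError("side must be 'pre' or 'post'")
    seg = six_tone_samples(epochs.fs, f0)
    c = epochs.onset_sample
    if side == "post":
        lo, hi = c, c + seg
    else:
        lo, hi = c - seg, c
    if lo < 0 or hi > epochs.data.shape[2]:
        raise ValueError("six-tone window exceeds the epoch extent")
    x = epochs.data if channels is None else epochs.data[:, channels, :]
    segs = x[:, :, lo:hi]                       # trials x ch x seg
    return np.concatenate(list(segs), axis=1)   # ch x (trials*seg)


def normalized_peak_power(sig: np.ndarray, fs: float, f0: float = F0,
                          pad_windows: int = PAD_WINDOWS,
                          neighbor_band: tuple[float, float] = NEIGHBOR_BAND
                          ) -> np.ndarray:
    """Energy at f0 divided by mean energy at surrounding frequencies.

    ``sig`` is (..., n_samples); the last axis is zero-padded to
    ``pad_windows`` six-tone windows before the FFT so the frequency grid
    is identical for all conditions. The f0 bin is the nearest grid point
    and is excluded from the neighbor mean.
    """
    sig = np.asarray(sig, dtype=float)
    if sig.shape[-1] == 0:
        raise ValueError("empty signal")
    n_pad = pad_windows * six_tone_samples(fs, f0)
    if sig.shape[-1] > n_pad:
        raise ValueError(
            f"signal ({sig.shape[-1]} samples) exceeds the fixed pad "
            f"length ({n_pad}); increase pad_windows")
    spec = np.fft.rfft(sig, n=n_pad, axis=-1)
    energy = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n_pad, 1.0 / fs)
    k0 = int(np.argmin(np.abs(freqs - f0)))
    band = (freqs >= neighbor_band[0]) & (freqs <= neighbor_band[1])
    band[k0] = False
    if not band.any():
        raise ValueError("neighbor band contains no frequency bins")
    return energy[..., k0] / energy[..., band].mean(axis=-1)


def locking_change(epochs: Epochs, f0: float = F0,
                   pad_windows: int = PAD_WINDOWS) -> pd.DataFrame:
    """Pre/post normalized peak power and its change per condition and tier.

    Ratios are computed per electrode of the central+frontal union on the
    concatenated segments of each condition pool, the change (post minus
    pre) is formed per electrode, then averaged over electrodes. Rows for
    the three salience tiers are included when salient epochs are present.
    A missing condition yields no row (partial result).
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
        pre = segment_and_concatenate(pool, "pre", f0, channels)
        post = segment_and_concatenate(pool, "post", f0, channels)
        r_pre = normalized_peak_power(pre, epochs.fs, f0, pad_windows)
        r_post = normalized_peak_power(post, epochs.fs, f0, pad_windows)
        rows.append({
            "condition": kind, "tier": tier, "n_trials": pool.n_trials,
            "pre": float(r_pre.mean()), "post": float(r_post.mean()),
            "change": float((r_post - r_pre).mean()),
        })
    return pd.DataFrame(rows)


def locking_by_subject(per_subject_epochs: dict[int, Epochs],
                       f0: float = F0,
                       pad_windows: int = PAD_WINDOWS) -> pd.DataFrame:
    """Stack per-subject locking changes into one long table."""
    frames = []
    for subject, ep in per_subject_epochs.items():
        df = locking_change(ep, f0, pad_windows)
        df.insert(0, "subject", subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
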