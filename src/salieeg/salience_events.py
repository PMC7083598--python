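"""Salient-event derivation from behavioral salience curves, strength
tiering, and acoustic control analyses (Bhattacharyya overlap, loudness /
ERB-band exclusions, feature splits)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .types import SalienceCurve

#: strength = W_SLOPE * z(slope) + W_PEAK * z(peak); equal weights by default
W_SLOPE = 0.5
W_PEAK = 0.5


def detect_events(curve: SalienceCurve, prominence: float = 0.02,
                  min_separation: float = 4.0,
                  smooth_s: float = 1.0) -> pd.DataFrame:
    """Salient events as peaks in the (smoothed) derivative of the curve.

    The derivative is smoothed with a ``smooth_s`` moving average before
    peak picking; peaks need a prominence of at least ``prominence`` (1/s)
    and are at least ``min_separation`` s apart. Returns a frame with
    columns time, slope, peak (the curve maximum in the 4 s window after
    the event).
    """
    v = np.asarray(curve.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty salience curve")
    fs = curve.fs
    if fs < 1.0:
        raise ValueError("salience curve must be sampled at >= 1 Hz")
    deriv = np.gradient(v, 1.0 / fs)
    w = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(w) / w
    deriv_s = np.convolve(deriv, kernel, mode="same")
    peaks, _ = signal.find_peaks(deriv_s, prominence=prominence,
                                 distance=max(int(round(min_separation * fs)), 1))
    rows = []
    for p in peaks:
        te = p / fs
        win = v[p: p + int(round(4.0 * fs))]
        rows.append({"time": te, "slope": float(deriv_s[p]),
                     "peak": float(win.max()) if len(win) else float(v[p]),
                     "scene": curve.scene})
    return pd.DataFrame(rows, columns=["time", "slope", "peak", "scene"])


def score_and_tier(events: pd.DataFrame, w_slope: float = W_SLOPE,
                   w_peak: float = W_PEAK) -> pd.DataFrame:
    """Attach strength and tertile tier (high / mid / low) to events.

    Strength is a linear combination of the z-scored event slope and the
    z-scored salience peak in the 4 s post-event window. Tiers partition
    the events into thirds (counts differing by at most one); ties are
    broken by stable input order.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events to form tiers")
    out = events.reset_index(drop=True).copy()
    strength = w_slope * _z(out["slope"].to_numpy(dtype=float)) + \
        w_peak * _z(out["peak"].to_numpy(dtype=float))
    out["strength"] = strength
    order = np.argsort(-strength, kind="stable")
    tiers = np.empty(len(out), dtype=object)
    for tier, chunk in zip(("high", "mid", "low"), np.array_split(order, 3)):
        tiers[chunk] = tier
    out["tier"] = tiers
    return out


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def bhattacharyya(sample_a: np.ndarray, sample_b: np.ndarray,
                  bins: int = 20) -> float:
    """Bhattacharyya coefficient between two samples on a shared histogram.

    BC = sum_k sqrt(p_k q_k) over bins spanning the pooled range: 1 for
    identical distributions, 0 for disjoint supports.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:        # degenerate: everything in one bin
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sqrt(p * q).sum())


def feature_at_events(events: pd.DataFrame, track: pd.DataFrame,
                      column: str, window: float = 1.0) -> np.ndarray:
    """Mean of a feature track in a +-window/2 interval around each event."""
    t = track["time"].to_numpy()
    x = track[column].to_numpy()
    out = []
    for te in events["time"]:
        m = (t >= te - window / 2) & (t <= te + window / 2)
        out.append(float(x[m].mean()) if m.any() else float("nan"))
    return np.asarray(out)


def exclusion_subsets(events: pd.DataFrame, tracks: pd.DataFrame,
                      top_fraction: float = 0.25) -> dict[str, pd.DataFrame]:
    """Acoustic-control event subsets.

    Returns the events minus the top-``top_fraction`` by loudness, minus the
    top fraction by 440 Hz ERB-band energy, and median splits by
    harmonicity and brightness. Requires at least 4 events.
    """
    if len(events) < 4:
        raise ValueError("exclusion subsets undefined for < 4 events")
    out: dict[str, pd.DataFrame] = {}
    for name, col in (("loudness_excluded", "loudness"),
                      ("erb440_excluded", "erb440")):
        vals = feature_at_events(events, tracks, col)
        n_drop = int(round(top_fraction * len(events)))
        keep = np.argsort(vals, kind="stable")[: len(events) - n_drop]
        out[name] = events.iloc[np.sort(keep)].reset_index(drop=True)
    for col in ("harmonicity", "brightness"):
        vals = feature_at_events(events, tracks, col)
        order = np.argsort(vals, kind="stable")
        half = len(events) - len(events) // 2
        out[f"{col}_low"] = events.iloc[np.sort(order[:half])].reset_index(drop=True)
        out[f"{col}_high"] = events.iloc[np.sort(order[half:])].reset_index(drop=True)
    return out


def erb_bandwidth(f_center: float) -> float:
    """Equivalent rectangular bandwidth (Hz) at a center frequency.

    Uses the standard Glasberg-Moore formula ERB = 24.7 (4.37 f/1000 + 1);
    about 72 Hz at 440 Hz.
    """
    return 24.7 * (4.37 * f_center / 1000.0 + 1.0)


def erb_band_energy(audio: np.ndarray, fs: float, f_center: float = 440.0,
                    track_fs: float = 10.0) -> pd.DataFrame:
    """Energy trace of ``audio`` in one ERB around ``f_center``."""
    bw = erb_bandwidth(f_center)
    lo, hi = f_center - bw / 2, f_center + bw / 2
    if hi >= fs / 2:
        raise ValueError("band exceeds Nyquist")
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, np.asarray(audio, dtype=float))
    power = band ** 2
    step = int(round(fs / track_fs))
    n_win = len(power) // step
    e = power[: n_win * step].reshape(n_win, step).mean(axis=1)
    t = (np.arange(n_win) + 0.5) * step / fs
    return pd.DataFrame({"time": t, "erb440": e})
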