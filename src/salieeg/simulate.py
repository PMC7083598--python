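"""Seeded synthetic study generator.

Emulates the experimental conditions this package analyzes: natural-scene
trials with behavioral salience curves whose derivative peaks define salient
events in three strength tertiles, a 2.6 Hz / 440 Hz / 300 ms attended tone
stream with 3-5 amplitude-modulated targets per scene kept at least 1.5 s
from any salient event, and multichannel EEG per subject containing

* a steady-state response (SSR) at the tone rate whose amplitude is scaled
  for the six tones following a target (enhancement) or following the tone
  nearest a salient event (suppression, graded by salience tier),
* baseline high-gamma (70-110 Hz) narrowband noise whose power receives a
  dB offset in a post-onset window after targets (positive) and salient
  events (negative, graded by tier),
* an envelope-following response (EFR) tracking the ignored scene envelope
  at a fixed neural lag, with a gain boost immediately after high-salience
  events,
* 1/f background noise, a power-line component, and optional bad channels
  and eye-blink transients with a dedicated virtual EOG channel.

Every draw is keyed on ``(config.seed, stream, scene[, subject])`` so that
identical configurations reproduce outputs bit for bit while streams remain
independent of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .config import SimConfig
from .types import EnvelopeTrace, Leadfield, Recording, SalienceCurve

# rng stream ids (arbitrary but fixed)
_S_CURVE, _S_ENV, _S_EEG, _S_PHASE, _S_TRACKS, _S_SCHED, _S_LEAD, _S_NET = range(8)


def _rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, *key])


# ---------------------------------------------------------------------------
# channel montage
# ---------------------------------------------------------------------------

def channel_layout(n_channels: int) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Deterministic schematic montage on the unit disc (+y toward the front).

    Returns channel positions, labels, and the named 'central' (around Cz at
    the origin) and 'frontal' (around Fz) groups, with group sizes scaled
    from the 24/22-of-128 electrode counts of the full montage.
    """
    i = np.arange(n_channels)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt((i + 0.5) / n_channels)
    th = i * golden
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    labels = [f"E{k + 1:03d}" for k in range(n_channels)]
    n_central = max(2, round(n_channels * 24 / 128))
    n_frontal = max(2, round(n_channels * 22 / 128))
    d_cz = np.hypot(pos[:, 0], pos[:, 1])
    d_fz = np.hypot(pos[:, 0], pos[:, 1] - 0.55)
    central = [labels[k] for k in np.argsort(d_cz)[:n_central]]
    frontal = [labels[k] for k in np.argsort(d_fz)[:n_frontal]]
    return pos, labels, {"central": sorted(central), "frontal": sorted(frontal)}


# ---------------------------------------------------------------------------
# salience curves and events
# ---------------------------------------------------------------------------

def gen_salience_curve(config: SimConfig, scene_id: int,
                       n_events: int | None = None
                       ) -> tuple[SalienceCurve, pd.DataFrame]:
    """Behavioral salience curve of one scene plus its ground-truth events.

    Events are sigmoidal rises (with a slow relaxation) on top of a weakly
    drifting baseline; the true event time is the maximum of the rise
    derivative, the true slope is that maximum derivative, and the true peak
    is the curve maximum in the 4 s window after the event. Events are
    spaced at least ``min_event_gap`` (>= 4 s) apart.
    """
    if n_events is None:
        n_events = config.events_per_scene()[scene_id]
    dur, fs = config.scene_dur, config.fs_curve
    rng = _rng(config.seed, _S_CURVE, scene_id)
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    # slowly drifting baseline, small enough not to create spurious events
    base = 0.15 + _lowpass_noise(rng, n, fs, cutoff=0.05, amp=0.03)

    margin, gap = config.edge_margin, config.min_event_gap
    span = dur - 2 * margin - max(n_events - 1, 0) * gap
    if n_events > 0 and span <= 0:
        raise ValueError(
            f"cannot place {n_events} events >= {gap} s apart in {dur} s")
    if n_events == 0:
        curve = SalienceCurve(np.clip(base, 0.0, 1.0), fs, scene_id)
        return curve, _empty_events()

    offsets = np.sort(rng.uniform(0.0, span, n_events))
    centers = margin + offsets + np.arange(n_events) * gap
    heights = rng.uniform(0.12, 0.45, n_events)
    taus = rng.uniform(0.2, 0.6, n_events)

    values = base.copy()
    fine_fs = 100.0
    rows = []
    for te, h, tau in zip(centers, heights, taus):
        values += _bump(t, te, h, tau)
        # ground truth from the noiseless bump on a fine grid
        tf = np.arange(int(8 * fine_fs)) / fine_fs + (te - 4.0)
        bf = _bump(tf, te, h, tau)
        db = np.gradient(bf, 1.0 / fine_fs)
        k = int(np.argmax(db))
        rows.append({"time": float(tf[k]), "slope": float(db[k])})
    values = np.clip(values, 0.0, 1.0)
    curve = SalienceCurve(values, fs, scene_id)

    events = pd.DataFrame(rows)
    peaks = []
    for te in events["time"]:
        w = values[int(te * fs): int((te + 4.0) * fs)]
        peaks.append(float(w.max()) if len(w) else float("nan"))
    events["peak"] = peaks
    events["scene"] = scene_id
    return curve, events


def _bump(t: np.ndarray, te: float, h: float, tau: float,
          t_decay: float = 6.0) -> np.ndarray:
    x = t - te
    rise = h / (1.0 + np.exp(-np.clip(x / tau, -60, 60)))
    return rise * np.exp(-np.clip(x, 0.0, None) / t_decay)


def _lowpass_noise(rng: np.random.Generator, n: int, fs: float,
                   cutoff: float, amp: float) -> np.ndarray:
    white = rng.standard_normal(n + int(4 * fs))
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[int(2 * fs): int(2 * fs) + n]
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["time", "slope", "peak", "scene"])


# ---------------------------------------------------------------------------
# tone schedule
# ---------------------------------------------------------------------------

@dataclass
class ToneSchedule:
    """Tone onsets of one scene on the exact presentation-rate grid."""

    scene: int
    onsets: np.ndarray            # s
    is_target: np.ndarray         # bool per tone
    tone_rate: float

    @property
    def target_times(self) -> np.ndarray:
        return self.onsets[self.is_target]

    def nearest_tone(self, time: float) -> int:
        return int(np.argmin(np.abs(self.onsets - time)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.onsets,
            "kind": np.where(self.is_target, "target", "tone"),
            "scene": self.scene,
        })


def gen_tone_schedule(config: SimConfig, events: pd.DataFrame,
                      scene_id: int) -> ToneSchedule:
    """Tone grid with 3-5 amplitude-modulated targets per scene.

    Targets are placed at least ``min_target_event_gap`` from every salient
    event and at least ``min_target_sep`` from each other, away from the
    scene edges.
    """
    rng = _rng(config.seed, _S_SCHED, scene_id)
    onsets = np.arange(config.tones_per_scene) / config.tone_rate
    ev = np.asarray(events["time"], dtype=float) if len(events) else np.empty(0)

    ok = (onsets >= config.edge_margin) & \
         (onsets <= config.scene_dur - config.edge_margin)
    if len(ev):
        ok &= np.abs(onsets[:, None] - ev[None, :]).min(axis=1) >= \
            config.min_target_event_gap
    lo, hi = config.n_targets_per_scene
    n_targets = int(rng.integers(lo, hi + 1)) if hi > 0 else 0

    chosen: list[int] = []
    candidates = list(np.flatnonzero(ok))
    rng.shuffle(candidates)
    for idx in candidates:
        if len(chosen) == n_targets:
            break
        if all(abs(onsets[idx] - onsets[j]) >= config.min_target_sep
               for j in chosen):
            chosen.append(idx)
    if len(chosen) < n_targets:
        if len(chosen) < lo:
            raise ValueError(
                f"scene {scene_id}: only {len(chosen)} feasible target "
                f"slots for the minimum of {lo} targets")
        # fewer slots than the draw asked for; keep the feasible count
        # (still inside the configured range)
    is_target = np.zeros(len(onsets), dtype=bool)
    is_target[chosen] = True
    return ToneSchedule(scene_id, onsets, is_target, config.tone_rate)


# ---------------------------------------------------------------------------
# scene envelope and acoustic feature tracks
# ---------------------------------------------------------------------------

def gen_scene_envelope(config: SimConfig, scene_id: int,
                       fs: float | None = None) -> EnvelopeTrace:
    """Slow (<= 4 Hz) positive envelope standing in for the scene acoustics."""
    fs = fs or config.fs_raw
    rng = _rng(config.seed, _S_ENV, scene_id)
    n = int(round(config.scene_dur * fs))
    x = _lowpass_noise(rng, n, fs, cutoff=4.0, amp=1.0)
    env = x - x.min() + 0.1
    return EnvelopeTrace(env, fs, scene_id)


FEATURES = ("loudness", "brightness", "harmonicity", "pitch", "scale")


def gen_acoustic_tracks(config: SimConfig, events: pd.DataFrame,
                        scene_id: int) -> pd.DataFrame:
    """Per-scene time series of low-level acoustic features.

    Each feature (plus the energy in one equivalent rectangular bandwidth
    around 440 Hz, 'erb440') is a smooth unit-variance process. With
    ``event_feature_shift`` = 0 the feature distribution at events matches
    the background by construction (Bhattacharyya overlap ~ 1); a positive
    shift adds that many SDs at event times via a 2 s bump.
    """
    rng = _rng(config.seed, _S_TRACKS, scene_id)
    fs = config.fs_curve
    n = int(round(config.scene_dur * fs))
    t = np.arange(n) / fs
    cols = {"time": t}
    shift = config.event_feature_shift
    ev = np.asarray(events["time"], dtype=float) if len(events) else np.empty(0)
    for name in FEATURES + ("erb440",):
        x = _lowpass_noise(rng, n, fs, cutoff=0.3, amp=1.0)
        if shift and len(ev):
            for te in ev:
                x += shift * _hann_bump(t, te, width=2.0)
        cols[name] = x
    return pd.DataFrame(cols)


def _hann_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    x = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(x) < 0.5
    out[m] = np.cos(np.pi * x[m]) ** 2
    return out


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Injected effects, for comparing recovered against true values."""

    events: pd.DataFrame                  # time, slope, peak, tier per scene
    target_times: dict[int, np.ndarray]   # scene -> target onsets
    ssr_target_gain: float
    ssr_event_gain: dict[str, float]
    gamma_target_gain: float
    gamma_event_gain: dict[str, float]
    efr_gain_high: float
    shared_voxels: np.ndarray | None = None
    network_lead: float | None = None


def gen_eeg(config: SimConfig, schedule: ToneSchedule, events: pd.DataFrame,
            envelope: EnvelopeTrace, subject: int) -> Recording:
    """One subject's raw recording for one scene.

    ``events`` must carry a ``tier`` column (assigned session-wide). The
    virtual EOG channel, when blinks are enabled, is appended last with
    label 'EOG' and belongs to no analysis group.
    """
    fs = config.fs_raw
    scene = schedule.scene
    n = int(round(config.scene_dur * fs))
    t = np.arange(n) / fs
    _, labels, groups = channel_layout(config.n_channels)
    rng = _rng(config.seed, _S_EEG, scene, subject)

    data = _pink_noise(rng, config.n_channels, n, config.noise_exponent)
    data *= config.noise_amp
    phases = rng.uniform(0, 2 * np.pi, config.n_channels)
    data += config.line_amp * np.sin(
        2 * np.pi * config.line_freq * t[None, :] + phases[:, None])

    in_group = np.array([lab in set(groups["central"]) | set(groups["frontal"])
                         for lab in labels])
    g_ch = np.where(in_group, 1.0, config.offgroup_gain)

    # --- steady-state response at the tone rate ---------------------------
    # the SSR is stimulus-locked: one phase for the whole experiment (tone
    # onsets sit on the rate grid, so every tone starts at the same phase
    # and concatenated segments stay coherent); optional per-scene jitter
    phase_rng = _rng(config.seed, _S_PHASE)
    phi = phase_rng.uniform(0, 2 * np.pi)
    if config.ssr_phase_jitter:
        phi += _rng(config.seed, _S_PHASE, scene, 1).normal(
            0.0, config.ssr_phase_jitter)
    amp_env = np.ones(n)
    seg = config.six_tone_dur
    for t0 in schedule.target_times:
        amp_env[_sl(t0, t0 + seg, fs, n)] = config.ssr_target_gain
    for _, row in events.iterrows():
        t0 = schedule.onsets[schedule.nearest_tone(row["time"])]
        amp_env[_sl(t0, t0 + seg, fs, n)] = config.ssr_event_gain[row["tier"]]
    ssr = config.ssr_amp * amp_env * np.sin(2 * np.pi * config.tone_rate * t + phi)
    data += g_ch[:, None] * ssr[None, :]

    # --- high-gamma band --------------------------------------------------
    if config.gamma_amp > 0:
        gamma = _band_noise(rng, config.n_channels, n, fs, 70.0, 110.0)
        gamma *= config.gamma_amp
        w0, w1 = config.gamma_burst_window
        g_env = np.ones(n)
        for t0 in schedule.target_times:
            g_env[_sl(t0 + w0, t0 + w1, fs, n)] = 10 ** (config.gamma_target_gain / 20)
        for _, row in events.iterrows():
            t0 = schedule.onsets[schedule.nearest_tone(row["time"])]
            g_env[_sl(t0 + w0, t0 + w1, fs, n)] = \
                10 ** (config.gamma_event_gain[row["tier"]] / 20)
        data += g_ch[:, None] * (gamma * g_env[None, :])

    # --- envelope-following response --------------------------------------
    if config.efr_amp > 0:
        env = np.interp(t, np.arange(len(envelope.values)) / envelope.fs,
                        envelope.values)
        env = (env - env.mean()) / (env.std() + 1e-12)
        lag = int(round(config.efr_lag * fs))
        env_l = np.concatenate([np.zeros(lag), env[: n - lag]])
        e_env = np.ones(n)
        for _, row in events.iterrows():
            if row["tier"] == "high":
                e_env[_sl(row["time"], row["time"] + config.efr_boost_dur,
                          fs, n)] = config.efr_gain_high
        data += g_ch[:, None] * (config.efr_amp * env_l * e_env)[None, :]

    # --- artifacts ---------------------------------------------------------
    if config.n_bad_channels > 0:
        bad = rng.choice(np.flatnonzero(~in_group) if (~in_group).sum()
                         >= config.n_bad_channels else np.arange(config.n_channels),
                         size=config.n_bad_channels, replace=False)
        data[bad] += 10 * config.noise_amp * rng.standard_normal((len(bad), n))

    if config.blink_rate > 0:
        eog = _blink_train(rng, n, fs, config.blink_rate, config.blink_amp)
        coupling = np.where(
            np.isin(labels, groups["frontal"]), 0.45,
            np.where(in_group, 0.10, 0.05))
        data += coupling[:, None] * eog[None, :]
        eog_channel = eog + 0.5 * rng.standard_normal(n)
        data = np.vstack([data, eog_channel])
        labels = labels + ["EOG"]

    return Recording(data, fs, list(labels), groups, reference="raw")


def _sl(t0: float, t1: float, fs: float, n: int) -> slice:
    return slice(max(int(round(t0 * fs)), 0), min(int(round(t1 * fs)), n))


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int,
                exponent: float) -> np.ndarray:
    """1/f**exponent noise, unit RMS per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape[None, :], n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _band_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _blink_train(rng: np.random.Generator, n: int, fs: float,
                 rate: float, amp: float) -> np.ndarray:
    dur_s = n / fs
    n_blinks = rng.poisson(rate * dur_s)
    times = rng.uniform(1.0, dur_s - 1.0, n_blinks)
    width = int(round(0.4 * fs))
    template = np.hanning(width) ** 2
    out = np.zeros(n)
    for tb in times:
        k = int(tb * fs)
        seg = out[k: k + width]
        seg += amp * template[: len(seg)] * rng.uniform(0.7, 1.3)
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def gen_responses(config: SimConfig, schedule: ToneSchedule,
                  subject: int) -> np.ndarray:
    """Simulated key presses for one subject and scene.

    Each target elicits a response with probability ``hit_rate`` at a
    uniform 250-650 ms latency; false alarms are added at a Poisson rate
    per scene away from targets.
    """
    rng = _rng(config.seed, 6, schedule.scene, subject)
    responses = []
    for t0 in schedule.target_times:
        if rng.random() < config.hit_rate:
            responses.append(t0 + rng.uniform(0.25, 0.65))
    n_fa = rng.poisson(config.false_alarms_per_scene)
    tt = schedule.target_times
    for _ in range(n_fa):
        for _attempt in range(20):
            t = rng.uniform(1.0, config.scene_dur - 1.0)
            if not len(tt) or np.abs(tt - t).min() > 1.5:
                responses.append(t)
                break
    return np.sort(np.asarray(responses))


# ---------------------------------------------------------------------------
# leadfield
# ---------------------------------------------------------------------------

def gen_leadfield(n_channels: int, n_voxels: int, seed: int = 0,
                  sigma: float = 0.4, max_tries: int = 5) -> Leadfield:
    """Smooth random gain matrix standing in for a head model.

    Channels sit on the upper unit hemisphere, voxels on an inner shell;
    gains decay smoothly with channel-voxel distance with mild random
    orientation scaling. The draw is repeated (new substream) if it is not
    of full row rank.
    """
    for attempt in range(max_tries):
        rng = _rng(seed, _S_LEAD, attempt)
        pos2d, _, _ = channel_layout(n_channels)
        r2 = np.minimum(np.sum(pos2d ** 2, axis=1), 1.0)
        chan = np.column_stack([pos2d, np.sqrt(1.0 - r2)])
        vox = rng.standard_normal((n_voxels, 3))
        vox /= np.linalg.norm(vox, axis=1, keepdims=True)
        vox[:, 2] = np.abs(vox[:, 2])
        vox *= rng.uniform(0.55, 0.8, n_voxels)[:, None]
        d2 = np.sum((chan[:, None, :] - vox[None, :, :]) ** 2, axis=2)
        orient = rng.uniform(0.5, 1.5, n_voxels)
        gain = np.exp(-d2 / (2 * sigma ** 2)) * orient[None, :]
        gain += 0.01 * rng.standard_normal(gain.shape)
        if np.linalg.matrix_rank(gain) == min(n_channels, n_voxels):
            return Leadfield(gain, positions=vox)
    raise RuntimeError("could not draw a full-rank leadfield")


# ---------------------------------------------------------------------------
# source-level network maps (post-localization emulation)
# ---------------------------------------------------------------------------

def gen_network_maps(n_subjects: int = 12, n_voxels: int = 80,
                     n_shared: int = 10, lags: np.ndarray | None = None,
                     center_s: float = 0.75, lead: float = 0.5,
                     amp: float = 4.0, width: float = 0.3,
                     noise: float = 1.0, seed: int = 0
                     ) -> dict[str, object]:
    """Subject x voxel gamma-activation maps for the network-overlap analysis.

    Emulates masked source maps after localization: a shared set of voxels
    carries a subject-coupled activation whose time course peaks at
    ``center_s`` for the bottom-up (salient-event) maps and ``lead`` seconds
    later for the top-down (target) maps, on top of unit voxel noise.
    Returns maps keyed 'S' and 'T' as arrays (n_lags, n_subjects, n_voxels)
    plus the planted voxel indices and lag axis.
    """
    if lags is None:
        lags = np.arange(0.0, 2.0 + 1e-9, 0.25)
    lags = np.asarray(lags, dtype=float)
    rng = _rng(seed, _S_NET)
    shared = rng.choice(n_voxels, size=n_shared, replace=False)
    loadings = rng.uniform(0.6, 1.4, n_shared)
    z = rng.standard_normal(n_subjects)          # subject coupling
    prof_s = np.exp(-0.5 * ((lags - center_s) / width) ** 2)
    prof_t = np.exp(-0.5 * ((lags - (center_s + lead)) / width) ** 2)

    def build(profile: np.ndarray) -> np.ndarray:
        maps = noise * rng.standard_normal((len(lags), n_subjects, n_voxels))
        sig = amp * profile[:, None, None] * z[None, :, None] \
            * loadings[None, None, :]
        maps[:, :, shared] += sig
        return maps

    return {
        "lags": lags,
        "S": build(prof_s),
        "T": build(prof_t),
        "shared_voxels": np.sort(shared),
        "lead": lead,
        "center_s": center_s,
    }


# ---------------------------------------------------------------------------
# classifier feature fixtures
# ---------------------------------------------------------------------------

def gen_feature_table(kind: str, n_events: int = 120, n_subjects: int = 12,
                      seed: int = 0) -> dict[str, object]:
    """Tone-level feature tables with known class structure.

    Each event contributes one 'before' (label 0) and one 'after' (label 1)
    tone sharing an event id, with one gamma and one tone-locking feature
    per subject (2 * n_subjects columns), mirroring the feature layout of
    the prediction stage.

    kinds:
      'separable'     -- classes far apart on every feature
      'null'          -- features independent of the label
      'complementary' -- each feature family is weakly informative alone
                         (AUC ~ 0.7) but the two families jointly separate
                         the classes (discriminative direction F1 - F2
                         masked marginally by a shared nuisance component)
    """
    rng = _rng(seed, 7)
    n = 2 * n_events
    y = np.tile([0, 1], n_events)
    event_id = np.repeat(np.arange(n_events), 2)
    s = y.astype(float)

    if kind == "separable":
        u1 = 2.0 * s + 0.1 * rng.standard_normal(n)
        u2 = -2.0 * s + 0.1 * rng.standard_normal(n)
        subj_noise = 0.05
    elif kind == "null":
        u1 = rng.standard_normal(n)
        u2 = rng.standard_normal(n)
        subj_noise = 1.0
    elif kind == "complementary":
        delta, nu, eps = 1.0, 1.2, 0.25
        sc = s - 0.5
        eta = rng.standard_normal(n)
        u1 = sc * delta / np.sqrt(2) + nu * eta / np.sqrt(2) \
            + eps * rng.standard_normal(n)
        u2 = -sc * delta / np.sqrt(2) + nu * eta / np.sqrt(2) \
            + eps * rng.standard_normal(n)
        subj_noise = 0.25
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    gamma = u1[:, None] + subj_noise * rng.standard_normal((n, n_subjects))
    lock = u2[:, None] + subj_noise * rng.standard_normal((n, n_subjects))
    X = np.hstack([gamma, lock])
    names = [f"gamma_s{j}" for j in range(n_subjects)] + \
            [f"lock_s{j}" for j in range(n_subjects)]
    return {"X": X, "y": y, "event_id": event_id, "names": names,
            "gamma_cols": np.arange(n_subjects),
            "lock_cols": np.arange(n_subjects, 2 * n_subjects)}


# ---------------------------------------------------------------------------
# whole-session orchestration
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """All stimulus-side material of one synthetic study, EEG on demand."""

    config: SimConfig
    curves: list[SalienceCurve]
    events: pd.DataFrame                  # session-wide, with tier + strength
    schedules: list[ToneSchedule]
    envelopes: list[EnvelopeTrace]
    tracks: list[pd.DataFrame] = field(default_factory=list)

    def scene_events(self, scene: int) -> pd.DataFrame:
        return self.events[self.events["scene"] == scene].reset_index(drop=True)

    def recording(self, subject: int, scene: int) -> Recording:
        return gen_eeg(self.config, self.schedules[scene],
                       self.scene_events(scene), self.envelopes[scene], subject)

    def iter_recordings(self, subject: int) -> Iterable[tuple[int, Recording]]:
        for scene in range(self.config.n_scenes):
            yield scene, self.recording(subject, scene)

    @property
    def ground_truth(self) -> GroundTruth:
        c = self.config
        return GroundTruth(
            events=self.events,
            target_times={s.scene: s.target_times for s in self.schedules},
            ssr_target_gain=c.ssr_target_gain,
            ssr_event_gain=dict(c.ssr_event_gain),
            gamma_target_gain=c.gamma_target_gain,
            gamma_event_gain=dict(c.gamma_event_gain),
            efr_gain_high=c.efr_gain_high,
        )


def simulate_session(config: SimConfig, with_tracks: bool = False) -> Session:
    """Generate curves, events (tiered session-wide), schedules and envelopes."""
    from .salience_events import score_and_tier

    curves, all_events = [], []
    for scene in range(config.n_scenes):
        curve, ev = gen_salience_curve(config, scene)
        curves.append(curve)
        all_events.append(ev)
    events = pd.concat(all_events, ignore_index=True)
    if len(events) >= 3:
        events = score_and_tier(events)
    else:
        events["strength"] = np.nan
        events["tier"] = "high"
    schedules = [gen_tone_schedule(config, events[events["scene"] == s], s)
                 for s in range(config.n_scenes)]
    envelopes = [gen_scene_envelope(config, s) for s in range(config.n_scenes)]
    tracks = [gen_acoustic_tracks(config, events[events["scene"] == s], s)
              for s in range(config.n_scenes)] if with_tracks else []
    return Session(config, curves, events, schedules, envelopes, tracks)
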