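"""EEG conditioning chain: filtering and downsampling, bad-channel
rejection, average re-referencing, automated blink removal, and epoching
with joint-probability artifact rejection.

Stage order is condition -> bad channels -> re-reference -> blink removal
-> epoching/rejection; filters are zero-phase (forward-backward)
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import ToneSchedule
from .types import Epochs, Recording

log = logging.getLogger(__name__)

TARGET_FS = 256.0


def condition_raw(rec: Recording, target_fs: float = TARGET_FS,
                  hp_cutoff: float = 0.5, line_freq: float = 60.0) -> Recording:
    """Demean, detrend, highpass (0.5 Hz, 3rd-order Butterworth,
    zero-phase), downsample to 256 Hz and notch out the line component."""
    if rec.fs < target_fs:
        raise ValueError(f"sampling rate {rec.fs} below target {target_fs}")
    x = signal.detrend(np.asarray(rec.data, dtype=float), axis=1, type="linear")
    sos = signal.butter(3, hp_cutoff, btype="high", fs=rec.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    if rec.fs != target_fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    if line_freq and line_freq < target_fs / 2:
        sos_n = signal.butter(2, [line_freq - 1.0, line_freq + 1.0],
                              btype="bandstop", fs=target_fs, output="sos")
        x = signal.sosfiltfilt(sos_n, x, axis=1)
    return rec.copy_with(x, fs=target_fs)


def reject_bad_channels(rec: Recording, n_sd: float = 2.5,
                        band: tuple[float, float] = (20.0, 40.0),
                        max_fraction: float = 0.2
                        ) -> tuple[Recording, list[str], bool]:
    """Drop channels whose 20-40 Hz band energy exceeds mean + 2.5 SD.

    Returns (cleaned recording, rejected labels, error flag). The flag is
    set (with a logged warning) when more than ``max_fraction`` of channels
    would be removed. The EOG channel is never considered.
    """
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels")
    eeg_idx = [i for i, lab in enumerate(rec.labels)
               if not lab.upper().startswith("EOG")]
    sos = signal.butter(4, band, btype="band", fs=rec.fs, output="sos")
    bp = signal.sosfiltfilt(sos, rec.data[eeg_idx], axis=1)
    energy = np.mean(bp ** 2, axis=1)
    thresh = energy.mean() + n_sd * energy.std()
    bad = [rec.labels[eeg_idx[k]] for k in np.flatnonzero(energy > thresh)]
    flag = len(bad) > max_fraction * len(eeg_idx)
    if flag:
        log.warning("rejecting %d/%d channels exceeds %.0f%% limit",
                    len(bad), len(eeg_idx), 100 * max_fraction)
    if bad:
        log.info("rejected channels: %s", bad)
    return rec.drop(bad), bad, flag


def band_energy(rec: Recording, band: tuple[float, float] = (20.0, 40.0)
                ) -> np.ndarray:
    """Mean 20-40 Hz band power per channel (EOG excluded -> nan)."""
    sos = signal.butter(4, band, btype="band", fs=rec.fs, output="sos")
    out = np.full(rec.n_channels, np.nan)
    eeg = [i for i, lab in enumerate(rec.labels)
           if not lab.upper().startswith("EOG")]
    bp = signal.sosfiltfilt(sos, rec.data[eeg], axis=1)
    out[eeg] = np.mean(bp ** 2, axis=1)
    return out


def session_bad_channels(recs: list[Recording], n_sd: float = 2.5,
                         max_fraction: float = 0.2
                         ) -> tuple[list[str], bool]:
    """Bad-channel labels from band energy pooled over a subject's scenes.

    Channels are rejected once per subject (energies averaged across
    scenes) so every scene retains an identical montage.
    """
    energies = np.nanmean([band_energy(r) for r in recs], axis=0)
    valid = ~np.isnan(energies)
    e = energies[valid]
    thresh = e.mean() + n_sd * e.std()
    labels = [recs[0].labels[i] for i in np.flatnonzero(valid)]
    bad = [lab for lab, v in zip(labels, e) if v > thresh]
    flag = len(bad) > max_fraction * len(labels)
    if flag:
        log.warning("rejecting %d/%d channels exceeds %.0f%% limit",
                    len(bad), len(labels), 100 * max_fraction)
    return bad, flag


def rereference_average(rec: Recording) -> Recording:
    """Common average reference over the EEG channels (EOG left untouched)."""
    x = rec.data.astype(float).copy()
    eeg = [i for i, lab in enumerate(rec.labels)
           if not lab.upper().startswith("EOG")]
    x[eeg] -= x[eeg].mean(axis=0, keepdims=True)
    return rec.copy_with(x, reference="average")


def remove_blinks(rec: Recording, eog_label: str = "EOG") -> Recording:
    """Regress the EOG channel out of every EEG channel.

    Stands in for manual ICA component rejection: blink transients couple
    linearly into (mostly frontal) channels, so least-squares regression on
    the simultaneously recorded EOG removes them while leaving narrowband
    neural components (which the EOG barely carries) intact. If no EOG
    channel is present the recording is returned unchanged with a warning.
    """
    if eog_label not in rec.labels:
        log.warning("no %s channel; skipping blink removal", eog_label)
        return rec
    k = rec.labels.index(eog_label)
    eog = rec.data[k].astype(float)
    eog = eog - eog.mean()
    denom = float(eog @ eog)
    x = rec.data.astype(float).copy()
    if denom > 0:
        idx = [i for i in range(rec.n_channels) if i != k]
        beta = (x[idx] @ eog) / denom
        x[idx] -= beta[:, None] * eog[None, :]
    return rec.copy_with(x)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochingResult:
    epochs: Epochs
    n_rejected: int
    rejected_info: pd.DataFrame


def pick_control_tones(schedule: ToneSchedule, events: pd.DataFrame,
                       n_controls: int, half_width: float = 5.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Random tones with no target and no event within +-half_width.

    With the default half_width the whole +-5 s epoch is clear; denser
    event schedules may need a smaller exclusion (still covering the
    analysis windows) to leave any candidates. Returns control tone onset
    times; if fewer candidates exist than requested, all candidates are
    returned with a logged warning.
    """
    rng = rng or np.random.default_rng(0)
    onsets = schedule.onsets
    ok = (onsets >= half_width) & \
         (onsets <= onsets[-1] + 1.0 / schedule.tone_rate - half_width)
    tt = schedule.target_times
    if len(tt):
        ok &= np.abs(onsets[:, None] - tt[None, :]).min(axis=1) > half_width
    ev = np.asarray(events["time"], dtype=float) if len(events) else np.empty(0)
    if len(ev):
        ok &= np.abs(onsets[:, None] - ev[None, :]).min(axis=1) > half_width
    cand = np.flatnonzero(ok)
    if len(cand) < n_controls:
        log.warning("scene %d: only %d control candidates for %d requested",
                    schedule.scene, len(cand), n_controls)
    take = min(n_controls, len(cand))
    if take == 0:
        return np.empty(0)
    chosen = rng.choice(cand, size=take, replace=False)
    return onsets[np.sort(chosen)]


def make_epochs(rec: Recording, schedule: ToneSchedule, events: pd.DataFrame,
                subject: int, n_controls: int = 12,
                window: tuple[float, float] = (-5.0, 5.0),
                rng: np.random.Generator | None = None,
                control_halfwidth: float | None = None) -> Epochs:
    """Cut +-5 s epochs around targets, tones nearest each salient event,
    and randomly drawn control tones."""
    if control_halfwidth is None:
        control_halfwidth = -window[0]
    onset_rows: list[dict] = []
    for t0 in schedule.target_times:
        onset_rows.append({"kind": "target", "tier": "", "onset_time": t0,
                           "event_time": np.nan})
    for _, row in events.iterrows():
        t0 = schedule.onsets[schedule.nearest_tone(row["time"])]
        onset_rows.append({"kind": "salient", "tier": row["tier"],
                           "onset_time": t0, "event_time": row["time"]})
    for t0 in pick_control_tones(schedule, events, n_controls,
                                 control_halfwidth, rng):
        onset_rows.append({"kind": "control", "tier": "", "onset_time": t0,
                           "event_time": np.nan})

    n_pre = int(round(-window[0] * rec.fs))
    n_post = int(round(window[1] * rec.fs))
    eeg = [i for i, lab in enumerate(rec.labels)
           if not lab.upper().startswith("EOG")]
    labels = [rec.labels[i] for i in eeg]
    trials, meta = [], []
    for row in onset_rows:
        c = int(round(row["onset_time"] * rec.fs))
        if c - n_pre < 0 or c + n_post > rec.n_samples:
            log.info("dropping %s onset %.2f s: window clipped by scene edge",
                     row["kind"], row["onset_time"])
            continue
        trials.append(rec.data[np.ix_(eeg, range(c - n_pre, c + n_post))])
        meta.append({**row, "scene": schedule.scene, "subject": subject})
    if not trials:
        raise ValueError(f"scene {schedule.scene}: no epochs could be cut")
    groups = {g: [n for n in m if n in labels] for g, m in rec.groups.items()}
    return Epochs(np.stack(trials), rec.fs, window, pd.DataFrame(meta),
                  labels, groups)


def joint_probability_reject(epochs: Epochs, local_sd: float = 6.0,
                             global_sd: float = 2.0,
                             n_bins: int = 100) -> EpochingResult:
    """Drop epochs with improbable amplitude distributions.

    For each channel, the amplitude distribution is estimated by a
    histogram over all epochs; each epoch's statistic is the mean negative
    log-probability of its samples (its 'improbability'). Epochs are
    rejected when any single channel exceeds ``local_sd`` standard
    deviations above the mean statistic, or when the channel-averaged
    statistic exceeds ``global_sd`` SDs. Thresholds are applied per
    condition pool by the caller.
    """
    x = epochs.data
    n_tr, n_ch, _ = x.shape
    if n_tr < 8:
        # too few epochs to estimate an amplitude distribution; keep all
        return EpochingResult(epochs, 0, pd.DataFrame())
    stat = np.empty((n_tr, n_ch))
    for c in range(n_ch):
        vals = x[:, c, :]
        lo, hi = vals.min(), vals.max()
        edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
        counts, _ = np.histogram(vals, bins=edges)
        p = counts / counts.sum()
        p = np.clip(p, 1e-12, None)
        idx = np.clip(np.searchsorted(edges, vals, side="right") - 1,
                      0, n_bins - 1)
        stat[:, c] = -np.log(p[idx]).mean(axis=1)
    z_local = _z_epochs(stat)
    z_global = _z_epochs(stat.mean(axis=1, keepdims=True))[:, 0]
    reject = (z_local > local_sd).any(axis=1) | (z_global > global_sd)
    info = []
    for k in np.flatnonzero(reject):
        reason = "local" if (z_local[k] > local_sd).any() else "global"
        info.append({"trial": int(k), "reason": reason,
                     "kind": epochs.meta.iloc[k]["kind"]})
        log.info("rejecting epoch %d (%s criterion)", k, reason)
    keep = ~reject
    kept = Epochs(x[keep], epochs.fs, epochs.window,
                  epochs.meta[keep].reset_index(drop=True),
                  epochs.labels, epochs.groups)
    return EpochingResult(kept, int(reject.sum()), pd.DataFrame(info))


def _z_epochs(stat: np.ndarray) -> np.ndarray:
    """Leave-one-out z-score across epochs (axis 0).

    With the epoch itself included in mean/SD, an outlier among n epochs
    can never exceed (n-1)/sqrt(n) SDs -- a 6 SD threshold would be
    unreachable for small condition pools -- so each epoch is scored
    against the statistics of the remaining epochs.
    """
    n = stat.shape[0]
    if n < 3:
        return np.zeros_like(stat)
    s = stat.sum(axis=0, keepdims=True)
    ss = (stat ** 2).sum(axis=0, keepdims=True)
    mu_loo = (s - stat) / (n - 1)
    var_loo = (ss - stat ** 2) / (n - 1) - mu_loo ** 2
    var_loo = var_loo * (n - 1) / max(n - 2, 1)
    sd_loo = np.sqrt(np.clip(var_loo, 0.0, None))
    return (stat - mu_loo) / np.where(sd_loo > 0, sd_loo, 1.0)


def epoch_and_reject(rec: Recording, schedule: ToneSchedule,
                     events: pd.DataFrame, subject: int,
                     n_controls: int = 12,
                     window: tuple[float, float] = (-5.0, 5.0),
                     rng: np.random.Generator | None = None,
                     local_sd: float = 6.0, global_sd: float = 2.0,
                     control_halfwidth: float | None = None) -> Epochs:
    """Epoching plus per-condition joint-probability rejection."""
    epochs = make_epochs(rec, schedule, events, subject, n_controls,
                         window, rng, control_halfwidth)
    parts = []
    for kind in Epochs.KINDS:
        pool = epochs.select(kind=kind)
        if pool.n_trials == 0:
            continue
        parts.append(joint_probability_reject(pool, local_sd, global_sd).epochs)
    out = Epochs.concatenate(parts)
    for kind in ("target", "salient"):
        if (epochs.meta["kind"] == kind).any() and \
                not (out.meta["kind"] == kind).any():
            raise ValueError(f"all {kind} epochs rejected")
    return out


def preprocess_recording(rec: Recording, schedule: ToneSchedule,
                         events: pd.DataFrame, subject: int,
                         n_controls: int = 12,
                         rng: np.random.Generator | None = None,
                         control_halfwidth: float | None = None,
                         bad_channels: list[str] | None = None,
                         ) -> tuple[Epochs, Recording, list[str]]:
    """Full chain for one scene; returns epochs, the cleaned continuous
    recording, and the rejected channel labels.

    If ``bad_channels`` is given (e.g. determined once per subject over
    all scenes) it is applied instead of per-scene detection.
    """
    rec = condition_raw(rec)
    if bad_channels is None:
        rec, bad, _ = reject_bad_channels(rec)
    else:
        bad = list(bad_channels)
        rec = rec.drop(bad)
    rec = rereference_average(rec)
    rec = remove_blinks(rec)
    epochs = epoch_and_reject(rec, schedule, events, subject,
                              n_controls=n_controls, rng=rng,
                              control_halfwidth=control_halfwidth)
    return epochs, rec, bad
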