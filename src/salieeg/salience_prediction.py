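"""Predicting salient-event moments from neural markers.

Tones starting 1-2.5 s before an event are labeled 'before' and tones
starting 1-2.5 s after an event 'after' (tones qualifying for both are
dropped). Each tone is described by a per-subject tone-locking feature
(2.6 Hz energy in a 5 s window normalized by the 2.5-2.7 Hz neighborhood)
and a per-subject high-gamma feature (70-110 Hz energy in a 2 s window),
averaged over the central+frontal electrodes. A small feed-forward network
classifies before vs after under event-grouped 10-fold cross-validation;
complementarity of the two feature families is quantified by interaction
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .types import Recording

log = logging.getLogger(__name__)

BEFORE_WINDOW = (-2.5, -1.0)
AFTER_WINDOW = (1.0, 2.5)
LOCK_WINDOW_S = 5.0
LOCK_NEIGHBORS = (2.5, 2.7)
GAMMA_WINDOW_S = 2.0
GAMMA_BAND = (70.0, 110.0)


def label_tones(tone_times: np.ndarray, event_times: np.ndarray
                ) -> pd.DataFrame:
    """Before/after labels for tones relative to salient events.

    Returns a frame (tone_time, label in {0: before, 1: after}, event_idx)
    containing only unambiguous tones; tones qualifying as both before one
    event and after another are removed. Raises if nothing remains.
    """
    tone_times = np.asarray(tone_times, float)
    event_times = np.asarray(event_times, float)
    rows = []
    for t0 in tone_times:
        rel = t0 - event_times
        is_before = (rel >= BEFORE_WINDOW[0]) & (rel <= BEFORE_WINDOW[1])
        is_after = (rel >= AFTER_WINDOW[0]) & (rel <= AFTER_WINDOW[1])
        if is_before.any() and is_after.any():
            continue                      # ambiguous: two events too close
        if is_before.any():
            rows.append({"tone_time": t0, "label": 0,
                         "event_idx": int(np.argmax(is_before))})
        elif is_after.any():
            rows.append({"tone_time": t0, "label": 1,
                         "event_idx": int(np.argmax(is_after))})
    if not rows:
        raise ValueError("no tones fall in the labeling windows")
    return pd.DataFrame(rows)


def tone_features(rec: Recording, tone_time: float, f0: float = 2.6
                  ) -> tuple[float, float] | None:
    """(locking, gamma) features of one tone from a continuous recording.

    Tone-locking: 2.6 Hz energy in a 5 s window centered on the tone,
    divided by the mean energy between 2.5 and 2.7 Hz (excluding the rate
    bin). Gamma: mean 70-110 Hz energy in a 2 s window around onset. Both
    averaged over the central+frontal electrode union. Returns None when a
    window is clipped by the scene edge.
    """
    idx = rec.group_union_index()
    fs = rec.fs
    out = []
    for width, kind in ((LOCK_WINDOW_S, "lock"), (GAMMA_WINDOW_S, "gamma")):
        half = int(round(width * fs / 2))
        c = int(round(tone_time * fs))
        if c - half < 0 or c + half > rec.n_samples:
            log.info("tone at %.2f s dropped: %s window clipped", tone_time, kind)
            return None
        seg = rec.data[idx, c - half: c + half]
        if kind == "lock":
            # a raw 5 s window has 0.2 Hz resolution: the 2.5-2.7 Hz
            # neighborhood would hold no bin besides the rate bin itself,
            # so pad 8x for a 0.025 Hz grid
            n_fft = 8 * seg.shape[1]
            spec = np.abs(np.fft.rfft(seg, n=n_fft, axis=1)) ** 2
            freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
            k0 = int(np.argmin(np.abs(freqs - f0)))
            band = (freqs >= LOCK_NEIGHBORS[0]) & (freqs <= LOCK_NEIGHBORS[1])
            band[k0] = False
            val = spec[:, k0] / spec[:, band].mean(axis=1)
        else:
            spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2
            freqs = np.fft.rfftfreq(seg.shape[1], 1.0 / fs)
            band = (freqs >= GAMMA_BAND[0]) & (freqs <= GAMMA_BAND[1])
            val = spec[:, band].mean(axis=1)
        out.append(float(val.mean()))
    return out[0], out[1]


def extract_features(recordings: dict[int, Recording],
                     labeled: pd.DataFrame, f0: float = 2.6) -> dict[str, object]:
    """Feature table over subjects for the labeled tones of one scene.

    ``recordings`` maps subject -> preprocessed continuous Recording.
    Produces one gamma and one locking column per subject
    (2 x n_subjects features); tones whose windows are clipped for any
    subject are dropped.
    """
    subjects = sorted(recordings)
    rows, y, event_id = [], [], []
    for _, tone in labeled.iterrows():
        feats_g, feats_l = [], []
        ok = True
        for s in subjects:
            f = tone_features(recordings[s], tone["tone_time"], f0)
            if f is None:
                ok = False
                break
            feats_l.append(f[0])
            feats_g.append(f[1])
        if not ok:
            continue
        rows.append(feats_g + feats_l)
        y.append(int(tone["label"]))
        event_id.append(int(tone["event_idx"]))
    X = np.asarray(rows)
    names = [f"gamma_s{s}" for s in subjects] + [f"lock_s{s}" for s in subjects]
    return {"X": X, "y": np.asarray(y), "event_id": np.asarray(event_id),
            "names": names,
            "gamma_cols": np.arange(len(subjects)),
            "lock_cols": np.arange(len(subjects), 2 * len(subjects))}


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    fold_aucs: dict[str, np.ndarray]
    mean_auc: dict[str, float]
    pooled_auc: dict[str, float]

    def best_single(self) -> float:
        return max(self.mean_auc.get("gamma", 0.0),
                   self.mean_auc.get("locking", 0.0))


def _make_net(seed: int) -> MLPClassifier:
    # two hidden layers (16 -> 8) + softmax readout; small enough to train
    # with lbfgs on a few hundred tones
    return MLPClassifier(hidden_layer_sizes=(16, 8), activation="relu",
                         solver="lbfgs", max_iter=600, random_state=seed)


def _event_folds(event_id: np.ndarray, n_folds: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Sample indices per fold, all tones of an event staying together."""
    events = np.unique(event_id)
    perm = rng.permutation(events)
    return [np.flatnonzero(np.isin(event_id, chunk))
            for chunk in np.array_split(perm, n_folds)]


def train_eval(X: np.ndarray, y: np.ndarray, event_id: np.ndarray,
               feature_sets: dict[str, np.ndarray], n_folds: int = 10,
               seed: int = 0, max_refolds: int = 10) -> PredictionResult:
    """Event-grouped cross-validated ROC AUC per feature set.

    ``feature_sets`` maps a name ('gamma', 'locking', 'both') to column
    indices. Folds are drawn over events so that the before/after tones of
    one event never straddle the train/test split; folds with a
    single-class training set trigger a reseeded refold (logged).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_refolds):
        folds = _event_folds(event_id, n_folds, rng)
        ok = all(len(np.unique(y[np.setdiff1d(np.arange(len(y)), f)])) == 2
                 for f in folds if len(f))
        if ok:
            break
        log.info("single-class training fold; refolding (attempt %d)", attempt)
    fold_aucs: dict[str, list[float]] = {k: [] for k in feature_sets}
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = \
        {k: [] for k in feature_sets}
    for f in folds:
        if len(f) == 0 or len(np.unique(y[f])) < 2:
            continue
        train = np.setdiff1d(np.arange(len(y)), f)
        for name, cols in feature_sets.items():
            scaler = StandardScaler().fit(X[np.ix_(train, cols)])
            net = _make_net(seed)
            net.fit(scaler.transform(X[np.ix_(train, cols)]), y[train])
            scores = net.predict_proba(scaler.transform(X[np.ix_(f, cols)]))[:, 1]
            fold_aucs[name].append(roc_auc_score(y[f], scores))
            pooled[name].append((y[f], scores))
    mean_auc = {k: float(np.mean(v)) for k, v in fold_aucs.items()}
    pooled_auc = {}
    for k, parts in pooled.items():
        yy = np.concatenate([p[0] for p in parts])
        ss = np.concatenate([p[1] for p in parts])
        pooled_auc[k] = float(roc_auc_score(yy, ss))
    return PredictionResult({k: np.asarray(v) for k, v in fold_aucs.items()},
                            mean_auc, pooled_auc)


def default_feature_sets(table: dict[str, object]) -> dict[str, np.ndarray]:
    g = np.asarray(table["gamma_cols"])
    l = np.asarray(table["lock_cols"])
    return {"gamma": g, "locking": l, "both": np.concatenate([g, l])}


def noise_floor(X: np.ndarray, y: np.ndarray, event_id: np.ndarray,
                feature_sets: dict[str, np.ndarray], n_shuffles: int = 10,
                n_folds: int = 10, seed: int = 0) -> dict[str, object]:
    """Label-shuffled AUC distribution (classification noise floor).

    Labels are permuted at the event level, the networks retrained, and
    the mean AUCs collected; the spread is max - min of the mean AUCs per
    feature set across shuffles.
    """
    rng = np.random.default_rng(seed)
    aucs: dict[str, list[float]] = {k: [] for k in feature_sets}
    for i in range(n_shuffles):
        # shuffle the before/after label across tones, breaking its
        # correspondence with the neural features; folds stay event-grouped
        y_shuf = rng.permutation(y)
        res = train_eval(X, y_shuf, event_id, feature_sets, n_folds,
                         seed=seed + 1 + i)
        for k, v in res.mean_auc.items():
            aucs[k].append(v)
    return {
        "aucs": {k: np.asarray(v) for k, v in aucs.items()},
        "mean": {k: float(np.mean(v)) for k, v in aucs.items()},
        "spread": {k: float(np.max(v) - np.min(v)) for k, v in aucs.items()},
    }


# ---------------------------------------------------------------------------
# interaction information
# ---------------------------------------------------------------------------

def _mi_from_joint(p: np.ndarray, axes_a: tuple[int, ...],
                   axes_b: tuple[int, ...]) -> float:
    """Mutual information (bits) between two variable groups of a joint pmf."""
    p = np.asarray(p, float)
    p = p / p.sum()
    pa = p.sum(axis=axes_b)
    pb = p.sum(axis=axes_a)
    # I = sum p log p(ab) / (p(a) p(b)); iterate over the flattened support
    idx = np.argwhere(p > 0)
    total = 0.0
    for k in idx:
        pab = p[tuple(k)]
        ia = tuple(k[list(set(range(p.ndim)) - set(axes_b))])
        ib = tuple(k[list(set(range(p.ndim)) - set(axes_a))])
        total += pab * np.log2(pab / (pa[ia] * pb[ib]))
    return float(total)


def interaction_information(f1: np.ndarray, f2: np.ndarray, s: np.ndarray,
                            bins: int = 8) -> dict[str, float]:
    """Plug-in interaction information I(F1,F2;S) - I(F1;S) - I(F2;S), bits.

    Continuous features are discretized into equal-frequency bins; a
    constant feature contributes zero marginal information. Positive
    values indicate synergy (the features are complementary about the
    label), negative values redundancy.
    """
    f1b = _discretize(np.asarray(f1), bins)
    f2b = _discretize(np.asarray(f2), bins)
    sb = _discretize(np.asarray(s), bins)
    joint = _joint_pmf(f1b, f2b, sb)
    return interaction_information_from_pmf(joint)


def interaction_information_from_pmf(p: np.ndarray) -> dict[str, float]:
    """Exact interaction information of a finite joint pmf p[f1, f2, s]."""
    i_12s = _mi_from_joint(p, (0, 1), (2,))
    i_1s = _mi_from_joint(p.sum(axis=1), (0,), (1,))
    i_2s = _mi_from_joint(p.sum(axis=0), (0,), (1,))
    return {"I_f1f2_s": i_12s, "I_f1_s": i_1s, "I_f2_s": i_2s,
            "interaction": i_12s - i_1s - i_2s}


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    if np.issubdtype(x.dtype, np.integer) or len(np.unique(x)) <= bins:
        _, inv = np.unique(x, return_inverse=True)
        return inv
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _joint_pmf(*codes: np.ndarray) -> np.ndarray:
    dims = [int(c.max()) + 1 for c in codes]
    p = np.zeros(dims)
    np.add.at(p, tuple(codes), 1.0)
    return p / p.sum()
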