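"""Behavioral scoring and the shared statistical toolkit.

Detection scoring matches each target to at most one response 200-800 ms
after tone onset; the signed error of a scene is the reported minus the
actual target count, a proxy for top-down attentional focus. The test
suite used across the pipeline wraps paired/two-sample t-tests, one-way
ANOVA with Tukey HSD, and a default-prior (JZS) Bayes factor used to
support null results (BF10 < 0.33).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

HIT_WINDOW = (0.2, 0.8)
NEAR_WINDOW = (0.25, 1.25)
FAR_GAP = 4.0
BF_NULL_THRESHOLD = 1.0 / 3.0


@dataclass
class BehaviorScore:
    hits: int
    misses: int
    false_alarms: int
    accuracy: float                  # percent
    signed_error: int                # detected - actual
    matches: list[tuple[float, float]] = field(default_factory=list)


def score_detection(target_times: np.ndarray, response_times: np.ndarray,
                    window: tuple[float, float] = HIT_WINDOW) -> BehaviorScore:
    """Greedy earliest-response matching of targets to key presses.

    A target is a hit when some unmatched response falls 200-800 ms after
    its onset; each response can serve one target (the earliest response in
    the window wins; extra in-window responses are logged). Responses that
    match no target are false alarms.
    """
    targets = np.sort(np.asarray(target_times, float))
    responses = np.sort(np.asarray(response_times, float))
    used = np.zeros(len(responses), dtype=bool)
    matches = []
    for t0 in targets:
        rel = responses - t0
        ok = np.flatnonzero((rel >= window[0]) & (rel <= window[1]) & ~used)
        if len(ok):
            if len(ok) > 1:
                log.info("target %.2f s: %d candidate responses, "
                         "earliest wins", t0, len(ok))
            used[ok[0]] = True
            matches.append((float(t0), float(responses[ok[0]])))
    hits = len(matches)
    n_t = len(targets)
    fa = int((~used).sum())
    acc = 100.0 * hits / n_t if n_t else float("nan")
    signed = (hits + fa) - n_t
    return BehaviorScore(hits, n_t - hits, fa, acc, signed, matches)


def post_event_grouping(target_times: np.ndarray, event_times: np.ndarray,
                        near: tuple[float, float] = NEAR_WINDOW,
                        far_gap: float = FAR_GAP) -> list[str]:
    """Label each target 'near' (0.25-1.25 s after an event), 'far'
    (more than 4 s after every event, i.e. unlikely to be affected), or
    'unused' (anything in between)."""
    ev = np.asarray(event_times, float)
    labels = []
    for t0 in np.asarray(target_times, float):
        rel = t0 - ev if len(ev) else np.empty(0)
        post = rel[rel >= 0]
        if len(post) and np.any((post >= near[0]) & (post <= near[1])):
            labels.append("near")
        elif len(post) == 0 or post.min() > far_gap:
            labels.append("far")
        else:
            labels.append("unused")
    return labels


# ---------------------------------------------------------------------------
# statistical test suite
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    return "**" if p <= 0.01 else ("*" if p <= 0.05 else "")


def paired_t(x: np.ndarray, y: np.ndarray | float = 0.0) -> dict[str, float | str]:
    """Paired (or one-sample, when y is scalar) t-test with exact dof."""
    x = np.asarray(x, float)
    d = x - y if np.isscalar(y) else x - np.asarray(y, float)
    if len(d) < 3:
        raise ValueError("need n >= 3")
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return {"t": 0.0, "df": len(d) - 1, "p": 1.0, "sig": ""}
        raise ValueError("zero variance with nonzero mean")
    t, p = stats.ttest_1samp(d, 0.0)
    return {"t": float(t), "df": len(d) - 1, "p": float(p), "sig": _stars(p)}


def two_sample_t(x: np.ndarray, y: np.ndarray) -> dict[str, float | str]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 per group")
    t, p = stats.ttest_ind(x, y)
    return {"t": float(t), "df": len(x) + len(y) - 2, "p": float(p),
            "sig": _stars(p)}


def anova_tukey(groups: dict[str, np.ndarray]) -> dict[str, object]:
    """One-way ANOVA plus Tukey HSD over named groups."""
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("need n >= 3 per group")
    if all(a.std() == 0 for a in arrays) and \
            len({a.mean() for a in arrays}) == 1:
        raise ValueError("zero variance in every group")
    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"a": names[i], "b": names[j],
                         "diff": float(arrays[i].mean() - arrays[j].mean()),
                         "p": float(tk.pvalue[i, j]),
                         "sig": _stars(float(tk.pvalue[i, j]))})
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    return {"F": float(f), "df_between": k - 1, "df_within": n_total - k,
            "p": float(p), "sig": _stars(float(p)),
            "tukey": pd.DataFrame(rows)}


def bayes_factor_null(t_stat: float, n: int) -> dict[str, float | bool]:
    """JZS Bayes factor BF10 for a one-sample/paired t statistic.

    Uses the default Cauchy prior on effect size (scale 0.707). BF10 below
    1/3 is flagged as positive support for the null.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    import pingouin
    bf = float(pingouin.bayesfactor_ttest(t_stat, n, paired=True))
    return {"bf10": bf, "supports_null": bf < BF_NULL_THRESHOLD}
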