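"""Source imaging and network-overlap analysis.

sLORETA source estimation on a supplied leadfield, per-voxel gamma time
courses, unique-voxel masking against control activations, and cross-lag
sparse non-negative CCA with permutation inference quantifying the overlap
of bottom-up (salient-event) and top-down (target) activation networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import Leadfield

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sLORETA
# ---------------------------------------------------------------------------

def default_alpha(leadfield: Leadfield, scale: float = 1e-2) -> float:
    L = leadfield.gain
    return float(np.trace(L @ L.T) / L.shape[0] * scale)


def sloreta(leadfield: Leadfield, sensor_data: np.ndarray,
            alpha: float | None = None) -> np.ndarray:
    """Standardized minimum-norm source estimate.

    J = L' (L L' + alpha I)^-1 v, with each source standardized by the
    square root of the corresponding diagonal of the resolution operator
    R = L' (L L' + alpha I)^-1 L. The standardization removes the depth
    bias of the minimum-norm estimate; in the noiseless single-source case
    the standardized power peaks exactly at the true source.

    ``sensor_data`` may be (n_channels,) or (n_channels, n_times); the
    result has voxels on the first axis.
    """
    L = leadfield.gain
    if alpha is None:
        alpha = default_alpha(leadfield)
    M = L @ L.T + alpha * np.eye(L.shape[0])
    if alpha <= 0 and np.linalg.matrix_rank(M) < M.shape[0]:
        raise np.linalg.LinAlgError(
            "rank-deficient sensor covariance; use alpha > 0")
    Minv = np.linalg.inv(M)
    T = L.T @ Minv                                   # v x c
    j = T @ np.atleast_2d(sensor_data.T).T if sensor_data.ndim > 1 \
        else T @ sensor_data
    res_diag = np.einsum("vc,cw,wv->v", L.T, Minv, L)
    denom = np.sqrt(np.clip(res_diag, 1e-30, None))
    if j.ndim == 1:
        return j / denom
    return j / denom[:, None]


def source_gamma(source_ts: np.ndarray, fs: float, win: float = 0.5,
                 step: float = 0.2,
                 band: tuple[float, float] = (70.0, 110.0)
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel z-scored gamma power time course of one trial.

    70-110 Hz mean power in 500 ms windows at 200 ms steps, z-scored
    across windows per voxel. Returns (window_centers_s, z) with z shaped
    (n_voxels, n_windows). Scaling the input leaves the z-scores unchanged.
    """
    v, n = source_ts.shape
    n_win = int(round(win * fs))
    n_step = max(int(round(step * fs)), 1)
    if n_win > n:
        raise ValueError("trial shorter than the analysis window")
    starts = np.arange(0, n - n_win + 1, n_step)
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    taper = np.hanning(n_win)
    power = np.empty((v, len(starts)))
    for j, s0 in enumerate(starts):
        spec = np.abs(np.fft.rfft(source_ts[:, s0:s0 + n_win] * taper,
                                  axis=1)) ** 2
        power[:, j] = spec[:, m].mean(axis=1)
    mu = power.mean(axis=1, keepdims=True)
    sd = power.std(axis=1, keepdims=True)
    z = (power - mu) / np.where(sd > 0, sd, 1.0)
    centers = (starts + n_win / 2) / fs
    return centers, z


def unique_voxels(x_cond: np.ndarray, x_ctrl: np.ndarray,
                  p: float = 0.005) -> tuple[np.ndarray, np.ndarray]:
    """Zero out voxels not uniquely activated relative to control.

    Voxel-wise paired t-test (condition vs control across matched trials)
    at significance ``p`` with Bonferroni correction over voxels; columns
    that do not differ are set to zero. Returns (masked maps, keep mask).
    """
    x_cond = np.asarray(x_cond, float)
    x_ctrl = np.asarray(x_ctrl, float)
    if x_cond.shape != x_ctrl.shape:
        raise ValueError("condition and control maps must be matched")
    n, v = x_cond.shape
    if n < 3:
        raise ValueError("need at least 3 matched trials")
    diff = x_cond - x_ctrl
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_rel(x_cond, x_ctrl, axis=0)
    pvals = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    pvals = np.where(diff.std(axis=0) == 0, 1.0, pvals)
    keep = pvals < (p / v)
    masked = x_cond.copy()
    masked[:, ~keep] = 0.0
    return masked, keep


# ---------------------------------------------------------------------------
# sparse non-negative CCA
# ---------------------------------------------------------------------------

@dataclass
class CanonicalPair:
    w1: np.ndarray
    w2: np.ndarray
    q: float
    penalty: float = 0.0
    p: float | None = None
    lags: tuple[float, float] | None = None


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def _project(V: np.ndarray, frac: float | np.ndarray,
             nonneg: bool) -> np.ndarray:
    """Soft-threshold (at ``frac`` of the per-row max) and L2-normalize.

    ``frac`` may be a scalar or a per-row array. With ``nonneg``, each row
    is first folded onto whichever half-space (v or -v, clipped at zero)
    carries more energy -- the overall sign of a canonical pair is
    arbitrary while the weights stay non-negative. Rows that vanish
    entirely stay zero.
    """
    V = np.atleast_2d(V)
    frac = np.asarray(frac, float).reshape(-1, 1) if np.ndim(frac) else frac
    if nonneg:
        vp = np.maximum(V, 0.0)
        vn = np.maximum(-V, 0.0)
        use_n = np.einsum("bp,bp->b", vn, vn) > np.einsum("bp,bp->b", vp, vp)
        V = np.where(use_n[:, None], vn, vp)
        V = np.maximum(V - frac * V.max(axis=1, keepdims=True), 0.0)
    else:
        mag = np.abs(V)
        V = np.sign(V) * np.maximum(mag - frac * mag.max(axis=1, keepdims=True),
                                    0.0)
    nrm = np.sqrt(np.einsum("bp,bp->b", V, V))[:, None]
    return V / np.where(nrm > 0, nrm, 1.0)


def _scca_core(C: np.ndarray, S1: np.ndarray, S2: np.ndarray,
               frac: float | np.ndarray, nonneg: bool,
               max_iter: int = 200, tol: float = 1e-6
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating soft-thresholded power iterations, batched over axis 0.

    C is (B, p1, p2) cross-covariance (``frac`` may vary per batch item);
    S1 (p1, p1) and S2 (p2, p2) are the shared within-set covariances (row
    permutations leave them unchanged), used only to report q as a true
    correlation of the projections.
    """
    B, p1, p2 = C.shape
    w2 = _project(np.sqrt((C ** 2).sum(axis=1)), 0.0, False)
    w1 = np.zeros((B, p1))
    w2_old = w2
    for it in range(max_iter):
        w1 = _project(np.matmul(C, w2[:, :, None])[:, :, 0], frac, nonneg)
        w2 = _project(np.matmul(w1[:, None, :], C)[:, 0, :], frac, nonneg)
        # unit-norm weight change bounds the change of the objective, so
        # this is a cheap proxy for the q-change stopping rule
        if it and float(np.abs(w2 - w2_old).max()) < tol:
            break
        w2_old = w2
    return w1, w2, _q_of(C, S1, S2, w1, w2)


def _q_of(C: np.ndarray, S1: np.ndarray, S2: np.ndarray,
          w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    num = np.einsum("bp,bpq,bq->b", w1, C, w2)
    v1 = np.einsum("bp,pq,bq->b", w1, S1, w1)
    v2 = np.einsum("bp,pq,bq->b", w2, S2, w2)
    denom = np.sqrt(np.clip(v1 * v2, 1e-30, None))
    q = num / denom
    return np.clip(q, 0.0, 1.0)


def sparse_cca(X1: np.ndarray, X2: np.ndarray, penalty: float = 0.3,
               nonneg: bool = True, standardize: bool = True,
               max_iter: int = 200, tol: float = 1e-6) -> CanonicalPair:
    """Leading sparse (non-negative) canonical pair of two data matrices.

    Maximizes w1' X1' X2 w2 with unit-norm weights, an L1-type penalty
    (soft threshold at ``penalty`` x the largest weight magnitude; 0 means
    unpenalized) and optional non-negativity, by alternating power
    iterations; the reported q is the Pearson correlation of the two
    projections at the optimizing weights. Within-set covariances are
    treated as identity during the maximization, as is standard for
    high-dimensional sparse CCA.
    """
    X1s = _standardize(X1) if standardize else np.asarray(X1, float)
    X2s = _standardize(X2) if standardize else np.asarray(X2, float)
    if X1s.shape[0] != X2s.shape[0]:
        raise ValueError("X1 and X2 must have the same number of rows")
    if not np.any(X1s) or not np.any(X2s):
        return CanonicalPair(np.zeros(X1s.shape[1]), np.zeros(X2s.shape[1]),
                             0.0, penalty)
    C = (X1s.T @ X2s)[None]
    w1, w2, q = _scca_core(C, X1s.T @ X1s, X2s.T @ X2s, penalty, nonneg,
                           max_iter, tol)
    return CanonicalPair(w1[0], w2[0], float(q[0]), penalty)


def permutation_scca(X1: np.ndarray, X2: np.ndarray, n_perm: int = 500,
                     penalty_grid: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9),
                     nonneg: bool = True,
                     rng: np.random.Generator | int | None = None,
                     max_iter: int = 25, tol: float = 1e-6
                     ) -> CanonicalPair:
    """Penalty selection and significance by row permutation.

    Rows of X1 are permuted independently of X2 (identity permutation
    excluded). For every penalty on the grid the observed q is reduced to
    a z-score against the permuted q distribution at that penalty; the
    penalty with the largest z is selected. Significance accounts for that
    selection: each permutation is itself reduced to its maximum z over
    the penalty grid (its q values entering the z-scores of the remaining
    permutations), and p = (1 + #{max-z_perm >= max-z_obs}) / (1 + n_perm),
    which is positive and conservative under the null by construction.
    """
    if n_perm < 200:
        log.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    rng = np.random.default_rng(rng)
    X1s, X2s = _standardize(X1), _standardize(X2)
    n = X1s.shape[0]
    if not np.any(X1s) or not np.any(X2s):
        return CanonicalPair(np.zeros(X1s.shape[1]), np.zeros(X2s.shape[1]),
                             0.0, penalty_grid[0], p=1.0)
    S1, S2 = X1s.T @ X1s, X2s.T @ X2s
    perms = np.empty((n_perm, n), dtype=int)
    for b in range(n_perm):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)):
                break
        perms[b] = perm
    # one batched solve over (penalty x [observed + permutations])
    n_grid = len(penalty_grid)
    block = 1 + n_perm
    C_one = np.concatenate([(X1s.T @ X2s)[None],
                            np.matmul(np.swapaxes(X1s[perms], 1, 2), X2s)])
    C_all = np.ascontiguousarray(
        np.broadcast_to(C_one, (n_grid,) + C_one.shape)
    ).reshape(n_grid * block, *C_one.shape[1:])
    frac_all = np.repeat(np.asarray(penalty_grid, float), block)
    w1a, w2a, qa = _scca_core(C_all, S1, S2, frac_all, nonneg, max_iter, tol)
    qa = qa.reshape(n_grid, block)
    q_obs, q_perm = qa[:, 0], qa[:, 1:]
    mu = q_perm.mean(axis=1)
    sd = np.maximum(q_perm.std(axis=1), 1e-12)
    z_obs = (q_obs - mu) / sd
    z_perm = (q_perm - mu[:, None]) / sd[:, None]
    k_best = int(np.argmax(z_obs))
    max_z_perm = z_perm.max(axis=0)
    p = (1.0 + int(np.sum(max_z_perm >= z_obs[k_best]))) / (1.0 + n_perm)
    row = k_best * block
    return CanonicalPair(w1a[row], w2a[row], float(q_obs[k_best]),
                         penalty_grid[k_best], p=p)


# ---------------------------------------------------------------------------
# lag grid
# ---------------------------------------------------------------------------

@dataclass
class LagGrid:
    """Canonical correlation and significance over all lag pairs.

    Axis 0 indexes the bottom-up (salient) lag, axis 1 the top-down
    (target) lag.
    """

    lags_s: np.ndarray
    lags_t: np.ndarray
    q: np.ndarray
    p: np.ndarray
    pairs: dict[tuple[int, int], CanonicalPair] = field(default_factory=dict)
    p_threshold: float = 0.005

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.p_threshold

    def peak_offset(self) -> float:
        """Off-diagonal lag (target minus salient) of the significant
        region's center: the time by which bottom-up activity leads.

        Computed as the q-weighted centroid over significant cells, which
        is robust when q saturates over a plateau of cells.
        """
        sig = self.significant
        if not sig.any():
            return float("nan")
        w = np.where(sig, self.q, 0.0)
        off = self.lags_t[None, :] - self.lags_s[:, None]
        return float((w * off).sum() / w.sum())

    def peak_cell(self) -> tuple[int, int]:
        qs = np.where(self.significant, self.q, -np.inf)
        i, j = np.unravel_index(np.argmax(qs), qs.shape)
        return int(i), int(j)

    def vectors_at(self, i: int, j: int) -> CanonicalPair:
        return self.pairs[(i, j)]


def lag_grid(maps_s: np.ndarray, maps_t: np.ndarray, lags: np.ndarray,
             n_perm: int = 200,
             penalty_grid: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9),
             nonneg: bool = True,
             rng: np.random.Generator | int | None = None,
             p_threshold: float = 0.005) -> LagGrid:
    """Sparse CCA with permutation inference at every lag pair.

    ``maps_s`` and ``maps_t`` are (n_lags, n_subjects, n_voxels) masked
    activation maps for the salient-event and target conditions. Cells with
    an empty (all-zero) map at either lag record q = 0, p = 1.
    """
    rng = np.random.default_rng(rng)
    L = maps_s.shape[0]
    q = np.zeros((L, L))
    p = np.ones((L, L))
    pairs: dict[tuple[int, int], CanonicalPair] = {}
    for i in range(L):
        for j in range(L):
            pair = permutation_scca(maps_s[i], maps_t[j], n_perm,
                                    penalty_grid, nonneg, rng)
            pair.lags = (float(lags[i]), float(lags[j]))
            q[i, j], p[i, j] = pair.q, pair.p
            pairs[(i, j)] = pair
    return LagGrid(np.asarray(lags, float), np.asarray(lags, float),
                   q, p, pairs, p_threshold)
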