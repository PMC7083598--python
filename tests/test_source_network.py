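"""Source imaging, voxel masking, and sparse CCA with permutation
inference."""

import numpy as np
import pytest

from salieeg.simulate import gen_leadfield, gen_network_maps
from salieeg.source_network import (default_alpha, lag_grid,
                                    permutation_scca, sloreta, source_gamma,
                                    sparse_cca, unique_voxels)


class TestSloreta:
    @pytest.fixture(scope="class")
    def lf(self):
        return gen_leadfield(32, 200, seed=0)

    def test_zero_localization_error_for_every_source(self, lf):
        for s in range(lf.n_voxels):
            j = sloreta(lf, lf.gain[:, s])
            assert int(np.argmax(j ** 2)) == s

    def test_zero_sensor_data_gives_zero_sources(self, lf):
        assert not sloreta(lf, np.zeros(32)).any()

    def test_two_equal_sources_map_symmetrically(self, lf):
        v = lf.gain[:, 10] + lf.gain[:, 90]
        j = sloreta(lf, v) ** 2
        top2 = set(np.argsort(j)[-2:])
        assert top2 == {10, 90}

    def test_time_series_input_shape(self, lf):
        data = np.random.default_rng(0).standard_normal((32, 50))
        assert sloreta(lf, data).shape == (200, 50)


class TestSourceGamma:
    def test_zscore_contract_on_stationary_noise(self, rng):
        ts = rng.standard_normal((10, 2560))
        _, z = source_gamma(ts, fs=256.0)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_burst_peaks_at_its_window(self, rng):
        from scipy import signal as sps
        fs = 256.0
        ts = 0.1 * rng.standard_normal((3, 2560))
        sos = sps.butter(4, [70, 110], btype="band", fs=fs, output="sos")
        burst = sps.sosfiltfilt(sos, rng.standard_normal(2560))
        ts[1, int(1.0 * fs):int(1.5 * fs)] += 3 * burst[int(1.0 * fs):int(1.5 * fs)]
        centers, z = source_gamma(ts, fs)
        assert abs(centers[np.argmax(z[1])] - 1.25) < 0.3

    def test_scaling_invariance(self, rng):
        ts = rng.standard_normal((4, 2000))
        _, z1 = source_gamma(ts, 256.0)
        _, z2 = source_gamma(7.0 * ts, 256.0)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_short_trial_errors(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            source_gamma(rng.standard_normal((2, 50)), 256.0)


class TestUniqueVoxels:
    def test_identical_maps_fully_masked(self, rng):
        x = rng.standard_normal((10, 30))
        masked, keep = unique_voxels(x, x.copy())
        assert not keep.any()
        assert not masked.any()

    def test_planted_active_voxels_recovered(self):
        hits, false = [], []
        for seed in range(50):
            r = np.random.default_rng(seed)
            xc = r.standard_normal((24, 200))
            xk = r.standard_normal((24, 200))
            active = r.choice(200, 20, replace=False)
            xc[:, active] += 3.0
            _, keep = unique_voxels(xc, xk)
            hits.append(np.isin(active, np.flatnonzero(keep)).sum())
            false.append(int(keep.sum()) - hits[-1])
        assert min(hits) >= 18
        assert max(false) <= 1

    def test_masking_is_idempotent(self, rng):
        xc = rng.standard_normal((12, 40))
        xk = rng.standard_normal((12, 40))
        m1, _ = unique_voxels(xc, xk)
        m2, _ = unique_voxels(m1, xk)
        np.testing.assert_array_equal(m1, m2)

    def test_too_few_trials_error(self, rng):
        with pytest.raises(ValueError, match="3"):
            unique_voxels(rng.standard_normal((2, 5)),
                          rng.standard_normal((2, 5)))


class TestSparseCCA:
    def test_one_dimensional_inputs_reduce_to_pearson_r(self, rng):
        x = rng.standard_normal((80, 1))
        y = 0.6 * x + 0.8 * rng.standard_normal((80, 1))
        pair = sparse_cca(x, y, penalty=0.0)
        r = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert pair.q == pytest.approx(r, abs=1e-10)

    def test_self_correlation_approaches_one(self, rng):
        x = rng.standard_normal((40, 10))
        pair = sparse_cca(x, x.copy(), penalty=0.0)
        assert pair.q > 0.999

    def test_matches_full_cca_on_whitened_small_problem(self, rng):
        n, p = 60, 5
        X1 = rng.standard_normal((n, p))
        X2 = 0.8 * X1 @ rng.standard_normal((p, p)) \
            + 0.2 * rng.standard_normal((n, p))

        def whiten(X):
            X = X - X.mean(0)
            U, _, _ = np.linalg.svd(X, full_matrices=False)
            return U * np.sqrt(n - 1)

        Qa, _ = np.linalg.qr(X1 - X1.mean(0))
        Qb, _ = np.linalg.qr(X2 - X2.mean(0))
        q_oracle = np.linalg.svd(Qa.T @ Qb, compute_uv=False)[0]
        pair = sparse_cca(whiten(X1), whiten(X2), penalty=0.0, nonneg=False,
                          standardize=False, max_iter=2000, tol=1e-12)
        assert pair.q == pytest.approx(q_oracle, abs=1e-6)

    def test_all_zero_input_returns_zero_pair(self):
        pair = sparse_cca(np.zeros((10, 4)), np.zeros((10, 4)))
        assert pair.q == 0.0 and not pair.w1.any()

    def test_sparsity_monotone_in_penalty(self, rng):
        x = rng.standard_normal((30, 25))
        y = rng.standard_normal((30, 25))
        nnz = [int((sparse_cca(x, y, penalty=p).w1 > 0).sum())
               for p in (0.0, 0.3, 0.6, 0.9)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))
        assert 0.0 <= sparse_cca(x, y, penalty=0.5).q <= 1.0

    def test_nonneg_weights_are_nonnegative(self, rng):
        pair = sparse_cca(rng.standard_normal((20, 15)),
                          rng.standard_normal((20, 15)), penalty=0.4)
        assert (pair.w1 >= 0).all() and (pair.w2 >= 0).all()


class TestPermutationScca:
    def test_planted_shared_component_maximally_significant(self, rng):
        z = rng.standard_normal(20)
        X1 = np.outer(z, rng.uniform(0.5, 1, 10)) \
            + 0.3 * rng.standard_normal((20, 10))
        X2 = np.outer(z, rng.uniform(0.5, 1, 12)) \
            + 0.3 * rng.standard_normal((20, 12))
        res = permutation_scca(X1, X2, n_perm=200, rng=rng)
        assert res.p == pytest.approx(1.0 / 201.0)

    def test_p_value_strictly_positive(self, rng):
        res = permutation_scca(rng.standard_normal((10, 5)),
                               rng.standard_normal((10, 5)),
                               n_perm=200, rng=rng)
        assert res.p >= 1.0 / 201.0

    def test_all_zero_maps_yield_null_result(self):
        res = permutation_scca(np.zeros((10, 4)), np.zeros((10, 4)),
                               n_perm=200)
        assert res.q == 0.0 and res.p == 1.0


class TestLagGrid:
    def test_planted_lead_recovered_with_voxel_hits(self):
        maps = gen_network_maps(seed=3, n_voxels=60)
        grid = lag_grid(maps["S"], maps["T"], maps["lags"], n_perm=200,
                        rng=3)
        assert grid.significant.any()
        assert abs(grid.peak_offset() - maps["lead"]) <= 0.25
        i, j = grid.peak_cell()
        pair = grid.vectors_at(i, j)
        support = np.union1d(np.flatnonzero(pair.w1 > 0),
                             np.flatnonzero(pair.w2 > 0))
        assert np.isin(maps["shared_voxels"], support).mean() >= 0.9

    def test_empty_maps_record_q0_p1(self):
        lags = np.array([0.0, 0.25])
        zero = np.zeros((2, 8, 10))
        grid = lag_grid(zero, zero, lags, n_perm=200)
        assert (grid.q == 0).all() and (grid.p == 1).all()
        assert np.isnan(grid.peak_offset())


def test_default_alpha_positive():
    lf = gen_leadfield(16, 40, seed=1)
    assert default_alpha(lf) > 0
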