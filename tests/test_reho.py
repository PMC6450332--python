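import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from neoreho import fisher_z, kendall_w, mean_pairwise_tau, reho_map, tau_to_pearson
from neoreho.reho import neighborhood_kernel

from conftest import kendall_w_oracle


class TestKendallW:
    def test_perfect_concordance(self):
        base = np.arange(10, dtype=float)
        assert kendall_w(np.stack([base, base, base])) == pytest.approx(1.0)

    def test_reversed_rankings_cancel(self):
        ts = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert kendall_w(ts) == pytest.approx(0.0, abs=1e-15)

    def test_two_vs_one_disagreement(self):
        ts = np.array([[1, 2, 3], [1, 2, 3], [3, 2, 1]], dtype=float)
        assert kendall_w(ts) == pytest.approx(1 / 9)

    def test_degenerate_all_constant(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(kendall_w(np.ones((3, 5))))

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            kendall_w(np.ones((1, 5)))
        with pytest.raises(ValueError):
            kendall_w(np.array([[1.0, np.nan], [1.0, 2.0]]))

    @given(st.integers(0, 2**31 - 1), st.integers(2, 10), st.integers(2, 12), st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_oracle(self, seed, m, n, with_ties):
        rng = np.random.default_rng(seed)
        ts = rng.integers(0, 4, size=(m, n)).astype(float) if with_ties else rng.standard_normal((m, n))
        w = kendall_w(ts)
        expected = kendall_w_oracle(ts)
        if np.isnan(expected):
            assert np.isnan(w)
        else:
            assert w == pytest.approx(expected, abs=1e-12)


class TestTransforms:
    @pytest.mark.parametrize("tau,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, np.sin(np.pi / 4))])
    def test_greiner_relation(self, tau, expected):
        assert tau_to_pearson(tau) == pytest.approx(expected, abs=1e-12)

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            tau_to_pearson(1.5)

    def test_fisher_z_values_and_symmetry(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.7071) == pytest.approx(np.arctanh(0.7071))
        for r in (0.3, 0.9, 0.99):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r))
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)
        with pytest.raises(ValueError):
            fisher_z(np.nan)

    def test_transform_chain_is_monotone_in_w(self):
        w = np.linspace(0.01, 0.99, 50)
        z_literal = np.arctanh(tau_to_pearson(w))
        assert (np.diff(z_literal) > 0).all()
        m = 27
        r_spear = (m * w - 1) / (m - 1)
        assert (np.diff(np.arctanh(r_spear)) > 0).all()


class TestReHoMap:
    def test_identical_series_gives_full_concordance(self):
        series = np.random.default_rng(0).standard_normal(60)
        data = np.broadcast_to(series, (8, 8, 8, 60)).copy()
        rh = reho_map(data, np.ones((8, 8, 8), bool))
        assert np.nanmin(rh.w) == pytest.approx(1.0)

    def test_corner_neighborhood_size(self):
        data = np.random.default_rng(0).standard_normal((6, 6, 6, 30))
        rh = reho_map(data, np.ones((6, 6, 6), bool))
        assert rh.m_used[0, 0, 0] == 8
        assert rh.m_used[3, 3, 3] == 27
        rh6 = reho_map(data, np.ones((6, 6, 6), bool), neighborhood=6)
        assert rh6.m_used[3, 3, 3] == 7

    def test_white_noise_mean_w_near_independence_limit(self):
        rng = np.random.default_rng(42)
        data = rng.standard_normal((18, 18, 18, 120))
        rh = reho_map(data, np.ones((18, 18, 18), bool))
        interior = rh.m_used == 27
        assert np.nanmean(rh.w[interior]) == pytest.approx(1 / 27, abs=2e-3)

    def test_map_agrees_with_scalar_kendall_w(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 5, 5, 20))
        mask = rng.random((5, 5, 5)) > 0.3
        mask[2, 2, 2] = True
        rh = reho_map(data, mask)
        kernel = neighborhood_kernel(26)
        offs = np.argwhere(kernel > 0) - 1
        for idx in np.argwhere(mask):
            nbrs = [
                data[tuple(p)]
                for p in (idx + offs)
                if (p >= 0).all() and (p < 5).all() and mask[tuple(p)]
            ]
            if len(nbrs) >= 2:
                assert rh.w[tuple(idx)] == pytest.approx(kendall_w(np.asarray(nbrs)), abs=1e-10)
            else:
                assert np.isnan(rh.w[tuple(idx)])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((7, 7, 7, 30))
        mask = np.ones((7, 7, 7), bool)
        w1 = reho_map(data, mask).w
        w2 = reho_map(np.exp(2.0 * data) + 5.0, mask).w
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_smoothing_increases_median_w(self):
        rng = np.random.default_rng(11)
        noise = rng.standard_normal((16, 16, 16, 60))
        mask = np.ones((16, 16, 16), bool)
        medians = []
        for fwhm in (0.0, 1.0, 2.0):
            sigma = fwhm / 2.3548
            data = noise if fwhm == 0 else ndimage.gaussian_filter(noise, (sigma, sigma, sigma, 0))
            medians.append(float(np.nanmedian(reho_map(data, mask).w)))
        assert medians[0] < medians[1] < medians[2]

    def test_nan_outside_mask_and_grid_mismatch(self):
        data = np.random.default_rng(0).standard_normal((6, 6, 6, 20))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:5, 2:5, 2:5] = True
        rh = reho_map(data, mask)
        for arr in (rh.w, rh.tau, rh.r, rh.z, rh.m_used):
            assert np.isnan(arr[~mask]).all()
            assert np.isfinite(arr[mask]).all()
        with pytest.raises(ValueError, match="grid"):
            reho_map(data, np.ones((5, 6, 6), bool))

    def test_conversion_modes_are_consistent(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((6, 6, 6, 25))
        mask = np.ones((6, 6, 6), bool)
        lit = reho_map(data, mask, mode="literal")
        spear = reho_map(data, mask, mode="mean_spearman")
        mtau = reho_map(data, mask, mode="mean_tau")
        np.testing.assert_allclose(lit.w, spear.w, atol=1e-12)
        np.testing.assert_allclose(lit.r[mask], np.sin(np.pi * lit.w[mask] / 2), atol=1e-12)
        m = spear.m_used[mask]
        np.testing.assert_allclose(spear.tau[mask], (m * spear.w[mask] - 1) / (m - 1), atol=1e-12)
        # mean pairwise tau-b at one interior voxel vs the independent pairwise route
        idx = (3, 3, 3)
        kernel = neighborhood_kernel(26)
        offs = np.argwhere(kernel > 0) - 1
        nbrs = np.asarray([data[tuple(np.array(idx) + o)] for o in offs])
        assert mtau.tau[idx] == pytest.approx(mean_pairwise_tau(nbrs), abs=1e-10)
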