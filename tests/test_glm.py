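import math

import numpy as np
import pytest

from neoreho import (
    DesignMatrix,
    bh_fdr,
    build_design_interaction,
    build_design_main,
    extract_clusters,
    freedman_lane_permutation,
    ols_tstat,
    permutation_glm,
    simulate_zmap_cohort,
)


def _two_group_design():
    x = np.array([[1.0, 0.0], [1, 0], [1, 1], [1, 1]])
    return DesignMatrix(x, ["intercept", "group"], np.array([0.0, 1.0]))


class TestDesigns:
    def test_main_design_structure(self, cohort_frame):
        design = build_design_main(cohort_frame)
        assert design.matrix.shape == (36, 5)
        np.testing.assert_array_equal(design.contrast, [0, 1, 0, 0, 0])
        assert design.regressor_names[1] == "group"
        # centered covariates
        assert abs(design.matrix[:, 2].sum()) < 1e-9
        assert abs(design.matrix[:, 3].sum()) < 1e-9
        assert design.matrix[:, 1].sum() == 18  # R+ coded 1

    def test_interaction_design_structure(self, cohort_frame):
        design = build_design_interaction(cohort_frame)
        assert design.regressor_names == ["intercept", "group", "pma_c", "group_x_pma", "sex"]
        np.testing.assert_array_equal(design.contrast, [0, 0, 0, 1, 0])
        # positive contrast = steeper PMA slope in the group coded 1
        pma_c = design.matrix[:, 2]
        np.testing.assert_allclose(design.matrix[:, 3], design.matrix[:, 1] * pma_c)

    def test_single_group_and_degenerate_inputs_rejected(self, cohort_frame):
        with pytest.raises(ValueError):
            build_design_main(cohort_frame[cohort_frame.group == "R+"])
        flat = cohort_frame.copy()
        flat["pma_scan_weeks"] = 42.0
        with pytest.raises(ValueError, match="PMA"):
            build_design_interaction(flat)

    def test_rank_deficiency_detected(self, cohort_frame):
        tiny = cohort_frame.iloc[[0, 1, 18, 19]].copy()
        tiny["birth_ga_weeks"] = tiny["pma_scan_weeks"]  # collinear covariates
        tiny["postnatal_age_days"] = 1.0
        with pytest.raises(ValueError, match="rank"):
            build_design_main(tiny)


class TestOlsT:
    def test_hand_computed_two_sample_t(self):
        y = np.array([[1.0, 2.0, 3.0, 4.0]])
        t = ols_tstat(y, _two_group_design())
        assert t[0] == pytest.approx(2 * math.sqrt(2), abs=1e-9)

    def test_orthogonal_response_gives_zero(self):
        y = np.array([[1.0, -1.0, 1.0, -1.0]])
        assert ols_tstat(y, _two_group_design())[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_least_squares(self, cohort_frame):
        rng = np.random.default_rng(0)
        design = build_design_main(cohort_frame)
        y = rng.standard_normal((50, 36))
        t = ols_tstat(y, design)
        import statsmodels.api as sm

        for v in range(0, 50, 10):
            fit = sm.OLS(y[v], design.matrix).fit()
            assert t[v] == pytest.approx(fit.tvalues[1], abs=1e-8)


class TestFreedmanLane:
    def test_constant_response_gives_p_one(self, cohort_frame):
        design = build_design_main(cohort_frame)
        y = np.full((3, 36), 2.5) + np.arange(3)[:, None] * 0.0
        y += np.random.default_rng(0).standard_normal((3, 1)) * 0  # constant per voxel
        t, p = freedman_lane_permutation(y, design, n_permutations=200, seed=1)
        np.testing.assert_allclose(p, 1.0)

    def test_reproducible_given_seed(self, cohort_frame):
        rng = np.random.default_rng(5)
        design = build_design_main(cohort_frame)
        y = rng.standard_normal((20, 36))
        _, p1 = freedman_lane_permutation(y, design, n_permutations=300, seed=99)
        _, p2 = freedman_lane_permutation(y, design, n_permutations=300, seed=99)
        np.testing.assert_array_equal(p1, p2)

    def test_exhaustive_enumeration_for_tiny_n(self):
        # n=4 -> 24 distinct permutations; requesting more enumerates all
        design = _two_group_design()
        y = np.array([[0.3, 1.2, 2.9, 4.1]])
        with pytest.warns(UserWarning, match="exhaustively"):
            _, p_ex = freedman_lane_permutation(y, design, n_permutations=500, seed=3)
        # oracle: proportion of all 24 label permutations with |t*| >= |t_obs|
        from itertools import permutations

        t_obs = abs(ols_tstat(y, design)[0])
        z = design.matrix[:, :1]
        hz = z @ np.linalg.inv(z.T @ z) @ z.T
        resid = (np.eye(4) - hz) @ y[0]
        fitted = hz @ y[0]
        count = sum(
            abs(ols_tstat((fitted + resid[list(perm)])[None, :], design)[0]) >= t_obs - 1e-12
            for perm in permutations(range(4))
        )
        assert p_ex[0] == pytest.approx(count / 24)

    def test_power_increases_with_effect_size(self):
        rates = []
        for effect in (0.0, 0.15, 0.4):
            hits = 0
            for rep in range(5):
                parts, z4d, atlas, mask = simulate_zmap_cohort(
                    effect_z=effect, seed=1000 + rep
                )
                design = build_design_main(parts)
                y = z4d[atlas.data == 1]
                _, p = freedman_lane_permutation(y, design, n_permutations=200, seed=rep)
                hits += (p <= 0.05).mean()
            rates.append(hits / 5)
        assert rates[0] < rates[1] < rates[2]

    def test_requires_seed_and_minimum_permutations(self, cohort_frame):
        design = build_design_main(cohort_frame)
        y = np.zeros((2, 36))
        with pytest.raises(ValueError, match="seed"):
            freedman_lane_permutation(y, design, n_permutations=200)
        with pytest.raises(ValueError, match="at least 100"):
            freedman_lane_permutation(y, design, n_permutations=10, seed=0)


class TestFdr:
    def test_step_up_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        adj, reject = bh_fdr(p, q=0.05)
        assert reject.sum() == 3
        assert not reject[3]
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()

    def test_edge_cases(self):
        adj, reject = bh_fdr(np.ones(5), q=0.05)
        assert reject.sum() == 0
        adj, reject = bh_fdr(np.array([0.04]), q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)
        adj, reject = bh_fdr(np.array([]))
        assert adj.size == 0 and reject.size == 0

    def test_bh_superset_of_bonferroni(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 0.2, size=100)
        _, bh = bh_fdr(p, q=0.05)
        bonf = p <= 0.05 / p.size
        assert (bh | ~bonf).all()


class TestClusters:
    def test_single_voxel_and_empty(self):
        sig = np.zeros((5, 5, 5), bool)
        _, table = extract_clusters(sig)
        assert table.empty
        sig[2, 2, 2] = True
        labels, table = extract_clusters(sig)
        assert len(table) == 1 and table.loc[0, "size"] == 1

    def test_corner_touching_voxels_depend_on_connectivity(self):
        sig = np.zeros((4, 4, 4), bool)
        sig[1, 1, 1] = sig[2, 2, 2] = True  # touch only at a corner
        _, t26 = extract_clusters(sig, connectivity=26)
        _, t6 = extract_clusters(sig, connectivity=6)
        assert len(t26) == 1 and len(t6) == 2

    def test_peak_location_tracks_max_abs_t(self):
        sig = np.zeros((4, 4, 4), bool)
        sig[1, 1, 1:4] = True
        t = np.zeros((4, 4, 4))
        t[1, 1, 2] = -5.0
        _, table = extract_clusters(sig, t=t)
        assert (table.loc[0, ["peak_x", "peak_y", "peak_z"]] == [1, 1, 2]).all()
        assert table.loc[0, "peak_t"] == -5.0


def test_permutation_glm_end_to_end_maps():
    parts, z4d, atlas, mask = simulate_zmap_cohort(effect_z=0.3, seed=2)
    design = build_design_main(parts)
    res = permutation_glm(z4d, atlas.data == 1, design, n_permutations=300, seed=4)
    inside = atlas.data == 1
    assert np.isfinite(res.t[inside]).all()
    assert np.isnan(res.t[~inside]).all()
    assert res.n_significant > 0
    assert ((res.p_fdr[inside] >= res.p_perm[inside]) | np.isclose(res.p_fdr[inside], res.p_perm[inside])).all()
    sig_idx = res.sig == 1
    assert (res.p_fdr[sig_idx] <= res.q + 1e-12).all()
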