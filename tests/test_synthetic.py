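import numpy as np
import pytest

from neoreho import (
    SimulationConfig,
    generate_atlas,
    reho_map,
    sample_participants,
    simulate_bold,
    simulate_cohort,
    simulate_motion_params,
    simulate_zmap_cohort,
)


class TestAtlas:
    def test_default_parcellation_17_disjoint_regions(self):
        atlas, mask = generate_atlas((24, 24, 24), n_rois=16, n_control=1, seed=0)
        labels = atlas.roi_labels
        assert labels == list(range(1, 18))
        sizes = [(atlas.data == lab).sum() for lab in labels]
        assert all(s > 0 for s in sizes)
        assert atlas.control_labels == frozenset({17})
        assert (mask.data[atlas.data > 0]).all()  # blobs inside the mask

    def test_single_roi_and_determinism(self):
        a1, _ = generate_atlas((16, 16, 16), n_rois=1, n_control=0, seed=5)
        assert a1.roi_labels == [1]
        a2, _ = generate_atlas((16, 16, 16), n_rois=1, n_control=0, seed=5)
        np.testing.assert_array_equal(a1.data, a2.data)
        a3, _ = generate_atlas((16, 16, 16), n_rois=1, n_control=0, seed=6)
        assert not np.array_equal(a1.data, a3.data)

    def test_infeasible_packing_fails(self):
        with pytest.raises(ValueError, match="packing"):
            generate_atlas((8, 8, 8), n_rois=200, n_control=0, seed=0, max_attempts=500)


class TestSimulateBold:
    def test_unsmoothed_field_sits_at_independence_limit(self):
        cfg = SimulationConfig(shape=(16, 16, 16), n_volumes=120, baseline_fwhm=0.0, seed=1)
        atlas, mask = generate_atlas(cfg.shape, 2, 1, seed=1)
        bold = simulate_bold(cfg, atlas, "R-", 42.0, np.random.default_rng(1))
        rh = reho_map(bold, mask)
        w27 = rh.w[rh.m_used == 27]
        assert np.nanmedian(w27) == pytest.approx(1 / 27, abs=5e-3)

    def test_smoothing_dial_is_monotone(self):
        atlas, mask = generate_atlas((16, 16, 16), 2, 1, seed=2)
        medians = []
        for fwhm in (0.5, 2.5):
            vals = []
            for seed in range(4):
                cfg = SimulationConfig(
                    shape=(16, 16, 16), n_volumes=80, baseline_fwhm=fwhm, seed=seed + 1
                )
                bold = simulate_bold(cfg, atlas, "R-", 42.0, np.random.default_rng(seed))
                vals.append(np.nanmedian(reho_map(bold, mask).w))
            medians.append(np.mean(vals))
        assert medians[0] < medians[1]

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(shape=(12, 12, 12), n_volumes=60, seed=3)
        atlas, mask = generate_atlas(cfg.shape, 2, 1, seed=3)
        b1 = simulate_bold(cfg, atlas, "R+", 41.0, np.random.default_rng(7))
        b2 = simulate_bold(cfg, atlas, "R+", 41.0, np.random.default_rng(7))
        np.testing.assert_array_equal(b1.data, b2.data)

    def test_negative_effective_fwhm_rejected(self):
        cfg = SimulationConfig(
            shape=(12, 12, 12),
            n_volumes=60,
            baseline_fwhm=0.2,
            age_effect_rois=(1,),
            age_slope_fwhm={"R+": 0.0, "R-": 1.0},
            seed=4,
        )
        atlas, _ = generate_atlas(cfg.shape, 2, 1, seed=4)
        with pytest.raises(ValueError, match="negative effective"):
            simulate_bold(cfg, atlas, "R-", 39.3, np.random.default_rng(0))


class TestConfigValidation:
    def test_invariants(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig()
        with pytest.raises(ValueError, match=">= 8"):
            SimulationConfig(shape=(4, 12, 12), seed=1)
        with pytest.raises(ValueError, match="n_volumes"):
            SimulationConfig(n_volumes=10, seed=1)
        with pytest.raises(ValueError, match="PMA"):
            SimulationConfig(pma_range=(42.0, 42.0), seed=1)


class TestCohort:
    def test_cohort_structure_and_determinism(self):
        cfg = SimulationConfig(
            shape=(12, 12, 12), n_volumes=60, n_per_group=4, n_male_per_group=3,
            n_rois=2, n_control=1, seed=11,
        )
        sim = simulate_cohort(cfg)
        assert len(sim.participants) == 8
        counts = sim.participants.groupby(["group", "sex"]).size()
        assert counts[("R+", "male")] == 3 and counts[("R+", "female")] == 1
        assert sim.z4d.shape == (12, 12, 12, 8)
        assert np.isfinite(sim.z4d[sim.mask.data]).all()
        assert len(sim.motion_params) == 8
        sim2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(sim.z4d, sim2.z4d)

    def test_default_sex_split_matches_cohort_structure(self):
        rng = np.random.default_rng(0)
        parts = sample_participants(18, 13, (39.3, 44.9), rng)
        counts = parts.groupby(["group", "sex"]).size()
        assert counts[("R+", "male")] == 13 and counts[("R+", "female")] == 5
        assert counts[("R-", "male")] == 13 and counts[("R-", "female")] == 5
        assert (parts["pma_scan_weeks"] >= parts["birth_ga_weeks"]).all()

    def test_motion_spikes_at_configured_rate(self):
        rng = np.random.default_rng(1)
        params = simulate_motion_params(2000, rng, spike_rate=0.05, spike_magnitude_mm=1.0)
        from neoreho import framewise_displacement

        fd = framewise_displacement(params)
        assert 0.02 < (fd > 0.5).mean() < 0.09


class TestZmapCohort:
    def test_effect_and_slope_enter_only_the_effect_roi(self):
        parts, z4d, atlas, mask = simulate_zmap_cohort(
            effect_z=5.0, noise_sd=0.01, seed=8
        )
        grp = (parts["group"] == "R+").to_numpy()
        eff = z4d[atlas.data == 1].mean(axis=0)
        ctl = z4d[atlas.data == 2].mean(axis=0)
        assert eff[grp].mean() - eff[~grp].mean() == pytest.approx(5.0, abs=0.1)
        assert abs(ctl[grp].mean() - ctl[~grp].mean()) < 0.1

    def test_pure_function_of_seed(self):
        a = simulate_zmap_cohort(effect_z=0.15, seed=123)
        b = simulate_zmap_cohort(effect_z=0.15, seed=123)
        np.testing.assert_array_equal(a[1], b[1])
        assert a[0].equals(b[0])
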