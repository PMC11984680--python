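import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionpipe.errors import InvalidSpecError
from lesionpipe.phantom import (BundleSpec, CohortEffectSpec, Diffusivities,
                                GradientTable, LesionSpec, PhantomSpec,
                                build_phantom, cohort_phantom_spec,
                                default_phantom_spec, generate_cohort,
                                make_gradient_table, simulate_voxel_signal)


class TestMakeGradientTable:
    def test_paper_protocol_138_entries_two_shells(self):
        gtab = make_gradient_table(10, 64, [1500, 3000])
        assert len(gtab) == 138
        assert gtab.b0_mask.sum() == 10
        assert gtab.shell_bvalues == (1500.0, 3000.0)

    def test_small_table_counts_and_angles(self):
        gtab = make_gradient_table(1, 6, [1000])
        assert len(gtab) == 7
        dirs = gtab.bvecs[~gtab.b0_mask]
        dots = dirs @ dirs.T
        np.fill_diagonal(dots, 0.0)
        assert np.all(dots < 1.0 - 1e-6)  # min pairwise angle > 0

    def test_near_uniform_mean_direction(self):
        gtab = make_gradient_table(0, 64, [3000])
        assert len(gtab) == 64
        assert np.linalg.norm(gtab.bvecs.mean(axis=0)) < 0.2

    def test_deterministic(self):
        a = make_gradient_table(4, 30, [2000])
        b = make_gradient_table(4, 30, [2000])
        np.testing.assert_array_equal(a.bvecs, b.bvecs)

    @pytest.mark.parametrize("bad", [[0.0], [-500.0], [1000, 1000]])
    def test_invalid_shells_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            make_gradient_table(1, 6, bad)

    def test_unit_norm_invariant(self):
        gtab = make_gradient_table(2, 20, [1000, 2500])
        nz = ~gtab.b0_mask
        np.testing.assert_allclose(np.linalg.norm(gtab.bvecs[nz], axis=1),
                                   1.0, atol=1e-6)


class TestSimulateVoxelSignal:
    def test_pure_eci_closed_form(self, gtab138):
        s = simulate_voxel_signal(gtab138, (1, 0, 0), None)
        outer = gtab138.shell_mask(3000.0)
        np.testing.assert_allclose(s[outer], np.exp(-9.0), rtol=1e-12)

    def test_pure_ica_parallel_closed_form(self):
        gtab = GradientTable(bvals=np.array([0.0, 3000.0]),
                             bvecs=np.array([[0, 0, 0], [0, 0, 1.0]]))
        s = simulate_voxel_signal(gtab, (0, 0, 1), (0, 0, 1))
        assert s[1] == pytest.approx(np.exp(-5.1), rel=1e-12)

    def test_mixture_linearity(self, gtab138):
        """50/50 ICA/ECI equals the average of the pure compartments."""
        v = np.array([0.0, 0.0, 1.0])
        s_mix = simulate_voxel_signal(gtab138, (0.5, 0, 0.5), v)
        s_ica = simulate_voxel_signal(gtab138, (0, 0, 1), v)
        s_eci = simulate_voxel_signal(gtab138, (1, 0, 0), None)
        np.testing.assert_allclose(s_mix, 0.5 * (s_ica + s_eci), atol=1e-12)

    def test_b0_is_one_noiseless(self, gtab138):
        s = simulate_voxel_signal(gtab138, (0.3, 0.3, 0.4), (1, 0, 0))
        np.testing.assert_allclose(s[gtab138.b0_mask], 1.0, atol=1e-12)

    def test_missing_fiber_dir_rejected(self, gtab138):
        with pytest.raises(InvalidSpecError):
            simulate_voxel_signal(gtab138, (0.5, 0, 0.5), None)

    def test_rician_bias_at_b0(self, gtab138):
        """Monte-Carlo mean of noisy b0 exceeds 1, approaching 1 as SNR grows."""
        rng = np.random.default_rng(0)
        means = {}
        for snr in (5.0, 50.0):
            vals = [simulate_voxel_signal(gtab138, (1, 0, 0), None, snr=snr,
                                          rng=rng)[gtab138.b0_mask].mean()
                    for _ in range(300)]
            means[snr] = np.mean(vals)
        assert means[5.0] > 1.0
        assert means[50.0] > 1.0 - 1e-3
        assert abs(means[50.0] - 1.0) < abs(means[5.0] - 1.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=25, deadline=None)
    def test_fraction_validation(self, a, b):
        gtab = GradientTable(bvals=np.array([0.0]), bvecs=np.zeros((1, 3)))
        f = (a, b, 1.0 - a - b)
        if min(f) < 0:
            with pytest.raises(InvalidSpecError):
                simulate_voxel_signal(gtab, f, (0, 0, 1))
        else:
            s = simulate_voxel_signal(gtab, f, (0, 0, 1))
            assert s[0] == pytest.approx(1.0, abs=1e-9)


class TestBuildPhantom:
    def test_straight_bundle_direction(self, phantom20):
        _, _, truth = phantom20
        wm = truth.tissue_masks["wm"]
        dirs = truth.fiber_direction[wm]
        np.testing.assert_allclose(np.abs(dirs[:, 2]), 1.0, atol=1e-9)

    def test_lesion_volume_matches_bruteforce_sphere(self):
        spec = default_phantom_spec(grid_shape=(12, 12, 12),
                                    lesion_radius=2 * 1.7)
        _, truth = build_phantom(spec)
        les = spec.lesions[0]
        # independent oracle: rasterize the sphere by voxel centers
        count = 0
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    c = (np.array([i, j, k]) + 0.5) * 1.7
                    if np.linalg.norm(c - np.array(les.center)) <= les.radius:
                        count += 1
        assert truth.wmh_mask.sum() == count

    def test_empty_lesions_empty_mask(self, phantom20):
        _, _, truth = phantom20
        assert truth.wmh_mask.sum() == 0

    def test_fractions_sum_to_one(self, phantom20):
        _, _, truth = phantom20
        assert truth.true_fractions.check_simplex(atol=1e-9)

    def test_noiseless_b0_is_one_everywhere(self, phantom20, gtab138):
        _, dwi, _ = phantom20
        b0 = dwi.data[..., gtab138.b0_mask]
        np.testing.assert_allclose(b0, 1.0, atol=1e-12)

    def test_bit_reproducible(self):
        spec = default_phantom_spec(grid_shape=(8, 8, 8), snr=25.0, seed=5)
        d1, _ = build_phantom(spec)
        d2, _ = build_phantom(spec)
        np.testing.assert_array_equal(d1.data, d2.data)

    def test_fiber_direction_defined_where_ica_positive(self, phantom20):
        _, _, truth = phantom20
        has_ica = truth.true_fractions.f_ica > 0
        assert np.all(np.isfinite(truth.fiber_direction[has_ica]))
        assert np.all(~np.isfinite(truth.fiber_direction[~has_ica]))

    def test_overlapping_bundles_blend(self):
        extent = 8 * 1.7
        mid = extent / 2
        b1 = BundleSpec(centerline=np.array([[mid, mid, 0], [mid, mid, extent]]),
                        radius=3.0, fractions=(0.1, 0.1, 0.8))
        b2 = BundleSpec(centerline=np.array([[mid, 0, mid], [mid, extent, mid]]),
                        radius=3.0, fractions=(0.2, 0.2, 0.6))
        spec = PhantomSpec(grid_shape=(8, 8, 8), bundles=(b1, b2))
        _, truth = build_phantom(spec)
        # crossing voxel: fractions renormalized sum, direction of larger ICA
        center_vox = (4, 4, 4)
        f = truth.true_fractions
        np.testing.assert_allclose(
            [f.f_eci[center_vox], f.f_ici[center_vox], f.f_ica[center_vox]],
            np.array([0.3, 0.3, 1.4]) / 2.0, atol=1e-9)
        assert abs(truth.fiber_direction[center_vox][2]) == pytest.approx(1.0)

    def test_lesion_outside_grid_rejected(self):
        with pytest.raises(InvalidSpecError):
            default_phantom_spec(grid_shape=(6, 6, 6), lesion_radius=50.0)

    def test_background_with_ica_rejected(self):
        from lesionpipe.phantom import RegionSpec
        with pytest.raises(InvalidSpecError):
            build_phantom(PhantomSpec(
                grid_shape=(4, 4, 4),
                background_tissue={"bad": RegionSpec(fractions=(0.0, 0.5, 0.5))}))


class TestGenerateCohort:
    def test_deterministic(self):
        c1, s1 = generate_cohort(12, seed=3)
        c2, s2 = generate_cohort(12, seed=3)
        assert c1.equals(c2)
        for tp in (0, 1):
            a, b = s1["sub-001"][tp], s2["sub-001"][tp]
            assert a.bundles[0].fractions == b.bundles[0].fractions
            assert a.lesions[0].radius == b.lesions[0].radius
            assert a.seed == b.seed

    def test_schema_and_ranges(self):
        cohort, specs = generate_cohort(20, seed=1)
        base = cohort[cohort.timepoint == "baseline"]
        assert len(base) == 20 and len(specs) == 20
        assert base.age_years.between(58, 81).all()
        assert set(base.sex) <= {"M", "F"}
        assert (base.wmh_volume >= 0).all()
        # AgeAccelGrim is the OLS residual: mean 0, orthogonal to age
        assert abs(base.age_accel_grim.mean()) < 1e-9
        assert abs(np.corrcoef(base.age_accel_grim, base.age_years)[0, 1]) < 1e-9

    def test_too_few_subjects(self):
        with pytest.raises(InvalidSpecError):
            generate_cohort(5, seed=0)

    def test_negative_variance_rejected(self):
        with pytest.raises(InvalidSpecError):
            CohortEffectSpec(grimage_sd=-1.0)

    def test_null_slope_ci_covers_zero(self):
        """gamma1 = 0: the WMH~accel slope CI covers 0 in >= 90% of seeds."""
        from lesionpipe.stats import fit_glm

        eff = CohortEffectSpec(wmh_volume_accel_slope=0.0)
        covered = 0
        n_rep = 30
        for seed in range(n_rep):
            cohort, _ = generate_cohort(60, eff, seed=seed)
            base = cohort[cohort.timepoint == "baseline"]
            res = fit_glm(base.wmh_volume,
                          {"age_accel_grim": base.age_accel_grim},
                          term_of_interest="age_accel_grim")
            t = res["age_accel_grim"]
            lo = t["coef"] - 1.96 * t["se"]
            hi = t["coef"] + 1.96 * t["se"]
            covered += lo <= 0.0 <= hi
        assert covered >= 0.9 * n_rep

    def test_planted_slope_recovered(self):
        """Planted gamma1 > 0 at n=98: positive slope in >= 95% of seeds."""
        eff = CohortEffectSpec()
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            cohort, _ = generate_cohort(98, eff, seed=seed)
            base = cohort[cohort.timepoint == "baseline"]
            slope = np.polyfit(base.age_accel_grim, base.wmh_volume, 1)[0]
            hits += slope > 0
        assert hits >= 0.95 * n_rep

    def test_whole_phantom_mean_identical_across_subjects(self):
        """Mirrored control bundle: composition is subject-independent."""
        eff = CohortEffectSpec(grid_shape=(8, 8, 8), gm_eci_noise_sd=0.0)
        cohort, specs = generate_cohort(10, eff, seed=4)
        means = []
        for sid in list(specs)[:4]:
            _, truth = build_phantom(specs[sid][0])
            means.append(truth.true_fractions.f_eci.mean())
        np.testing.assert_allclose(means, means[0], atol=1e-9)

    def test_retention_is_bernoulli_and_recorded(self):
        cohort, _ = generate_cohort(98, seed=2)
        base = cohort[cohort.timepoint == "baseline"]
        n_ret = base.retained_at_followup.sum()
        assert 20 <= n_ret <= 70  # ~42% retention
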