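import numpy as np
import pytest
from scipy import stats as sps

from lesionpipe.csd import FODField
from lesionpipe.errors import InvalidSpecError, TrackingError
from lesionpipe.tracking import (Streamline, Tractogram, TrackingParams,
                                 generate_tractogram, propagate_streamline,
                                 seed_points, sift_filter, streamline_voxels,
                                 track_density_map)


def _toy_tractogram(point_lists, affine=np.eye(4), step=1.0):
    return Tractogram(streamlines=[Streamline(points=np.asarray(p, float),
                                              step_size=step)
                                   for p in point_lists],
                      affine=np.asarray(affine, float))


class TestSeedPoints:
    def test_single_voxel_mask_bounds(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[2, 1, 3] = True
        pts = seed_points(mask, np.eye(4), 500, np.random.default_rng(0))
        # voxel (2,1,3) is [1.5, 2.5) x [0.5, 1.5) x [2.5, 3.5) in world mm
        assert np.all(pts[:, 0] >= 1.5) and np.all(pts[:, 0] < 2.5)
        assert np.all(pts[:, 1] >= 0.5) and np.all(pts[:, 1] < 1.5)
        assert np.all(pts[:, 2] >= 2.5) and np.all(pts[:, 2] < 3.5)

    def test_uniformity_chi_square(self):
        """Per-voxel seed counts consistent with a uniform multinomial."""
        mask = np.ones((4, 4, 4), dtype=bool)
        n = 64000
        pts = seed_points(mask, np.eye(4), n, np.random.default_rng(1))
        vox = np.floor(pts + 0.5).astype(int)
        counts = np.bincount(np.ravel_multi_index(vox.T, (4, 4, 4)),
                             minlength=64)
        expected = n / 64
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # 4-sigma bound for chi-square with 63 dof
        assert chi2 < 63 + 4 * np.sqrt(2 * 63)

    def test_deterministic(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        a = seed_points(mask, np.eye(4), 100, np.random.default_rng(9))
        b = seed_points(mask, np.eye(4), 100, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_empty_mask(self):
        with pytest.raises(InvalidSpecError):
            seed_points(np.zeros((2, 2, 2), dtype=bool), np.eye(4), 1,
                        np.random.default_rng(0))


class TestPropagateStreamline:
    def test_zero_fod_rejected(self):
        fod = FODField(coeffs=np.zeros((5, 5, 5, 45)), affine=np.eye(4),
                       lmax=8)
        res = propagate_streamline(fod, (2.0, 2.0, 2.0),
                                   TrackingParams(step_size=0.5),
                                   np.random.default_rng(0),
                                   mask=np.ones((5, 5, 5), dtype=bool))
        assert res is None

    def test_bundle_streamlines_along_z(self, phantom20, fitted20):
        _, dwi, truth = phantom20
        _, fod, _, _ = fitted20
        rng = np.random.default_rng(5)
        params = TrackingParams()
        center = np.array(dwi.grid_shape) * 1.7 / 2
        n_acc, n_aligned = 0, 0
        for _ in range(60):
            res = propagate_streamline(fod, center + rng.normal(0, 0.5, 3),
                                       params, rng, mask=dwi.brain_mask)
            if res is None:
                continue
            n_acc += 1
            seg = np.diff(res.points, axis=0)
            m = seg.mean(axis=0)
            m /= np.linalg.norm(m)
            n_aligned += abs(m[2]) > np.cos(np.radians(15))
        assert n_acc >= 30
        assert n_aligned >= 0.9 * n_acc

    def test_step_size_invariant(self, phantom20, fitted20):
        _, dwi, _ = phantom20
        _, fod, _, _ = fitted20
        params = TrackingParams(step_size=0.65)
        res = propagate_streamline(fod, np.array(dwi.grid_shape) * 1.7 / 2,
                                   params, np.random.default_rng(1),
                                   mask=dwi.brain_mask)
        seg = np.linalg.norm(np.diff(res.points, axis=0), axis=1)
        np.testing.assert_allclose(seg, 0.65, atol=1e-6)
        assert res.length == pytest.approx((len(res) - 1) * 0.65)


class TestGenerateTractogram:
    def test_exact_count_and_min_length(self, tract2000):
        params, tg = tract2000
        assert len(tg) == 2000
        assert tg.lengths().min() >= params.min_length

    def test_deterministic(self, phantom20, fitted20):
        _, dwi, _ = phantom20
        _, fod, _, _ = fitted20
        params = TrackingParams(target_count=150)
        t1 = generate_tractogram(fod, dwi.brain_mask, params, 11)
        t2 = generate_tractogram(fod, dwi.brain_mask, params, 11)
        assert len(t1) == len(t2)
        for a, b in zip(t1.streamlines, t2.streamlines):
            np.testing.assert_array_equal(a.points, b.points)

    def test_acceptance_rate_stable_across_batches(self, phantom20, fitted20):
        """Accepted fraction consistent between two disjoint seed batches."""
        from lesionpipe.tracking import _Tracker

        _, dwi, _ = phantom20
        _, fod, _, _ = fitted20
        tracker = _Tracker(fod, dwi.brain_mask, TrackingParams())
        rng = np.random.default_rng(3)
        k = []
        n = 1500
        for _ in range(2):
            seeds = seed_points(dwi.brain_mask, fod.affine, n, rng)
            k.append(sum(r is not None for r in tracker.propagate(seeds, rng)))
        # two-proportion z-test at alpha = 1e-4 (sampling error bound)
        p = (k[0] + k[1]) / (2 * n)
        z = abs(k[0] - k[1]) / np.sqrt(2 * n * p * (1 - p) + 1e-9)
        assert z < 4.0

    def test_degenerate_field_raises(self):
        fod = FODField(coeffs=np.zeros((4, 4, 4, 15)), affine=np.eye(4),
                       lmax=4)
        with pytest.raises(TrackingError):
            generate_tractogram(fod, np.ones((4, 4, 4), dtype=bool),
                                TrackingParams(target_count=50, step_size=0.3),
                                np.random.default_rng(0))

    def test_points_inside_mask_bounding_box(self, tract2000, phantom20):
        _, dwi, _ = phantom20
        _, tg = tract2000
        hi = np.asarray(dwi.grid_shape) * 1.7
        for s in tg.streamlines[::100]:
            assert np.all(s.points >= 0.0) and np.all(s.points <= hi)


class TestTrackDensityMap:
    def test_axis_aligned_line(self):
        tg = _toy_tractogram([[[0.2, 0.2, 0.2], [4.2, 0.2, 0.2]]])
        td = track_density_map(tg, (6, 2, 2))
        expect = np.zeros((6, 2, 2), dtype=int)
        expect[0:5, 0, 0] = 1
        np.testing.assert_array_equal(td, expect)

    def test_duplicate_streamlines_count_twice(self):
        line = [[0.2, 0.2, 0.2], [3.2, 0.2, 0.2]]
        td = track_density_map(_toy_tractogram([line, line]), (5, 2, 2))
        assert td.max() == 2
        assert set(np.unique(td)) <= {0, 2}

    def test_single_streamline_counts_once_per_voxel(self):
        # a streamline re-entering the same voxel still counts once
        zigzag = [[0.5, 0.5, 0.5], [1.5, 0.5, 0.5], [0.5, 0.6, 0.5]]
        td = track_density_map(_toy_tractogram([zigzag]), (3, 3, 3))
        assert td.max() == 1

    def test_matches_oversampled_bruteforce(self):
        """Exact traversal equals dense point-membership on random lines."""
        rng = np.random.default_rng(12)
        affine = np.diag([1.7, 1.7, 1.7, 1.0])
        affine[:3, 3] = 0.85
        inv = np.linalg.inv(affine)
        for _ in range(40):
            # step-sized random walk, like tracker output
            n = int(rng.integers(2, 40))
            steps = rng.normal(size=(n - 1, 3))
            steps = 0.65 * steps / np.linalg.norm(steps, axis=1)[:, None]
            pts = np.cumsum(np.vstack([rng.uniform(4, 12, 3), steps]), axis=0)
            exact = {tuple(v) for v in
                     streamline_voxels(pts, affine, (10, 10, 10))}
            dense = []
            for a, b in zip(pts[:-1], pts[1:]):
                ts = np.linspace(0.0, 1.0, 100)
                dense.append(a + ts[:, None] * (b - a))
            g = np.vstack(dense) @ inv[:3, :3].T + inv[:3, 3] + 0.5
            brute = {tuple(v) for v in np.unique(np.floor(g).astype(int),
                                                 axis=0)
                     if all(0 <= c < 10 for c in v)}
            assert exact == brute


class TestSiftFilter:
    def test_identity_when_keeping_all(self, tract2000, fitted20):
        _, tg = tract2000
        _, fod, _, _ = fitted20
        out = sift_filter(tg, fod, len(tg))
        assert len(out) == len(tg)

    def test_invalid_keep_count(self, tract2000, fitted20):
        _, tg = tract2000
        _, fod, _, _ = fitted20
        with pytest.raises(InvalidSpecError):
            sift_filter(tg, fod, 0)
        with pytest.raises(InvalidSpecError):
            sift_filter(tg, fod, len(tg) + 1)

    def test_duplicates_removed_first_vs_bruteforce(self):
        """Greedy matches exhaustive search on the duplicate-oversupply toy."""
        line_a = [[0.5, 0.5, 0.5], [3.5, 0.5, 0.5]]  # oversupplied voxels
        line_b = [[0.5, 2.5, 2.5], [3.5, 2.5, 2.5]]  # lone streamline
        tg = _toy_tractogram([line_a] * 10 + [line_b])
        coeffs = np.zeros((5, 4, 4, 1))
        # amplitude ~1 along both tracks: one streamline each is ideal
        coeffs[0:4, 0, 0, 0] = np.sqrt(4 * np.pi)
        coeffs[0:4, 2, 2, 0] = np.sqrt(4 * np.pi)
        fod = FODField(coeffs=coeffs, affine=np.eye(4), lmax=0)
        kept = sift_filter(tg, fod, 5)
        # brute force: evaluate all 5-subsets' costs
        import itertools

        a_vox = [(i, 0, 0) for i in range(4)]
        b_vox = [(i, 2, 2) for i in range(4)]

        def cost(n_a, n_b):
            td = np.zeros((5, 4, 4))
            for v in a_vox:
                td[v] = n_a
            for v in b_vox:
                td[v] = n_b
            amp = coeffs[..., 0] / np.sqrt(4 * np.pi)
            mu = (amp * td).sum() / max((td ** 2).sum(), 1e-12)
            return ((mu * td - amp) ** 2).sum()

        # feasible kept-counts: at most 10 duplicates, at most 1 lone
        best = min(((n_a, 5 - n_a) for n_a in (4, 5)),
                   key=lambda x: cost(*x))
        n_a_kept = sum(np.allclose(s.points, line_a) for s in kept.streamlines)
        n_b_kept = sum(np.allclose(s.points, line_b) for s in kept.streamlines)
        assert (n_a_kept, n_b_kept) == best
        assert n_b_kept == 1  # the lone streamline survives

    def test_cost_nonincreasing_at_moderate_prune(self, tract2000, fitted20):
        _, tg = tract2000
        _, fod, _, _ = fitted20
        kept, trace = sift_filter(tg, fod, 1000, return_trace=True)
        assert len(kept) == 1000
        assert np.all(np.diff(trace) <= 1e-9)

    def test_output_is_subset_in_order(self, tract2000, fitted20):
        _, tg = tract2000
        _, fod, _, _ = fitted20
        kept = sift_filter(tg, fod, 1500)
        ids = [id(s) for s in tg.streamlines]
        kept_ids = [id(s) for s in kept.streamlines]
        assert set(kept_ids) <= set(ids)
        pos = [ids.index(i) for i in kept_ids]
        assert pos == sorted(pos)

    def test_density_fod_coupling_improves(self, tract2000, fitted20,
                                           phantom20):
        _, dwi, truth = phantom20
        _, fod, _, _ = fitted20
        _, tg = tract2000
        amp = fod.coeffs[..., 0] / np.sqrt(4 * np.pi)
        td_pre = track_density_map(tg, dwi.grid_shape)
        sel = (td_pre > 0) | (amp > 1e-6)
        kept = sift_filter(tg, fod, 1000)
        td_post = track_density_map(kept, dwi.grid_shape)
        r_pre = np.corrcoef(td_pre[sel], amp[sel])[0, 1]
        r_post = np.corrcoef(td_post[sel], amp[sel])[0, 1]
        assert r_post > r_pre
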