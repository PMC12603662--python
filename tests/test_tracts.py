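"""Streamline utilities: resampling, density, cleaning, profiles, yield."""

import numpy as np
import pytest

from freewater.tracts import (
    TractBundle,
    TractDensityMap,
    clean_bundle,
    density_map,
    load_tck,
    resample_streamline,
    save_tck,
    tract_profile,
    tract_yield,
    wmh_overlap,
)


def _line(start, end, n=2):
    return np.linspace(start, end, n)


def _coherent_bundle(n=50, seed=0, jitter=0.05):
    rng = np.random.default_rng(seed)
    sls = []
    for _ in range(n):
        offset = rng.normal(0, jitter, 3)
        sls.append(_line([0, 0, 0], [10, 0, 0], 20) + offset)
    return TractBundle(streamlines=tuple(sls), name="test")


class TestResample:
    def test_straight_segment(self):
        out = resample_streamline(np.array([[0.0, 0, 0], [9.9, 0, 0]]), n=100)
        assert out.shape == (100, 3)
        np.testing.assert_allclose(np.diff(out[:, 0]), 0.1, rtol=1e-9)
        np.testing.assert_allclose(out[[0, -1]], [[0, 0, 0], [9.9, 0, 0]])

    def test_idempotent_on_equal_spacing(self):
        line = _line([0, 0, 0], [5, 5, 0], 100)
        np.testing.assert_allclose(resample_streamline(line), line, atol=1e-9)

    def test_arc_length_preserved(self):
        # exactly preserved for a straight, non-uniformly sampled line
        t = np.sort(np.random.default_rng(4).uniform(0, 1, 40))
        t[0], t[-1] = 0.0, 1.0
        straight = np.outer(t, [3.0, 4.0, 0.0])
        out = resample_streamline(straight, n=100)
        len_out = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert abs(len_out - 5.0) / 5.0 < 1e-9
        # and to discretization accuracy for a smooth curve
        s = np.linspace(0, np.pi, 2000)
        curve = np.column_stack([np.cos(s), np.sin(s), np.zeros_like(s)])
        out = resample_streamline(curve, n=2000)
        len_in = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()
        len_out = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert abs(len_out - len_in) / len_in < 1e-6

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_streamline(np.zeros((3, 3)))


class TestDensityMap:
    def test_axis_aligned_visitation(self):
        sl = _line([0.0, 0, 0], [4.0, 0, 0], 50)
        bundle = TractBundle(streamlines=(sl,))
        dm = density_map(bundle, (5, 3, 3), np.eye(4))
        assert dm.counts[:, 0, 0].tolist() == [1, 1, 1, 1, 1]
        assert dm.counts.sum() == 5

    def test_duplicate_streamline_counts_twice(self):
        sl = _line([0.0, 0, 0], [4.0, 0, 0], 50)
        bundle = TractBundle(streamlines=(sl, sl.copy()))
        dm = density_map(bundle, (5, 3, 3), np.eye(4))
        assert dm.counts[:, 0, 0].tolist() == [2, 2, 2, 2, 2]

    def test_single_visit_regardless_of_points(self):
        # many points inside one voxel still increment it once
        sl = _line([0.0, 0, 0], [0.4, 0, 0], 100)
        dm = density_map(TractBundle(streamlines=(sl,)), (3, 3, 3), np.eye(4))
        assert dm.counts.max() == 1

    def test_diagonal_matches_dense_oracle(self):
        sl = _line([0.0, 0.0, 0.0], [6.0, 6.0, 2.0], 4)  # coarse polyline
        dm = density_map(TractBundle(streamlines=(sl,)), (8, 8, 4), np.eye(4))
        # oracle: oversample the polyline very densely, collect unique voxels
        dense = resample_streamline(sl, n=10000)
        vox = np.unique(np.round(dense).astype(int), axis=0)
        expected = np.zeros((8, 8, 4), dtype=int)
        expected[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
        np.testing.assert_array_equal(dm.counts, expected)

    def test_empty_bundle_zero_map(self):
        dm = density_map(TractBundle(streamlines=()), (2, 2, 2), np.eye(4))
        assert dm.counts.sum() == 0


class TestCleanBundle:
    def test_identical_streamlines_untouched(self):
        sl = _line([0, 0, 0], [10, 0, 0], 20)
        bundle = TractBundle(streamlines=tuple(sl.copy() for _ in range(30)))
        assert len(clean_bundle(bundle)) == 30

    def test_gross_outlier_removed(self):
        bundle = _coherent_bundle(n=50)
        outlier = _line([0, 10, 0], [10, 10, 0], 20)  # 10x the bundle spread
        dirty = TractBundle(streamlines=bundle.streamlines + (outlier,))
        cleaned = clean_bundle(dirty)
        assert len(cleaned) == 50
        assert not any(np.allclose(s, outlier) for s in cleaned.streamlines)

    def test_small_bundle_passes_through(self):
        bundle = _coherent_bundle(n=5)
        outlier = _line([0, 99, 0], [10, 99, 0], 5)
        dirty = TractBundle(streamlines=bundle.streamlines + (outlier,))
        assert len(clean_bundle(dirty)) == 6

    def test_idempotent(self):
        dirty = TractBundle(
            streamlines=_coherent_bundle(n=50).streamlines
            + (_line([0, 10, 0], [10, 10, 0], 20),)
        )
        once = clean_bundle(dirty)
        twice = clean_bundle(once)
        assert len(twice) == len(once)


class TestTractProfile:
    def test_constant_map_constant_profile(self):
        bundle = _coherent_bundle(n=10)
        scalar = np.full((12, 3, 3), 0.42)
        prof = tract_profile(bundle, scalar, np.eye(4))
        np.testing.assert_allclose(prof.values, 0.42, rtol=1e-12)

    def test_single_streamline_samples_map(self):
        sl = _line([0.0, 1.0, 1.0], [10.0, 1.0, 1.0], 50)
        scalar = np.zeros((12, 3, 3))
        scalar[:, 1, 1] = np.arange(12, dtype=float)
        prof = tract_profile(TractBundle(streamlines=(sl,)), scalar, np.eye(4))
        expected = np.round(np.linspace(0, 10, 100))
        np.testing.assert_allclose(prof.values, expected)

    def test_symmetric_pair_averages(self):
        a = _line([0, 1.0, 0], [10, 1.0, 0], 20)
        b = _line([0, -1.0, 0], [10, -1.0, 0], 20)
        scalar = np.zeros((12, 5, 3))
        # world y=1 -> voxel j=3 value 2.0 ; y=-1 -> j=1 value 6.0
        affine = np.eye(4)
        affine[1, 3] = -2.0  # voxel j maps to world y = j - 2
        scalar[:, 3, :] = 2.0
        scalar[:, 1, :] = 6.0
        prof = tract_profile(
            TractBundle(streamlines=(a, b)), scalar, affine, weighting="euclidean"
        )
        np.testing.assert_allclose(prof.values, 4.0, rtol=1e-9)

    def test_affine_transform_of_map_transforms_profile(self):
        bundle = _coherent_bundle(n=12, jitter=0.2)
        rng = np.random.default_rng(8)
        scalar = rng.uniform(0, 1, (12, 3, 3))
        p1 = tract_profile(bundle, scalar, np.eye(4))
        p2 = tract_profile(bundle, 3.0 * scalar + 1.0, np.eye(4))
        np.testing.assert_allclose(p2.values, 3.0 * p1.values + 1.0, rtol=1e-9)

    def test_outside_nodes_flagged_missing(self):
        sl = _line([0, 1, 1], [30.0, 1, 1], 20)  # runs off the 12-voxel grid
        prof = tract_profile(TractBundle(streamlines=(sl,)), np.ones((12, 3, 3)), np.eye(4))
        assert prof.missing.any()
        assert np.isfinite(prof.values[0])


class TestYieldAndOverlap:
    def test_yield_boundary_at_ten(self):
        def bundle_of(n):
            sl = _line([0, 0, 0], [1, 0, 0], 5)
            return TractBundle(streamlines=tuple(sl.copy() for _ in range(n)))

        assert tract_yield([bundle_of(10)]) == 1
        assert tract_yield([bundle_of(9)]) == 0
        assert tract_yield([]) == 0
        assert tract_yield([bundle_of(3), bundle_of(25), bundle_of(10)]) == 2

    def test_wmh_overlap_identity_and_disjoint(self):
        counts = np.zeros((4, 4, 4), dtype=int)
        counts[1, 1, 1] = counts[2, 2, 2] = 3
        dm = TractDensityMap(counts=counts, affine=np.eye(4))
        full = counts > 0
        assert wmh_overlap(dm, full) == pytest.approx(1.0)
        assert wmh_overlap(dm, ~full) == 0.0

    def test_wmh_overlap_hand_computed(self):
        # tract: two voxels weight 0.5 each; mask: 4 voxels incl. one tract
        # voxel -> overlap voxel has w_tract=0.5, w_mask=0.25 ->
        # (0.5+0.25)/(1+1) = 0.375
        counts = np.zeros((4, 4, 1), dtype=int)
        counts[0, 0, 0] = counts[1, 0, 0] = 2
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[1, 0, 0] = mask[2, 0, 0] = mask[2, 1, 0] = mask[3, 3, 0] = True
        dm = TractDensityMap(counts=counts, affine=np.eye(4))
        assert wmh_overlap(dm, mask) == pytest.approx(0.375)


def test_tck_roundtrip(tmp_path):
    bundle = _coherent_bundle(n=4)
    path = tmp_path / "bundle.tck"
    save_tck(bundle, path)
    loaded = load_tck(path)
    assert len(loaded) == 4
    for a, b in zip(loaded.streamlines, bundle.streamlines):
        np.testing.assert_allclose(a, b, atol=1e-5)
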