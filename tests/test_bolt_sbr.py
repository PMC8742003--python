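import numpy as np
import pytest

from datspect.bolt_sbr import (
    AnalysisParams,
    AnalysisError,
    PlacementError,
    analyze,
    build_reference_region,
    compute_sbr,
    place_striatal_vois,
    smooth_within_mask,
    striatal_centroids_mm,
)
from datspect.phantom import region_volume

SPACING = (3.2, 3.2, 3.2)
CENTROIDS = {"left": (-24.0, 8.0, 4.0), "right": (24.0, 8.0, 4.0)}


def uniform_image(value=3.0, n=64):
    return np.full((n, n, n), value)


class TestComputeSbr:
    def test_identity_at_voi_plus_striatum(self):
        # Cs_total/Cr = Vs_VOI + Vs  =>  SBR = 1 exactly
        assert compute_sbr(79.74, 1.0, 70.78, 8.96) == pytest.approx(1.0)

    def test_uniform_image_sbr_is_zero(self):
        res = analyze(uniform_image(), CENTROIDS, spacing=SPACING)
        assert res.sbr_mean == pytest.approx(0.0, abs=1e-9)
        assert res.sbr["left"] == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_cr_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_sbr(100.0, 0.0, 70.78, 8.96)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        img = uniform_image() + 0.2 * rng.random((64, 64, 64))
        a = analyze(img, CENTROIDS, spacing=SPACING)
        b = analyze(5.0 * img, CENTROIDS, spacing=SPACING)
        assert b.sbr_mean == pytest.approx(a.sbr_mean, rel=1e-9)

    def test_monotone_in_cs_and_cr(self):
        base = compute_sbr(100.0, 1.0, 70.78, 8.96)
        assert compute_sbr(110.0, 1.0, 70.78, 8.96) > base
        assert compute_sbr(100.0, 1.1, 70.78, 8.96) < base


class TestStriatalVois:
    def test_mirror_symmetric_volumes(self):
        img = uniform_image()
        left, right = place_striatal_vois(img, CENTROIDS, spacing=SPACING)
        assert left.volume_cm3 == right.volume_cm3
        assert not (left.mask & right.mask).any()

    def test_per_side_volume_near_target(self):
        left, _ = place_striatal_vois(uniform_image(), CENTROIDS, spacing=SPACING)
        assert left.volume_cm3 == pytest.approx(141.56 / 2, rel=0.10)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(PlacementError):
            place_striatal_vois(
                uniform_image(n=32),
                {"left": (-45.0, 0.0, 0.0), "right": (45.0, 0.0, 0.0)},
                spacing=SPACING,
            )


class TestReferenceRegion:
    def test_uniform_image_reference_is_eroded_support(self):
        img = uniform_image()
        vois = place_striatal_vois(img, CENTROIDS, spacing=SPACING)
        mask, smoothed = build_reference_region(img, vois, spacing=SPACING)
        assert mask.any()
        # margin removed from the outer border: nothing within 20 mm of it
        # (voxel centres closer than margin + half a voxel are removed)
        border = int((20.0 + 0.5 * 3.2) / 3.2)
        assert not mask[:border].any() and not mask[-border:].any()
        assert mask[border].any()  # and no more than the margin is removed
        # striatal VOI voxels never in the reference
        for voi in vois:
            assert not (mask & voi.mask).any()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        img = uniform_image() * (0.5 + rng.random((64, 64, 64)))
        vois = place_striatal_vois(img, CENTROIDS, spacing=SPACING)
        low, _ = build_reference_region(
            img, vois, AnalysisParams(reference_threshold=0.3), spacing=SPACING
        )
        high, _ = build_reference_region(
            img, vois, AnalysisParams(reference_threshold=0.7), spacing=SPACING
        )
        assert (high & ~low).sum() == 0

    def test_empty_after_margin_raises(self):
        img = uniform_image(n=24)  # 77 mm of support; a 40 mm margin empties it
        params = AnalysisParams(vs_voi_cm3=20.0, vs_cm3=5.0, margin_mm=40.0)
        vois = place_striatal_vois(
            img, {"left": (-12.0, 0.0, 0.0), "right": (12.0, 0.0, 0.0)},
            params, spacing=SPACING,
        )
        with pytest.raises(AnalysisError):
            build_reference_region(img, vois, params, spacing=SPACING)


class TestSmoothWithinMask:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((20, 20, 20))
        mask = rng.random((20, 20, 20)) < 0.5
        out = smooth_within_mask(img, mask, 0.0, spacing=(2, 2, 2))
        np.testing.assert_array_equal(out[mask], img[mask])
        assert (out[~mask] == 0).all()

    def test_constant_field_preserved(self):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[4:20, 4:20, 4:20] = True
        img = np.full((24, 24, 24), 7.0)
        out = smooth_within_mask(img, mask, 12.0, spacing=(2, 2, 2))
        np.testing.assert_allclose(out[mask], 7.0, rtol=1e-9)

    def test_mean_preserved_on_random_fields(self):
        rng = np.random.default_rng(6)
        img = 1.0 + 0.3 * rng.random((32, 32, 32))
        mask = np.zeros((32, 32, 32), dtype=bool)
        mask[6:26, 6:26, 6:26] = True
        out = smooth_within_mask(img, mask, 8.0, spacing=(2, 2, 2))
        assert out[mask].mean() == pytest.approx(img[mask].mean(), rel=0.005)


class TestAnalyze:
    def test_left_right_symmetry_on_symmetric_image(self):
        n = 64
        ax = (np.arange(n) - (n - 1) / 2) * 3.2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        img = np.exp(-(x**2 + y**2 + z**2) / (2 * 60.0**2))
        res = analyze(img, CENTROIDS, spacing=SPACING)
        assert res.sbr["left"] == pytest.approx(res.sbr["right"], rel=1e-6)

    def test_cs_is_cs_total_per_voxel(self):
        rng = np.random.default_rng(9)
        img = uniform_image() + 0.1 * rng.random((64, 64, 64))
        res = analyze(img, CENTROIDS, spacing=SPACING)
        left, _ = place_striatal_vois(img, CENTROIDS, spacing=SPACING)
        n_vox = left.mask.sum()
        assert res.cs["left"] == pytest.approx(res.cs_total["left"] / n_vox)

    def test_ideal_chain_recovers_ratio_minus_one(self, head, segments):
        """Two-compartment digital phantom analysed directly: concentration
        algebra gives SBR = ratio - 1 when Vs equals the true striatal
        volume and the reference is uniform background."""
        cents = striatal_centroids_mm(
            segments.striatum_left, segments.striatum_right, segments.spacing
        )
        vs_true = region_volume(segments.striatum, head.spacing)
        base = np.zeros(head.shape, dtype=np.float64)
        base[segments.parenchyma | segments.ventricles] = 3.6  # no CSF holes
        for ratio in (8.0, 6.0, 4.0):
            act = base.copy()
            act[segments.striatum] = 3.6 * ratio
            res = analyze(
                act, cents, AnalysisParams(vs_cm3=vs_true), spacing=head.spacing
            )
            assert res.sbr_mean == pytest.approx(ratio - 1, rel=0.02)
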