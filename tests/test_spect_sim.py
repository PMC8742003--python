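
import numpy as np
import pytest

from datspect.atrophy import build_bam
from datspect.spect_sim import (
    AcquisitionGeometry,
    DensityParams,
    SourceParams,
    add_scatter,
    make_attenuation_map,
    make_source_map,
    project,
    sample_counts,
)


def small_geometry(**kw):
    defaults = dict(
        n_views=12,
        step_deg=30.0,
        matrix=32,
        pixel_mm=3.2,
        rotation_radius_mm=150.0,
        psf_enabled=False,
        scatter_fraction=0.0,
        n_replicates=3,
    )
    defaults.update(kw)
    return AcquisitionGeometry(**defaults)


class TestSourceMap:
    def test_compartment_concentrations(self, segments):
        bam = build_bam(segments, 2)
        activity = make_source_map(bam, SourceParams(striatum_to_background_ratio=8))
        assert activity[bam.masks["background"]] == pytest.approx(3.60)
        striatum = bam.masks["striatum_left"] | bam.masks["striatum_right"]
        assert activity[striatum] == pytest.approx(28.8)
        assert activity[bam.masks["csf_gap"]] == pytest.approx(0.0)
        assert activity[bam.masks["bone"]] == pytest.approx(0.0)

    def test_total_activity_decreases_with_atrophy(self, segments, head):
        from datspect.atrophy import AtrophyLevel

        totals = [
            make_source_map(
                build_bam(segments, AtrophyLevel(lvl, pixel_mm=head.spacing[0])),
                SourceParams(),
            ).sum()
            for lvl in (1, 2, 3)
        ]
        assert totals[0] > totals[1] > totals[2]

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            SourceParams(striatum_to_background_ratio=0.5)


class TestAttenuationMap:
    def test_compartment_mu_values(self, segments):
        bam = build_bam(segments, 1)
        dens = DensityParams()
        mu = make_attenuation_map(bam, dens)
        assert mu[bam.masks["bone"]] == pytest.approx(1.22 * 0.1444)
        assert mu[bam.masks["background"]] == pytest.approx(1.04 * 0.1464)
        # enclosed CSF attenuates as soft tissue; exterior air does not
        assert mu[bam.masks["csf_gap"]] == pytest.approx(1.04 * 0.1464)
        assert mu[0, 0, 0] == 0.0

    def test_mu_linear_in_density(self):
        dens = DensityParams(soft_density_g_cm3=2.08)
        assert dens.mu("soft") == pytest.approx(2 * 1.04 * 0.1464)
        assert dens.mu("air") == 0.0

    def test_missing_coefficient_raises(self):
        dens = DensityParams(mass_attenuation_cm2_g={"bone": 0.1444})
        with pytest.raises(KeyError):
            dens.mu("soft")


class TestProjector:
    def test_point_source_view_totals_conserved(self):
        geom = small_geometry()
        act = np.zeros((32, 32, 32), dtype=np.float32)
        act[16, 16, 16] = 1.0
        views = project(act, np.zeros_like(act), (3.2,) * 3, geom)
        totals = views.sum(axis=(1, 2))
        assert totals.max() / totals.min() - 1 < 1e-3

    def test_uniform_sphere_attenuation_factor(self):
        # odd-sized input grid puts the point source exactly at the world
        # centre of the mu sphere, so every ray crosses exactly one radius
        geom = small_geometry(matrix=48)
        n, h = 49, 3.2
        ax = (np.arange(n) - (n - 1) / 2) * h
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        r = np.sqrt(x**2 + y**2 + z**2)
        act = np.zeros((n, n, n), dtype=np.float32)
        act[n // 2, n // 2, n // 2] = 1.0
        mu_val, radius_mm = 0.15, 40.0
        mu = np.where(r <= radius_mm, mu_val, 0.0).astype(np.float32)
        vacuum = project(act, np.zeros_like(mu), (h,) * 3, geom)
        attenuated = project(act, mu, (h,) * 3, geom)
        factor = attenuated.sum(axis=(1, 2)) / vacuum.sum(axis=(1, 2))
        expected = np.exp(-mu_val * radius_mm / 10.0)
        assert factor == pytest.approx(expected, rel=0.01)

    def test_linear_in_activity(self):
        rng = np.random.default_rng(5)
        geom = small_geometry()
        a = rng.random((32, 32, 32)).astype(np.float32)
        b = rng.random((32, 32, 32)).astype(np.float32)
        mu = (0.1 * rng.random((32, 32, 32))).astype(np.float32)
        pa = project(a, mu, (3.2,) * 3, geom)
        pb = project(b, mu, (3.2,) * 3, geom)
        pab = project(a + b, mu, (3.2,) * 3, geom)
        np.testing.assert_allclose(pab, pa + pb, rtol=1e-5, atol=1e-7)

    def test_grid_mismatch_rejected(self):
        geom = small_geometry()
        with pytest.raises(ValueError):
            project(np.zeros((8, 8, 8)), np.zeros((9, 8, 8)), (3.2,) * 3, geom)


class TestScatter:
    def make_views(self):
        views = np.zeros((4, 64, 64))
        views[:, 32, 32] = 100.0
        return views

    def test_zero_fraction_is_identity(self):
        geom = small_geometry(n_views=4, step_deg=90.0, matrix=64)
        views = self.make_views()
        np.testing.assert_array_equal(add_scatter(views, geom), views)

    def test_view_totals_preserved(self):
        geom = small_geometry(n_views=4, step_deg=90.0, matrix=64, scatter_fraction=0.3)
        views = self.make_views()
        out = add_scatter(views, geom)
        np.testing.assert_allclose(
            out.sum(axis=(1, 2)), views.sum(axis=(1, 2)), rtol=1e-3
        )

    def test_broadens_point_profile(self):
        geom = small_geometry(n_views=4, step_deg=90.0, matrix=64, scatter_fraction=0.3)
        views = self.make_views()
        out = add_scatter(views, geom)

        def rms_width(img):
            prof = img[32]
            x = np.arange(prof.size)
            c = (prof * x).sum() / prof.sum()
            return np.sqrt((prof * (x - c) ** 2).sum() / prof.sum())

        assert rms_width(out[0]) > rms_width(views[0]) + 1.0


class TestSampleCounts:
    def test_grand_totals_near_requested(self):
        rng = np.random.default_rng(11)
        geom = small_geometry(total_counts=1.5e6, n_replicates=5)
        expectation = rng.random((12, 32, 32))
        reps = sample_counts(expectation, geom, seed=3)
        sigma = np.sqrt(1.5e6)
        for rep in reps:
            assert abs(rep.counts.sum() - 1.5e6) < 4 * sigma
            assert rep.expectation.sum() == pytest.approx(1.5e6)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        geom = small_geometry(n_replicates=2)
        expectation = rng.random((12, 32, 32))
        a = sample_counts(expectation, geom, seed=9)
        b = sample_counts(expectation, geom, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.counts, rb.counts)
        c = sample_counts(expectation, geom, seed=10)
        assert any((ra.counts != rc.counts).any() for ra, rc in zip(a, c))

    def test_poisson_variance_equals_mean(self):
        geom = small_geometry(
            n_views=4, step_deg=90.0, matrix=16, total_counts=200 * 4 * 16 * 16,
            n_replicates=200,
        )
        expectation = np.ones((4, 16, 16))
        reps = sample_counts(expectation, geom, seed=21)
        counts = np.stack([r.counts for r in reps])
        ratio = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        assert 0.8 < ratio.mean() < 1.2

    def test_zero_expectation_rejected(self):
        geom = small_geometry()
        with pytest.raises(ValueError):
            sample_counts(np.zeros((12, 32, 32)), geom, seed=0)


class TestGeometry:
    def test_angle_coverage_enforced(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(n_views=90, step_deg=3.0)

    def test_psf_sigma_grows_with_distance(self):
        geom = AcquisitionGeometry()
        assert geom.psf_sigma_mm(200.0) > geom.psf_sigma_mm(50.0)
        near = geom.psf_sigma_mm(0.0) * 2 * np.sqrt(2 * np.log(2))
        assert near == pytest.approx(3.8)
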