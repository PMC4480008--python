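"""Camera model: aperture, linearity, skin term, depth scan, calibration."""

import numpy as np
import pytest

import tissuebeam as tb
from tissuebeam.imaging import (
    ImagingConfig,
    backscatter_image,
    backscatter_radial_profile,
    calibrate_refractive_index,
    depth_scan,
    image_from_exits,
    skin_psf_contribution,
    sum_plane_contributions,
)
from tissuebeam.montecarlo import ExitRecords


def records(x, y, dx, dy, dz, w, origin):
    arr = lambda v: np.asarray(v, dtype=float)
    return ExitRecords(arr(x), arr(y), arr(dx), arr(dy), arr(dz), arr(w), arr(origin))


BEAM = tb.BeamSpec(focal_depth_um=100.0)
FINE = ImagingConfig(pixel_um=0.02, half_extent_um=5.12)


class TestImageFormation:
    def test_on_axis_focal_records_give_ideal_psf(self):
        """Rays leaving straight from the focus image to the ideal waist."""
        n = 1000
        rec = records(
            np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n), -np.ones(n),
            np.ones(n), np.full(n, 100.0),
        )
        img = image_from_exits(rec, BEAM, 100.0, cfg=FINE)
        r, prof = img.radial_profile((0.0, 0.0))
        xx = np.concatenate([-r[::-1], r])
        yy = np.concatenate([prof[::-1], prof])
        assert tb.fwhm(xx, yy) == pytest.approx(0.13, rel=0.15)

    def test_rays_outside_collection_cone_rejected(self):
        inside = records([0], [0], [0.01], [0], [-np.sqrt(1 - 1e-4)], [1.0], [100.0])
        outside = records([0], [0], [0.9], [0], [-np.sqrt(1 - 0.81)], [1.0], [100.0])
        img_in = image_from_exits(inside, BEAM, 100.0, cfg=FINE)
        with pytest.warns(UserWarning, match="collection cone"):
            img_out = image_from_exits(outside, BEAM, 100.0, cfg=FINE)
        assert img_in.values.sum() > 0
        assert img_out.values.sum() == 0

    def test_linearity_over_record_sets(self):
        """Imaging the union of two record sets equals the image sum."""
        rng = np.random.default_rng(5)
        n = 500
        mk = lambda seed_shift: records(
            rng.normal(0, 20, n), rng.normal(0, 20, n),
            rng.normal(0, 0.1, n), rng.normal(0, 0.1, n), -np.ones(n),
            rng.random(n), np.full(n, 50.0),
        )
        r1, r2 = mk(0), mk(1)
        both = ExitRecords.concatenate([r1, r2])
        img = image_from_exits(both, BEAM, 100.0, cfg=FINE)
        img_sum = (
            image_from_exits(r1, BEAM, 100.0, cfg=FINE).values
            + image_from_exits(r2, BEAM, 100.0, cfg=FINE).values
        )
        np.testing.assert_allclose(img.values, img_sum, atol=1e-10)

    def test_aperture_monotonicity(self):
        """A larger NA never collects less weight."""
        rng = np.random.default_rng(9)
        n = 2000
        sin_t = rng.random(n) * 0.9
        phi = rng.random(n) * 2 * np.pi
        rec = records(
            rng.normal(0, 5, n), rng.normal(0, 5, n),
            sin_t * np.cos(phi), sin_t * np.sin(phi), -np.sqrt(1 - sin_t**2),
            np.ones(n), np.full(n, 100.0),
        )
        collected = []
        for na in (0.4, 0.6, 0.8, 1.0):
            beam = tb.BeamSpec(focal_depth_um=100.0, numerical_aperture=na)
            img = image_from_exits(rec, beam, 100.0, cfg=ImagingConfig())
            collected.append(img.values.sum())
        assert np.all(np.diff(collected) >= 0)

    def test_sum_plane_contributions(self):
        rec = records([0], [0], [0], [0], [-1], [1.0], [100.0])
        img = image_from_exits(rec, BEAM, 100.0, cfg=FINE)
        zero = tb.CameraImage(
            np.zeros_like(img.values), img.pixel_um, img.half_extent_um, 100.0
        )
        total, (r, prof) = sum_plane_contributions([img, zero])
        np.testing.assert_allclose(total.values, img.values)
        other = tb.CameraImage(np.zeros((4, 4)), 0.1, 0.2, 100.0)
        with pytest.raises(ValueError):
            sum_plane_contributions([img, other])


class TestSkinContribution:
    def test_width_grows_and_peak_decays_with_depth(self):
        imgs = [
            skin_psf_contribution(d, tb.BeamSpec(focal_depth_um=d), 0.03)
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        peaks = [im.values.max() for im in imgs]
        assert np.all(np.diff(peaks) < 0)
        # widths grow ~linearly with depth
        sig = []
        for im in imgs:
            r, prof = im.radial_profile((0.0, 0.0))
            sig.append(tb.fwhm(np.concatenate([-r[::-1], r]),
                               np.concatenate([prof[::-1], prof])))
        assert np.all(np.diff(sig) > 0)
        assert sig[2] == pytest.approx(2 * sig[1], rel=0.1)

    def test_shallow_limit_is_ideal_psf(self):
        img = skin_psf_contribution(1e-6, tb.BeamSpec(focal_depth_um=1.0), 0.03,
                                    cfg=ImagingConfig(pixel_um=0.02, half_extent_um=2.56))
        r, prof = img.radial_profile((0.0, 0.0))
        w = tb.fwhm(np.concatenate([-r[::-1], r]), np.concatenate([prof[::-1], prof]))
        assert w == pytest.approx(0.13, rel=0.15)

    def test_negative_reflectivity_rejected(self):
        with pytest.raises(ValueError):
            skin_psf_contribution(10.0, BEAM, -0.1)


class TestBackscatterPipeline:
    def test_focal_plane_dominates_deep_plane(self):
        """The focal plane's contribution is sharply peaked while a plane
        100 um deeper contributes a much weaker, flatter profile."""
        region = tb.region_preset("pvl")
        beam = tb.BeamSpec(focal_depth_um=100.0)
        cfg = tb.SimulationConfig(n_photons=4000, rng_seed=71, record_spacing_um=4.0)
        total, per_plane, res = backscatter_image(
            region, beam, cfg, return_per_plane=True
        )
        z = np.array([c.z_um for c in res.crossings])
        k_focus = int(np.argmin(np.abs(z - 100.0)))
        k_deep = int(np.argmin(np.abs(z - 200.0)))
        peak = lambda img: img.radial_profile((0.0, 0.0))[1].max()
        assert peak(per_plane[k_focus]) > 10 * peak(per_plane[k_deep])

    def test_decomposition_matches_single_image(self):
        """Summing per-plane images equals imaging all exits in one pass."""
        region = tb.region_preset("neuropil")
        beam = tb.BeamSpec(focal_depth_um=50.0)
        cfg = tb.SimulationConfig(n_photons=2000, rng_seed=73, record_spacing_um=10.0)
        total, per_plane, _ = backscatter_image(
            region, beam, cfg, return_per_plane=True
        )
        summed, _ = sum_plane_contributions(per_plane)
        np.testing.assert_allclose(total.values, summed.values, atol=1e-12)

    def test_depth_scan_components(self):
        """Total backscatter decreases smoothly; skin dominates at the
        shallowest depths, the brain return around mid depths."""
        region = tb.region_preset("pvl")
        beam = tb.BeamSpec(focal_depth_um=10.0)
        cfg = tb.SimulationConfig(n_photons=2500, rng_seed=79, record_spacing_um=4.0)
        scan = depth_scan(
            np.array([8.0, 20.0, 35.0, 50.0]), region, beam, cfg
        )
        df = scan.to_dataframe()
        assert np.all(np.diff(df.peak_total) < 0)
        assert df.peak_skin[0] > df.peak_brain[0]
        ratio_mid = df.peak_brain[2] / df.peak_skin[2]
        assert ratio_mid > df.peak_brain[0] / df.peak_skin[0]

    def test_depth_scan_needs_two_depths(self):
        with pytest.raises(ValueError):
            depth_scan(np.array([10.0]), tb.region_preset("pvl"), BEAM,
                       tb.SimulationConfig(n_photons=100, rng_seed=1))


class TestRefractiveIndexCalibration:
    @pytest.fixture(scope="class")
    def reference(self):
        region = tb.region_preset("pvl")
        beam = tb.BeamSpec(focal_depth_um=40.0)
        cfg = tb.SimulationConfig(n_photons=3000, rng_seed=5, record_spacing_um=4.0)
        r, prof = backscatter_radial_profile(region, beam, cfg)
        return region, beam, cfg, r, prof

    def test_self_recovery_and_identifiability(self, reference):
        """Calibration recovers the generating index; the objective grows
        with |n - n_true| on both sides of the optimum."""
        region, beam, cfg, r, prof = reference
        grid = np.array([1.342, 1.346, 1.35, 1.354, 1.358])
        out = calibrate_refractive_index(r, prof, grid, region, beam, cfg)
        assert out["best_n_nucleus"] == 1.35
        obj = out["objective"]
        i = int(np.argmin(obj))
        assert np.all(np.diff(obj[: i + 1]) <= 0)
        assert np.all(np.diff(obj[i:]) >= 0)

    def test_grid_outside_allowed_band_rejected(self, reference):
        region, beam, cfg, r, prof = reference
        with pytest.raises(ValueError):
            calibrate_refractive_index(
                r, prof, np.array([1.30]), region, beam, cfg
            )
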