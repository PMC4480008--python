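"""Photon transport: launch geometry, free paths, conservation, convolution."""

import dataclasses
import math

import numpy as np
import pytest

import tissuebeam as tb
from tissuebeam.montecarlo import (
    IntensityGrid,
    backscatter_pass,
    default_radial_edges,
    diffraction_convolution,
    launch_photons,
    propagate,
)
from tissuebeam.tissue import transport_parameters


class TestLaunch:
    def test_rays_aim_exactly_at_focus(self):
        beam = tb.BeamSpec(focal_depth_um=100.0)
        cfg = tb.SimulationConfig(n_photons=1000, rng_seed=3)
        batch = launch_photons(beam, cfg, n_medium=1.34)
        t = beam.focal_depth_um / batch.directions[:, 2]
        hit = batch.positions[:, :2] + t[:, None] * batch.directions[:, :2]
        assert np.all(np.abs(hit) < 1e-9)
        assert np.allclose(np.linalg.norm(batch.directions, axis=1), 1.0, atol=1e-12)

    def test_on_axis_ray_points_down_z(self):
        beam = tb.BeamSpec(focal_depth_um=50.0)
        cfg = tb.SimulationConfig(n_photons=2000, rng_seed=4)
        batch = launch_photons(beam, cfg, n_medium=1.34)
        i = int(np.argmin(np.hypot(batch.positions[:, 0], batch.positions[:, 1])))
        # a ray launched (almost) on axis travels (almost) straight down
        assert batch.directions[i, 2] == pytest.approx(1.0, abs=1e-3)

    def test_launch_centred_and_scaled(self):
        beam = tb.BeamSpec(focal_depth_um=100.0)
        cfg = tb.SimulationConfig(n_photons=100_000, rng_seed=5)
        batch = launch_photons(beam, cfg, n_medium=1.34)
        sigma_expected = 100.0 * math.tan(math.asin(0.8 / 1.34)) / 2.0
        se = sigma_expected / math.sqrt(cfg.n_photons)
        assert abs(batch.positions[:, 0].mean()) < 3 * se
        assert abs(batch.positions[:, 1].mean()) < 3 * se
        assert batch.positions[:, 0].std() == pytest.approx(sigma_expected, rel=0.02)

    def test_na_above_medium_index_rejected(self):
        beam = tb.BeamSpec(focal_depth_um=100.0, numerical_aperture=1.4)
        cfg = tb.SimulationConfig(n_photons=10, rng_seed=0)
        with pytest.raises(ValueError):
            launch_photons(beam, cfg, n_medium=1.34)


class TestPropagation:
    def test_ballistic_rays_converge_to_focal_bin(self, ballistic_run):
        beam, cfg, result = ballistic_run
        k = int(np.argmin(np.abs(result.grid.z_um - beam.focal_depth_um)))
        row = result.grid.values[k]
        assert row[0] == pytest.approx(row.sum(), rel=1e-12)  # all in central bin

    def test_zero_contrast_reproduces_ballistic(self, ballistic_run):
        beam, cfg, ballistic = ballistic_run
        matched = tb.TissueRegion(
            "matched", volume_fraction=0.45, nucleus_diameter_um=4.0, n_nucleus=1.34
        )
        res = tb.simulate(beam, matched, cfg)
        np.testing.assert_array_equal(res.grid.values, ballistic.grid.values)

    def test_deterministic_given_seed(self):
        beam = tb.BeamSpec(focal_depth_um=40.0)
        cfg = tb.SimulationConfig(n_photons=20_000, rng_seed=17)
        r1 = tb.simulate(beam, tb.region_preset("pvl"), cfg)
        r2 = tb.simulate(beam, tb.region_preset("pvl"), cfg)
        np.testing.assert_array_equal(r1.grid.values, r2.grid.values)

    def test_free_path_oracle(self, isotropic_props):
        """Mean logged inter-event path agrees with 1/mu_s within 3 SE.

        Walkers start mid-slab (via the reflection pass) in a slab thousands
        of mean free paths thick and stop on the event cap, so no free-path
        draw is censored by a boundary.
        """
        from tissuebeam.montecarlo import _transport_pass

        region = tb.TissueRegion("iso", volume_fraction=0.3, nucleus_diameter_um=2.0)
        tp = transport_parameters(region, isotropic_props)
        n = 20_000
        rng = np.random.default_rng(23)
        pos = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, 5000.0)])
        dirs = np.column_stack([np.zeros(n), np.zeros(n), np.ones(n)])
        stats = _transport_pass(
            pos, dirs, np.ones(n), tp, isotropic_props, rng,
            z_hi=10_000.0, max_events=50,
        )
        assert stats["forward_exit_weight"] == 0.0  # nobody reaches a boundary
        assert stats["backward_exit_weight"] == 0.0
        mean_path = stats["event_path_sum"] / stats["n_scatter_events"]
        se = tp.mean_free_path_um / math.sqrt(stats["n_scatter_events"])
        assert abs(mean_path - tp.mean_free_path_um) < 3 * se

    def test_energy_conservation(self, nucleus_props):
        """launched = forward + backward + capped, to 1e-9."""
        beam = tb.BeamSpec(focal_depth_um=100.0)
        cfg = tb.SimulationConfig(n_photons=50_000, rng_seed=31)
        res = tb.simulate(beam, tb.region_preset("pvl"), cfg)
        b = res.bookkeeping
        total = b["forward_exit_weight"] + b["backward_exit_weight"] + b["capped_weight"]
        assert total == pytest.approx(b["launched_weight"], abs=1e-9)
        assert b["cap_breaches"] == 0

    def test_backscatter_fraction_small_for_forward_scatterers(self, nucleus_props):
        """With g > 0.9, under 1% of the launched weight returns upward."""
        beam = tb.BeamSpec(focal_depth_um=100.0)
        cfg = tb.SimulationConfig(n_photons=50_000, rng_seed=37)
        res = tb.simulate(beam, tb.region_preset("pvl"), cfg)
        b = res.bookkeeping
        assert b["backward_exit_weight"] < 0.01 * b["launched_weight"]


class TestBackscatterPass:
    def _ballistic_crossings(self, n=2000, depth=60.0, seed=41):
        beam = tb.BeamSpec(focal_depth_um=depth)
        region = tb.region_preset("ballistic")
        props = tb.scattering_properties(region.scatterer(beam.wavelength_um))
        tp = transport_parameters(region, props)
        cfg = tb.SimulationConfig(
            n_photons=n, rng_seed=seed, record_planes=True,
            record_halfspan_um=depth, record_spacing_um=depth,
            accumulate_fluence=False,
        )
        rng = np.random.default_rng(cfg.rng_seed)
        batch = launch_photons(beam, cfg, region.n_medium, rng)
        res = propagate(batch, tp, props, cfg, beam, rng)
        return beam, cfg, tp, props, batch, res, rng

    def test_ballistic_retrace_mirrors_launch(self):
        """Reflected at the focal plane with mu_s = 0, every ray exits at the
        mirror image of its launch position with reversed z-direction."""
        beam, cfg, tp, props, batch, res, rng = self._ballistic_crossings()
        focal_plane = [c for c in res.crossings if c.z_um == beam.focal_depth_um][0]
        exits = backscatter_pass(focal_plane, tp, props, cfg, beam, rng)
        assert exits.n == batch.n
        np.testing.assert_allclose(exits.x, -batch.positions[:, 0], atol=1e-3)
        np.testing.assert_allclose(exits.y, -batch.positions[:, 1], atol=1e-3)
        np.testing.assert_allclose(exits.dz, -batch.directions[:, 2], atol=1e-6)

    def test_exit_weight_bookkeeping(self, nucleus_props):
        """Exit weight never exceeds reflected weight; equal when no caps."""
        beam = tb.BeamSpec(focal_depth_um=60.0)
        region = tb.region_preset("pvl")
        tp = transport_parameters(region, nucleus_props)
        cfg = tb.SimulationConfig(
            n_photons=5000, rng_seed=43, record_planes=True,
            record_halfspan_um=60.0, record_spacing_um=30.0,
            accumulate_fluence=False,
        )
        rng = np.random.default_rng(cfg.rng_seed)
        batch = launch_photons(beam, cfg, region.n_medium, rng)
        res = propagate(batch, tp, nucleus_props, cfg, beam, rng)
        for pc in res.crossings:
            if pc.weight.size == 0:
                continue
            exits = backscatter_pass(pc, tp, nucleus_props, cfg, beam, rng,
                                     reflectivity=0.5)
            reflected = 0.5 * pc.total_weight
            assert exits.total_weight <= reflected * (1 + 1e-9)

    def test_negative_reflectivity_rejected(self, nucleus_props):
        beam, cfg, tp, props, batch, res, rng = self._ballistic_crossings(n=10)
        with pytest.raises(ValueError):
            backscatter_pass(res.crossings[0], tp, props, cfg, beam, rng,
                             reflectivity=-1.0)


class TestDiffractionConvolution:
    def _delta_grid(self, z0=50.0):
        z = z0 + np.arange(-3.0, 3.0001, 0.02)
        edges = default_radial_edges()
        vals = np.zeros((len(z), len(edges) - 1))
        vals[len(z) // 2, 0] = 1.0
        return IntensityGrid(edges, z, vals)

    def test_delta_maps_to_kernel(self):
        """A point source becomes the ideal waist: 0.13 / 0.29 um FWHM."""
        beam = tb.BeamSpec(focal_depth_um=50.0)
        gc = diffraction_convolution(self._delta_grid(), beam)
        x = gc.r_centers
        prof = gc.values[len(gc.z_um) // 2]
        xx = np.concatenate([-x[::-1], x])
        yy = np.concatenate([prof[::-1], prof])
        assert tb.fwhm(xx, yy) == pytest.approx(0.13, rel=0.01)
        assert tb.fwhm(gc.z_um, gc.values[:, 0]) == pytest.approx(0.29, rel=0.01)

    def test_weight_conserved(self):
        """Total weight is preserved by the convolution up to truncation.

        The mass sits in the finely binned core so the grid's own annulus
        quadrature resolves the smoothed result.
        """
        g = self._delta_grid()
        g.values[:] = 0.0
        g.values[len(g.z_um) // 2] = np.exp(-g.r_centers**2 / (2 * 0.15**2)) * g.bin_areas
        w0 = g.values.sum()
        gc = diffraction_convolution(g, tb.BeamSpec(focal_depth_um=50.0))
        w1 = (gc.values * gc.bin_areas[None, :]).sum()
        assert w1 == pytest.approx(w0, rel=1e-3)

    def test_gaussian_semigroup(self):
        """Convolving twice with kernel/sqrt(2) equals one full convolution."""
        beam = tb.BeamSpec(focal_depth_um=50.0)
        half = dataclasses.replace(
            beam,
            ideal_fwhm_transverse_um=0.13 / math.sqrt(2),
            ideal_fwhm_axial_um=0.29 / math.sqrt(2),
        )
        g = self._delta_grid()
        once = diffraction_convolution(g, beam)
        first = diffraction_convolution(g, half)
        # re-wrap the density as bin weights for the second pass
        gm = IntensityGrid(
            first.r_edges, first.z_um, first.values * first.bin_areas[None, :]
        )
        twice = diffraction_convolution(gm, half)
        k = len(g.z_um) // 2
        a = once.values[k] / once.values[k].max()
        b = twice.values[k] / twice.values[k].max()
        np.testing.assert_allclose(a[:40], b[:40], atol=0.02)

    def test_double_convolution_rejected(self):
        beam = tb.BeamSpec(focal_depth_um=50.0)
        gc = diffraction_convolution(self._delta_grid(), beam)
        with pytest.raises(ValueError):
            diffraction_convolution(gc, beam)

    def test_kernel_wider_than_grid_rejected(self):
        z = 50.0 + np.arange(-0.05, 0.0501, 0.02)
        edges = default_radial_edges()
        g = IntensityGrid(edges, z, np.zeros((len(z), len(edges) - 1)))
        with pytest.raises(ValueError):
            diffraction_convolution(g, tb.BeamSpec(focal_depth_um=50.0))


class TestConfigValidation:
    def test_bad_configs_raise(self):
        with pytest.raises(ValueError):
            tb.SimulationConfig(n_photons=0)
        with pytest.raises(ValueError):
            tb.SimulationConfig(radial_edges=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            tb.BeamSpec(focal_depth_um=-5.0)

    def test_photon_batch_validates_directions(self):
        with pytest.raises(ValueError):
            tb.PhotonBatch(
                positions=np.zeros((2, 3)),
                directions=np.array([[0, 0, 1.0], [0, 0, 2.0]]),
                weights=np.ones(2),
                alive=np.ones(2, bool),
            )
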