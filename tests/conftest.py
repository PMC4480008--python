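import numpy as np
import pytest

import tissuebeam as tb


@pytest.fixture(scope="session")
def nucleus_scatterer() -> tb.SphereScatterer:
    """The model's reference scatterer: a 4 um nucleus (n 1.35) in neural
    tissue (n 1.34) at 488 nm."""
    return tb.SphereScatterer(
        diameter_um=4.0, n_sphere=1.35, n_medium=1.34, wavelength_um=0.488
    )


@pytest.fixture(scope="session")
def nucleus_props(nucleus_scatterer) -> tb.ScatteringProperties:
    return tb.scattering_properties(nucleus_scatterer)


@pytest.fixture(scope="session")
def isotropic_props() -> tb.ScatteringProperties:
    """Synthetic isotropic scatterer (uniform over solid angle) with unit
    cross-section; handy for transport oracles where g = 0 exactly."""
    theta = np.linspace(0.0, np.pi, 1801)
    pdf = np.full_like(theta, 1.0 / (4.0 * np.pi))
    cdf = (1.0 - np.cos(theta)) / 2.0
    return tb.ScatteringProperties(
        cross_section_um2=1.0, anisotropy_g=0.0, theta=theta, pdf=pdf, cdf=cdf
    )


@pytest.fixture(scope="session")
def ballistic_run():
    """Scatter-free reference simulation at 100 um focus, 1e5 rays."""
    beam = tb.BeamSpec(focal_depth_um=100.0)
    cfg = tb.SimulationConfig(n_photons=100_000, rng_seed=101)
    result = tb.simulate(beam, tb.region_preset("ballistic"), cfg)
    return beam, cfg, result
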