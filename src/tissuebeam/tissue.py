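"""Tissue descriptions and their conversion to photon-transport parameters.

Brain tissue is modelled as a homogeneous background medium containing
discrete, independently scattering nuclei.  A region is summarised by the
nuclear volume fraction, the nucleus diameter, and the two refractive
indices; these map onto a number density, a scattering coefficient mu_s, and
a mean free path.

Two presets emulate the larval zebrafish optic tectum: the periventricular
layer (PVL), densely packed with cell bodies and hence nuclei, and the
neuropil, which is nearly devoid of them.  The preset volume fractions are
placeholders on the right anatomical scale, not measured values, and are
meant to be overridden from config when better numbers exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mie import ScatteringProperties, SphereScatterer

__all__ = [
    "TissueRegion",
    "TransportParameters",
    "transport_parameters",
    "region_preset",
    "REGION_PRESETS",
]


@dataclass(frozen=True)
class TissueRegion:
    """A homogeneous tissue region populated by identical spherical nuclei."""

    name: str
    volume_fraction: float
    nucleus_diameter_um: float
    n_medium: float = 1.34
    n_nucleus: float = 1.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction < 1.0:
            raise ValueError(f"volume_fraction must lie in [0, 1), got {self.volume_fraction}")
        if self.nucleus_diameter_um <= 0:
            raise ValueError("nucleus_diameter_um must be positive")

    def scatterer(self, wavelength_um: float) -> SphereScatterer:
        return SphereScatterer(
            diameter_um=self.nucleus_diameter_um,
            n_sphere=self.n_nucleus,
            n_medium=self.n_medium,
            wavelength_um=wavelength_um,
        )


@dataclass(frozen=True)
class TransportParameters:
    """Monte Carlo transport parameters for a tissue region.

    ``mean_free_path_um`` is infinite for a ballistic (scatter-free) medium;
    that is a valid state, not an error.
    """

    number_density_per_um3: float
    mu_s_per_um: float
    mean_free_path_um: float
    anisotropy_g: float

    @property
    def ballistic(self) -> bool:
        return self.mu_s_per_um == 0.0


def transport_parameters(
    region: TissueRegion, props: ScatteringProperties
) -> TransportParameters:
    """Combine region geometry with single-scatterer optics.

    number_density = volume_fraction / (pi d^3 / 6); mu_s = density * sigma_s.
    """
    nucleus_volume = math.pi * region.nucleus_diameter_um**3 / 6.0
    density = region.volume_fraction / nucleus_volume
    mu_s = density * props.cross_section_um2
    return TransportParameters(
        number_density_per_um3=density,
        mu_s_per_um=mu_s,
        mean_free_path_um=math.inf if mu_s == 0.0 else 1.0 / mu_s,
        anisotropy_g=props.anisotropy_g,
    )


#: Nuclear volume fractions: the PVL is rich with nuclei, the neuropil nearly
#: devoid of them.  Nucleus diameter 4.0 um sits below the measured tectal
#: cell-body diameters (4.84/5.68 um transverse).  All values config-exposed.
REGION_PRESETS: dict[str, TissueRegion] = {
    "pvl": TissueRegion("pvl", volume_fraction=0.45, nucleus_diameter_um=4.0),
    "neuropil": TissueRegion("neuropil", volume_fraction=0.02, nucleus_diameter_um=4.0),
    "ballistic": TissueRegion("ballistic", volume_fraction=0.0, nucleus_diameter_um=4.0),
}


def region_preset(name: str, **overrides) -> TissueRegion:
    """Fetch a named preset, optionally overriding fields."""
    try:
        base = REGION_PRESETS[name.lower()]
    except KeyError as exc:
        raise KeyError(
            f"unknown region preset {name!r}; known: {sorted(REGION_PRESETS)}"
        ) from exc
    if not overrides:
        return base
    kwargs = {
        "name": base.name,
        "volume_fraction": base.volume_fraction,
        "nucleus_diameter_um": base.nucleus_diameter_um,
        "n_medium": base.n_medium,
        "n_nucleus": base.n_nucleus,
    }
    kwargs.update(overrides)
    return TissueRegion(**kwargs)


def region_from_config(block: dict) -> TissueRegion:
    """Build a region from a ``tissue:`` YAML config block entry."""
    return TissueRegion(
        name=block.get("name", "custom"),
        volume_fraction=float(block["volume_fraction"]),
        nucleus_diameter_um=float(block.get("nucleus_diameter_um", 4.0)),
        n_medium=float(block.get("n_medium", 1.34)),
        n_nucleus=float(block.get("n_nucleus", 1.35)),
    )
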