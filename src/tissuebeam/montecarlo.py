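"""Monte Carlo transport of a focused beam through nucleus-scattering tissue.

The beam is treated as a bundle of rays: launch positions are drawn from a
2-D Gaussian on the skin plane (z = 0) whose 1/e^2 radius equals the
geometric footprint of the focusing cone, and every ray initially points at
the focal point.  Rays fly in straight lines between scattering events; free
paths are exponential with the region's mean free path, and each event
rotates the direction by a polar angle drawn from the Lorenz–Mie phase
function (uniform azimuth).  Scattering is elastic and absorption-free, so
ray weights never change; rays terminate only by leaving the slab or by
hitting the event cap.

Fluence is accumulated on a cylindrical (r, z) grid of plane crossings
around the focus.  Because this is ray optics, diffraction is restored
afterwards by convolving with the ideal beam's Gaussian waist
(:func:`diffraction_convolution` for the grid, or the 1-D helpers for
extracted profiles).

For backscatter imaging, crossings of coarser recording planes (1 um apart,
focus +/- 100 um) can be logged with directions; :func:`backscatter_pass`
re-launches those rays with the axial direction mirrored (every ray
reflected, specular reversal) and transports them back to the skin,
producing exit records for the camera model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .mie import ScatteringProperties
from .tissue import TissueRegion, TransportParameters, transport_parameters
from . import mie

__all__ = [
    "BeamSpec",
    "SimulationConfig",
    "PhotonBatch",
    "IntensityGrid",
    "PlaneCrossings",
    "ExitRecords",
    "PropagationResult",
    "launch_photons",
    "propagate",
    "backscatter_pass",
    "diffraction_convolution",
    "simulate",
    "gaussian_kernel1d",
    "convolve_profile",
    "hankel_gaussian_smooth",
    "default_radial_edges",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class BeamSpec:
    """A focused Gaussian beam entering the tissue at the skin plane.

    The ideal FWHMs describe the diffraction-limited focal spot of the
    objective; they parameterise the waist used to restore diffraction on
    top of the ray-optics result.
    """

    focal_depth_um: float
    wavelength_um: float = 0.488
    numerical_aperture: float = 0.8
    ideal_fwhm_transverse_um: float = 0.13
    ideal_fwhm_axial_um: float = 0.29
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.focal_depth_um <= 0:
            raise ValueError("focal_depth_um must be positive")
        if self.numerical_aperture <= 0:
            raise ValueError("numerical_aperture must be positive")
        if self.ideal_fwhm_transverse_um <= 0 or self.ideal_fwhm_axial_um <= 0:
            raise ValueError("ideal FWHMs must be positive")

    def half_angle(self, n_medium: float) -> float:
        """Marginal-ray half angle inside the medium, asin(NA / n_medium)."""
        if self.numerical_aperture >= n_medium:
            raise ValueError(
                f"NA = {self.numerical_aperture} must be below the medium index {n_medium}"
            )
        return math.asin(self.numerical_aperture / n_medium)


def default_radial_edges() -> np.ndarray:
    """Non-uniform radial bin edges: ~1 nm near the axis, coarsening outward.

    The innermost bins must be far narrower than the ideal waist so the
    central-cylinder estimate of the axial profile is effectively a line
    sample (the geometric cone's axial tails bias the estimate by ~r0^2,
    so the first edge sits at 1.25 nm); coarse outer bins keep the grid
    small.
    """
    return np.concatenate(
        [
            [0.0, 0.00125, 0.0025, 0.00375],
            np.arange(0.005, 0.1, 0.005),
            np.arange(0.1, 1.0, 0.02),
            np.arange(1.0, 12.0001, 0.1),
        ]
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Problem sizes and grids for one transport run."""

    n_photons: int = 100_000
    rng_seed: int = 0
    fine_halfspan_um: float = 6.0      # fluence planes span focus +/- this
    fine_spacing_um: float = 0.02
    radial_edges: np.ndarray = field(default_factory=default_radial_edges)
    record_planes: bool = False        # log directional crossings for imaging
    record_spacing_um: float = 1.0
    record_halfspan_um: float = 100.0
    accumulate_fluence: bool = True
    max_events: int = 10_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be at least 1")
        if self.fine_spacing_um <= 0 or self.record_spacing_um <= 0:
            raise ValueError("plane spacings must be positive")
        edges = np.asarray(self.radial_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("radial_edges must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "radial_edges", edges)

    def fine_planes(self, focal_depth_um: float) -> np.ndarray:
        z = focal_depth_um + np.arange(
            -self.fine_halfspan_um,
            self.fine_halfspan_um + self.fine_spacing_um / 2,
            self.fine_spacing_um,
        )
        return z[z > 0.0]

    def recording_planes(self, focal_depth_um: float) -> np.ndarray:
        z = focal_depth_um + np.arange(
            -self.record_halfspan_um,
            self.record_halfspan_um + self.record_spacing_um / 2,
            self.record_spacing_um,
        )
        return z[z >= 0.0]


@dataclass
class PhotonBatch:
    """In-flight rays: positions (N, 3) um, unit directions (N, 3), weights."""

    positions: np.ndarray
    directions: np.ndarray
    weights: np.ndarray
    alive: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors to 1e-9")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.weights)


@dataclass
class IntensityGrid:
    """Cylindrical (r, z) fluence map around the focus.

    ``values`` holds raw crossing weight per (plane, radial bin) when
    ``convolved`` is False, and point intensity (weight per um^2) sampled at
    the radial bin centres after :func:`diffraction_convolution`.
    """

    r_edges: np.ndarray
    z_um: np.ndarray
    values: np.ndarray  # shape (nz, nr)
    convolved: bool = False

    @property
    def r_centers(self) -> np.ndarray:
        return (self.r_edges[:-1] + self.r_edges[1:]) / 2.0

    @property
    def bin_areas(self) -> np.ndarray:
        return np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)

    def density(self) -> np.ndarray:
        """Fluence per um^2 at each (plane, radial bin)."""
        if self.convolved:
            return self.values
        return self.values / self.bin_areas[None, :]

    def radial_profile(self, z_um: float) -> tuple[np.ndarray, np.ndarray]:
        """Azimuthally averaged intensity vs radius at the plane nearest z."""
        k = int(np.argmin(np.abs(self.z_um - z_um)))
        return self.r_centers, self.density()[k]

    def axial_profile(self, r_max_um: float = 0.00125) -> tuple[np.ndarray, np.ndarray]:
        """On-axis intensity vs z: fluence inside a thin central cylinder.

        Only meaningful on the raw grid; after transverse convolution the
        on-axis column is already a point sample and this raises.
        """
        if self.convolved:
            raise ValueError("axial_profile is defined on the raw (unconvolved) grid")
        nbins = int(np.searchsorted(self.r_edges, r_max_um * (1 + 1e-9)) - 1)
        nbins = max(nbins, 1)
        area = math.pi * self.r_edges[nbins] ** 2
        return self.z_um, self.values[:, :nbins].sum(axis=1) / area


@dataclass
class PlaneCrossings:
    """Forward (downward) ray crossings of one recording plane."""

    z_um: float
    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    weight: np.ndarray

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())


@dataclass
class ExitRecords:
    """Rays leaving the tissue through the skin plane (z = 0), headed out."""

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray  # negative: out of the tissue
    weight: np.ndarray
    origin_plane_um: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.dz >= 0):
            raise ValueError("exit directions must have negative z-component")

    @property
    def n(self) -> int:
        return len(self.weight)

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "dx": self.dx,
                "dy": self.dy,
                "dz": self.dz,
                "weight": self.weight,
                "origin_plane_um": self.origin_plane_um,
            }
        )

    @staticmethod
    def concatenate(records: list["ExitRecords"]) -> "ExitRecords":
        records = [r for r in records if r.n > 0]
        if not records:
            empty = np.empty(0)
            return ExitRecords(empty, empty, empty, empty, empty - 1.0, empty, empty)
        return ExitRecords(
            *(
                np.concatenate([getattr(r, f) for r in records])
                for f in ("x", "y", "dx", "dy", "dz", "weight", "origin_plane_um")
            )
        )


@dataclass
class PropagationResult:
    grid: IntensityGrid | None
    crossings: list[PlaneCrossings] | None
    bookkeeping: dict
    beam: BeamSpec
    transport: TransportParameters
    config: SimulationConfig


def launch_photons(
    beam: BeamSpec,
    cfg: SimulationConfig,
    n_medium: float,
    rng: np.random.Generator | None = None,
) -> PhotonBatch:
    """Sample the ray bundle on the skin plane.

    Positions: 2-D Gaussian with 1/e^2 radius equal to the cone footprint
    focal_depth * tan(half_angle).  Directions: exactly at the focal point.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    half = beam.half_angle(n_medium)
    sigma = beam.focal_depth_um * math.tan(half) / 2.0  # 1/e^2 radius = 2 sigma
    xy = rng.normal(0.0, sigma, size=(cfg.n_photons, 2))
    pos = np.column_stack([xy, np.zeros(cfg.n_photons)])
    dirs = np.column_stack([-xy, np.full(cfg.n_photons, beam.focal_depth_um)])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    w = np.full(cfg.n_photons, beam.power / cfg.n_photons)
    return PhotonBatch(pos, dirs, w, np.ones(cfg.n_photons, dtype=bool))


def _rotate_directions(
    d: np.ndarray, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Rotate unit vectors by polar angle theta about themselves, azimuth phi."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    ux, uy, uz = d[:, 0], d[:, 1], d[:, 2]
    near_axis = np.abs(uz) > 0.999999
    s = np.sqrt(np.maximum(1.0 - uz**2, 1e-30))
    nx = st * (ux * uz * cp - uy * sp) / s + ux * ct
    ny = st * (uy * uz * cp + ux * sp) / s + uy * ct
    nz = -st * cp * s + uz * ct
    sign = np.sign(uz)
    nx = np.where(near_axis, st * cp * sign, nx)
    ny = np.where(near_axis, st * sp * sign, ny)
    nz = np.where(near_axis, ct * sign, nz)
    out = np.column_stack([nx, ny, nz])
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _transport_pass(
    pos: np.ndarray,
    dirs: np.ndarray,
    weights: np.ndarray,
    tp: TransportParameters,
    props: ScatteringProperties,
    rng: np.random.Generator,
    *,
    z_hi: float,
    max_events: int,
    fine: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    recorders: tuple[np.ndarray, list] | None = None,
    collect_exits: bool = False,
) -> dict:
    """Shared straight-flight / scatter / record loop.

    fine: (z_planes, r_edges, H) fluence accumulator (H modified in place).
    recorders: (z_planes, per-plane list) capturing forward crossings with
    directions.  collect_exits: gather rays crossing z = 0 headed out.
    """
    n = len(weights)
    mfp = tp.mean_free_path_um
    exit_lists: list[tuple] = []
    stats = {
        "forward_exit_weight": 0.0,
        "backward_exit_weight": 0.0,
        "capped_weight": 0.0,
        "n_scatter_events": 0,
        "event_path_sum": 0.0,
        "cap_breaches": 0,
    }
    pos = pos.copy()
    dirs = dirs.copy()
    alive = np.ones(n, dtype=bool)
    sinks: list[tuple[np.ndarray, str]] = []
    if fine is not None and len(fine[0]):
        sinks.append((fine[0], "fine"))
    if recorders is not None and len(recorders[0]):
        sinks.append((recorders[0], "rec"))
    for _ in range(max_events + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        p0 = pos[idx]
        d = dirs[idx]
        if math.isinf(mfp):
            # ballistic flight straight out of the slab
            length = (z_hi + 1.0 - p0[:, 2]) / np.maximum(d[:, 2], 1e-12)
            length = np.where(d[:, 2] > 0, length, 4.0 * z_hi + 4.0)
        else:
            length = -mfp * np.log(rng.random(idx.size))
        p1 = p0 + length[:, None] * d

        z0, z1 = p0[:, 2], p1[:, 2]
        lo = np.minimum(z0, z1)
        hi = np.maximum(z0, z1)
        for planes, sink in sinks:
            k0 = np.searchsorted(planes, lo, side="left")
            k1 = np.searchsorted(planes, hi, side="right")
            active = np.flatnonzero(k1 > k0)
            if active.size == 0:
                continue
            kmin, kmax = k0[active].min(), k1[active].max()
            for k in range(kmin, kmax):
                sel = active[(k0[active] <= k) & (k1[active] > k)]
                if sel.size == 0:
                    continue
                if sink == "rec":
                    sel = sel[d[sel, 2] > 0]  # forward crossings only
                    if sel.size == 0:
                        continue
                t = (planes[k] - z0[sel]) / (z1[sel] - z0[sel])
                cx = p0[sel, 0] + t * (p1[sel, 0] - p0[sel, 0])
                cy = p0[sel, 1] + t * (p1[sel, 1] - p0[sel, 1])
                if sink == "fine":
                    r_edges, H = fine[1], fine[2]
                    r = np.hypot(cx, cy)
                    b = np.searchsorted(r_edges, r, side="right") - 1
                    ok = (b >= 0) & (b < len(r_edges) - 1)
                    if ok.any():
                        H[k] += np.bincount(
                            b[ok], weights=weights[idx[sel[ok]]], minlength=len(r_edges) - 1
                        )
                else:
                    recorders[1][k].append(
                        (
                            cx.astype(np.float32),
                            cy.astype(np.float32),
                            d[sel].astype(np.float32),
                            weights[idx[sel]].astype(np.float32),
                        )
                    )

        # exits through the skin plane, headed out
        out_lo = z1 < 0.0
        if collect_exits and out_lo.any():
            sel = np.flatnonzero(out_lo)
            t = (0.0 - z0[sel]) / (z1[sel] - z0[sel])
            ex = p0[sel, 0] + t * (p1[sel, 0] - p0[sel, 0])
            ey = p0[sel, 1] + t * (p1[sel, 1] - p0[sel, 1])
            exit_lists.append((ex, ey, d[sel], weights[idx[sel]]))
        stats["backward_exit_weight"] += float(weights[idx[out_lo]].sum())

        out_hi = (z1 > z_hi) & ~out_lo
        stats["forward_exit_weight"] += float(weights[idx[out_hi]].sum())

        pos[idx] = p1
        done = out_lo | out_hi
        alive[idx[done]] = False
        idx = idx[~done]
        if idx.size == 0:
            continue
        if math.isinf(mfp):
            # ballistic rays always leave; nothing left to scatter
            stats["capped_weight"] += float(weights[idx].sum())
            alive[idx] = False
            continue
        stats["n_scatter_events"] += idx.size
        stats["event_path_sum"] += float(length[~done].sum())
        theta = props.sample_angle(rng.random(idx.size))
        phi = rng.random(idx.size) * 2.0 * np.pi
        dirs[idx] = _rotate_directions(dirs[idx], theta, phi)
    else:
        surv = np.flatnonzero(alive)
        stats["capped_weight"] += float(weights[surv].sum())
        stats["cap_breaches"] = int(surv.size)

    stats["exits"] = exit_lists
    return stats


def propagate(
    batch: PhotonBatch,
    tp: TransportParameters,
    props: ScatteringProperties,
    cfg: SimulationConfig,
    beam: BeamSpec,
    rng: np.random.Generator | None = None,
) -> PropagationResult:
    """Forward pass from the skin plane into the tissue.

    Accumulates the (r, z) fluence grid around the focus and, when
    ``cfg.record_planes``, the directional crossings of the coarse recording
    planes needed by :func:`backscatter_pass`.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    fine = None
    if cfg.accumulate_fluence:
        fz = cfg.fine_planes(beam.focal_depth_um)
        H = np.zeros((len(fz), len(cfg.radial_edges) - 1))
        fine = (fz, cfg.radial_edges, H)
    recorders = None
    if cfg.record_planes:
        rz = cfg.recording_planes(beam.focal_depth_um)
        recorders = (rz, [[] for _ in rz])

    z_hi = beam.focal_depth_um + max(
        cfg.record_halfspan_um if cfg.record_planes else 0.0, cfg.fine_halfspan_um
    )
    stats = _transport_pass(
        batch.positions,
        batch.directions,
        batch.weights,
        tp,
        props,
        rng,
        z_hi=z_hi,
        max_events=cfg.max_events,
        fine=fine,
        recorders=recorders,
    )

    grid = None
    if fine is not None:
        grid = IntensityGrid(r_edges=cfg.radial_edges, z_um=fine[0], values=fine[2])
    crossings = None
    if recorders is not None:
        crossings = []
        for zk, chunks in zip(recorders[0], recorders[1]):
            if chunks:
                x = np.concatenate([c[0] for c in chunks])
                y = np.concatenate([c[1] for c in chunks])
                dd = np.concatenate([c[2] for c in chunks])
                w = np.concatenate([c[3] for c in chunks])
            else:
                x = y = w = np.empty(0, dtype=np.float32)
                dd = np.empty((0, 3), dtype=np.float32)
            crossings.append(
                PlaneCrossings(float(zk), x, y, dd[:, 0], dd[:, 1], dd[:, 2], w)
            )

    launched = float(batch.weights.sum())
    book = {
        "launched_weight": launched,
        "forward_exit_weight": stats["forward_exit_weight"],
        "backward_exit_weight": stats["backward_exit_weight"],
        "capped_weight": stats["capped_weight"],
        "cap_breaches": stats["cap_breaches"],
        "n_scatter_events": stats["n_scatter_events"],
        "event_path_sum": stats["event_path_sum"],
    }
    return PropagationResult(grid, crossings, book, beam, tp, cfg)


def backscatter_pass(
    crossings: PlaneCrossings,
    tp: TransportParameters,
    props: ScatteringProperties,
    cfg: SimulationConfig,
    beam: BeamSpec,
    rng: np.random.Generator,
    reflectivity: float = 1.0,
) -> ExitRecords:
    """Reflect the rays recorded at one plane and transport them back out.

    Every ray is reflected (specular z-reversal) with amplitude
    ``reflectivity``; the return trip uses the same transport parameters.
    Rays reaching z = 0 headed outward become exit records.
    """
    if reflectivity < 0:
        raise ValueError("reflectivity must be nonnegative")
    if crossings.weight.size == 0:
        empty = np.empty(0)
        return ExitRecords(empty, empty, empty, empty, empty - 1.0, empty, empty)
    pos = np.column_stack(
        [
            crossings.x.astype(float),
            crossings.y.astype(float),
            np.full(crossings.weight.size, crossings.z_um),
        ]
    )
    dirs = np.column_stack(
        [crossings.dx, crossings.dy, -crossings.dz]
    ).astype(float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    w = crossings.weight.astype(float) * reflectivity
    z_hi = crossings.z_um + 2.0 * beam.focal_depth_um + 100.0
    stats = _transport_pass(
        pos,
        dirs,
        w,
        tp,
        props,
        rng,
        z_hi=z_hi,
        max_events=cfg.max_events,
        collect_exits=True,
    )
    if not stats["exits"]:
        empty = np.empty(0)
        return ExitRecords(empty, empty, empty, empty, empty - 1.0, empty, empty)
    ex = np.concatenate([c[0] for c in stats["exits"]])
    ey = np.concatenate([c[1] for c in stats["exits"]])
    dd = np.concatenate([c[2] for c in stats["exits"]])
    ww = np.concatenate([c[3] for c in stats["exits"]])
    return ExitRecords(
        ex,
        ey,
        dd[:, 0],
        dd[:, 1],
        dd[:, 2],
        ww,
        np.full(ww.size, crossings.z_um),
    )


def simulate(
    beam: BeamSpec,
    region: TissueRegion,
    cfg: SimulationConfig,
    props: ScatteringProperties | None = None,
) -> PropagationResult:
    """Convenience pipeline: Mie optics -> transport parameters -> forward pass."""
    if props is None:
        props = mie.scattering_properties(region.scatterer(beam.wavelength_um))
    tp = transport_parameters(region, props)
    rng = np.random.default_rng(cfg.rng_seed)
    batch = launch_photons(beam, cfg, region.n_medium, rng)
    return propagate(batch, tp, props, cfg, beam, rng)


# ---------------------------------------------------------------------------
# diffraction restoration


def gaussian_kernel1d(fwhm: float, dx: float) -> np.ndarray:
    """Unit-sum Gaussian kernel sampled at spacing dx, truncated at 4 sigma."""
    sigma = fwhm * FWHM_TO_SIGMA
    half = int(math.ceil(4.0 * sigma / dx))
    xx = np.arange(-half, half + 1) * dx
    k = np.exp(-(xx**2) / (2.0 * sigma**2))
    return k / k.sum()


def convolve_profile(y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(y, kernel, mode="same")


def hankel_gaussian_smooth(
    r_in: np.ndarray, bin_weights: np.ndarray, r_out: np.ndarray, sigma: float
) -> np.ndarray:
    """Convolve an azimuthally symmetric mass distribution with a 2-D Gaussian.

    ``bin_weights`` are total weights at radii ``r_in`` (point-mass rings);
    returns intensity (weight per um^2) sampled at radii ``r_out``.  Uses the
    exponentially scaled Bessel I0 for numerical stability.
    """
    s2 = sigma**2
    ro = r_out[:, None]
    ri = r_in[None, :]
    log_k = -((ro - ri) ** 2) / (2.0 * s2)
    kern = np.exp(log_k) * special.i0e(ro * ri / s2) / (2.0 * np.pi * s2)
    return kern @ np.asarray(bin_weights, dtype=float).T if bin_weights.ndim == 1 else (
        kern @ bin_weights.T
    ).T


def diffraction_convolution(grid: IntensityGrid, beam: BeamSpec) -> IntensityGrid:
    """Restore diffraction: convolve the ray-optics grid with the ideal waist.

    Separable Gaussian kernel with the beam's ideal transverse/axial FWHMs.
    Returns a new grid whose values are point intensities at the radial bin
    centres; total weight is conserved up to boundary truncation.
    """
    if grid.convolved:
        raise ValueError("grid already convolved")
    nz = len(grid.z_um)
    if nz > 1:
        dz = float(grid.z_um[1] - grid.z_um[0])
        span = grid.z_um[-1] - grid.z_um[0]
        if beam.ideal_fwhm_axial_um > span:
            raise ValueError("axial kernel wider than the grid extent")
        kz = gaussian_kernel1d(beam.ideal_fwhm_axial_um, dz)
        vals = np.apply_along_axis(lambda c: np.convolve(c, kz, mode="same"), 0, grid.values)
    else:
        vals = grid.values.copy()
    if beam.ideal_fwhm_transverse_um > 2 * grid.r_edges[-1]:
        raise ValueError("transverse kernel wider than the grid extent")
    sigma = beam.ideal_fwhm_transverse_um * FWHM_TO_SIGMA
    dens = hankel_gaussian_smooth(grid.r_centers, vals, grid.r_centers, sigma)
    return IntensityGrid(
        r_edges=grid.r_edges.copy(), z_um=grid.z_um.copy(), values=dens, convolved=True
    )
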