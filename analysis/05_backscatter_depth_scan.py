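#!/usr/bin/env python
"""Backscattered peak intensity versus focal depth (skin, brain, total).

Scans the focal depth through the PVL preset, reconstructs the camera
image at each depth (every recording plane reflecting, plus the analytic
skin term), and tabulates peak intensities.  Writes results/depth_scan.csv.

Finding: the skin reflection dominates at the shallowest depths and decays
as 1/depth^2 (geometric defocus of the skin plane); the brain return takes
over beyond ~15-20 um and decays faster (ballistic attenuation both ways),
giving a smooth, monotone total — the model has no sawtooth because the
medium is homogeneous at the ray level.
"""

import argparse
from pathlib import Path

import numpy as np

import tissuebeam as tb
from tissuebeam.imaging import depth_scan

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--photons", type=int, default=3000)
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--depths", default="10:200:10")
    ap.add_argument("--region", default="pvl")
    args = ap.parse_args()

    start, stop, step = (float(v) for v in args.depths.split(":"))
    depths = np.arange(start, stop + step / 2, step)
    region = tb.region_preset(args.region)
    beam = tb.BeamSpec(focal_depth_um=depths[0])
    cfg = tb.SimulationConfig(
        n_photons=args.photons, rng_seed=args.seed, record_spacing_um=4.0
    )
    scan = depth_scan(depths, region, beam, cfg)
    df = scan.to_dataframe()
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "depth_scan.csv", index=False)
    crossover = df.depth_um[np.argmax(df.peak_brain > df.peak_skin)]
    print(df.head(8).to_string(index=False))
    print(f"skin/brain crossover near {crossover:.0f} um; wrote {RESULTS/'depth_scan.csv'}")


if __name__ == "__main__":
    main()
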