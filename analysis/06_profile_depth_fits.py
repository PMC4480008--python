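#!/usr/bin/env python
"""Two-Gaussian decomposition of backscatter profiles across depth.

For the nucleus-rich PVL and the nucleus-poor neuropil, simulates the
backscattered radial profile at a series of focal depths and fits the
two-Gaussian model.  Writes results/profile_depth_fits.csv.

Finding: the narrow, intense component (the refocused focal-plane return,
width set by the ideal waist) stays essentially constant with depth, while
the wide, weak component — fed by out-of-focus plane reflections whose
defocus disc grows linearly with distance from focus — widens steadily.
The ratio of the two slopes exceeds 100x in both tissue presets.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import tissuebeam as tb
from tissuebeam.imaging import backscatter_radial_profile

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--photons", type=int, default=4000)
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()

    depths = np.array([20.0, 40.0, 60.0, 80.0, 100.0])
    rows = []
    for name in ("neuropil", "pvl"):
        region = tb.region_preset(name)
        cfg = tb.SimulationConfig(
            n_photons=args.photons, rng_seed=args.seed, record_spacing_um=2.0
        )
        for d in depths:
            beam = tb.BeamSpec(focal_depth_um=float(d))
            r, prof = backscatter_radial_profile(region, beam, cfg)
            fit = tb.fit_two_gaussians(r, prof)
            rows.append(
                {
                    "region": name,
                    "depth_um": d,
                    "sigma_narrow": fit.sigma_narrow,
                    "sigma_wide": fit.sigma_wide,
                    "amp_narrow": fit.amp_narrow,
                    "amp_wide": fit.amp_wide,
                    "offset": fit.offset,
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "profile_depth_fits.csv", index=False)
    for name, grp in df.groupby("region"):
        sn = np.polyfit(grp.depth_um, grp.sigma_narrow, 1)[0]
        sw = np.polyfit(grp.depth_um, grp.sigma_wide, 1)[0]
        print(
            f"{name}: narrow-sigma slope {sn:.2e} um/um, wide-sigma slope "
            f"{sw:.2e} um/um (ratio {sw / max(abs(sn), 1e-12):.0f}x)"
        )
    print(f"wrote {RESULTS / 'profile_depth_fits.csv'}")


if __name__ == "__main__":
    main()
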