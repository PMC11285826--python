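#!/usr/bin/env python
"""Long-running structural checks at production colony sizes.

These validations need colonies of biomass 10^4-10^5 (hours of CPU per
replicate) and are deliberately kept out of the default test suite:

* late-time biomass scaling: under severe nutrient limitation and slow
  diffusion (Ks* = 10, DN* = 100) the biomass is expected to grow as t^3
  at late times, the signature of growth confined to the colony surface;
* local nematic domains: at moderate biomass (m ~ 10^4) and fast uptake
  (low Ks*) the orientational correlation g2(r) stays above 0.3 out to
  distances of order 10 sigma.

Usage examples:
    python scripts/longrun_validation.py t3-scaling --seed 1 \
        --max-biomass 5e4 --out scratch/t3.json
    python scripts/longrun_validation.py nematic-domains --seed 1 \
        --max-biomass 1e4 --out scratch/g2.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from biofilmsim.driver import Simulation
from biofilmsim.observables import orientational_correlation
from biofilmsim.params import ModelParams


def t3_scaling(seed: int, max_biomass: float) -> dict:
    params = ModelParams(Ks_star=10.0, DN_star=100.0,
                         max_biomass=max_biomass, seed=seed)
    sim = Simulation(params)
    frames = sim.run()
    t = np.array([f.t for f in frames])
    m = np.array([f.m for f in frames])
    # fit the exponent over the last decade of biomass
    late = m > m[-1] / 10.0
    slope = np.polyfit(np.log(t[late]), np.log(m[late]), 1)[0]
    return {"late_time_exponent": float(slope),
            "final_biomass": float(m[-1]), "final_time": float(t[-1])}


def nematic_domains(seed: int, max_biomass: float) -> dict:
    params = ModelParams(Ks_star=0.01, DN_star=1000.0,
                         max_biomass=max_biomass, seed=seed)
    sim = Simulation(params)
    sim.run()
    g2 = orientational_correlation(sim.colony, r_max=40.0, bin_width=1.0)
    filled = g2.dropna(subset=["g2"])
    above = filled[filled["g2"] > 0.3]
    extent = float(above["r_mid"].max()) if len(above) else 0.0
    return {"g2_above_0p3_extent": extent,
            "g2_table": filled[["r_mid", "g2", "n_pairs"]]
            .to_dict("records"),
            "final_biomass": float(sim.colony.biomass)}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("check", choices=["t3-scaling", "nematic-domains"])
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--max-biomass", type=float, default=1e4)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    if args.check == "t3-scaling":
        result = t3_scaling(args.seed, args.max_biomass)
    else:
        result = nematic_domains(args.seed, args.max_biomass)
    text = json.dumps(result, indent=2)
    if args.out is not None:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
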