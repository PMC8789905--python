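#!/usr/bin/env python
"""Full synthetic study via the orchestrated pipeline.

One `run_pipeline` call with the shipped demo configuration: relay
simulations (WT and Lefty1/2-KO) with front tracking, colony renders
quantified to a radial-profile ensemble and a kymograph, and a
juxtaposition scene quantified to border profiles with a decay fit.  The
same command is available from the shell as

    nodalrelay run --config configs/demo_gastruloid.yaml \
        --out results/pipeline_demo --seed 1

Finding: all stages complete deterministically; the Lefty decay length
fitted from the rendered scene agrees with the configured truth.
"""

import pandas as pd

from nodalrelay.config import load_config
from nodalrelay.pipeline import run_pipeline

cfg = load_config("configs/demo_gastruloid.yaml",
                  out_dir="results/pipeline_demo", seed=1)
out = run_pipeline(cfg)

fronts = pd.read_csv(out / "front_positions.csv")
last = fronts.groupby("genotype").front_tiers.last()
print("final front position (tiers):")
print(last.to_string())
fits = pd.read_csv(out / "decay_fits.csv")
lefty = fits[fits.channel == "lefty"].iloc[0]
print(f"lefty decay length: fitted {lefty.lambda_um:.1f} um, "
      f"true {lefty.true_lambda_um:.1f} um")
print(f"outputs in {out}")
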