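import time, numpy as np, pandas as pd
from spinerd.experiments import ExperimentConfig, run_anchoring_grid, ANCHORING_GRID
from spinerd.model import AnchoringConfig

t0=time.time()
base = ExperimentConfig(protocol="one_train_ltp", scale=0.03, n_trials=3, base_seed=101)
configs = list(ANCHORING_GRID) + [AnchoringConfig("uniform","spine")]
metrics, _ = run_anchoring_grid(base, configs=configs)
metrics.to_csv("/root/pkg/scratch_grid_metrics.csv", index=False)
piv = metrics.pivot_table(index="config", columns="metric", values="value", aggfunc="mean")
print(piv.round(4).to_string(), flush=True)
print("elapsed grid:", round(time.time()-t0), flush=True)
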