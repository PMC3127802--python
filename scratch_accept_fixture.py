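import os, sys, time, pandas as pd
from dataclasses import replace
from spinerd.experiments import ExperimentConfig, prepare, run_trial, ANCHORING_GRID, reduction_percent
from spinerd.model import AnchoringConfig
from spinerd.metrics import auc_metric

CSV = "/root/pkg/scratch_accept_metrics.csv"
base = ExperimentConfig(protocol="four_train_ltp", scale=0.03, n_trials=2, base_seed=7)
configs = list(ANCHORING_GRID) + [AnchoringConfig("uniform","spine")]
done = set()
rows = []
if os.path.exists(CSV):
    old = pd.read_csv(CSV)
    rows = old.to_dict("records")
    done = set(zip(old["config"], old["seed"], old["metric"]))

budget = float(sys.argv[1]) if len(sys.argv) > 1 else 500.0
t_start = time.time()
for ac in configs:
    cfg = replace(base, anchoring=ac)
    todo = [s for s in cfg.seeds() if (cfg.label, s, "auc_pka_catalytic") not in done]
    if not todo:
        continue
    prepared = prepare(cfg)
    for seed in todo:
        if time.time() - t_start > budget:
            pd.DataFrame(rows).to_csv(CSV, index=False); print("BUDGET STOP", flush=True); sys.exit(0)
        traj, m = run_trial(cfg, seed, prepared)
        spine = [g for g in ("spine_head","psd") if g in traj.group_names]
        dend = [g for g in traj.group_names if g.startswith("dendrite")]
        m["peak_spine_Ca"] = float(traj.concentration_series("Ca", spine).max())
        m["peak_dend_Ca"] = float(traj.concentration_series("Ca", dend).max())
        m["auc_spine_cAMP"] = auc_metric(traj, "cAMP", spine)
        m["auc_dend_cAMP"] = auc_metric(traj, "cAMP", dend)
        for k, v in m.items():
            rows.append({"config": cfg.label, "seed": seed, "metric": k, "value": v})
        pd.DataFrame(rows).to_csv(CSV, index=False)
        print(f"done {cfg.label} seed {seed} ({time.time()-t_start:.0f}s)", flush=True)

df = pd.DataFrame(rows)
piv = df.pivot_table(index="config", columns="metric", values="value", aggfunc="mean")
print(piv.round(4).to_string(), flush=True)
lab = lambda a: replace(base, anchoring=a).label
red = reduction_percent(df[df.metric.isin(["auc_pka_catalytic","mean_phospho_I1","mean_frac_pS845_GluR1","mean_phospho_PDE4","auc_phospho_PDE4"])],
                        lab(AnchoringConfig("uniform","spine")), lab(AnchoringConfig("spine","spine")))
print("ht31 reductions:", {k: round(v,1) for k,v in red.items()})
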