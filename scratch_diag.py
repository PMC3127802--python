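import numpy as np
import spinerd.model as Mo
from spinerd.mesh import build_single_spine_mesh
from spinerd.engine import run, EngineConfig
from spinerd.protocols import build_four_train_ltp

mesh = build_single_spine_mesh(axial_step=0.25, n_width=3)
sched = build_four_train_ltp(mesh, n_trains=1, train_interval=3.0, first_onset=0.25)
model = Mo.build_model()
model.anchored_molecules.update({"AC1":2400,"AC8":1200,"R":300,"Gabg":900,"PKA":2400})
m = Mo.apply_anchoring(model, mesh, Mo.AnchoringConfig("spine","spine"))
cfg = EngineConfig(dt=40e-6, t_end=3.0, rng_seed=11, sample_interval=0.02)
traj = run(m, mesh, sched.events, cfg)
spine=["spine_head","psd"]
t = traj.times
for sp in ["Ca","CaMCa2","CaMCa4","AC1CaMCa4","AC1GaGTP","AC1GaGTPCaMCa4","GaGTP","DaR","Da","cAMP","AC8CaMCa4"]:
    c_sp = traj.count_series(sp, spine)
    c_all = traj.count_series(sp)
    print(f"{sp:>16}: spine max={c_sp.max():6d} at t={t[np.argmax(c_sp)]:.2f}  total max={c_all.max():7d} end={c_all[-1]}")
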