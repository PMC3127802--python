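import time, numpy as np
import spinerd.model as Mo
from spinerd.mesh import build_single_spine_mesh
from spinerd.engine import run, EngineConfig
from spinerd.protocols import build_four_train_ltp

mesh = build_single_spine_mesh(axial_step=0.25, n_width=3)
sched = build_four_train_ltp(mesh, n_trains=4, train_interval=3.0, first_onset=0.25)

model = Mo.build_model()
model.anchored_molecules.update({"AC1":2400,"AC8":1200,"R":300,"Gabg":900,"PKA":2400})
for anch in (Mo.AnchoringConfig("spine","spine"), Mo.AnchoringConfig("uniform","spine")):
    m = Mo.apply_anchoring(model, mesh, anch)
    cfg = EngineConfig(dt=40e-6, t_end=16.0, rng_seed=11, sample_interval=0.02)
    t0=time.time()
    traj = run(m, mesh, sched.events, cfg)
    spine=[g for g in ("spine_head","psd") if g in traj.group_names]
    camp_sp = traj.concentration_series("cAMP", spine)
    camp_d = traj.concentration_series("cAMP", [g for g in traj.group_names if g.startswith("dendrite")])
    pkac = traj.count_series("PKAc")
    bound = traj.count_series(["PKAcAMP2","PKAcAMP4","R2CcAMP4","PKAr"])
    t = traj.times
    stim = t >= 0.25
    from numpy import trapezoid
    auc = trapezoid(pkac[stim]/ (0.602214076*traj.group_volumes.sum()), t[stim])
    print(f"{anch.label}: ({time.time()-t0:.0f}s) peak cAMP sp={camp_sp.max():.0f} d={camp_d.max():.0f}"
          f" PKAc max={pkac.max()} mean={pkac[stim].mean():.1f} bound end={bound[-1]} auc={auc:.1f}", flush=True)
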