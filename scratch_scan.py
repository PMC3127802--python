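import time, itertools, numpy as np
from dataclasses import replace
import spinerd.model as Mo
from spinerd.mesh import build_single_spine_mesh
from spinerd.engine import run, EngineConfig, CompiledSystem
from spinerd.protocols import build_four_train_ltp

mesh = build_single_spine_mesh(axial_step=0.25, n_width=3)
sched = build_four_train_ltp(mesh, n_trains=1, first_onset=0.25)

for ac1 in (600, 1200, 2400):
    model = Mo.build_model()
    model.anchored_molecules.update({"AC1": ac1, "AC8": ac1//2, "R": 300, "Gabg": 900, "PKA": 1200})
    for anch in (Mo.AnchoringConfig("spine","spine"), Mo.AnchoringConfig("spine","dendrite_focal"),
                 Mo.AnchoringConfig("uniform","spine")):
        m = Mo.apply_anchoring(model, mesh, anch)
        cfg = EngineConfig(dt=25e-6, t_end=5.0, rng_seed=11, sample_interval=0.01)
        t0=time.time()
        traj = run(m, mesh, sched.events, cfg)
        spine=[g for g in ("spine_head","psd") if g in traj.group_names]
        dend=[g for g in traj.group_names if g.startswith("dendrite")]
        camp_sp = traj.concentration_series("cAMP", spine); camp_d = traj.concentration_series("cAMP", dend)
        pkac = traj.count_series("PKAc")
        pkacamp4 = traj.count_series(["PKAcAMP2","PKAcAMP4","R2CcAMP4"])
        print(f"AC1={ac1} {anch.label}: peak cAMP spine={camp_sp.max():.0f} dend={camp_d.max():.0f} "
              f"end cAMP sp={camp_sp[-1]:.0f} PKAc max={pkac.max()} bound_max={pkacamp4.max()} ({time.time()-t0:.0f}s)", flush=True)
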