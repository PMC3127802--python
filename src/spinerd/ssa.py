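"""Exact stochastic simulation (Gillespie direct method) with diffusion
channels, used as a statistically exact oracle for the tau-leap engine on
small systems (few voxels, modest molecule numbers).

Every (voxel, reaction) pair and every (directed coupling, diffusible
species) pair is a channel; propensities are recomputed after each event,
so cost grows with the number of events -- keep systems tiny.
"""

from __future__ import annotations

import numpy as np

from .engine import (
    CompiledSystem,
    EngineConfig,
    InjectionEvent,
    Trajectory,
    _compile_schedule,
)
from .mesh import Mesh
from .model import NAV, ModelSpec


def run_ssa_exact(
    model: ModelSpec,
    mesh: Mesh,
    schedule: list[InjectionEvent],
    config: EngineConfig,
    groups: dict[str, list[int]] | None = None,
    system: CompiledSystem | None = None,
) -> Trajectory:
    if system is None:
        system = CompiledSystem(model, mesh, groups)
    inj_spec, inj_on, inj_off, inj_ptr, inj_vox, inj_rate = _compile_schedule(
        system, schedule
    )
    rng = np.random.default_rng(config.rng_seed)

    n_vox = mesh.n_voxels
    n_spec = len(system.species_names)
    volumes = system.volumes
    clamped = system.clamped

    # initial counts (same stochastic rounding convention as the leap engine)
    expected = system.init_expected
    counts = np.floor(expected).astype(np.int64)
    counts += (rng.random(expected.shape) < (expected - counts)).astype(np.int64)

    # channel tables -------------------------------------------------------
    rx_channels = []  # (voxel, rx_index)
    for v in range(n_vox):
        for ci in range(system.cand_ptr[v], system.cand_ptr[v + 1]):
            rx_channels.append((v, int(system.cand_rx[ci])))
    diff_channels = []  # (edge, species)
    for di, s in enumerate(system.diff_species):
        for e in range(len(system.edge_from)):
            diff_channels.append((e, int(s)))
    inj_channels = []  # (event, slot) zeroth-order sources
    for e in range(len(inj_spec)):
        for q in range(inj_ptr[e], inj_ptr[e + 1]):
            inj_channels.append((e, q))

    boundaries = sorted(set(list(inj_on) + list(inj_off)))

    def rx_propensity(v, r):
        i1 = system.rx_r1[r]
        n1 = counts[v, i1]
        if n1 <= 0:
            return 0.0
        i2 = system.rx_r2[r]
        if i2 >= 0:
            n2 = counts[v, i2]
            if n2 <= 0:
                return 0.0
            return system.rx_k[r] * n1 * n2 / (NAV * volumes[v])
        if system.rx_homo[r]:
            if n1 < 2:
                return 0.0
            return system.rx_k[r] * n1 * (n1 - 1) / (NAV * volumes[v])
        return system.rx_k[r] * n1

    def propensities(t):
        a = np.zeros(len(rx_channels) + len(diff_channels) + len(inj_channels))
        k = 0
        for v, r in rx_channels:
            a[k] = rx_propensity(v, r)
            k += 1
        for e, s in diff_channels:
            n = counts[system.edge_from[e], s]
            if n > 0:
                a[k] = system.D[s] * system.edge_geom[e] * n
            k += 1
        for e, q in inj_channels:
            if inj_on[e] <= t < inj_off[e]:
                a[k] = inj_rate[q]
            k += 1
        return a

    def fire(idx):
        if idx < len(rx_channels):
            v, r = rx_channels[idx]
            i1, i2 = system.rx_r1[r], system.rx_r2[r]
            if not clamped[i1]:
                counts[v, i1] -= system.rx_c1[r]
            if i2 >= 0 and not clamped[i2]:
                counts[v, i2] -= system.rx_c2[r]
            for j in range(4):
                p = system.rx_prod_idx[r, j]
                if p < 0:
                    break
                if not clamped[p]:
                    counts[v, p] += system.rx_prod_n[r, j]
            return
        idx -= len(rx_channels)
        if idx < len(diff_channels):
            e, s = diff_channels[idx]
            counts[system.edge_from[e], s] -= 1
            counts[system.edge_to[e], s] += 1
            return
        idx -= len(diff_channels)
        e, q = inj_channels[idx]
        counts[inj_vox[q], inj_spec[e]] += 1

    # sampling -------------------------------------------------------------
    n_samples = int(round(config.t_end / config.sample_interval)) + 1
    times = np.arange(n_samples) * config.sample_interval
    n_groups = len(system.group_names)
    out = np.zeros((n_samples, n_groups, n_spec), dtype=np.int64)

    def record(isample):
        for v in range(n_vox):
            out[isample, system.group_of[v]] += counts[v]

    t = 0.0
    isample = 0
    record(0)
    isample = 1
    while isample < n_samples:
        a = propensities(t)
        a_tot = a.sum()
        # next stimulus boundary after t
        nb = next((b for b in boundaries if b > t + 1e-15), np.inf)
        if a_tot <= 0:
            t_next = nb
        else:
            t_next = t + rng.exponential(1.0 / a_tot)
        if t_next >= nb:
            t = nb  # propensity landscape changes here; redraw
            continue
        while isample < n_samples and times[isample] <= t_next:
            record(isample)
            isample += 1
        t = t_next
        if isample >= n_samples and t > times[-1]:
            break
        cum = np.cumsum(a)
        fire(int(np.searchsorted(cum, rng.random() * a_tot, side="right")))

    if counts.min() < 0:
        raise RuntimeError("internal error: negative count in SSA")
    return Trajectory(
        times=times,
        counts=out,
        group_names=list(system.group_names),
        group_volumes=system.group_volumes.copy(),
        species_names=list(system.species_names),
        meta={"seed": config.rng_seed, "mode": "ssa_exact", "t_end": config.t_end},
    )
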