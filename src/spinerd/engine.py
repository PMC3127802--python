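"""Mesoscopic stochastic reaction-diffusion engine.

Reactions are advanced with fixed-step tau-leaping: per voxel and reaction
channel the event count over ``dt`` is Poisson with mean a*dt (propensity
``a`` from mass action), capped at the available molecules so counts never
go negative.  Diffusion uses a leaping scheme of the same spirit: for every
directed coupling and diffusible species, the number of molecules jumping
within ``dt`` is binomial with per-molecule probability D*A/(V*d)*dt.
Species fast enough that this probability would exceed ~0.1 on some edge
are substepped.  All randomness flows from a single seed; trajectories are
bit-reproducible.

The per-voxel/per-channel loops are compiled with numba; the first call in
a process pays a one-time JIT cost (~30 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from numba import njit

from .mesh import Coupling, Mesh, Region
from .model import NAV, ModelSpec, ReactionSpec

P_MAX = 0.1  # target upper bound for per-edge jump probability per substep


# --------------------------------------------------------------------------
# spec-level primitives (also used by the exact SSA and in tests)
# --------------------------------------------------------------------------

def reaction_propensity(
    reaction: ReactionSpec, counts_in_voxel: dict[str, int], volume: float
) -> float:
    """Mass-action event rate (events/s) of one reaction in one voxel.

    First order: a = k*n.  Second order A+B: a = k*n_A*n_B/(NAV*V) with V in
    um^3 (k printed in nM^-1 s^-1).  Homodimeric 2A: a = k*n*(n-1)/(NAV*V).
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    n1 = counts_in_voxel.get(reaction.reactants[0][0], 0)
    if n1 < 0:
        raise ValueError("negative count")
    if reaction.order == 1 and not reaction.homodimer:
        return reaction.rate_constant * n1
    kconv = reaction.rate_constant / (NAV * volume)
    if reaction.homodimer:
        return kconv * n1 * max(n1 - 1, 0)
    n2 = counts_in_voxel.get(reaction.reactants[1][0], 0)
    if n2 < 0:
        raise ValueError("negative count")
    return kconv * n1 * n2


def diffusion_rate(D: float, coupling: Coupling, from_voxel_volume: float) -> float:
    """Per-molecule jump rate (1/s) across a coupling; 0 for anchored species."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if D == 0:
        return 0.0
    return D * coupling.face_area / (from_voxel_volume * coupling.center_distance)


# --------------------------------------------------------------------------
# configuration / events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionEvent:
    """Timed molecule injection into a named voxel set.

    ``rate`` is the total injection rate in molecules/ms over the whole set
    (split volume-proportionally across its voxels).
    """

    species: str
    voxel_set: str
    rate: float  # molecules/ms
    onset: float  # s
    duration: float  # s

    def __post_init__(self):
        if self.rate < 0 or self.duration < 0:
            raise ValueError("rate and duration must be >= 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def expected_molecules(self) -> float:
        return self.rate * self.duration * 1e3


@dataclass
class EngineConfig:
    dt: float = 5e-6
    t_end: float = 1.0
    rng_seed: int = 1
    sample_interval: float = 0.01
    mode: Literal["tau_leap", "ssa_exact", "ode_wellmixed"] = "tau_leap"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sample_interval < self.dt:
            raise ValueError("sample_interval must be >= dt")


@dataclass
class Trajectory:
    """Sampled counts per (time, voxel group, species), plus region metadata."""

    times: np.ndarray  # (n_samples,)
    counts: np.ndarray  # (n_samples, n_groups, n_species) int64
    group_names: list[str]
    group_volumes: np.ndarray  # (n_groups,) um^3
    species_names: list[str]
    meta: dict = field(default_factory=dict)

    def _species_idx(self, species: str | Sequence[str]) -> list[int]:
        if isinstance(species, str):
            species = [species]
        smap = {n: i for i, n in enumerate(self.species_names)}
        missing = [s for s in species if s not in smap]
        if missing:
            raise KeyError(f"unknown species {missing}")
        return [smap[s] for s in species]

    def _group_idx(self, groups: str | Sequence[str] | None) -> list[int]:
        if groups is None:
            return list(range(len(self.group_names)))
        if isinstance(groups, str):
            groups = [groups]
        gmap = {n: i for i, n in enumerate(self.group_names)}
        missing = [g for g in groups if g not in gmap]
        if missing:
            raise KeyError(f"unknown groups {missing}")
        return [gmap[g] for g in groups]

    def count_series(
        self,
        species: str | Sequence[str],
        groups: str | Sequence[str] | None = None,
        weights: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Total molecule counts over time, summed over species and groups.

        ``weights`` optionally weighs each species (e.g. moiety stoichiometry).
        """
        sidx = self._species_idx(species)
        gidx = self._group_idx(groups)
        sub = self.counts[:, gidx, :][:, :, sidx].sum(axis=1)
        if weights is not None:
            names = [species] if isinstance(species, str) else list(species)
            w = np.array([weights.get(n, 1.0) for n in names])
            return sub @ w
        return sub.sum(axis=1)

    def concentration_series(
        self, species: str | Sequence[str], groups: str | Sequence[str] | None = None
    ) -> np.ndarray:
        """Concentration in nM: counts / (NAV * region volume)."""
        gidx = self._group_idx(groups)
        vol = float(self.group_volumes[gidx].sum())
        return self.count_series(species, groups) / (NAV * vol)

    def to_frame(self):
        import pandas as pd

        n_t, n_g, n_s = self.counts.shape
        t = np.repeat(self.times, n_g * n_s)
        g = np.tile(np.repeat(np.arange(n_g), n_s), n_t)
        s = np.tile(np.arange(n_s), n_t * n_g)
        vols = self.group_volumes[g]
        cnt = self.counts.reshape(-1)
        return pd.DataFrame(
            {
                "time": t,
                "group": np.array(self.group_names)[g],
                "species": np.array(self.species_names)[s],
                "count": cnt,
                "concentration_nM": cnt / (NAV * vols),
            }
        )


# --------------------------------------------------------------------------
# compilation of (model, mesh, schedule) into flat arrays
# --------------------------------------------------------------------------

def default_groups(mesh: Mesh) -> dict[str, list[int]]:
    """Region-based voxel groups; the focal dendritic zone is split out."""
    focal = set(mesh.metadata.get("sets", {}).get("focal_dendrite", []))
    groups: dict[str, list[int]] = {}
    for v in mesh.voxels:
        if v.index in focal:
            key = "dendrite_focal"
        else:
            key = v.region.value
        groups.setdefault(key, []).append(v.index)
    return groups


def axial_groups(mesh: Mesh, bin_width: float) -> dict[str, list[int]]:
    """Groups of dendrite voxels binned by axial position (spines grouped
    separately per spine), for spatial-profile analysis."""
    groups: dict[str, list[int]] = {}
    for v in mesh.voxels:
        if v.spine_id is not None:
            key = f"spine_{v.spine_id}"
        else:
            key = f"dend_x{int(v.center[0] / bin_width) * bin_width:07.3f}"
        groups.setdefault(key, []).append(v.index)
    return groups


class CompiledSystem:
    """Flat-array form of (model, mesh, groups) consumed by the kernels."""

    def __init__(self, model: ModelSpec, mesh: Mesh, groups: dict[str, list[int]] | None = None):
        if not model.anchored_counts:
            raise ValueError(
                "model has no anchored placement; call apply_anchoring first"
            )
        self.model = model
        self.mesh = mesh
        self.species_names = model.species_names()
        self.sidx = {n: i for i, n in enumerate(self.species_names)}
        n_spec = len(self.species_names)
        n_vox = mesh.n_voxels
        self.volumes = mesh.volumes()
        smap = model.species_map()
        self.D = np.array(
            [smap[n].diffusion_constant for n in self.species_names]
        )
        self.clamped = np.array([smap[n].clamped for n in self.species_names])

        # --- initial expected counts (float), stochastic-rounded at run time
        self.init_expected = np.zeros((n_vox, n_spec))
        for name, conc in model.initial_conditions_nM.items():
            self.init_expected[:, self.sidx[name]] += conc * NAV * self.volumes
        for name, per_vox in model.anchored_counts.items():
            self.init_expected[:, self.sidx[name]] += per_vox

        # --- reactions
        elem = model.elementary()
        self.elementary = elem
        n_rx = len(elem)
        self.rx_r1 = np.zeros(n_rx, dtype=np.int32)
        self.rx_c1 = np.zeros(n_rx, dtype=np.int32)
        self.rx_r2 = np.full(n_rx, -1, dtype=np.int32)
        self.rx_c2 = np.zeros(n_rx, dtype=np.int32)
        self.rx_homo = np.zeros(n_rx, dtype=np.bool_)
        self.rx_k = np.zeros(n_rx)
        self.rx_prod_idx = np.full((n_rx, 4), -1, dtype=np.int32)
        self.rx_prod_n = np.zeros((n_rx, 4), dtype=np.int32)
        for i, rx in enumerate(elem):
            (s1, c1) = rx.reactants[0]
            self.rx_r1[i] = self.sidx[s1]
            self.rx_c1[i] = c1
            self.rx_homo[i] = rx.homodimer
            if rx.order == 2:
                (s2, c2) = rx.reactants[1]
                self.rx_r2[i] = self.sidx[s2]
                self.rx_c2[i] = c2
            self.rx_k[i] = rx.rate_constant
            if len(rx.products) > 4:
                raise ValueError(f"{rx.name}: too many products")
            for j, (p, c) in enumerate(rx.products):
                self.rx_prod_idx[i, j] = self.sidx[p]
                self.rx_prod_n[i, j] = c

        # --- directed diffusion edges
        ef, et, geom = [], [], []
        for c in mesh.couplings:
            vi, vj = c.voxel_i, c.voxel_j
            ef.append(vi); et.append(vj)
            geom.append(c.face_area / (self.volumes[vi] * c.center_distance))
            ef.append(vj); et.append(vi)
            geom.append(c.face_area / (self.volumes[vj] * c.center_distance))
        self.edge_from = np.array(ef, dtype=np.int32)
        self.edge_to = np.array(et, dtype=np.int32)
        self.edge_geom = np.array(geom)
        self.diff_species = np.array(
            [i for i in range(n_spec) if self.D[i] > 0], dtype=np.int32
        )

        # --- groups
        if groups is None:
            groups = default_groups(mesh)
        self.group_names = list(groups)
        self.group_of = np.full(n_vox, -1, dtype=np.int32)
        for gi, (gname, idxs) in enumerate(groups.items()):
            for v in idxs:
                if self.group_of[v] != -1:
                    raise ValueError(f"voxel {v} assigned to two groups")
                self.group_of[v] = gi
        if (self.group_of == -1).any():
            raise ValueError("groups must cover every voxel")
        self.group_volumes = np.zeros(len(self.group_names))
        for v in range(n_vox):
            self.group_volumes[self.group_of[v]] += self.volumes[v]

        self._build_candidates()

    def _build_candidates(self):
        """Static reachability: reaction r is a candidate in voxel v only if
        every reactant can ever be present in v (anchored species stay where
        placed; diffusible species can be anywhere)."""
        n_spec = len(self.species_names)
        n_vox = self.mesh.n_voxels
        support = np.zeros((n_spec, n_vox), dtype=bool)
        for i in range(n_spec):
            if self.D[i] > 0:
                support[i] = True  # diffusible (or injectable anywhere)
            else:
                support[i] = self.init_expected[:, i] > 0
        # injected species may appear in their target voxels even if D=0;
        # schedules are not known here, so treat any species that appears as
        # an injection target in practice (Ca, Da, CaB) via their D or ICs.
        # Ca and CaB are handled below by marking them fully supported when
        # their support is partial (conservative).
        changed = True
        while changed:
            changed = False
            for rx_i in range(len(self.rx_r1)):
                r1 = self.rx_r1[rx_i]
                r2 = self.rx_r2[rx_i]
                s = support[r1].copy()
                if r2 >= 0:
                    s &= support[r2]
                if not s.any():
                    continue
                for j in range(4):
                    p = self.rx_prod_idx[rx_i, j]
                    if p < 0:
                        break
                    new = support[p] | s
                    if (new != support[p]).any():
                        support[p] = new
                        changed = True
        self.support = support
        cand: list[list[int]] = [[] for _ in range(n_vox)]
        for rx_i in range(len(self.rx_r1)):
            ok = support[self.rx_r1[rx_i]].copy()
            if self.rx_r2[rx_i] >= 0:
                ok &= support[self.rx_r2[rx_i]]
            for v in np.nonzero(ok)[0]:
                cand[v].append(rx_i)
        self.cand_ptr = np.zeros(n_vox + 1, dtype=np.int64)
        flat: list[int] = []
        for v in range(n_vox):
            flat.extend(cand[v])
            self.cand_ptr[v + 1] = len(flat)
        self.cand_rx = np.array(flat, dtype=np.int32)

    def mark_supported(self, species: str):
        """Widen the support of an injected species to all voxels (called for
        schedule targets before candidate lists are built into the kernel)."""
        i = self.sidx[species]
        if not self.support[i].all():
            self.support[i] = True
            self._propagate_and_rebuild()

    def _propagate_and_rebuild(self):
        # re-run closure from current support
        n_vox = self.mesh.n_voxels
        changed = True
        while changed:
            changed = False
            for rx_i in range(len(self.rx_r1)):
                s = self.support[self.rx_r1[rx_i]].copy()
                if self.rx_r2[rx_i] >= 0:
                    s &= self.support[self.rx_r2[rx_i]]
                if not s.any():
                    continue
                for j in range(4):
                    p = self.rx_prod_idx[rx_i, j]
                    if p < 0:
                        break
                    new = self.support[p] | s
                    if (new != self.support[p]).any():
                        self.support[p] = new
                        changed = True
        cand: list[list[int]] = [[] for _ in range(n_vox)]
        for rx_i in range(len(self.rx_r1)):
            ok = self.support[self.rx_r1[rx_i]].copy()
            if self.rx_r2[rx_i] >= 0:
                ok &= self.support[self.rx_r2[rx_i]]
            for v in np.nonzero(ok)[0]:
                cand[v].append(rx_i)
        self.cand_ptr = np.zeros(n_vox + 1, dtype=np.int64)
        flat: list[int] = []
        for v in range(n_vox):
            flat.extend(cand[v])
            self.cand_ptr[v + 1] = len(flat)
        self.cand_rx = np.array(flat, dtype=np.int32)


def _compile_schedule(
    system: CompiledSystem, schedule: Sequence[InjectionEvent]
) -> tuple[np.ndarray, ...]:
    mesh = system.mesh
    sets = mesh.metadata.get("sets", {})
    n = len(schedule)
    inj_spec = np.zeros(n, dtype=np.int32)
    inj_on = np.zeros(n)
    inj_off = np.zeros(n)
    ptr = np.zeros(n + 1, dtype=np.int64)
    vox_flat: list[int] = []
    rate_flat: list[float] = []
    for i, ev in enumerate(sorted(schedule, key=lambda e: (e.onset, e.species))):
        if ev.species not in system.sidx:
            raise ValueError(f"injection species {ev.species} not in model")
        if ev.voxel_set == "all":
            idxs = list(range(mesh.n_voxels))
        elif ev.voxel_set not in sets:
            raise ValueError(f"injection targets unknown voxel set {ev.voxel_set!r}")
        else:
            idxs = list(sets[ev.voxel_set])
        if not idxs:
            raise ValueError(f"injection voxel set {ev.voxel_set!r} is empty")
        bad = [v for v in idxs if v < 0 or v >= mesh.n_voxels]
        if bad:
            raise ValueError(f"injection voxel(s) {bad} not in mesh")
        inj_spec[i] = system.sidx[ev.species]
        inj_on[i] = ev.onset
        inj_off[i] = ev.end
        vols = system.volumes[idxs]
        share = vols / vols.sum()
        total_per_s = ev.rate * 1e3
        vox_flat.extend(idxs)
        rate_flat.extend(total_per_s * share)
        ptr[i + 1] = len(vox_flat)
        system.mark_supported(ev.species)
    return (
        inj_spec,
        inj_on,
        inj_off,
        ptr,
        np.array(vox_flat, dtype=np.int32),
        np.array(rate_flat),
    )


# --------------------------------------------------------------------------
# the tau-leap kernel
# --------------------------------------------------------------------------

@njit(cache=False)
def _poisson_count(lam):
    """Poisson draw with a cheap zero fast path for small lambda."""
    if lam <= 0.0:
        return 0
    if lam < 10.0:
        u = np.random.random()
        if u < 1.0 - lam:  # 1-lam <= exp(-lam): certainly zero
            return 0
        p = math.exp(-lam)
        if u < p:
            return 0
        cdf = p
        m = 0
        while m < 200:
            m += 1
            p *= lam / m
            cdf += p
            if u < cdf:
                return m
        return m
    return np.random.poisson(lam)


@njit(cache=False)
def _binomial_count(n, p):
    """Binomial(n, p) with fast paths for the common regimes."""
    if n <= 0 or p <= 0.0:
        return 0
    mean = n * p
    if mean < 1e-4:
        return 1 if np.random.random() < mean else 0
    var = mean * (1.0 - p)
    if var > 25.0:
        m = int(round(mean + math.sqrt(var) * np.random.standard_normal()))
        if m < 0:
            m = 0
        elif m > n:
            m = n
        return m
    return np.random.binomial(n, p)


@njit(cache=False)
def _run_tau_leap(
    counts,
    volumes,
    clamped,
    rx_r1, rx_c1, rx_r2, rx_c2, rx_homo, rx_k, rx_prod_idx, rx_prod_n,
    cand_ptr, cand_rx,
    diff_species, diff_nsub, edge_from, edge_to, edge_p,
    inj_spec, inj_on, inj_off, inj_ptr, inj_vox, inj_rate,
    dt, n_steps, sample_every,
    out, group_of,
    seed,
):
    np.random.seed(seed)
    n_vox, n_spec = counts.shape
    n_inj = inj_spec.shape[0]
    n_dsp = diff_species.shape[0]
    n_edge = edge_from.shape[0]
    snap = np.empty_like(counts)
    isample = 0

    for step in range(n_steps + 1):
        if step % sample_every == 0 and isample < out.shape[0]:
            for v in range(n_vox):
                g = group_of[v]
                for s in range(n_spec):
                    out[isample, g, s] += counts[v, s]
            isample += 1
        if step == n_steps:
            break
        t = step * dt

        # injections (stochastic rounding of the fractional expectation)
        for e in range(n_inj):
            if inj_on[e] <= t and t < inj_off[e]:
                s = inj_spec[e]
                for q in range(inj_ptr[e], inj_ptr[e + 1]):
                    exp_m = inj_rate[q] * dt
                    m = int(exp_m)
                    if np.random.random() < exp_m - m:
                        m += 1
                    if m > 0:
                        counts[inj_vox[q], s] += m

        # reactions: propensities from the start-of-step state
        snap[:, :] = counts
        for v in range(n_vox):
            kconv_fac = 1.0 / (NAV_K * volumes[v])
            for ci in range(cand_ptr[v], cand_ptr[v + 1]):
                r = cand_rx[ci]
                i1 = rx_r1[r]
                n1 = snap[v, i1]
                if n1 <= 0:
                    continue
                i2 = rx_r2[r]
                if i2 >= 0:
                    n2 = snap[v, i2]
                    if n2 <= 0:
                        continue
                    lam = rx_k[r] * kconv_fac * n1 * n2 * dt
                elif rx_homo[r]:
                    if n1 < 2:
                        continue
                    lam = rx_k[r] * kconv_fac * n1 * (n1 - 1) * dt
                else:
                    lam = rx_k[r] * n1 * dt
                m = _poisson_count(lam)
                if m <= 0:
                    continue
                # cap at currently available molecules
                if not clamped[i1]:
                    avail = counts[v, i1] // rx_c1[r]
                    if m > avail:
                        m = avail
                if i2 >= 0 and not clamped[i2]:
                    avail = counts[v, i2] // rx_c2[r]
                    if m > avail:
                        m = avail
                if m <= 0:
                    continue
                if not clamped[i1]:
                    counts[v, i1] -= rx_c1[r] * m
                if i2 >= 0 and not clamped[i2]:
                    counts[v, i2] -= rx_c2[r] * m
                for j in range(4):
                    p = rx_prod_idx[r, j]
                    if p < 0:
                        break
                    if not clamped[p]:
                        counts[v, p] += rx_prod_n[r, j] * m

        # diffusion: sequential per-edge binomial transfers; fast edges
        # (thin spine couplings) are substepped individually
        for di in range(n_dsp):
            s = diff_species[di]
            for e in range(n_edge):
                nfrom = counts[edge_from[e], s]
                if nfrom <= 0:
                    continue
                nsub = diff_nsub[di, e]
                if nsub == 1:
                    m = _binomial_count(nfrom, edge_p[di, e])
                else:
                    m = 0
                    for _sub in range(nsub):
                        m += _binomial_count(nfrom - m, edge_p[di, e])
                if m > 0:
                    counts[edge_from[e], s] -= m
                    counts[edge_to[e], s] += m
    return isample


# NAV constant accessible inside the kernel
NAV_K = NAV


def run(
    model: ModelSpec,
    mesh: Mesh,
    schedule: Sequence[InjectionEvent],
    config: EngineConfig,
    groups: dict[str, list[int]] | None = None,
    system: CompiledSystem | None = None,
) -> Trajectory:
    """Run the tau-leap engine; deterministic given (model, mesh, schedule,
    config, seed)."""
    if system is None:
        system = CompiledSystem(model, mesh, groups)
    inj = _compile_schedule(system, schedule)

    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    sample_every = max(1, int(round(config.sample_interval / dt)))
    n_samples = n_steps // sample_every + 1

    # per-(species, edge) jump probabilities; edges whose probability would
    # exceed P_MAX are substepped individually
    n_dsp = len(system.diff_species)
    n_edge = len(system.edge_geom)
    diff_nsub = np.ones((n_dsp, n_edge), dtype=np.int32)
    edge_p = np.zeros((n_dsp, n_edge))
    for k, si in enumerate(system.diff_species):
        p_full = system.D[si] * system.edge_geom * dt
        diff_nsub[k] = np.maximum(1, np.ceil(p_full / P_MAX)).astype(np.int32)
        edge_p[k] = np.minimum(p_full / diff_nsub[k], 1.0)

    # initial counts: integer part + seeded Bernoulli for the fraction
    rng = np.random.default_rng(config.rng_seed)
    expected = system.init_expected
    counts0 = np.floor(expected).astype(np.int64)
    counts0 += (rng.random(expected.shape) < (expected - counts0)).astype(np.int64)

    out = np.zeros(
        (n_samples, len(system.group_names), len(system.species_names)), dtype=np.int64
    )
    kernel_seed = np.int64(config.rng_seed & 0x7FFFFFFF)
    got = _run_tau_leap(
        counts0,
        system.volumes,
        system.clamped,
        system.rx_r1, system.rx_c1, system.rx_r2, system.rx_c2,
        system.rx_homo, system.rx_k, system.rx_prod_idx, system.rx_prod_n,
        system.cand_ptr, system.cand_rx,
        system.diff_species, diff_nsub, system.edge_from, system.edge_to, edge_p,
        *inj,
        dt, n_steps, sample_every,
        out, system.group_of,
        kernel_seed,
    )
    assert got == n_samples
    if counts0.min() < 0:
        raise RuntimeError("internal error: negative count after run")
    times = np.arange(n_samples) * (sample_every * dt)
    return Trajectory(
        times=times,
        counts=out,
        group_names=list(system.group_names),
        group_volumes=system.group_volumes.copy(),
        species_names=list(system.species_names),
        meta={
            "seed": config.rng_seed,
            "dt": dt,
            "t_end": config.t_end,
            "mode": "tau_leap",
            "model_hash": model.content_hash(),
            "variant": model.variant,
        },
    )
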