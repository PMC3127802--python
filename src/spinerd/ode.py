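"""Deterministic well-mixed reference: mass-action ODEs for the full
network (or any subnetwork), used to validate the stochastic engines and
for the large-copy-number limit.

Concentrations are in nM; second-order rate constants in nM^-1 s^-1 need no
volume conversion.  Clamped reservoir species are held constant.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .model import NAV, ModelSpec, ReactionSpec


def integrate_mass_action(
    species_names: list[str],
    reactions: list[ReactionSpec],
    y0_nM: dict[str, float],
    t_eval: np.ndarray,
    clamped: set[str] = frozenset(),
    rtol: float = 1e-8,
    atol: float = 1e-9,
):
    """Integrate d[c]/dt = S v(c) for elementary mass-action reactions.

    Returns (t, Y) with Y shaped (n_times, n_species), nM.  Raises
    RuntimeError naming the failure time if the integrator gives up.
    """
    sidx = {n: i for i, n in enumerate(species_names)}
    n = len(species_names)

    # precompute reactant indices and stoichiometry
    terms = []
    stoich = np.zeros((len(reactions), n))
    for k, rx in enumerate(reactions):
        idx = [sidx[s] for s, _ in rx.reactants]
        terms.append((idx, rx.homodimer, rx.rate_constant))
        for s, c in rx.reactants:
            stoich[k, sidx[s]] -= c
        for s, c in rx.products:
            stoich[k, sidx[s]] += c
    clamp_mask = np.zeros(n, dtype=bool)
    for s in clamped:
        clamp_mask[sidx[s]] = True
    stoich[:, clamp_mask] = 0.0

    def rhs(t, y):
        v = np.empty(len(reactions))
        for k, (idx, homo, rate) in enumerate(terms):
            if len(idx) == 1:
                ci = y[idx[0]]
                v[k] = rate * ci * ci if homo else rate * ci
            else:
                v[k] = rate * y[idx[0]] * y[idx[1]]
        return v @ stoich

    y0 = np.array([y0_nM.get(s, 0.0) for s in species_names])
    sol = solve_ivp(
        rhs,
        (float(t_eval[0]), float(t_eval[-1])),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else t_eval[0]
        raise RuntimeError(f"stiff integration failed at t = {t_fail:.6g} s: {sol.message}")
    if not np.isfinite(sol.y).all():
        bad = np.nonzero(~np.isfinite(sol.y).all(axis=0))[0]
        t_fail = sol.t[bad[0]] if len(bad) else sol.t[-1]
        raise RuntimeError(f"stiff integration failed at t = {t_fail:.6g} s: "
                           "non-finite concentrations")
    return sol.t, sol.y.T


def run_ode_wellmixed(
    model: ModelSpec,
    t_end: float,
    n_samples: int = 201,
    volume_um3: float | None = None,
    membrane_area_um2: float | None = None,
    extra_initial_nM: dict[str, float] | None = None,
    rtol: float = 1e-8,
):
    """Integrate the full network in a single well-mixed compartment.

    Anchored quantities (molecules) and pump surface densities
    (molecules/um^2 x ``membrane_area_um2``) are converted to average
    concentrations using ``volume_um3``; pass the mesh totals for a
    geometry-matched comparison.  Returns (t, Y, species_names).
    """
    names = model.species_names()
    y0 = dict(model.initial_conditions_nM)
    if volume_um3 is not None:
        for sp, total in model.anchored_molecules.items():
            y0[sp] = y0.get(sp, 0.0) + total / (NAV * volume_um3)
        if membrane_area_um2 is not None:
            for pump, dens in model.pump_density_per_um2.items():
                y0[pump] = y0.get(pump, 0.0) + dens * membrane_area_um2 / (
                    NAV * volume_um3
                )
    if extra_initial_nM:
        for sp, c in extra_initial_nM.items():
            y0[sp] = y0.get(sp, 0.0) + c
    clamped = {s.name for s in model.species if s.clamped}
    t_eval = np.linspace(0.0, t_end, n_samples)
    t, Y = integrate_mass_action(
        names, model.elementary(), y0, t_eval, clamped=clamped, rtol=rtol
    )
    return t, Y, names


def default_morphology_totals() -> tuple[float, float]:
    """(total volume um^3, total membrane area um^2) of the default
    single-spine morphology, for geometry-matched well-mixed runs."""
    from .mesh import build_single_spine_mesh

    mesh = build_single_spine_mesh()
    return (
        float(mesh.total_volume()),
        float(sum(v.membrane_area for v in mesh.voxels)),
    )


def basal_drift_report(
    model: ModelSpec,
    t_end: float = 60.0,
    volume_um3: float | None = None,
    membrane_area_um2: float | None = None,
) -> dict[str, float]:
    """Relative drift of every species with a printed nonzero basal
    concentration after ``t_end`` s without stimulation.

    Species equilibrated to the unprinted anchored-enzyme activities (the
    cAMP production/degradation axis) relax to a model-defined baseline
    within seconds and are expected to drift; the slow buffered pools should
    hold.  Interpretation and the asserted subset live with the callers.
    """
    if volume_um3 is None or membrane_area_um2 is None:
        vol, area = default_morphology_totals()
        volume_um3 = volume_um3 if volume_um3 is not None else vol
        membrane_area_um2 = (
            membrane_area_um2 if membrane_area_um2 is not None else area
        )
    t, Y, names = run_ode_wellmixed(
        model, t_end=t_end, volume_um3=volume_um3,
        membrane_area_um2=membrane_area_um2,
    )
    out = {}
    for sp, c0 in model.initial_conditions_nM.items():
        if c0 <= 0:
            continue
        c1 = Y[-1, names.index(sp)]
        out[sp] = (c1 - c0) / c0
    return out
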