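"""Outcome metrics computed from trajectories.

The headline readouts follow the study design: total activity (area under
the concentration curve) of the free PKA catalytic subunit and of
phosphorylated PDE4 (4B+4D), mean phospho-inhibitor-1, and the mean
fraction of GluR1 phosphorylated on Ser845 (all pS845-carrying forms over
the GluR1 moiety).
"""

from __future__ import annotations

import numpy as np

from .engine import Trajectory
from .model import ModelSpec

# metric names used in MetricsTable rows
METRIC_NAMES = (
    "auc_pka_catalytic",
    "mean_phospho_I1",
    "mean_phospho_PDE4",
    "auc_phospho_PDE4",
    "mean_frac_pS845_GluR1",
)


def auc_metric(
    traj: Trajectory,
    species: str | list[str],
    groups: str | list[str] | None = None,
    window: tuple[float, float] | None = None,
    baseline: float = 0.0,
) -> float:
    """Trapezoidal integral (nM*s) of the summed concentration series over
    ``window`` (default: the whole trajectory); baseline subtraction is off
    by default."""
    if isinstance(species, list) and not species:
        raise ValueError("empty species set")
    series = traj.concentration_series(species, groups)
    t = traj.times
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise ValueError(f"window {window} outside trajectory span ({t[0]}, {t[-1]})")
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        t, series = t[mask], series[mask]
    return float(np.trapezoid(series - baseline, t))


def mean_metric(
    traj: Trajectory,
    species: str | list[str],
    groups: str | list[str] | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Time-averaged concentration (nM) over ``window``."""
    t = traj.times
    if window is None:
        window = (float(t[0]), float(t[-1]))
    span = window[1] - window[0]
    if span <= 0:
        raise ValueError("empty averaging window")
    return auc_metric(traj, species, groups, window) / span


def phospho_i1_species(model: ModelSpec) -> list[str]:
    return model.tagged_species("pI1")


def phospho_pde4_species(model: ModelSpec) -> list[str]:
    return model.tagged_species("pPDE4")


def frac_phospho_s845(traj: Trajectory, model: ModelSpec) -> np.ndarray:
    """Fraction of the GluR1 moiety carrying the pS845 mark, over time."""
    glur1 = model.moiety_species("GluR1")
    ps845 = [s for s in model.tagged_species("pS845") if s in glur1]
    total = traj.count_series(list(glur1), weights=glur1).astype(float)
    if (total <= 0).any():
        raise ValueError("zero total GluR1 moiety in trajectory")
    phospho = traj.count_series(ps845, weights={s: glur1[s] for s in ps845})
    return phospho / total


def frac_phospho_s845_from_counts(counts: dict[str, int], model: ModelSpec) -> float:
    """Same bookkeeping on a plain counts mapping (used for hand checks)."""
    glur1 = model.moiety_species("GluR1")
    total = sum(glur1.get(s, 0) * n for s, n in counts.items())
    if total <= 0:
        raise ValueError("zero total GluR1 moiety")
    ps845 = set(model.tagged_species("pS845"))
    phos = sum(glur1.get(s, 0) * n for s, n in counts.items() if s in ps845)
    return phos / total


def compute_trial_metrics(
    traj: Trajectory,
    model: ModelSpec,
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """All standard metrics for one trial.

    ``window`` is the averaging/integration window; default is from the
    first stimulus onset (if recorded in traj.meta) to the end.
    """
    t = traj.times
    if window is None:
        start = float(traj.meta.get("stim_onset", t[0]))
        window = (start, float(t[-1]))
    span = window[1] - window[0]
    pi1 = phospho_i1_species(model)
    ppde4 = phospho_pde4_species(model)
    mask = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    frac = frac_phospho_s845(traj, model)[mask]
    return {
        "auc_pka_catalytic": auc_metric(traj, "PKAc", window=window),
        "mean_phospho_I1": mean_metric(traj, pi1, window=window),
        "mean_phospho_PDE4": mean_metric(traj, ppde4, window=window),
        "auc_phospho_PDE4": auc_metric(traj, ppde4, window=window),
        "mean_frac_pS845_GluR1": float(frac.mean()),
    }


def spatial_profiles(
    traj: Trajectory,
    times: list[float],
    species: str | list[str],
    bin_prefix: str = "dend_x",
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Concentration versus axial distance at the requested times (nearest
    sample), for trajectories grouped with :func:`engine.axial_groups`.

    Returns {time: (distances_um, concentration_nM)} ordered by distance
    from the stimulated end (x = 0).
    """
    bins = [(g, i) for i, g in enumerate(traj.group_names) if g.startswith(bin_prefix)]
    if not bins:
        raise ValueError("trajectory was not grouped by axial bins")
    bins.sort(key=lambda p: p[0])
    out = {}
    for t_req in times:
        it = int(np.argmin(np.abs(traj.times - t_req)))
        xs, cs = [], []
        for gname, gi in bins:
            xs.append(float(gname[len(bin_prefix):]))
            sub = traj.counts[it, gi, :]
            sidx = traj._species_idx(species)
            cs.append(sub[sidx].sum() / (0.602214076 * traj.group_volumes[gi]))
        out[t_req] = (np.array(xs), np.array(cs))
    return out


def profile_slope(distances: np.ndarray, conc: np.ndarray) -> float:
    """Least-squares slope of a normalized profile (peak = 1), per bin index;
    used to contrast the spatial specificity of different messengers."""
    peak = conc.max()
    if peak <= 0:
        return 0.0
    y = conc / peak
    x = distances / max(distances.max(), 1.0)
    return float(np.polyfit(x, y, 1)[0])
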