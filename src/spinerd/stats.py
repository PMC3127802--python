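"""One-way fixed-effects ANOVA with planned comparisons, implemented from
sums of squares (between/within); contrasts are t-tests on linear
combinations of group means with pooled within-group variance.  No
multiple-testing correction is applied beyond the planning of contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    t: float
    p: float
    df: int


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    dfb, dfw = k - 1, N - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0.0:
        F = 0.0 if msb == 0.0 else np.inf
    else:
        F = msb / msw
    p = float(sps.f.sf(F, dfb, dfw)) if np.isfinite(F) else 0.0
    return AnovaResult(F=float(F), p=p, df_between=dfb, df_within=dfw,
                       ms_between=msb, ms_within=msw)


def planned_contrast(groups: list[np.ndarray], weights: list[float]) -> ContrastResult:
    """t-test of sum(w_i * mean_i) against 0 with pooled variance."""
    if len(weights) != len(groups):
        raise ValueError("one weight per group required")
    anova = one_way_anova(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.asarray(g, dtype=float).mean() for g in groups])
    w = np.asarray(weights, dtype=float)
    est = float(w @ means)
    se = float(np.sqrt(anova.ms_within * (w**2 / ns).sum()))
    if se == 0.0:
        t = 0.0 if est == 0.0 else np.inf * np.sign(est)
    else:
        t = est / se
    p = float(2 * sps.t.sf(abs(t), anova.df_within)) if np.isfinite(t) else 0.0
    return ContrastResult(estimate=est, se=se, t=float(t), p=p, df=anova.df_within)


def one_way_anova_planned(
    metrics,  # MetricsTable-style DataFrame
    metric: str,
    contrasts: dict[str, dict[str, float]] | None = None,
    group_col: str = "config",
):
    """ANOVA over configurations for one metric, plus planned contrasts.

    ``contrasts`` maps contrast name -> {config label: weight}.  Returns
    (AnovaResult, {name: ContrastResult}), with group order taken from the
    sorted config labels.
    """
    sub = metrics[metrics["metric"] == metric]
    labels = sorted(sub[group_col].unique())
    groups = [sub[sub[group_col] == lab]["value"].to_numpy() for lab in labels]
    anova = one_way_anova(groups)
    results = {}
    for name, wmap in (contrasts or {}).items():
        w = [wmap.get(lab, 0.0) for lab in labels]
        results[name] = planned_contrast(groups, w)
    return anova, results
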