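"""Publication-bias diagnostics: Egger regression, Begg rank correlation,
and funnel-plot coordinates.

Egger's test regresses the standardized effect (log OR / SE) on precision
(1 / SE) by ordinary least squares; under no small-study effect the
intercept is zero, and intercept / SE(intercept) is referred to a t
distribution with k-2 degrees of freedom.  This unweighted standardized
form is algebraically equivalent to the classic weighted regression of
log OR on SE.

Begg's test rank-correlates the variance-stabilised deviates of the study
effects from the fixed-effects pooled value with the study variances
(Kendall's tau, tie-corrected normal approximation, no continuity
correction).
"""

from __future__ import annotations

import enum
import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta import EffectEstimate, PooledResult, Z_95

__all__ = ["BiasMethod", "BiasTestResult", "egger_test", "begg_test", "funnel_coordinates"]


class BiasMethod(str, enum.Enum):
    EGGER = "egger"
    BEGG = "begg"


@dataclass(frozen=True)
class BiasTestResult:
    method: BiasMethod
    statistic: float          # t for Egger, z for Begg
    p_value: float
    k: int
    intercept: float | None = None     # Egger only
    slope: float | None = None         # Egger only
    kendall_tau: float | None = None   # Begg only


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's regression intercept test for funnel asymmetry.

    Requires k >= 3 studies (the t reference has k-2 df).
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Egger's test needs at least 3 studies, got {k}")
    se = np.array([e.se for e in effects])
    y = np.array([e.log_or for e in effects]) / se
    x = 1.0 / se
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise ValueError("all studies have identical precision; Egger slope undefined")
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = float(np.sum(resid**2)) / (k - 2)
    se_intercept = math.sqrt(s2 * (1.0 / k + xbar**2 / sxx))
    t = intercept / se_intercept
    p = float(2 * stats.t.sf(abs(t), k - 2))
    return BiasTestResult(BiasMethod.EGGER, t, p, k, intercept=intercept, slope=slope)


def _kendall(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b and its normal-approximation z by
    explicit pair counting (no continuity correction)."""
    n = len(x)
    s = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))

    def tie_sizes(v):
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1]

    tx, ty = tie_sizes(x), tie_sizes(y)
    n0 = n * (n - 1) / 2
    n1 = float(np.sum(tx * (tx - 1) / 2)) if len(tx) else 0.0
    n2 = float(np.sum(ty * (ty - 1) / 2)) if len(ty) else 0.0
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom if denom > 0 else float("nan")
    # Tie-corrected variance of S (Kendall 1970).
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5))) if len(tx) else 0.0
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5))) if len(ty) else 0.0
    v1 = (float(np.sum(tx * (tx - 1))) * float(np.sum(ty * (ty - 1)))) / (2 * n * (n - 1)) \
        if len(tx) and len(ty) else 0.0
    v2 = (float(np.sum(tx * (tx - 1) * (tx - 2))) * float(np.sum(ty * (ty - 1) * (ty - 2)))) \
        / (9 * n * (n - 1) * (n - 2)) if len(tx) and len(ty) and n > 2 else 0.0
    var_s = (v0 - vt - vu) / 18 + v1 + v2
    z = s / math.sqrt(var_s) if var_s > 0 else 0.0
    return tau, z


def begg_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for publication bias.

    The study log ORs are centred on the fixed-effects (inverse-variance)
    pooled value and standardised by sqrt(v_i - 1/sum(w)), the variance of
    the deviate; Kendall's tau between these deviates and the study
    variances is referred to its tie-corrected normal approximation.
    """
    k = len(effects)
    if k < 2:
        raise ValueError(f"Begg's test needs at least 2 studies, got {k}")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    v_star = v - 1.0 / float(np.sum(w))
    if np.all(v == v[0]):
        _warnings.warn(
            "all study variances are equal; Begg rank correlation is degenerate",
            stacklevel=2,
        )
        # All x-ranks tied: tau is undefined (0/0); report 0 with z=0.
        return BiasTestResult(BiasMethod.BEGG, 0.0, 1.0, k, kendall_tau=0.0)
    # v_star is strictly positive unless a study carries all the weight.
    u = (y - mu) / np.sqrt(np.maximum(v_star, np.finfo(float).tiny))
    tau, z = _kendall(v, u)
    p = float(2 * stats.norm.sf(abs(z)))
    return BiasTestResult(BiasMethod.BEGG, z, p, k, kendall_tau=tau)


def funnel_coordinates(
    effects: Sequence[EffectEstimate],
    pooled: PooledResult,
    n_guide: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Funnel-plot data: one (log_or, se) point per study, plus pseudo-95%%
    confidence guide lines around the pooled log OR over the observed SE
    range.  The SE axis is conventionally drawn inverted (0 on top).
    """
    if not effects:
        raise ValueError("no effects to plot")
    points = pd.DataFrame({
        "study_id": [e.study_id for e in effects],
        "log_or": [e.log_or for e in effects],
        "se": [e.se for e in effects],
    })
    center = math.log(pooled.pooled_or)
    se_grid = np.linspace(0.0, points["se"].max(), n_guide)
    guides = pd.DataFrame({
        "se": se_grid,
        "lower": center - Z_95 * se_grid,
        "center": center,
        "upper": center + Z_95 * se_grid,
    })
    return points, guides
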