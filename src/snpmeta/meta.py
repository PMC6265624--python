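"""Per-study effect estimation and pooled meta-analytic inference.

Each study contributes a 2x2 exposure table; its log odds ratio and
Woolf standard error are the meta-analytic inputs.  Pooling follows the
classic two-stage recipe for count data:

* Cochran's Q on inverse-variance weights measures between-study
  heterogeneity; its chi-square p-value (df = k-1) drives model choice.
* ``p_het > 0.10`` selects the fixed-effects Mantel-Haenszel pooled OR
  (with the Robins-Breslow-Greenland variance for its log); otherwise the
  DerSimonian-Laird random-effects estimate is used, with the moment
  estimator tau^2 inflating each study's variance.
* The pooled log OR is tested against zero with a two-sided Z-test.

I^2 = max(0, (Q - df)/Q) is reported as the standard companion summary of
heterogeneity although model selection uses the Q p-value alone.
"""

from __future__ import annotations

import enum
import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .models import ContrastTable, Model, apply_continuity_correction, build_contrast
from .studies import ControlSource, Ethnicity, StudyRecord, by_snp

__all__ = [
    "Z_95",
    "HETEROGENEITY_ALPHA",
    "PoolingMethod",
    "EffectEstimate",
    "HeterogeneityResult",
    "PooledResult",
    "study_effect",
    "heterogeneity",
    "pool",
    "analyze",
    "leave_one_out",
    "results_table",
]

#: Two-sided 95% normal quantile used for every confidence interval.
Z_95 = 1.959964

#: Q-test p-value above which the fixed-effects model is selected.
HETEROGENEITY_ALPHA = 0.10


class PoolingMethod(str, enum.Enum):
    AUTO = "auto"
    FIXED_MH = "fixed_mh"
    RANDOM_DL = "random_dl"


@dataclass(frozen=True)
class EffectEstimate:
    """One study's odds ratio on the log scale with its Woolf SE."""

    study_id: str
    model: Model
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    iv_weight: float

    @classmethod
    def from_log(cls, study_id: str, model: Model, log_or: float, se: float) -> "EffectEstimate":
        return cls(
            study_id=study_id,
            model=model,
            log_or=log_or,
            se=se,
            or_value=math.exp(log_or),
            ci_low=math.exp(log_or - Z_95 * se),
            ci_high=math.exp(log_or + Z_95 * se),
            iv_weight=1.0 / se**2,
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value, I^2 and the DL tau^2."""

    q: float
    df: int
    p_het: float
    i_squared: float
    tau_squared: float


@dataclass(frozen=True)
class PooledResult:
    snp: str
    model: Model
    stratum: str
    k: int
    n_cases: int
    n_controls: int
    method: PoolingMethod
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p_z: float
    heterogeneity: HeterogeneityResult
    per_study: tuple[EffectEstimate, ...]
    omitted_study: str | None = None


def study_effect(table: ContrastTable, study_id: str = "") -> EffectEstimate:
    """Odds ratio, Woolf SE and 95% CI from a 2x2 exposure table.

    Requires strictly positive cells; zero cells must first be handled by
    :func:`snpmeta.models.apply_continuity_correction`.
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "zero cell in contrast table; apply_continuity_correction first"
        )
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate.from_log(study_id, table.model, log_or, se)


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q, its p-value, I^2 and the DerSimonian-Laird tau^2.

    Q is the inverse-variance weighted sum of squared deviations of the
    study log ORs from their IV-weighted mean; tau^2 is the DL moment
    estimator max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no effects to test for heterogeneity")
    if k == 1:
        _warnings.warn("heterogeneity of a single study is undefined; Q=0 by convention",
                       stacklevel=2)
        return HeterogeneityResult(0.0, 0, 1.0, 0.0, 0.0)
    y = np.array([e.log_or for e in effects])
    w = np.array([e.iv_weight for e in effects])
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    df = k - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q, df, p_het, i2, tau2)


def _mh_pool(tables: Sequence[ContrastTable]) -> tuple[float, float]:
    """Mantel-Haenszel pooled log OR and its Robins-Breslow-Greenland SE."""
    a = np.array([t.case_exposed for t in tables], dtype=float)
    b = np.array([t.case_unexposed for t in tables], dtype=float)
    c = np.array([t.control_exposed for t in tables], dtype=float)
    d = np.array([t.control_unexposed for t in tables], dtype=float)
    n = a + b + c + d
    r_i = a * d / n
    s_i = b * c / n
    r, s = r_i.sum(), s_i.sum()
    if r <= 0 or s <= 0:
        raise ValueError("Mantel-Haenszel pooling undefined: zero cross-product sum")
    log_or = math.log(r / s)
    p_i = (a + d) / n
    q_i = (b + c) / n
    var = (
        float(np.sum(p_i * r_i)) / (2 * r * r)
        + float(np.sum(p_i * s_i + q_i * r_i)) / (2 * r * s)
        + float(np.sum(q_i * s_i)) / (2 * s * s)
    )
    return log_or, math.sqrt(var)


def _dl_pool(effects: Sequence[EffectEstimate], tau2: float) -> tuple[float, float]:
    """Random-effects pooled log OR with tau^2-inflated IV weights."""
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return mu, math.sqrt(1.0 / float(np.sum(w)))


def pool(
    effects: Sequence[EffectEstimate],
    tables: Sequence[ContrastTable],
    method: PoolingMethod | str = PoolingMethod.AUTO,
    *,
    snp: str = "",
    stratum: str = "overall",
    n_cases: int = 0,
    n_controls: int = 0,
    omitted_study: str | None = None,
) -> PooledResult:
    """Pool per-study effects into one summary OR with CI, Z-test and Q.

    ``method='auto'`` applies the heterogeneity switching rule: fixed
    Mantel-Haenszel when the Q-test p-value exceeds 0.10, random
    DerSimonian-Laird otherwise.  Either method can also be forced.
    """
    method = PoolingMethod(method) if not isinstance(method, PoolingMethod) else method
    k = len(effects)
    if k == 0:
        raise ValueError("cannot pool an empty study set")
    if len(tables) != k:
        raise ValueError(f"effects ({k}) and tables ({len(tables)}) are misaligned")
    het = heterogeneity(effects) if k > 1 else HeterogeneityResult(0.0, 0, 1.0, 0.0, 0.0)
    if method is PoolingMethod.AUTO:
        method = (
            PoolingMethod.FIXED_MH if het.p_het > HETEROGENEITY_ALPHA else PoolingMethod.RANDOM_DL
        )
    if method is PoolingMethod.FIXED_MH:
        log_or, se = _mh_pool(tables)
    else:
        log_or, se = _dl_pool(effects, het.tau_squared)
    z = log_or / se
    p_z = float(2 * stats.norm.sf(abs(z)))
    return PooledResult(
        snp=snp,
        model=effects[0].model,
        stratum=stratum,
        k=k,
        n_cases=n_cases,
        n_controls=n_controls,
        method=method,
        pooled_or=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        z=z,
        p_z=p_z,
        heterogeneity=het,
        per_study=tuple(effects),
        omitted_study=omitted_study,
    )


def _pool_records(
    records: Sequence[StudyRecord],
    snp: str,
    model: Model,
    stratum: str,
    method: PoolingMethod | str = PoolingMethod.AUTO,
    omitted_study: str | None = None,
) -> PooledResult:
    tables = [
        apply_continuity_correction(build_contrast(r.case_counts, r.control_counts, model))
        for r in records
    ]
    effects = [study_effect(t, r.study_id) for t, r in zip(tables, records)]
    return pool(
        effects,
        tables,
        method,
        snp=snp,
        stratum=stratum,
        n_cases=sum(r.case_counts.total for r in records),
        n_controls=sum(r.control_counts.total for r in records),
        omitted_study=omitted_study,
    )


#: Stratification axes understood by :func:`analyze`.
_STRATA_AXES = {
    "ethnicity": lambda r: r.ethnicity.value,
    "source": lambda r: r.source.value,
}


def analyze(
    records: Iterable[StudyRecord],
    snp: str,
    models: Sequence[Model | str] | None = None,
    strata: Sequence[str] = ("ethnicity", "source"),
    method: PoolingMethod | str = PoolingMethod.AUTO,
) -> list[PooledResult]:
    """Overall and stratified pooled results for one SNP.

    For each genetic model one overall result is produced, plus one per
    observed level of each requested stratification axis (``ethnicity``
    and/or ``source``).  Single-study strata are reported as the study's
    own estimate (k=1, fixed label, p_het=1 by convention).
    """
    recs = by_snp(records, snp)
    if not recs:
        raise ValueError(f"no studies found for SNP {snp!r}")
    models = [Model.coerce(m) for m in (models or list(Model))]
    for axis in strata:
        if axis not in _STRATA_AXES:
            raise ValueError(f"unknown stratification axis {axis!r}")
    results = []
    for model in models:
        results.append(_pool_records(recs, snp, model, "overall", method))
        for axis in strata:
            key = _STRATA_AXES[axis]
            for level in sorted({key(r) for r in recs}):
                sub = [r for r in recs if key(r) == level]
                results.append(
                    _pool_records(sub, snp, model, f"{axis}={level}", method)
                )
    return results


def leave_one_out(
    records: Iterable[StudyRecord],
    snp: str,
    model: Model | str,
    method: PoolingMethod | str = PoolingMethod.AUTO,
) -> list[PooledResult]:
    """Sensitivity analysis: re-pool with each study omitted in turn.

    The fixed/random auto-selection is re-run on every reduced set, so an
    omission that removes the heterogeneity can flip the pooling method.
    """
    recs = by_snp(records, snp)
    if len(recs) < 2:
        raise ValueError("leave-one-out requires at least two studies")
    model = Model.coerce(model)
    out = []
    for i, omitted in enumerate(recs):
        kept = recs[:i] + recs[i + 1:]
        out.append(
            _pool_records(kept, snp, model, "overall", method, omitted_study=omitted.study_id)
        )
    return out


def results_table(results: Iterable[PooledResult]):
    """Long-format results frame, one row per (snp, stratum, model)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "snp": r.snp,
            "stratum": r.stratum,
            "model": r.model.value,
            "k": r.k,
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
            "method": r.method.value,
            "or": r.pooled_or,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "z": r.z,
            "p_z": r.p_z,
            "q": r.heterogeneity.q,
            "p_het": r.heterogeneity.p_het,
            "i_squared": r.heterogeneity.i_squared,
            "tau_squared": r.heterogeneity.tau_squared,
            "omitted_study": r.omitted_study,
        })
    return pd.DataFrame(rows)
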