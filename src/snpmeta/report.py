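"""End-to-end orchestration: read a study table, run every analysis stage,
and write a deterministic report bundle.

The bundle mirrors the tables of a published meta-analysis:

``results.tsv`` / ``results.json``
    one row per (snp, stratum, genetic model): k, sample sizes, pooling
    method chosen by the heterogeneity rule, pooled OR with 95% CI, Z-test,
    Q, p_het, I^2, tau^2.  The TSV is rounded (half-even) to the configured
    number of decimals; the JSON always carries full precision.
``hwe.tsv``
    per-study control-group HWE chi-square/p and effect-allele frequency.
``bias.tsv``
    Egger and Begg results per (snp, model), overall studies.
``sensitivity.tsv``
    leave-one-out pooled rows per (snp, model).
``funnel_<snp>_<model>.tsv`` / ``forest_<snp>_<model>.tsv``
    plotting coordinates; images themselves are left to the caller.
``run.log``
    reconcile warnings and the method chosen for every pooled row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .meta import Model, PoolingMethod, analyze, leave_one_out, results_table
from .models import apply_continuity_correction, build_contrast, effect_allele_freq, hwe_test
from .meta import study_effect, pool
from .studies import StudyRecord, parse_studies, validate_studies

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    input_path: str | Path
    output_dir: str | Path
    snps: Sequence[str] | None = None          # None = all SNPs present
    models: Sequence[str] | None = None        # None = all five models
    strata: Sequence[str] = ("ethnicity", "source")
    reconcile_policy: str = "reconcile"
    rounding: int = 2
    log_level: str = "INFO"


def _round_df(df: pd.DataFrame, nd: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = np.round(out[col].astype(float), nd)
    return out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results frames, keyed like the
    output files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    records = parse_studies(Path(config.input_path))
    records = validate_studies(records, policy=config.reconcile_policy)
    for r in records:
        for w in r.warnings:
            log_lines.append(f"reconcile [{r.study_id}]: {w}")

    snps = list(config.snps) if config.snps else sorted({r.snp for r in records})
    for snp in snps:
        if not any(r.snp == snp for r in records):
            raise ValueError(f"no studies for SNP {snp!r}")
    models = [Model.coerce(m) for m in (config.models or list(Model))]

    # HWE / allele-frequency table
    hwe_rows = []
    for r in records:
        res = hwe_test(r.control_counts)
        hwe_rows.append({
            "study_id": r.study_id, "snp": r.snp,
            "chi_square": res.chi_square, "p_value": res.p_value,
            "control_eaf": res.effect_allele_freq,
            "case_eaf": effect_allele_freq(r.case_counts),
            "reported_hwe_p": r.reported_hwe_p,
        })
    hwe_df = pd.DataFrame(hwe_rows)

    # Pooled results, bias tests, sensitivity, plot coordinates
    all_results = []
    bias_rows = []
    loo_results = []
    for snp in snps:
        res = analyze(records, snp, models=models, strata=config.strata)
        all_results.extend(res)
        for row in res:
            log_lines.append(
                f"method [{snp} {row.stratum} {row.model.value}]: {row.method.value} "
                f"(p_het={row.heterogeneity.p_het:.4f}, k={row.k})"
            )
        snp_records = [r for r in records if r.snp == snp]
        for model in models:
            overall = next(
                r for r in res if r.stratum == "overall" and r.model is model
            )
            effects = list(overall.per_study)
            if len(effects) >= 3:
                egger = bias_mod.egger_test(effects)
                bias_rows.append({
                    "snp": snp, "model": model.value, "method": "egger",
                    "statistic": egger.statistic, "p_value": egger.p_value,
                    "intercept": egger.intercept, "kendall_tau": None, "k": egger.k,
                })
            if len(effects) >= 2:
                begg = bias_mod.begg_test(effects)
                bias_rows.append({
                    "snp": snp, "model": model.value, "method": "begg",
                    "statistic": begg.statistic, "p_value": begg.p_value,
                    "intercept": None, "kendall_tau": begg.kendall_tau, "k": begg.k,
                })
            points, guides = bias_mod.funnel_coordinates(effects, overall)
            points.to_csv(out / f"funnel_{snp}_{model.value}.tsv", sep="\t", index=False)
            forest = pd.DataFrame({
                "study_id": [e.study_id for e in effects] + ["pooled"],
                "or": [e.or_value for e in effects] + [overall.pooled_or],
                "ci_low": [e.ci_low for e in effects] + [overall.ci_low],
                "ci_high": [e.ci_high for e in effects] + [overall.ci_high],
                "weight": [e.iv_weight for e in effects] + [float("nan")],
            })
            forest.to_csv(out / f"forest_{snp}_{model.value}.tsv", sep="\t", index=False)
            if len(snp_records) >= 2:
                loo_results.extend(leave_one_out(records, snp, model))

    results_df = results_table(all_results)
    bias_df = pd.DataFrame(bias_rows)
    loo_df = results_table(loo_results)

    nd = config.rounding
    _round_df(results_df, nd).to_csv(out / "results.tsv", sep="\t", index=False)
    results_df.to_json(out / "results.json", orient="records", indent=2)
    _round_df(hwe_df, nd).to_csv(out / "hwe.tsv", sep="\t", index=False)
    if not bias_df.empty:
        _round_df(bias_df, nd).to_csv(out / "bias.tsv", sep="\t", index=False)
        bias_df.to_json(out / "bias.json", orient="records", indent=2)
    if not loo_df.empty:
        _round_df(loo_df, nd).to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "results": results_df,
        "hwe": hwe_df,
        "bias": bias_df,
        "sensitivity": loo_df,
        "records": records,
    }
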