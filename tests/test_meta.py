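import math

import numpy as np
import pytest

from snpmeta import (
    ContrastTable,
    GenotypeCounts,
    Model,
    PoolingMethod,
    analyze,
    build_contrast,
    heterogeneity,
    leave_one_out,
    pool,
    study_effect,
)
from snpmeta.meta import _dl_pool, Z_95
from snpmeta.simulate import SimulationConfig, simulate_studies

# ---------------------------------------------------------------------------
# independent oracles, written directly from the textbook algebra
# ---------------------------------------------------------------------------


def brute_mh(tables):
    num = sum(t.case_exposed * t.control_unexposed / t.n for t in tables)
    den = sum(t.case_unexposed * t.control_exposed / t.n for t in tables)
    return math.log(num / den)


def brute_dl(effects):
    y = [e.log_or for e in effects]
    v = [e.se**2 for e in effects]
    w = [1 / vi for vi in v]
    mu = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - mu) ** 2 for wi, yi in zip(w, y))
    tau2 = max(0.0, (q - (len(y) - 1)) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
    ws = [1 / (vi + tau2) for vi in v]
    return sum(wi * yi for wi, yi in zip(ws, y)) / sum(ws), tau2


def random_tables(rng, k):
    cells = rng.integers(5, 200, size=(k, 4))
    return [ContrastTable(Model.ALLELE, *map(float, row)) for row in cells]


# ---------------------------------------------------------------------------


class TestStudyEffect:
    def test_symmetric_table_has_unit_odds_ratio(self):
        t = ContrastTable(Model.ALLELE, 50, 50, 50, 50)
        e = study_effect(t)
        assert e.log_or == 0 and e.or_value == 1.0

    def test_equal_reference_cells_cancel(self, rs266882):
        cicek = rs266882[0]
        t = build_contrast(cicek.case_counts, cicek.control_counts, "heterozygote")
        assert study_effect(t).or_value == pytest.approx(196 / 236)

    def test_transpose_gives_reciprocal_or_same_se(self):
        a = study_effect(ContrastTable(Model.ALLELE, 1, 10, 10, 1))
        b = study_effect(ContrastTable(Model.ALLELE, 10, 1, 1, 10))
        assert a.log_or == pytest.approx(-b.log_or)
        assert a.se == pytest.approx(b.se)

    def test_ci_is_symmetric_on_log_scale(self):
        e = study_effect(ContrastTable(Model.ALLELE, 12, 34, 56, 78))
        assert math.log(e.ci_low) == pytest.approx(e.log_or - Z_95 * e.se)
        assert math.log(e.ci_high) == pytest.approx(e.log_or + Z_95 * e.se)

    def test_zero_cell_requires_correction_first(self):
        with pytest.raises(ValueError, match="continuity"):
            study_effect(ContrastTable(Model.ALLELE, 0, 10, 10, 10))


class TestHeterogeneity:
    def test_identical_effects_have_zero_dispersion(self):
        e = study_effect(ContrastTable(Model.ALLELE, 20, 30, 25, 25))
        het = heterogeneity([e, e, e])
        assert het.q == pytest.approx(0, abs=1e-12)
        assert het.i_squared == 0 and het.tau_squared == 0
        assert het.p_het == pytest.approx(1.0)

    def test_published_heterozygote_q_p_value(self, rs266882):
        tabs = [build_contrast(r.case_counts, r.control_counts, "heterozygote") for r in rs266882]
        effects = [study_effect(t, r.study_id) for t, r in zip(tabs, rs266882)]
        assert round(heterogeneity(effects).p_het, 3) == 0.240

    def test_two_study_closed_form(self):
        a = study_effect(ContrastTable(Model.ALLELE, 30, 70, 50, 50))
        b = study_effect(ContrastTable(Model.ALLELE, 60, 40, 50, 50))
        het = heterogeneity([a, b])
        expected = (a.log_or - b.log_or) ** 2 / (a.se**2 + b.se**2)
        assert het.q == pytest.approx(expected, rel=1e-12)

    def test_single_study_is_conventionally_homogeneous(self):
        e = study_effect(ContrastTable(Model.ALLELE, 20, 30, 25, 25))
        with pytest.warns(UserWarning):
            het = heterogeneity([e])
        assert (het.q, het.df, het.p_het) == (0.0, 0, 1.0)


class TestPool:
    def test_single_study_pool_is_the_study_itself(self):
        t = ContrastTable(Model.ALLELE, 30, 70, 50, 50)
        e = study_effect(t, "only")
        res = pool([e], [t], "auto")
        assert res.pooled_or == pytest.approx(e.or_value)
        assert res.ci_low == pytest.approx(e.ci_low)
        assert res.method is PoolingMethod.FIXED_MH

    def test_auto_selects_fixed_when_homogeneous(self, rs266882):
        tabs = [build_contrast(r.case_counts, r.control_counts, "heterozygote") for r in rs266882]
        effects = [study_effect(t, r.study_id) for t, r in zip(tabs, rs266882)]
        res = pool(effects, tabs, "auto")
        assert res.method is PoolingMethod.FIXED_MH
        assert round(res.pooled_or, 2) == 0.95
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.81, 1.12)

    def test_auto_selects_random_when_heterogeneous(self, rs1058205):
        tabs = [build_contrast(r.case_counts, r.control_counts, "allele") for r in rs1058205]
        effects = [study_effect(t, r.study_id) for t, r in zip(tabs, rs1058205)]
        res = pool(effects, tabs, "auto")
        assert res.method is PoolingMethod.RANDOM_DL
        assert round(res.pooled_or, 2) == 0.75
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.64, 0.88)

    def test_mismatched_lengths_rejected(self):
        t = ContrastTable(Model.ALLELE, 30, 70, 50, 50)
        with pytest.raises(ValueError, match="misaligned"):
            pool([study_effect(t)], [t, t])

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(20240915)
        for _ in range(200):
            k = int(rng.integers(2, 11))
            tabs = random_tables(rng, k)
            effects = [study_effect(t, str(i)) for i, t in enumerate(tabs)]
            mh = pool(effects, tabs, "fixed_mh")
            dl = pool(effects, tabs, "random_dl")
            assert math.log(mh.pooled_or) == pytest.approx(brute_mh(tabs), abs=1e-6)
            mu, tau2 = brute_dl(effects)
            assert math.log(dl.pooled_or) == pytest.approx(mu, abs=1e-6)
            assert dl.heterogeneity.tau_squared == pytest.approx(tau2, abs=1e-6)

    def test_fixed_iv_equals_dl_when_tau_is_zero(self):
        # three studies with identical effects: Q=0 so tau^2=0 and the DL
        # weights collapse to plain inverse-variance weights
        t = ContrastTable(Model.ALLELE, 40, 60, 55, 45)
        effects = [study_effect(t, s) for s in "abc"]
        mu_dl, _ = _dl_pool(effects, 0.0)
        res = pool(effects, [t] * 3, "random_dl")
        assert math.log(res.pooled_or) == pytest.approx(mu_dl, abs=1e-12)

    def test_mh_close_to_iv_fixed_on_all_fixture_contrasts(self, table1):
        # MH and IV-fixed weighting coincide only asymptotically; on these
        # dense tables the largest observed log-OR gap is ~0.023 (the
        # heterogeneous rs2735839 homozygote contrast)
        from snpmeta import by_snp

        for snp in ("rs1058205", "rs2735839", "rs266882"):
            recs = by_snp(table1, snp)
            for model in Model:
                tabs = [build_contrast(r.case_counts, r.control_counts, model) for r in recs]
                effects = [study_effect(t, r.study_id) for t, r in zip(tabs, recs)]
                mh = brute_mh(tabs)
                iv, _ = _dl_pool(effects, 0.0)
                assert abs(mh - iv) < 0.03

    def test_pooled_or_within_per_study_range(self, table1):
        from snpmeta import by_snp

        for snp in ("rs1058205", "rs2735839", "rs266882"):
            recs = by_snp(table1, snp)
            for model in Model:
                tabs = [build_contrast(r.case_counts, r.control_counts, model) for r in recs]
                effects = [study_effect(t, r.study_id) for t, r in zip(tabs, recs)]
                res = pool(effects, tabs, "random_dl")
                ors = [e.or_value for e in effects]
                assert min(ors) <= res.pooled_or <= max(ors)

    def test_exposure_relabelling_inverts_pooled_or(self):
        rng = np.random.default_rng(7)
        tabs = random_tables(rng, 5)
        flipped = [
            ContrastTable(t.model, t.case_unexposed, t.case_exposed,
                          t.control_unexposed, t.control_exposed)
            for t in tabs
        ]
        for method in ("fixed_mh", "random_dl"):
            a = pool([study_effect(t, str(i)) for i, t in enumerate(tabs)], tabs, method)
            b = pool([study_effect(t, str(i)) for i, t in enumerate(flipped)], flipped, method)
            assert a.pooled_or == pytest.approx(1 / b.pooled_or, rel=1e-10)
            assert a.ci_low == pytest.approx(1 / b.ci_high, rel=1e-10)

    def test_dl_pooling_matches_metafor(self, rs1058205, tmp_path):
        # independent cross-check against the reference R implementation
        import json
        import subprocess

        tabs = [build_contrast(r.case_counts, r.control_counts, "allele") for r in rs1058205]
        rows = "\n".join(
            f"{t.case_exposed} {t.case_unexposed} {t.control_exposed} {t.control_unexposed}"
            for t in tabs
        )
        script = tmp_path / "dl.R"
        script.write_text(
            'suppressMessages(library(metafor))\n'
            f'm <- read.table(text="{rows}")\n'
            'fit <- rma(ai=m$V1, bi=m$V2, ci=m$V3, di=m$V4, measure="OR",\n'
            '           method="DL", test="z")\n'
            'cat(sprintf("%.10f %.10f %.10f", fit$b[1], fit$se, fit$tau2))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        mu_r, se_r, tau2_r = map(float, out)
        effects = [study_effect(t, r.study_id) for t, r in zip(tabs, rs1058205)]
        res = pool(effects, tabs, "random_dl")
        assert math.log(res.pooled_or) == pytest.approx(mu_r, abs=1e-6)
        assert res.heterogeneity.tau_squared == pytest.approx(tau2_r, abs=1e-6)


class TestAnalyze:
    def test_caucasian_subgroup_allele_contrast(self, table1):
        res = analyze(table1, "rs1058205", models=["allele"], strata=("ethnicity",))
        cauc = next(r for r in res if r.stratum == "ethnicity=Caucasian")
        assert cauc.k == 4
        assert round(cauc.pooled_or, 2) == 0.77
        assert (round(cauc.ci_low, 2), round(cauc.ci_high, 2)) == (0.65, 0.91)

    def test_stratum_covering_all_studies_equals_overall(self, table1):
        # every rs266882 study is Caucasian, so that stratum is the overall set
        res = analyze(table1, "rs266882", models=["allele"], strata=("ethnicity",))
        overall = next(r for r in res if r.stratum == "overall")
        cauc = next(r for r in res if r.stratum == "ethnicity=Caucasian")
        assert cauc.pooled_or == pytest.approx(overall.pooled_or)
        assert cauc.k == overall.k

    def test_overall_homozygote_rs2735839(self, table1):
        res = analyze(table1, "rs2735839", models=["homozygote"], strata=())
        assert round(res[0].pooled_or, 2) == 0.85
        assert (round(res[0].ci_low, 2), round(res[0].ci_high, 2)) == (0.40, 1.82)

    def test_unknown_snp_is_an_error(self, table1):
        with pytest.raises(ValueError, match="rs0"):
            analyze(table1, "rs0")

    def test_single_study_stratum_flagged_k1(self, table1):
        res = analyze(table1, "rs1058205", models=["allele"], strata=("source",))
        hb = next(r for r in res if r.stratum == "source=HB")
        assert hb.k == 1
        assert hb.heterogeneity.p_het == 1.0
        assert hb.method is PoolingMethod.FIXED_MH


class TestLeaveOneOut:
    def test_identical_studies_give_identical_estimates(self):
        sim = simulate_studies(SimulationConfig(n_studies=1, seed=3))
        rec = sim.records[0]
        from dataclasses import replace

        clones = [replace(rec, study_id=f"c{i}") for i in range(4)]
        results = leave_one_out(clones, "rsSIM", "allele")
        ors = {round(r.pooled_or, 12) for r in results}
        assert len(ors) == 1

    def test_every_omission_preserves_protective_direction(self, table1):
        results = leave_one_out(table1, "rs1058205", "allele")
        assert len(results) == 5
        assert {r.omitted_study for r in results} == {
            r.study_id for r in table1 if r.snp == "rs1058205"
        }
        assert all(r.pooled_or < 1 for r in results)

    def test_two_studies_degenerate_to_single_study_estimates(self, rs266882):
        pair = rs266882[:2]
        results = leave_one_out(pair, "rs266882", "allele")
        assert all(r.k == 1 for r in results)

    def test_fewer_than_two_studies_rejected(self, rs266882):
        with pytest.raises(ValueError):
            leave_one_out(rs266882[:1], "rs266882", "allele")
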