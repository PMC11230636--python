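"""Differential analysis, evidence correlation and DDG assembly."""

import numpy as np
import pandas as pd
import pytest

from driversub import ddg
from driversub.synthetic import SyntheticCohortConfig, generate_cohort
from driversub.types import GeneFamily, OmicsMatrix, ProbeAnnotation

from conftest import make_matrix


class TestDifferentialExpression:
    def test_identical_groups_not_deg(self, rng):
        vals = rng.uniform(1, 10, size=(5, 8))
        t = make_matrix(vals)
        n = make_matrix(vals, samples=[f"n{j}" for j in range(8)])
        res = ddg.differential_expression(t, n)
        assert not any(r.is_deg for r in res)
        # identical value sets: log2fc exactly 0
        assert all(r.log2fc == 0 for r in res)

    def test_low_mean_expression_excluded(self):
        t = make_matrix(np.full((1, 10), 0.8))
        n = make_matrix(np.full((1, 10), 0.1), samples=[f"n{j}" for j in range(10)])
        res = ddg.differential_expression(t, n)
        assert res[0].mean_tumor == pytest.approx(0.8)
        assert not res[0].is_deg  # both means < 1 regardless of p

    def test_constant_gene_p_one(self):
        t = make_matrix(np.full((1, 5), 3.0))
        n = make_matrix(np.full((1, 5), 3.0), samples=[f"n{j}" for j in range(5)])
        res = ddg.differential_expression(t, n)
        assert res[0].p_value == 1.0

    def test_group_too_small_rejected(self):
        t = make_matrix(np.ones((2, 1)))
        n = make_matrix(np.ones((2, 5)), samples=[f"n{j}" for j in range(5)])
        with pytest.raises(ValueError, match="2 samples"):
            ddg.differential_expression(t, n)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_deg_recall(self, seed):
        """Planted DEGs (log2fc 2, noise sd 0.5) are recovered at >= 0.9 recall."""
        c = generate_cohort(SyntheticCohortConfig(seed=seed))
        res = ddg.differential_expression(c.expression_tumor, c.expression_normal)
        called = {r.gene_id for r in res if r.is_deg}
        planted = set(c.truth.planted_degs)
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9
        # and few false calls among unplanted genes
        assert len(called - planted) <= 3


class TestDmps:
    def test_delta_below_threshold_not_dmp(self, rng):
        # strong separation but |delta beta| = 0.19
        t = make_matrix(
            np.clip(0.50 + rng.normal(0, 0.005, (1, 50)), 0, 1), layer="methylation_beta"
        )
        n = make_matrix(
            np.clip(0.31 + rng.normal(0, 0.005, (1, 50)), 0, 1),
            layer="methylation_beta",
            samples=[f"n{j}" for j in range(50)],
        )
        out = ddg.call_dmps(t, n)
        assert out.loc[0, "p_adjusted"] < 0.05
        assert abs(out.loc[0, "delta_beta"]) < 0.2
        assert not out.loc[0, "is_dmp"]

    def test_identical_groups_no_dmps(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(4, 10))
        t = make_matrix(vals, layer="methylation_beta")
        n = make_matrix(vals, layer="methylation_beta", samples=[f"n{j}" for j in range(10)])
        assert not ddg.call_dmps(t, n)["is_dmp"].any()

    def test_planted_shift_detected(self, rng):
        t = make_matrix(
            np.clip(0.3 + rng.normal(0, 0.03, (1, 50)), 0, 1), layer="methylation_beta"
        )
        n = make_matrix(
            np.clip(0.6 + rng.normal(0, 0.03, (1, 50)), 0, 1),
            layer="methylation_beta",
            samples=[f"n{j}" for j in range(50)],
        )
        assert ddg.call_dmps(t, n)["is_dmp"].all()


class TestCnvGroups:
    def test_gain_above_ratio(self):
        vals = np.zeros((1, 100))
        vals[0, :25] = 1.5
        out = ddg.classify_cnv_groups(make_matrix(vals, layer="cnv_gene"))
        assert bool(out.loc[0, "gain"]) and not bool(out.loc[0, "loss"])

    def test_exactly_at_ratio_is_neither(self):
        vals = np.zeros((1, 100))
        vals[0, :20] = 1.5
        out = ddg.classify_cnv_groups(make_matrix(vals, layer="cnv_gene"))
        assert not bool(out.loc[0, "gain"])

    def test_all_zero_neither(self):
        out = ddg.classify_cnv_groups(make_matrix(np.zeros((2, 10)), layer="cnv_gene"))
        assert not out[["gain", "loss"]].any().any()

    def test_level_is_strict(self):
        vals = np.full((1, 10), 1.0)  # at the gain level, not above
        out = ddg.classify_cnv_groups(make_matrix(vals, layer="cnv_gene"))
        assert not bool(out.loc[0, "gain"])


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10, dtype=float)
        rho, _ = ddg.correlate_regulator_target(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = ddg.correlate_regulator_target(x, -np.exp(x))
        assert rho == pytest.approx(-1.0)

    def test_tied_sample_matches_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 7.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _ = ddg.correlate_regulator_target(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_skipped(self):
        assert ddg.correlate_regulator_target(np.ones(6), np.arange(6.0)) is None


class TestAssembleDdgs:
    def _setup(self, rng):
        samples = [f"s{j}" for j in range(30)]
        fam = GeneFamily("F1", frozenset({"gA", "gB"}))
        expr_vals = rng.uniform(2, 30, size=(2, 30))
        expr = make_matrix(expr_vals, features=["gA", "gB"], samples=samples)
        beta = np.clip(0.9 - 0.02 * expr_vals[0:1] + rng.normal(0, 0.01, (1, 30)), 0, 1)
        beta_t = make_matrix(beta, layer="methylation_beta", features=["p1"], samples=samples)
        dmps = pd.DataFrame(
            {"probe_id": ["p1"], "delta_beta": [-0.3], "p_value": [1e-6], "p_adjusted": [1e-6], "is_dmp": [True]}
        )
        ann = [ProbeAnnotation("p1", "promoter", "gA")]
        de = [
            ddg.DiffExprResult("gA", 2.0, 1e-8, 1e-8, 20.0, 4.0, True),
            ddg.DiffExprResult("gB", 2.0, 1e-8, 1e-8, 20.0, 4.0, True),
        ]
        return fam, expr, beta_t, dmps, ann, de

    def test_promoter_evidence_creates_ddg(self, rng):
        fam, expr, beta_t, dmps, ann, de = self._setup(rng)
        out = ddg.assemble_ddgs(
            de, [fam], expr, dmps=dmps, probe_annotation=ann, beta_tumor=beta_t
        )
        assert set(out) == {"gA"}
        ev = out["gA"][0]
        assert ev.evidence_type == "promoter_meth" and ev.rho < -0.2

    def test_non_deg_with_evidence_is_not_ddg(self, rng):
        fam, expr, beta_t, dmps, ann, de = self._setup(rng)
        de = [ddg.DiffExprResult("gA", 0.1, 0.9, 0.9, 20.0, 19.0, False)]
        out = ddg.assemble_ddgs(
            de, [fam], expr, dmps=dmps, probe_annotation=ann, beta_tumor=beta_t
        )
        assert out == {}

    def test_deg_without_evidence_is_not_ddg(self, rng):
        fam, expr, beta_t, dmps, ann, de = self._setup(rng)
        out = ddg.assemble_ddgs(de, [fam], expr)  # no evidence layers supplied
        assert out == {}

    def test_deg_outside_family_is_not_candidate(self, rng):
        fam, expr, beta_t, dmps, ann, de = self._setup(rng)
        ann = [ProbeAnnotation("p1", "promoter", "gZ")]
        de.append(ddg.DiffExprResult("gZ", 2.0, 1e-8, 1e-8, 20.0, 4.0, True))
        out = ddg.assemble_ddgs(
            de, [fam], expr, dmps=dmps, probe_annotation=ann, beta_tumor=beta_t
        )
        assert "gZ" not in out

    def test_evidence_rows_satisfy_thresholds(self, default_cohort):
        c = default_cohort
        de = ddg.differential_expression(c.expression_tumor, c.expression_normal)
        dmps = ddg.call_dmps(c.methylation, c.methylation_normal)
        dmi = ddg.differential_expression(c.mirna, c.mirna_normal)
        flags = ddg.classify_cnv_groups(c.cnv_gene)
        out = ddg.assemble_ddgs(
            de,
            c.families,
            c.expression_tumor,
            dmps=dmps,
            probe_annotation=c.probe_annotation,
            beta_tumor=c.methylation,
            dmi=dmi,
            mirna_tumor=c.mirna,
            mirna_targets=c.mirna_targets,
            cnv_flags=flags,
            cnv_gene=c.cnv_gene,
        )
        degs = {r.gene_id for r in de if r.is_deg}
        family_genes = set().union(*(f.member_gene_ids for f in c.families))
        assert set(out) <= degs <= set(c.expression_tumor.feature_ids)
        assert set(out) <= family_genes
        for rows in out.values():
            for ev in rows:
                assert abs(ev.rho) > 0.2 and ev.p_adjusted < 0.05
        # planted evidence genes that are DEGs should be recovered
        planted_ev = set(c.truth.meth_genes) | set(c.truth.mirna_genes) | set(c.truth.cnv_genes)
        assert len(set(out) & planted_ev) >= 0.8 * len(planted_ev & degs)

    def test_null_cohort_yields_no_ddgs(self, null_cohort):
        c = null_cohort
        de = ddg.differential_expression(c.expression_tumor, c.expression_normal)
        dmps = ddg.call_dmps(c.methylation, c.methylation_normal)
        dmi = ddg.differential_expression(c.mirna, c.mirna_normal)
        flags = ddg.classify_cnv_groups(c.cnv_gene)
        out = ddg.assemble_ddgs(
            de,
            c.families,
            c.expression_tumor,
            dmps=dmps,
            probe_annotation=c.probe_annotation,
            beta_tumor=c.methylation,
            dmi=dmi,
            mirna_tumor=c.mirna,
            mirna_targets=c.mirna_targets,
            cnv_flags=flags,
            cnv_gene=c.cnv_gene,
        )
        assert len(out) <= 1
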