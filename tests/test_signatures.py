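"""Enrichment scoring, differential markers, stages and regulons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icfuse.config import GSVAParams, MarkerThresholds, RegulonParams
from icfuse.signatures import (
    EnrichmentMatrix,
    assign_stage,
    cluster_markers,
    differential_expression,
    differential_methylation,
    dual_omics_markers,
    gsva_scores,
    infer_regulons,
    kruskal_wallis_screen,
    preranked_gsea,
    _preranked_es,
)
from icfuse.simulate import SimulationConfig, simulate_cohort
from icfuse.types import GeneSetCollection, Layer, ValidationError
from conftest import make_matrix
from oracles import gsva_oracle, preranked_es_oracle


class TestGSVA:
    def test_matches_explicit_walk_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        genes = [f"g{i}" for i in range(6)]
        sets = {"S1": ["g0", "g1", "g2"], "S2": ["g3", "g5"]}
        m = make_matrix(X, features=genes)
        E = gsva_scores(m, GeneSetCollection(sets))
        expected = gsva_oracle(X, genes, sets)
        for name in sets:
            np.testing.assert_allclose(
                E.values.loc[name].to_numpy(), expected[name], atol=1e-8
            )

    def test_top_genes_score_positive_complement_negative(self, rng):
        X = rng.normal(size=(20, 5))
        X[:5, 0] += 5.0  # first five genes high in sample 0
        genes = [f"g{i}" for i in range(20)]
        m = make_matrix(X, features=genes)
        sets = GeneSetCollection({"top": genes[:5], "rest": genes[5:]})
        E = gsva_scores(m, sets)
        assert E.values.loc["top", "s0"] > 0
        assert E.values.loc["rest", "s0"] < 0

    def test_duplicate_set_identical_rows(self, rng):
        X = rng.normal(size=(10, 4))
        genes = [f"g{i}" for i in range(10)]
        m = make_matrix(X, features=genes)
        E = gsva_scores(m, GeneSetCollection({"a": genes[:3], "b": genes[:3]}))
        np.testing.assert_allclose(E.values.loc["a"], E.values.loc["b"])

    def test_invariance_under_permutations(self, rng):
        X = rng.normal(size=(12, 6))
        genes = [f"g{i}" for i in range(12)]
        m = make_matrix(X, features=genes)
        sets = GeneSetCollection({"s": genes[2:7]})
        E = gsva_scores(m, sets)
        gperm = rng.permutation(12)
        sperm = rng.permutation(6)
        mp = make_matrix(X[np.ix_(gperm, sperm)],
                         features=[genes[i] for i in gperm],
                         samples=[f"s{j}" for j in sperm])
        Ep = gsva_scores(mp, sets)
        np.testing.assert_allclose(
            E.values.loc["s", Ep.sample_ids].to_numpy(),
            Ep.values.loc["s"].to_numpy(), atol=1e-10,
        )

    def test_scores_bounded(self, default_bundle):
        E = gsva_scores(default_bundle.expression, default_bundle.stage_sets)
        arr = E.to_numpy()
        assert arr.min() >= -1 and arr.max() <= 1


class TestPrerankedGSEA:
    def test_top_set_extreme(self, rng):
        metric = pd.Series(rng.normal(size=100),
                           index=[f"g{i}" for i in range(100)])
        top = list(metric.sort_values(ascending=False).index[:10])
        res = preranked_gsea(metric, top, n_perm=200, seed=1)
        assert res["es"] > 0.9
        assert res["p"] <= 1 / 201 + 1e-12

    def test_equal_metric_reduces_to_unweighted_ks(self):
        # 5 genes, constant metric, set = genes ranked 1 and 3 (stable order)
        metric = pd.Series(np.ones(5), index=list("abcde"))
        res = preranked_gsea(metric, ["a", "c"], n_perm=10, seed=0)
        # hand walk: +1/2, -1/3, +1/2, -1/3, -1/3 -> peak at 2/3
        assert res["es"] == pytest.approx(2 / 3)

    def test_complement_has_opposite_sign(self, rng):
        metric = pd.Series(rng.normal(size=30),
                           index=[f"g{i}" for i in range(30)])
        genes = list(metric.index)
        top = list(metric.sort_values(ascending=False).index[:8])
        rest = [g for g in genes if g not in top]
        es_top = preranked_gsea(metric, top, n_perm=10, seed=0)["es"]
        es_rest = preranked_gsea(metric, rest, n_perm=10, seed=0)["es"]
        assert np.sign(es_top) == -np.sign(es_rest)

    def test_es_matches_loop_oracle(self, rng):
        metric = rng.normal(size=25)
        in_set = np.zeros(25, dtype=bool)
        in_set[rng.choice(25, size=7, replace=False)] = True
        assert _preranked_es(metric, in_set) == pytest.approx(
            preranked_es_oracle(metric, in_set), abs=1e-10
        )

    def test_trivial_sets_rejected(self, rng):
        metric = pd.Series(rng.normal(size=10),
                           index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            preranked_gsea(metric, [], n_perm=10)
        with pytest.raises(ValidationError):
            preranked_gsea(metric, list(metric.index), n_perm=10)


class TestDifferential:
    def test_identical_groups_null(self, rng):
        X = rng.normal(size=(10, 8))
        m = make_matrix(np.hstack([X[:, :4], X[:, :4]]),
                        samples=[f"s{j}" for j in range(8)])
        de = differential_expression(m, [f"s{j}" for j in range(4)],
                                     [f"s{j}" for j in range(4, 8)])
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(de["padj"], 1.0)

    def test_antisymmetric_in_group_order(self, rng):
        m = make_matrix(rng.normal(size=(15, 10)))
        a = [f"s{j}" for j in range(5)]
        b = [f"s{j}" for j in range(5, 10)]
        de_ab = differential_expression(m, a, b)
        de_ba = differential_expression(m, b, a)
        np.testing.assert_allclose(de_ab["log2fc"], -de_ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(de_ab["p"], de_ba["p"], atol=1e-12)

    def test_planted_shift_flagged(self, rng):
        X = rng.normal(0, 0.3, size=(50, 20))
        X[0, :10] += 2.5  # planted log2 shift on gene 0, group a
        m = make_matrix(X)
        de = differential_expression(m, [f"s{j}" for j in range(10)],
                                     [f"s{j}" for j in range(10, 20)])
        assert abs(de.loc["f0", "log2fc"]) >= 2
        assert de.loc["f0", "padj"] < 0.05

    def test_methylation_delta_beta_antisymmetric(self, rng):
        betas = rng.uniform(0.1, 0.9, size=(20, 10))
        m = make_matrix(betas, layer=Layer.METHYLATION_BETA)
        a = [f"s{j}" for j in range(5)]
        b = [f"s{j}" for j in range(5, 10)]
        dm_ab = differential_methylation(m, a, b)
        dm_ba = differential_methylation(m, b, a)
        np.testing.assert_allclose(dm_ab["delta_beta"], -dm_ba["delta_beta"],
                                   atol=1e-12)

    def test_methylation_planted_delta(self, rng):
        betas = np.clip(rng.normal(0.4, 0.03, size=(30, 16)), 0.01, 0.99)
        betas[0, :8] += 0.3  # planted delta-beta 0.3
        m = make_matrix(betas, layer=Layer.METHYLATION_BETA)
        dm = differential_methylation(m, [f"s{j}" for j in range(8)],
                                      [f"s{j}" for j in range(8, 16)])
        assert dm.loc["f0", "delta_beta"] >= 0.2
        assert dm.loc["f0", "padj"] < 0.05


class TestClusterMarkers:
    def test_planted_markers_in_top_lists(self, full_design_bundle):
        b = full_design_bundle
        markers = cluster_markers(b.expression, b.labels)
        for cluster, planted in b.marker_genes.items():
            up = set(markers[cluster]["up"])
            assert len(up & set(planted)) >= 80  # top-100 mostly planted

    def test_no_significant_genes_empty_lists(self, rng):
        m = make_matrix(rng.normal(size=(30, 12)))
        labels = pd.Series(["a"] * 6 + ["b"] * 6,
                           index=[f"s{j}" for j in range(12)])
        markers = cluster_markers(m, labels)
        assert markers["a"]["up"] == [] and markers["a"]["down"] == []

    def test_singleton_cluster_skipped(self, rng):
        m = make_matrix(rng.normal(size=(10, 7)))
        labels = pd.Series(["a"] * 6 + ["b"],
                           index=[f"s{j}" for j in range(7)])
        markers = cluster_markers(m, labels)
        assert "b" not in markers


class TestDualOmics:
    def _tables(self, lfc, dbeta):
        expr = {"c": pd.DataFrame({"log2fc": [lfc], "p": [1e-4],
                                   "padj": [1e-4]}, index=["G1"])}
        meth = {"c": pd.DataFrame({"delta_beta": [dbeta], "p": [1e-3],
                                   "padj": [1e-3]}, index=["p1"])}
        return expr, meth, pd.Series({"p1": "G1"})

    def test_opposite_direction_retained(self):
        expr, meth, pmap = self._tables(3.0, -0.3)
        assert dual_omics_markers(expr, meth, pmap)["c"] == ["G1"]

    def test_concordant_direction_excluded(self):
        expr, meth, pmap = self._tables(3.0, +0.3)
        assert dual_omics_markers(expr, meth, pmap)["c"] == []

    def test_simulated_recovery_no_false_positives(self):
        from icfuse.preprocess import beta_m_convert, remove_batch_effect

        for seed in range(3):
            b = simulate_cohort(SimulationConfig(seed=seed,
                                                 complementary_design=False))
            markers = cluster_markers(b.expression, b.labels)
            expr_tables = {c: markers[c]["table"] for c in markers}
            # platform term regressed out before differential testing, as
            # for any two-platform methylation cohort
            corrected = beta_m_convert(
                remove_batch_effect(
                    beta_m_convert(b.methylation, "beta_to_m"), b.batch
                ),
                "m_to_beta",
            )
            meth_tables = {}
            for c in pd.unique(b.labels):
                in_c = b.labels.index[b.labels == c]
                rest = b.labels.index[b.labels != c]
                meth_tables[str(c)] = differential_methylation(
                    corrected, in_c, rest
                )
            dual = dual_omics_markers(expr_tables, meth_tables,
                                      b.probe_gene_map)
            for cluster, found in dual.items():
                planted = set(b.dual_marker_genes[cluster])
                assert set(found) == planted


class TestAssignStage:
    def _enrichment(self, rows, samples=8):
        idx = list(rows)
        vals = np.array([rows[r] for r in idx], dtype=float)
        return EnrichmentMatrix(
            pd.DataFrame(vals, index=idx,
                         columns=[f"s{j}" for j in range(samples)])
        )

    def test_dominant_signature_assigned(self, rng):
        base = rng.normal(0, 0.01, size=(8,))
        E = self._enrichment({
            "HSC/MPP": base,
            "Pre-B": np.concatenate([base[:4] + 0.5, base[4:]]),
        })
        labels = pd.Series(["c1"] * 4 + ["c2"] * 4,
                           index=[f"s{j}" for j in range(8)])
        assert assign_stage(E, labels)["c1"] == "Pre-B"

    def test_hsc_exclusivity_rule(self, rng):
        base = rng.normal(0, 0.01, size=(8,))
        up = np.concatenate([base[:4] + 0.3, base[4:]])
        more_up = np.concatenate([base[:4] + 0.8, base[4:]])
        E = self._enrichment({"HSC/MPP": up, "Pre-B": more_up})
        labels = pd.Series(["c1"] * 4 + ["c2"] * 4,
                           index=[f"s{j}" for j in range(8)])
        # both significant, Pre-B more so -> exclusivity blocks HSC/MPP
        assert assign_stage(E, labels)["c1"] == "Pre-B"

    def test_no_significant_unassigned(self, rng):
        E = self._enrichment({"HSC/MPP": 0.1 * rng.normal(size=8),
                              "Pre-B": 0.1 * rng.normal(size=8)})
        labels = pd.Series(["c1"] * 4 + ["c2"] * 4,
                           index=[f"s{j}" for j in range(8)])
        out = assign_stage(E, labels)
        assert set(out.values()) <= {"unassigned", "HSC/MPP", "Pre-B"}

    def test_simulated_stage_recovery(self, full_design_bundle):
        b = full_design_bundle
        E = gsva_scores(b.expression, b.stage_sets)
        stages = assign_stage(E, b.labels)
        assert stages == b.stage_of_cluster


class TestRegulons:
    def test_monotone_copy_included_noise_excluded(self, rng):
        n = 50
        tf = rng.normal(size=n)
        X = np.vstack([tf, np.exp(tf), rng.normal(size=(20, n))])
        genes = ["TF", "copy"] + [f"g{i}" for i in range(20)]
        m = make_matrix(X, features=genes)
        regs = infer_regulons(m, ["TF"], RegulonParams(min_targets=1))
        assert "copy" in regs["TF"]
        assert len(set(regs["TF"]) & {f"g{i}" for i in range(20)}) == 0

    def test_planted_regulon_recovered(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            tf = rng.normal(size=n)
            targets = tf[None, :] + rng.normal(0, 0.7, size=(30, n))
            noise = rng.normal(size=(40, n))
            X = np.vstack([tf, targets, noise])
            genes = ["TF"] + [f"t{i}" for i in range(30)] + [
                f"n{i}" for i in range(40)
            ]
            m = make_matrix(X, features=genes)
            regs = infer_regulons(m, ["TF"])
            hits.append(len(set(regs["TF"]) & {f"t{i}" for i in range(30)}))
        assert min(hits) >= 28

    def test_small_regulon_dropped(self, rng):
        m = make_matrix(rng.normal(size=(15, 30)))
        regs = infer_regulons(m, ["f0"], RegulonParams(min_targets=10))
        assert "f0" not in regs.names


class TestKruskalWallis:
    def test_hand_instance(self):
        groups = {"a": [1, 2, 3, 4, 5], "b": [2, 3, 4, 5, 6],
                  "c": [7, 8, 9, 10, 11]}
        vals = np.concatenate([groups[g] for g in "abc"], dtype=float)
        E = make_matrix(vals[None, :], features=["sig"])
        labels = pd.Series(np.repeat(list("abc"), 5),
                           index=[f"s{j}" for j in range(15)])
        out = kruskal_wallis_screen(E, labels)
        h_ref, p_ref = stats.kruskal(groups["a"], groups["b"], groups["c"])
        assert out.loc["sig", "H"] == pytest.approx(h_ref)
        assert out.loc["sig", "p"] == pytest.approx(p_ref)

    def test_extreme_shift_significant(self, rng):
        vals = np.concatenate([rng.normal(size=20), rng.normal(size=20) + 50])
        E = make_matrix(vals[None, :], features=["sig"])
        labels = pd.Series(["a"] * 20 + ["b"] * 20,
                           index=[f"s{j}" for j in range(40)])
        assert kruskal_wallis_screen(E, labels).loc["sig", "p"] < 1e-6

    def test_all_tied_p_one(self):
        E = make_matrix(np.ones((1, 10)), features=["sig"])
        labels = pd.Series(["a"] * 5 + ["b"] * 5,
                           index=[f"s{j}" for j in range(10)])
        assert kruskal_wallis_screen(E, labels).loc["sig", "p"] == 1.0
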