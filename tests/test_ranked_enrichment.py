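"""Signed -log10(p) ranking and the weighted KS enrichment statistic."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_de_table
from vasctx.geneset_io import GeneSet, GeneSetCatalog
from vasctx.ranked_enrichment import (
    enrichment_score,
    filter_significant,
    gsea_preranked,
    rank_metric,
    read_rnk,
    write_rnk,
)


def brute_force_es(metric, hit_mask, weight=1.0):
    """Exhaustive prefix evaluation of the running sum (the oracle)."""
    n = len(metric)
    nh = int(hit_mask.sum())
    w = np.abs(metric[hit_mask]) ** weight
    total = w.sum()
    if total == 0:
        w = np.full(nh, 1.0 / nh)
        total = 1.0
    best = 0.0
    cur = 0.0
    j = 0
    for i in range(n):
        if hit_mask[i]:
            cur += w[j] / total
            j += 1
        else:
            cur -= 1.0 / (n - nh)
        if abs(cur) > abs(best):
            best = cur
    return best


def ranking_from(metrics, genes=None):
    genes = genes or [f"g{i}" for i in range(len(metrics))]
    return pd.DataFrame({"gene_id": genes, "metric": metrics})


class TestRankMetric:
    @pytest.mark.parametrize(
        "p,lfc,expected", [(0.01, 3.0, 2.0), (0.01, -3.0, -2.0), (1.0, 5.0, 0.0)]
    )
    def test_signed_neg_log10(self, p, lfc, expected):
        de = make_de_table(["a"], [lfc], [p])
        out = rank_metric(de)
        assert out["metric"].iloc[0] == pytest.approx(expected)

    def test_zero_lfc_gives_zero_metric(self):
        de = make_de_table(["a"], [0.0], [0.001])
        assert rank_metric(de)["metric"].iloc[0] == 0.0

    def test_sorted_descending_ties_lexicographic(self):
        de = make_de_table(["b", "a", "c"], [1.0, 1.0, -1.0], [0.1, 0.1, 0.01])
        out = rank_metric(de)
        assert out["gene_id"].tolist() == ["a", "b", "c"]
        assert (np.diff(out["metric"]) <= 0).all()

    def test_p_floor_bounds_metric(self):
        de = make_de_table(["a"], [1.0], [1e-320])
        out = rank_metric(de, p_floor=1e-300)
        assert out["metric"].iloc[0] == pytest.approx(300.0)

    def test_missing_values_excluded(self, caplog):
        de = make_de_table(["a", "b"], [1.0, np.nan], [0.01, 0.5])
        with caplog.at_level("INFO", logger="vasctx.ranked_enrichment"):
            out = rank_metric(de)
        assert out["gene_id"].tolist() == ["a"]

    def test_rnk_roundtrip(self, tmp_path):
        de = make_de_table(["a", "b", "c"], [2.0, -1.0, 0.5], [0.01, 0.2, 0.3])
        ranking = rank_metric(de)
        write_rnk(ranking, tmp_path / "x.rnk")
        again = read_rnk(tmp_path / "x.rnk")
        assert again["gene_id"].tolist() == ranking["gene_id"].tolist()
        np.testing.assert_allclose(again["metric"], ranking["metric"])


class TestEnrichmentScore:
    def test_single_top_hit_scores_one(self):
        ranking = ranking_from([3.0, 2.0, 1.0, -1.0, -2.0])
        es, _ = enrichment_score(ranking, GeneSet("S", "", ("g0",)))
        assert es == pytest.approx(1.0)

    def test_single_bottom_hit_scores_negative(self):
        ranking = ranking_from([3.0, 2.0, 1.0, -1.0, -2.0])
        es, _ = enrichment_score(ranking, GeneSet("S", "", ("g4",)))
        assert es < 0

    def test_no_hits_rejected(self):
        ranking = ranking_from([1.0, -1.0])
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(ranking, GeneSet("S", "", ("zz",)))

    def test_full_coverage_rejected(self):
        ranking = ranking_from([1.0, -1.0])
        with pytest.raises(ValueError, match="whole ranking"):
            enrichment_score(ranking, GeneSet("S", "", ("g0", "g1")))

    def test_matches_brute_force_oracle(self, rng):
        """500 random small instances agree exactly with prefix evaluation."""
        for _ in range(500):
            n = int(rng.integers(4, 13))
            metric = np.sort(np.round(rng.normal(0, 2, n), 3))[::-1]
            k = int(rng.integers(1, n))
            hit = np.zeros(n, bool)
            hit[rng.choice(n, k, replace=False)] = True
            genes = np.array([f"g{i}" for i in range(n)])
            ranking = ranking_from(metric.tolist(), genes.tolist())
            gs = GeneSet("S", "", tuple(genes[hit]))
            es, running = enrichment_score(ranking, gs, 1.0)
            assert es == brute_force_es(metric, hit, 1.0)
            assert len(running) == n
            assert abs(es) <= 1.0 + 1e-12

    def test_weight_zero_matches_unweighted_ks(self, rng):
        """weight=0 reduces to the classic equal-increment KS statistic."""
        for _ in range(100):
            n = int(rng.integers(5, 13))
            metric = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(1, n))
            hit = np.zeros(n, bool)
            hit[rng.choice(n, k, replace=False)] = True
            genes = np.array([f"g{i}" for i in range(n)])
            ranking = ranking_from(metric.tolist(), genes.tolist())
            es, _ = enrichment_score(ranking, GeneSet("S", "", tuple(genes[hit])), 0.0)
            # unweighted oracle: hits add 1/k regardless of metric
            cur, best = 0.0, 0.0
            for i in range(n):
                cur += 1.0 / k if hit[i] else -1.0 / (n - k)
                if abs(cur) > abs(best):
                    best = cur
            assert es == pytest.approx(best, abs=1e-12)

    def test_negating_and_reversing_negates_es(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 13))
            metric = np.sort(rng.normal(0, 2, n))[::-1]
            genes = np.array([f"g{i}" for i in range(n)])
            k = int(rng.integers(1, n))
            members = tuple(genes[rng.choice(n, k, replace=False)])
            fwd = ranking_from(metric.tolist(), genes.tolist())
            rev = ranking_from((-metric[::-1]).tolist(), genes[::-1].tolist())
            es_f, run_f = enrichment_score(fwd, GeneSet("S", "", members))
            es_r, run_r = enrichment_score(rev, GeneSet("S", "", members))
            assert abs(es_r) == pytest.approx(abs(es_f), abs=1e-12)
            # when the extreme is unique its sign must flip; on an exact
            # +/- tie the walk-order tie-break may keep either sign
            tied = abs(run_f.max() + run_f.min()) < 1e-12
            if not tied:
                assert es_r == pytest.approx(-es_f, abs=1e-12)

    def test_es_one_iff_all_hits_first(self):
        ranking = ranking_from([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        es, _ = enrichment_score(ranking, GeneSet("S", "", ("g0", "g1")))
        assert es == pytest.approx(1.0)
        es2, _ = enrichment_score(ranking, GeneSet("S", "", ("g0", "g2")))
        assert es2 < 1.0


class TestGseaPreranked:
    @staticmethod
    def _ranking(n=300, seed=0):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(0, 2, n))[::-1]
        genes = [f"g{i:04d}" for i in range(n)]
        return pd.DataFrame({"gene_id": genes, "metric": metric})

    def test_deterministic_given_seed(self):
        ranking = self._ranking()
        genes = ranking["gene_id"].to_numpy()
        cat = GeneSetCatalog(
            (
                GeneSet("A", "", tuple(genes[5:25])),
                GeneSet("B", "", tuple(genes[100:130])),
            )
        )
        a = gsea_preranked(ranking, cat, n_perm=200, seed=77)
        b = gsea_preranked(ranking, cat, n_perm=200, seed=77)
        pd.testing.assert_frame_equal(a, b)

    def test_top_k_set_is_significant(self):
        ranking = self._ranking(n=500)
        genes = ranking["gene_id"].to_numpy()
        cat = GeneSetCatalog((GeneSet("TOP", "", tuple(genes[:15])),))
        res = gsea_preranked(ranking, cat, n_perm=1000, seed=3)
        assert res["nes"].iloc[0] > 0
        assert res["nominal_p"].iloc[0] <= 0.05

    def test_sets_outside_ranking_skipped(self, caplog):
        ranking = self._ranking(n=50)
        genes = ranking["gene_id"].to_numpy()
        cat = GeneSetCatalog(
            (
                GeneSet("OK", "", tuple(genes[:5])),
                GeneSet("ALIEN", "", ("zz1", "zz2")),
            )
        )
        with caplog.at_level("INFO", logger="vasctx.ranked_enrichment"):
            res = gsea_preranked(ranking, cat, n_perm=100, seed=1)
        assert res["set_name"].tolist() == ["OK"]
        assert "ALIEN" in caplog.text

    def test_n_perm_floor(self):
        ranking = self._ranking(n=50)
        cat = GeneSetCatalog((GeneSet("S", "", ("g0000", "g0001")),))
        with pytest.raises(ValueError):
            gsea_preranked(ranking, cat, n_perm=10, seed=1)

    def test_bh_fdr_flag(self):
        ranking = self._ranking(n=200)
        genes = ranking["gene_id"].to_numpy()
        cat = GeneSetCatalog(
            tuple(
                GeneSet(f"S{i}", "", tuple(genes[i * 20 : i * 20 + 12]))
                for i in range(5)
            )
        )
        res = gsea_preranked(ranking, cat, n_perm=200, seed=5, fdr_method="bh")
        assert (res["fdr_q"] >= res["nominal_p"] - 1e-12).all()


class TestFilterSignificant:
    def _res(self, qs):
        return pd.DataFrame(
            {
                "set_name": [f"S{i}" for i in range(len(qs))],
                "n_genes_used": 10,
                "es": 0.5,
                "nes": 1.0,
                "nominal_p": 0.1,
                "fdr_q": qs,
            }
        )

    def test_any_timepoint_rule_keeps_all_rows(self):
        per_tp = {"t1": self._res([0.04, 0.5]), "t2": self._res([0.9, 0.6])}
        out = filter_significant(per_tp, q_max=0.05)
        assert set(out["set_name"]) == {"S0"}
        assert set(out["timepoint"]) == {"t1", "t2"}
        assert len(out) == 2

    def test_nowhere_significant_dropped(self):
        per_tp = {"t1": self._res([0.06]), "t2": self._res([0.07])}
        assert len(filter_significant(per_tp, q_max=0.05)) == 0

    def test_empty_input(self):
        assert len(filter_significant({}, q_max=0.05)) == 0

    def test_single_table_simple_subset(self):
        out = filter_significant(self._res([0.01, 0.2]), q_max=0.05)
        assert out["set_name"].tolist() == ["S0"]
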