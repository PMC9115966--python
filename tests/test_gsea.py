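import numpy as np
import pandas as pd
import pytest

from petflux.gsea import (
    GeneSetCollection,
    RankedGeneList,
    bonferroni_threshold,
    enrichment_score,
    gsea_run,
    leading_edge_overlap,
    permutation_null,
    rank_genes,
    read_gmt,
    write_gmt,
)
from petflux.simulate import make_planted_spec, simulate_expression


def make_ranked(stats, genes=None):
    stats = np.asarray(stats, dtype=float)
    order = np.argsort(-stats)
    if genes is None:
        genes = np.array([f"g{i}" for i in range(stats.size)])
    return RankedGeneList(genes=np.asarray(genes)[order], stats=stats[order],
                          method="pearson", tie_seed=0)


def brute_force_es(stats, hit, weight_exponent=1.0):
    """Literal step-by-step walk with the earlier-position tie rule."""
    n, nh = len(stats), int(hit.sum())
    w = np.abs(stats) ** weight_exponent
    denom = w[hit].sum()
    cur, walk = 0.0, []
    for i in range(n):
        cur += w[i] / denom if hit[i] else -1.0 / (n - nh)
        walk.append(cur)
    walk = np.array(walk)
    imax, imin = int(np.argmax(walk)), int(np.argmin(walk))
    if abs(walk[imax]) == abs(walk[imin]):
        return walk[min(imax, imin)]
    return walk[imax] if walk[imax] > -walk[imin] else walk[imin]


class TestGmtRoundTrip:
    def test_write_read_identity(self, tmp_path):
        coll = GeneSetCollection(
            sets={"A": ["g1", "g2", "g3"], "B": ["g9"]},
            descriptions={"A": "first", "B": ""},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions["A"] == "first"

    def test_single_member_set_preserved(self, tmp_path):
        coll = GeneSetCollection(sets={"solo": ["g1"]})
        path = tmp_path / "one.gmt"
        write_gmt(coll, path)
        assert read_gmt(path).sets["solo"] == ["g1"]

    def test_malformed_line_names_the_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ok\tdesc\tg1\ng2_only_two\tfields\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("A\td\tg1\nA\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection(sets={"E": []})


class TestRankGenes:
    @pytest.fixture()
    def expression(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 1.0, size=(20, 10))
        return pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                            columns=[f"P{j}" for j in range(10)])

    def test_perfectly_correlated_gene_ranks_first(self, expression):
        measure = np.linspace(0.0, 1.0, 10)
        expression.loc["g5"] = measure
        ranked = rank_genes(expression, measure)
        assert ranked.genes[0] == "g5"
        assert ranked.stats[0] == pytest.approx(1.0)

    def test_anticorrelated_gene_ranks_last(self, expression):
        measure = np.linspace(0.0, 1.0, 10)
        expression.loc["g7"] = -measure
        ranked = rank_genes(expression, measure)
        assert ranked.genes[-1] == "g7"
        assert ranked.stats[-1] == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self, expression):
        measure = np.linspace(0.1, 1.0, 10)
        r1 = rank_genes(expression, measure, method="spearman", seed=3)
        r2 = rank_genes(expression, np.exp(measure), method="spearman", seed=3)
        assert list(r1.genes) == list(r2.genes)
        p1 = rank_genes(expression, measure, method="pearson", seed=3)
        p2 = rank_genes(expression, np.exp(5 * measure), method="pearson",
                        seed=3)
        assert list(p1.genes) != list(p2.genes)

    def test_zero_variance_gene_dropped(self, expression):
        expression.loc["g3"] = 2.0
        ranked = rank_genes(expression, np.linspace(0, 1, 10))
        assert "g3" in ranked.dropped
        assert "g3" not in ranked.genes

    def test_tie_break_is_random_but_seeded(self):
        X = np.tile(np.linspace(0, 1, 10), (6, 1))  # all genes identical
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(6)])
        orders = {tuple(rank_genes(expr, np.linspace(0, 1, 10),
                                   seed=s).genes) for s in range(20)}
        assert len(orders) > 1  # ties permuted differently across seeds
        again = rank_genes(expr, np.linspace(0, 1, 10), seed=5)
        assert tuple(again.genes) == tuple(
            rank_genes(expr, np.linspace(0, 1, 10), seed=5).genes
        )


class TestEnrichmentScore:
    def test_single_top_hit_scores_one(self):
        ranked = make_ranked(np.linspace(2.0, -2.0, 10))
        es, leading, _ = enrichment_score(ranked, [ranked.genes[0]])
        assert es == pytest.approx(1.0)
        assert leading == [ranked.genes[0]]

    def test_single_bottom_hit_scores_minus_one(self):
        ranked = make_ranked(np.linspace(2.0, -2.0, 10))
        es, leading, _ = enrichment_score(ranked, [ranked.genes[-1]])
        assert es == pytest.approx(-1.0)
        assert leading == [ranked.genes[-1]]

    def test_matches_brute_force_walk(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(8, 51))
            ranked = make_ranked(rng.normal(size=n))
            k = int(rng.integers(1, min(8, n - 1) + 1))
            members = rng.choice(ranked.genes, size=k, replace=False)
            es, _, _ = enrichment_score(ranked, members)
            hit = np.isin(ranked.genes, members)
            assert es == pytest.approx(
                brute_force_es(ranked.stats, hit), abs=1e-12
            )

    def test_antisymmetric_under_ranking_reversal(self):
        rng = np.random.default_rng(2)
        stats = rng.normal(size=30)
        ranked = make_ranked(stats)
        flipped = RankedGeneList(genes=ranked.genes[::-1].copy(),
                                 stats=-ranked.stats[::-1].copy(),
                                 method="pearson", tie_seed=0)
        members = rng.choice(ranked.genes, size=6, replace=False)
        es_fwd, _, _ = enrichment_score(ranked, members)
        es_rev, _, _ = enrichment_score(flipped, members)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_weight_zero_reduces_to_classic_ks(self):
        rng = np.random.default_rng(3)
        ranked = make_ranked(rng.normal(size=40))
        members = rng.choice(ranked.genes, size=8, replace=False)
        es, _, _ = enrichment_score(ranked, members, weight_exponent=0.0)
        # direct Kolmogorov-Smirnov statistic between hit positions and
        # the uniform miss distribution
        hit = np.isin(ranked.genes, members)
        ecdf_hit = np.cumsum(hit) / hit.sum()
        ecdf_miss = np.cumsum(~hit) / (~hit).sum()
        d = ecdf_hit - ecdf_miss
        expected = d[np.argmax(np.abs(d))]
        assert es == pytest.approx(expected, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            ranked = make_ranked(rng.normal(size=25))
            members = rng.choice(ranked.genes, size=5, replace=False)
            es, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_full_coverage_set_rejected(self):
        ranked = make_ranked(np.linspace(1, -1, 5))
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, list(ranked.genes))

    def test_matches_external_reference_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        genes = [f"g{i}" for i in range(50)]
        stats = np.linspace(2.0, -2.0, 50)
        members = [f"g{i}" for i in range(0, 20, 3)]
        ranked = make_ranked(stats, genes)
        es, _, _ = enrichment_score(ranked, members)
        rnk = pd.DataFrame({"gene": genes, "score": stats})
        res = gseapy.prerank(rnk=rnk, gene_sets={"S": members},
                             permutation_num=10, min_size=2, max_size=50,
                             outdir=None, seed=1, threads=1, weight=1.0)
        assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), rel=1e-6)


class TestPermutationNull:
    def test_seeded_determinism(self):
        ranked = make_ranked(np.random.default_rng(0).normal(size=200))
        a = permutation_null(ranked, 15, 500, seed=9)
        b = permutation_null(ranked, 15, 500, seed=9)
        assert np.array_equal(a, b)

    def test_null_mean_near_zero_for_symmetric_statistics(self):
        rng = np.random.default_rng(1)
        ranked = make_ranked(rng.normal(size=500))
        null = permutation_null(ranked, 25, 10_000, seed=2)
        assert abs(null.mean()) < 0.05
        assert np.all(np.abs(null) <= 1.0)

    def test_matches_per_set_scoring_distribution(self):
        rng = np.random.default_rng(5)
        ranked = make_ranked(rng.normal(size=150))
        null = permutation_null(ranked, 10, 3000, seed=11)
        direct = []
        for _ in range(800):
            members = rng.choice(ranked.genes, size=10, replace=False)
            direct.append(enrichment_score(ranked, members)[0])
        from scipy.stats import ks_2samp

        assert ks_2samp(null, np.array(direct)).pvalue > 0.01

    def test_oversized_set_rejected(self):
        ranked = make_ranked(np.linspace(1, -1, 10))
        with pytest.raises(ValueError):
            permutation_null(ranked, 10, 100, seed=0)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(1) == pytest.approx(0.035)
        assert bonferroni_threshold(186) == pytest.approx(1.8817e-4, rel=1e-3)
        assert bonferroni_threshold(70) == pytest.approx(5e-4)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


@pytest.fixture(scope="module")
def planted_run():
    rng = np.random.default_rng(12)
    measure = rng.normal(size=30)
    spec = make_planted_spec(n_genes=600, n_patients=30,
                             planted=[("PW_PLANTED", 40, 0.9, "m")],
                             seed=8)
    expr, _ = simulate_expression(spec, {"m": measure})
    from petflux.simulate import make_collection

    coll = make_collection(spec, n_null_sets=19, null_size=40, seed=6)
    return gsea_run(expr, measure, coll, n_perm=2000, seed=4)


class TestGseaRun:

    def test_planted_pathway_significant_with_positive_nes(self, planted_run):
        planted = next(r for r in planted_run if r.set_name == "PW_PLANTED")
        assert planted.significant
        assert planted.nes > 0
        assert planted.es > 0

    def test_p_floor_respected(self, planted_run):
        for r in planted_run:
            assert r.p >= 1.0 / (2000 + 1)
            assert np.sign(r.nes) == np.sign(r.es)

    def test_duplicate_set_scores_identically(self):
        rng = np.random.default_rng(3)
        measure = rng.normal(size=20)
        spec = make_planted_spec(n_genes=300, n_patients=20, planted=[],
                                 seed=1)
        expr, _ = simulate_expression(spec, {"m": measure})
        ids = list(expr.index[:30])
        coll = GeneSetCollection(sets={"X": ids, "X_copy": list(ids),
                                       "other": list(expr.index[40:70])})
        results = {r.set_name: r for r in
                   gsea_run(expr, measure, coll, n_perm=500, seed=2)}
        assert results["X"].es == results["X_copy"].es
        assert results["X"].leading_edge == results["X_copy"].leading_edge


class TestLeadingEdgeOverlap:
    def _result(self, name, leading, significant=True):
        from petflux.gsea import EnrichmentResult

        return EnrichmentResult(set_name=name, set_size=len(leading),
                                es=0.5, nes=1.5, p=0.001,
                                significant=significant,
                                leading_edge=list(leading))

    def test_disjoint_edges_have_no_shared_genes(self):
        mat, counts = leading_edge_overlap(
            [self._result("A", ["g1", "g2"]), self._result("B", ["g3"])]
        )
        assert counts.max() == 1

    def test_planted_shared_gene_counted_in_k_pathways(self):
        results = [self._result(f"S{i}", ["shared", f"g{i}"])
                   for i in range(4)]
        mat, counts = leading_edge_overlap(results)
        assert counts["shared"] == 4

    def test_membership_totals_conserved(self):
        results = [self._result("A", ["g1", "g2", "g3"]),
                   self._result("B", ["g2", "g4"])]
        mat, _ = leading_edge_overlap(results)
        total = sum(len(r.leading_edge) for r in results)
        assert mat.to_numpy().sum() == total
        assert mat.sum(axis=0).sum() == mat.sum(axis=1).sum() == total

    def test_insignificant_results_excluded_by_default(self):
        results = [self._result("A", ["g1"]),
                   self._result("B", ["g2"], significant=False)]
        mat, _ = leading_edge_overlap(results)
        assert list(mat.columns) == ["A"]
        mat_all, _ = leading_edge_overlap(results, significant_only=False)
        assert set(mat_all.columns) == {"A", "B"}
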