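import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from autogeny.enrichment import (
    RankedGeneList,
    build_ranking,
    enrich_pathways,
    enrichment_score,
    permutation_null,
)
from autogeny.partition import ScoredPair
from autogeny.sequence_io import PairClass, PathwayAnnotation


def auto_pair(gene, pi, iso=1):
    return ScoredPair(
        protein_id=f"P_{gene}",
        rna_id=f"T_{gene}_{iso}",
        protein_gene=gene,
        rna_gene=gene,
        pair_class=PairClass.AUTOGENOUS,
        pi=pi,
    )


def ranking_of(metrics: dict) -> RankedGeneList:
    ordered = sorted(metrics.items(), key=lambda kv: (-kv[1], kv[0]))
    genes, values = zip(*ordered)
    return RankedGeneList(genes=genes, metric=np.array(values, dtype=float))


def oracle_es(genes, metric, gene_set, p_exp=1.0):
    """Independent pure-Python running-sum oracle."""
    n = len(genes)
    hits = [g in gene_set for g in genes]
    n_hit = sum(hits)
    hit_total = sum(abs(m) ** p_exp for g, m, h in zip(genes, metric, hits) if h)
    running, cur, best = [0.0], 0.0, 0.0
    for g, m, h in zip(genes, metric, hits):
        if h:
            cur += (abs(m) ** p_exp) / hit_total if hit_total > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, running


class TestBuildRanking:
    def test_isoform_aggregation_takes_max(self):
        pairs = [
            auto_pair("SNCA", 81.0, iso=1),
            auto_pair("SNCA", 71.0, iso=2),
            auto_pair("SNCA", 61.0, iso=3),
            auto_pair("OTHER", 20.0),
        ]
        ranking = build_ranking(pairs)
        assert ranking.genes[0] == "SNCA"
        assert ranking.metric[0] == 81.0

    def test_mean_aggregation_available(self):
        pairs = [
            auto_pair("G1", 81.0, iso=1),
            auto_pair("G1", 61.0, iso=2),
            auto_pair("G2", 20.0),
        ]
        assert build_ranking(pairs, agg="mean").metric[0] == pytest.approx(71.0)

    def test_equal_metric_orders_by_gene_id(self):
        pairs = [auto_pair("B", 10.0), auto_pair("A", 10.0), auto_pair("C", 5.0)]
        assert build_ranking(pairs).genes == ("A", "B", "C")

    def test_single_pair_metric_identity(self):
        pairs = [auto_pair("G1", 33.0), auto_pair("G2", 11.0)]
        assert dict(zip(*[build_ranking(pairs).genes,
                          build_ranking(pairs).metric]))["G1"] == 33.0

    def test_non_autogenous_pairs_ignored(self):
        hetero = ScoredPair(
            protein_id="P_G1", rna_id="T_G2", protein_gene="G1", rna_gene="G2",
            pair_class=PairClass.INTER_PATHWAY, pi=99.0,
        )
        with pytest.raises(ValueError):
            build_ranking([hetero, auto_pair("G3", 5.0)])


class TestEnrichmentScore:
    def test_front_loaded_set_scores_one(self):
        ranking = ranking_of({"A": 5.0, "B": 4.0, "C": 3.0, "D": 2.0, "E": 1.0})
        es, running = enrichment_score(ranking, {"A", "B"})
        assert es == pytest.approx(1.0)

    def test_bottom_set_scores_negative(self):
        ranking = ranking_of({"A": 5.0, "B": 4.0, "C": 3.0, "D": 2.0, "E": 1.0})
        es, _ = enrichment_score(ranking, {"D", "E"})
        assert es < 0

    def test_five_gene_toy_hand_stepped(self):
        """Metrics 5..1, set {A, C}: running sum 5/8, 7/24, 2/3, 1/3, 0."""
        ranking = ranking_of({"A": 5.0, "B": 4.0, "C": 3.0, "D": 2.0, "E": 1.0})
        es, running = enrichment_score(ranking, {"A", "C"})
        assert np.allclose(
            running, [0.0, 5 / 8, 5 / 8 - 1 / 3, 2 / 3, 1 / 3, 0.0]
        )
        assert es == pytest.approx(2 / 3)

    def test_empty_intersection_rejected(self):
        ranking = ranking_of({"A": 2.0, "B": 1.0})
        with pytest.raises(ValueError):
            enrichment_score(ranking, {"Z"})

    def test_full_coverage_rejected(self):
        ranking = ranking_of({"A": 2.0, "B": 1.0})
        with pytest.raises(ValueError):
            enrichment_score(ranking, {"A", "B"})

    @given(st.integers(0, 500))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        genes = [f"G{i:02d}" for i in range(n)]
        metric = {g: float(rng.normal(20, 15)) for g in genes}
        ranking = ranking_of(metric)
        size = int(rng.integers(1, n))
        gene_set = set(rng.choice(genes, size=size, replace=False))
        es, running = enrichment_score(ranking, gene_set)
        es_o, running_o = oracle_es(ranking.genes, ranking.metric, gene_set)
        assert es == pytest.approx(es_o, abs=1e-12)
        assert np.allclose(running, running_o)
        assert abs(es) <= 1.0 + 1e-12
        assert running[0] == 0.0 and running[-1] == pytest.approx(0.0, abs=1e-9)


class TestPermutationNull:
    def _ranking(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return ranking_of({f"G{i:03d}": float(rng.normal(20, 10)) for i in range(n)})

    def test_default_count_is_one_thousand(self):
        null = permutation_null(self._ranking(), 10, seed=0)
        assert len(null) == 1000

    def test_reproducible_from_seed(self):
        a = permutation_null(self._ranking(), 10, seed=5)
        b = permutation_null(self._ranking(), 10, seed=5)
        assert np.array_equal(a, b)

    def test_null_straddles_zero(self):
        null = permutation_null(self._ranking(), 10, seed=1)
        assert (null > 0).any() and (null < 0).any()

    def test_matches_scalar_path(self):
        """Vectorized permutation ES equals the scalar implementation."""
        ranking = self._ranking(n=30, seed=2)
        null = permutation_null(ranking, 6, n_perm=100, seed=3)
        rng = np.random.default_rng(np.random.SeedSequence(3, spawn_key=(6,)))
        keys = rng.random((100, 30))
        hit_idx = np.argpartition(keys, 6, axis=1)[:, :6]
        for row in range(0, 100, 17):
            gene_set = {ranking.genes[i] for i in hit_idx[row]}
            es, _ = enrichment_score(ranking, gene_set)
            assert null[row] == pytest.approx(es, abs=1e-12)

    def test_bad_sizes_rejected(self):
        ranking = self._ranking(n=20)
        with pytest.raises(ValueError):
            permutation_null(ranking, 0)
        with pytest.raises(ValueError):
            permutation_null(ranking, 20)
        with pytest.raises(ValueError):
            permutation_null(ranking, 5, n_perm=50)


class TestEnrichPathways:
    def _setup(self, n_genes=120, seed=0, planted=True):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:03d}" for i in range(n_genes)]
        memberships = {}
        pathways = {f"PW{p:02d}": list(rng.choice(genes, 10, replace=False))
                    for p in range(8)}
        metric = {g: float(rng.normal(20, 8)) for g in genes}
        if planted:
            pathways["PWX"] = genes[:10]
            for g in genes[:9]:
                metric[g] = float(rng.normal(120, 10))
        for pw, members in pathways.items():
            for g in members:
                memberships.setdefault(g, set()).add(pw)
        annotation = PathwayAnnotation(
            {g: frozenset(p) for g, p in memberships.items()}
        )
        return ranking_of(metric), annotation

    def test_planted_pathway_detected(self):
        ranking, annotation = self._setup(planted=True)
        results = enrich_pathways(ranking, annotation, n_perm=500, seed=1)
        best = results[0]
        assert best.pathway_id == "PWX"
        assert best.q_value < 0.05
        assert best.direction == "enriched"

    def test_size_gate_excludes_small_and_large(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i:03d}" for i in range(600)]
        metric = {g: float(rng.normal(size=1)[0]) for g in genes}
        memberships = {}
        for pw, members in {
            "too_small": genes[:4],
            "at_min": genes[4:9],
            "at_max": genes[9:509],
            "too_large": genes[10:511],
        }.items():
            for g in members:
                memberships.setdefault(g, set()).add(pw)
        annotation = PathwayAnnotation(
            {g: frozenset(p) for g, p in memberships.items()}
        )
        results = enrich_pathways(
            ranking_of(metric), annotation, n_perm=100, seed=0
        )
        tested = {r.pathway_id for r in results}
        assert tested == {"at_min", "at_max"}

    def test_rows_sorted_by_q_and_p_in_unit_interval(self):
        ranking, annotation = self._setup(planted=False, seed=3)
        results = enrich_pathways(ranking, annotation, n_perm=200, seed=3)
        qs = [r.q_value for r in results]
        assert qs == sorted(qs)
        assert all(0 < r.p_value <= 1 for r in results)
        assert all(abs(r.es) <= 1 for r in results)

    def test_no_admissible_pathway_returns_empty(self):
        ranking, _ = self._setup(planted=False)
        annotation = PathwayAnnotation({"G000": frozenset({"PW"})})
        assert enrich_pathways(ranking, annotation, n_perm=100) == []
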