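import dataclasses

import numpy as np
import pytest

from autogeny.defaults import FULL_STRENGTH_BOOST, default_model
from autogeny.disorder import disorder_fraction, disorder_scores, ks_two_sample
from autogeny.pipeline import load_catalog, RunConfig, score_catalog
from autogeny.propensity import SurrogateScorer
from autogeny.sequence_io import Kind, apply_length_filters
from autogeny.synthetic_data import (
    SimulationConfig,
    simulate_abundances,
    simulate_catalog,
    simulate_disorder_link,
    simulate_motif_pair,
    write_catalog,
)

SMALL = dict(n_pathways=6, genes_per_pathway=(5, 7), planted_pathways=(0, 1))


def small_cfg(**kw):
    return SimulationConfig(**{**SMALL, **kw})


class TestReproducibility:
    def test_same_seed_identical_catalog_truth_abundances(self):
        cfg = small_cfg(seed=7)
        cat_a, truth_a = simulate_catalog(cfg)
        cat_b, truth_b = simulate_catalog(small_cfg(seed=7))
        assert [r.sequence for r in cat_a.proteins] == [
            r.sequence for r in cat_b.proteins
        ]
        assert [r.sequence for r in cat_a.transcripts] == [
            r.sequence for r in cat_b.transcripts
        ]
        assert truth_a == truth_b
        pa, ra = simulate_abundances(cat_a, truth_a, cfg)
        pb, rb = simulate_abundances(cat_b, truth_b, cfg)
        assert pa.equals(pb) and ra.equals(rb)

    def test_different_seeds_differ(self):
        cat_a, _ = simulate_catalog(small_cfg(seed=0))
        cat_b, _ = simulate_catalog(small_cfg(seed=1))
        assert [r.sequence for r in cat_a.proteins] != [
            r.sequence for r in cat_b.proteins
        ]


class TestCatalogStructure:
    def test_all_lengths_pass_the_filters(self):
        cat, _ = simulate_catalog(small_cfg(seed=2))
        assert apply_length_filters(cat.proteins) == cat.proteins
        assert apply_length_filters(cat.transcripts) == cat.transcripts

    def test_every_gene_annotated_and_planted_pathways_exist(self):
        cat, truth = simulate_catalog(small_cfg(seed=3))
        assert set(cat.annotation.memberships) == cat.genes
        pathways = set().union(*cat.annotation.memberships.values())
        assert truth.planted_pathways <= pathways
        assert truth.planted_binder_genes <= cat.genes

    def test_binders_only_in_planted_pathways(self):
        cat, truth = simulate_catalog(small_cfg(seed=4))
        for gene in truth.planted_binder_genes:
            assert cat.annotation.memberships[gene] & truth.planted_pathways

    def test_motif_interval_recorded_within_transcript(self):
        cat, truth = simulate_catalog(small_cfg(seed=5))
        by_id = {r.id: r for r in cat.transcripts}
        for gene, (lo, hi) in truth.planted_rna_binding_intervals.items():
            rna = by_id[f"T_{gene}_1"]
            assert 0 <= lo < hi <= len(rna)
            motif = rna.sequence[lo:hi]
            gc = sum(c in "GC" for c in motif) / len(motif)
            assert gc > 0.7  # GC-rich hairpin element

    def test_infeasible_utr_rejected(self):
        with pytest.raises(ValueError, match="UTR"):
            simulate_catalog(small_cfg(utr5_len=(44, 50))).__repr__()


class TestSerialization:
    def test_round_trip_through_files(self, tmp_path):
        cfg = small_cfg(seed=6)
        cat, truth = simulate_catalog(cfg)
        paths = write_catalog(cat, truth, tmp_path)
        run_cfg = RunConfig(
            simulate=None,
            proteins=str(paths["proteins"]),
            transcripts=str(paths["transcripts"]),
            gene_map=str(paths["gene_map"]),
            annotation=str(paths["annotation"]),
        )
        loaded = load_catalog(run_cfg)
        assert loaded.genes == cat.genes
        assert loaded.proteins == cat.proteins
        assert loaded.transcripts == cat.transcripts
        assert loaded.annotation.memberships == dict(cat.annotation.memberships)


class TestPlantedSignal:
    def _auto_by_binder(self, cfg):
        cat, truth = simulate_catalog(cfg)
        pairs = score_catalog(
            cat, SurrogateScorer(default_model()), mode="autogenous_only"
        )
        binder = [p.pi for p in pairs if p.protein_gene in truth.planted_binder_genes]
        background = [
            p.pi for p in pairs if p.protein_gene not in truth.planted_binder_genes
        ]
        return binder, background, truth

    def test_zero_strength_plants_nothing(self):
        cat, truth = simulate_catalog(small_cfg(seed=8, motif_strength=0.0))
        assert truth.planted_binder_genes == set()
        assert truth.planted_rna_binding_intervals == {}

    def test_zero_strength_planted_pathways_indistinguishable(self):
        """With motif_strength = 0, autogenous propensities of genes in the
        planted pathways match the other genes' (KS, most replicates)."""
        ok = 0
        for seed in range(12):
            cfg = small_cfg(seed=seed, motif_strength=0.0, disorder_link=False)
            cat, truth = simulate_catalog(cfg)
            pairs = score_catalog(
                cat, SurrogateScorer(default_model()), mode="autogenous_only"
            )
            planted_genes = {
                g for g, pws in cat.annotation.memberships.items()
                if pws & truth.planted_pathways
            }
            a = [p.pi for p in pairs if p.protein_gene in planted_genes]
            b = [p.pi for p in pairs if p.protein_gene not in planted_genes]
            ok += ks_two_sample(a, b).p_value > 0.05
        assert ok >= 10

    def test_boost_increases_with_motif_strength(self):
        gaps = []
        for strength in (20.0, 40.0, FULL_STRENGTH_BOOST):
            binder, background, _ = self._auto_by_binder(
                small_cfg(seed=9, motif_strength=strength, disorder_link=False)
            )
            gaps.append(np.mean(binder) - np.mean(background))
        assert gaps[0] > 0
        assert gaps[0] < gaps[1] < gaps[2]

    def test_default_binders_clearly_separated(self):
        binder, background, _ = self._auto_by_binder(small_cfg(seed=10))
        assert np.mean(binder) > np.mean(background) + 30


class TestDisorderLink:
    def _fractions(self, cfg):
        cat, truth = simulate_catalog(cfg)
        by_gene = {r.gene_id: r for r in cat.proteins}
        case = [
            disorder_fraction(disorder_scores(by_gene[g]))
            for g in truth.planted_binder_genes
        ]
        background = [
            disorder_fraction(disorder_scores(r))
            for r in cat.proteins
            if r.gene_id not in truth.planted_binder_genes
        ]
        return case, background

    def test_link_raises_case_median(self):
        case, background = self._fractions(small_cfg(seed=11))
        assert np.median(case) > np.median(background)

    def test_no_link_non_significant_in_most_replicates(self):
        ok = 0
        for seed in range(12):
            case, background = self._fractions(
                small_cfg(seed=seed, disorder_link=False)
            )
            ok += ks_two_sample(case, background).p_value > 0.05
        assert ok >= 10

    def test_zero_bias_is_noop(self):
        cfg = small_cfg(seed=12, disorder_link=False)
        cat, truth = simulate_catalog(cfg)
        cfg_biased = dataclasses.replace(cfg, disorder_bias=0.0)
        out = simulate_disorder_link(cat, truth, cfg_biased)
        assert out.proteins == cat.proteins


class TestAbundances:
    def test_zero_injection_respects_nonzero_mean(self):
        cfg = small_cfg(seed=13)
        cat, truth = simulate_catalog(cfg)
        _, rna = simulate_abundances(cat, truth, cfg)
        tissues = rna.drop(columns=["gene_id"]).to_numpy()
        assert (tissues == 0.0).any()  # zeros exercised
        assert ((tissues > 0).sum(axis=1) >= 1).all()  # never all-zero

    def test_feedback_link_pushes_binder_ratios_below_one(self):
        cfg = small_cfg(seed=14)
        cat, truth = simulate_catalog(cfg)
        prot, rna = simulate_abundances(cat, truth, cfg)
        tissues = rna.drop(columns=["gene_id"]).to_numpy()
        rna_ppm = np.array([row[row > 0].mean() for row in tissues])
        ratio = dict(zip(rna["gene_id"], prot["ppm"].to_numpy() / rna_ppm))
        binder = [ratio[g] for g in truth.planted_binder_genes]
        other = [
            ratio[g] for g in cat.genes if g not in truth.planted_binder_genes
        ]
        assert np.median(binder) < 1.0 < np.median(other)


class TestMotifPair:
    def test_reproducible_and_interval_consistent(self):
        a = simulate_motif_pair(3)
        b = simulate_motif_pair(3)
        assert a[0].sequence == b[0].sequence
        assert a[1].sequence == b[1].sequence
        lo, hi = a[2]
        assert a[1].sequence[lo:hi].count("A") <= 10  # GC-rich up to the loop

    def test_infeasible_utr_rejected(self):
        with pytest.raises(ValueError):
            simulate_motif_pair(0, utr5=30)

    def test_kinds(self):
        prot, rna, _ = simulate_motif_pair(1)
        assert prot.kind == Kind.PROTEIN and rna.kind == Kind.TRANSCRIPT
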