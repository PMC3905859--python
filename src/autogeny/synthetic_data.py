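"""Seeded synthetic gene catalogs with planted autogenous binders.

The generator emulates the statistical structure the analysis assumes:

* a pathway-structured gene catalog (default 20 pathways of 8-12 genes,
  occasional multi-pathway membership, occasional transcript isoforms);
* *binder* genes inside the planted pathways whose transcript carries a
  GC-rich hairpin-forming element in the 5' UTR and whose protein carries a
  complementary hydrogen-bond-rich patch at the matched relative position;
* a gene-specific +/- composition code at fixed relative positions along
  both molecules.  Because the default scorer is bilinear (separable), a
  purely compositional motif would boost *every* binder x binder cross pair
  as much as the autogenous ones; the positional code makes the boost
  pair-specific: matched (same-gene) codes add coherently, mismatched codes
  cancel on average;
* optionally, disorder-enriched binder proteins (composition biased toward
  charged/hydrophilic residues) and protein/RNA abundance tables whose
  translation-efficiency ratio is pushed below 1 for binder genes (the
  negative-feedback signature).

The planted boost scales ~linearly with ``motif_strength`` (expressed in
propensity units; the mapping constant is the calibrated full-strength boost
in :mod:`autogeny.defaults`); ``motif_strength = 0`` plants nothing.
Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import scales
from .defaults import DEFAULT_MOTIF_STRENGTH, FULL_STRENGTH_BOOST
from .sequence_io import (
    GeneCatalog,
    Kind,
    PathwayAnnotation,
    SequenceRecord,
    write_annotation,
    write_fasta,
)

HAIRPIN_ARM = 18
HAIRPIN_LOOP = "AAAA"
MOTIF_LEN = 2 * HAIRPIN_ARM + len(HAIRPIN_LOOP)  # 40 nt

#: base relative positions of the gene-specific composition code; each gene
#: additionally shifts all slots by a common random phase jitter, which
#: dephases cross-gene pairs further while same-gene pairs stay matched
CODE_SLOTS = tuple(0.36 + 0.06 * i for i in range(10))
CODE_JITTER = 0.04
RNA_SLOT_LEN = 18
PROTEIN_SLOT_LEN = 12
PATCH_LEN = 24
ANCHOR_LEN = 20
#: mixing factors of the always-positive patch/anchor features, kept below
#: the code's so that position-key coincidences between different genes
#: cannot lift a cross pair into the autogenous score range
PATCH_MIX = 0.6
ANCHOR_MIX = 0.6

GC_RICH = {"G": 0.5, "C": 0.5}
AU_RICH = {"A": 0.5, "U": 0.5}
HBOND_RICH_AA = "NQR"  # side-chain H-bond capacity 4 each
HBOND_POOR_AA = "ALIVFG"  # side-chain H-bond capacity 0
#: disorder-promoting composition for the disorder-link bias.  Charged and
#: hydrophilic residues raise the surrogate disorder score, but most of them
#: also carry H-bond capacity; the proline/glycine share keeps the mixture's
#: mean side-chain H-bond capacity at the background value so the bias does
#: not leak into the interaction score of every pair the protein forms.
DISORDER_AA = {"P": 0.30, "G": 0.22, "E": 0.12, "K": 0.12, "D": 0.12, "S": 0.12}

#: background side-chain H-bond capacity and the deviations of the two code
#: compositions from it; the +/- code mixes are scaled so both signs move the
#: smoothed H-bond track by the same absolute amount (otherwise the nonzero
#: mean slot deviation would leak a shared boost into every binder x binder
#: cross pair)
_HBOND_BG_MEAN = sum(
    scales.HBOND[a] * f for a, f in scales.AA_BACKGROUND.items()
)
_CODE_DEV_TARGET = 1.0
_MIX_PLUS = _CODE_DEV_TARGET / (4.0 - _HBOND_BG_MEAN)
_MIX_MINUS = _CODE_DEV_TARGET / _HBOND_BG_MEAN

_DIS_AA, _DIS_P = zip(*sorted(DISORDER_AA.items()))
_DIS_P = np.array(_DIS_P) / np.sum(_DIS_P)
_DIS_AA = list(_DIS_AA)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pathways: int = 20
    genes_per_pathway: tuple[int, int] = (8, 12)
    planted_pathways: tuple[int, ...] = (0, 1, 2)
    binder_fraction: float = 0.9
    motif_strength: float = DEFAULT_MOTIF_STRENGTH
    disorder_link: bool = True
    feedback_link: bool = True
    protein_len: tuple[int, int] = (220, 420)
    transcript_len: tuple[int, int] = (380, 560)
    utr5_len: tuple[int, int] = (60, 120)
    isoform_prob: float = 0.2
    cross_membership_prob: float = 0.1
    disorder_bias: float = 0.3
    n_tissues: int = 5
    tissue_zero_prob: float = 0.2

    def validate(self) -> None:
        if not 0.0 <= self.binder_fraction <= 1.0:
            raise ValueError("binder_fraction must lie in [0, 1]")
        if self.motif_strength < 0:
            raise ValueError("motif_strength must be >= 0")
        if any(p >= self.n_pathways or p < 0 for p in self.planted_pathways):
            raise ValueError("planted pathways must index existing pathways")
        plants = (
            self.motif_strength > 0
            and self.binder_fraction > 0
            and len(self.planted_pathways) > 0
        )
        if plants and self.utr5_len[0] < MOTIF_LEN + 6:
            raise ValueError(
                f"5' UTR too short for the {MOTIF_LEN} nt motif: "
                f"need at least {MOTIF_LEN + 6}"
            )
        if not (50 <= self.protein_len[0] <= self.protein_len[1] <= 750):
            raise ValueError("protein lengths must lie within [50, 750]")
        if not (50 <= self.transcript_len[0] <= self.transcript_len[1] <= 1500):
            raise ValueError("transcript lengths must lie within [50, 1500]")


@dataclass
class SyntheticTruth:
    planted_binder_genes: set[str] = field(default_factory=set)
    planted_pathways: set[str] = field(default_factory=set)
    planted_rna_binding_intervals: dict[str, tuple[int, int]] = field(
        default_factory=dict
    )
    disorder_enriched_genes: set[str] = field(default_factory=set)
    protein_patch_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    protein_code_intervals: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict
    )


def _draw(rng: np.random.Generator, letters: str, n: int) -> list[str]:
    return list(rng.choice(list(letters), size=n))


def _background_protein(rng: np.random.Generator, n: int) -> list[str]:
    aa, p = zip(*sorted(scales.AA_BACKGROUND.items()))
    p = np.asarray(p) / np.sum(p)
    return list(rng.choice(aa, size=n, p=p))


def _background_rna(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGU"), size=n))


def _mix_segment(
    rng: np.random.Generator,
    seq: list[str],
    start: int,
    length: int,
    comp: dict[str, float] | str,
    alpha: float,
) -> None:
    """Replace positions with draws from ``comp`` with probability ``alpha``."""
    end = min(start + length, len(seq))
    if isinstance(comp, str):
        letters, probs = list(comp), None
    else:
        letters, probs = zip(*sorted(comp.items()))
        probs = np.asarray(probs) / np.sum(probs)
    for i in range(max(start, 0), end):
        if rng.random() < alpha:
            seq[i] = str(rng.choice(letters, p=probs))


def _slot_start(rel: float, length: int, slot_len: int) -> int:
    return int(np.clip(int(rel * length) - slot_len // 2, 0, max(length - slot_len, 0)))


def simulate_catalog(cfg: SimulationConfig) -> tuple[GeneCatalog, SyntheticTruth]:
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    alpha = (
        min(1.0, cfg.motif_strength / FULL_STRENGTH_BOOST)
        if cfg.motif_strength > 0
        else 0.0
    )
    truth = SyntheticTruth(
        planted_pathways={f"PW{p:02d}" for p in cfg.planted_pathways}
    )
    memberships: dict[str, set[str]] = {}
    proteins: list[SequenceRecord] = []
    transcripts: list[SequenceRecord] = []
    genes: set[str] = set()
    gene_counter = 0

    for pw in range(cfg.n_pathways):
        pathway_id = f"PW{pw:02d}"
        planted_pw = pw in cfg.planted_pathways
        size = int(rng.integers(cfg.genes_per_pathway[0], cfg.genes_per_pathway[1] + 1))
        for _ in range(size):
            gene = f"G{gene_counter:04d}"
            gene_counter += 1
            genes.add(gene)
            memberships[gene] = {pathway_id}
            is_binder = (
                planted_pw and alpha > 0 and rng.random() < cfg.binder_fraction
            )
            if is_binder:
                truth.planted_binder_genes.add(gene)
            elif rng.random() < cfg.cross_membership_prob and cfg.n_pathways > 1:
                other = int(rng.integers(cfg.n_pathways))
                if other != pw:
                    memberships[gene].add(f"PW{other:02d}")

            # ---- transcript (primary isoform) ----
            rna_len = int(rng.integers(cfg.transcript_len[0], cfg.transcript_len[1] + 1))
            utr5 = int(rng.integers(cfg.utr5_len[0], cfg.utr5_len[1] + 1))
            utr5 = min(utr5, rna_len - 20)
            rna = _background_rna(rng, rna_len)
            # balanced +/- code: a sign imbalance would shift the molecule's
            # bulk composition and leak a boost into every pair it forms
            signs = rng.permutation(
                [1] * (len(CODE_SLOTS) // 2)
                + [-1] * (len(CODE_SLOTS) - len(CODE_SLOTS) // 2)
            )
            # gene-specific relative position shared by the protein patch and
            # the RNA anchor; drawing it wide keeps cross-gene pairs dephased
            pos_key = float(rng.uniform(0.34, 0.92))
            jitter = float(rng.uniform(-CODE_JITTER, CODE_JITTER))
            if is_binder:
                for rel, sign in zip(CODE_SLOTS, signs):
                    s = _slot_start(rel + jitter, rna_len, RNA_SLOT_LEN)
                    comp = GC_RICH if sign > 0 else AU_RICH
                    _mix_segment(rng, rna, s, RNA_SLOT_LEN, comp, alpha)
                m_start = int(rng.integers(3, utr5 - MOTIF_LEN - 2))
                arm = _draw(rng, "GC", HAIRPIN_ARM)
                motif = arm + list(HAIRPIN_LOOP) + [_RC[c] for c in reversed(arm)]
                rna[m_start : m_start + MOTIF_LEN] = motif
                truth.planted_rna_binding_intervals[gene] = (
                    m_start,
                    m_start + MOTIF_LEN,
                )
                a_start = _slot_start(pos_key, rna_len, ANCHOR_LEN)
                _mix_segment(rng, rna, a_start, ANCHOR_LEN, GC_RICH, alpha * ANCHOR_MIX)
            rna_seq = "".join(rna)
            transcripts.append(
                SequenceRecord(
                    id=f"T_{gene}_1", gene_id=gene, kind=Kind.TRANSCRIPT,
                    sequence=rna_seq,
                )
            )
            if rng.random() < cfg.isoform_prob:
                delta = int(rng.integers(20, 80))
                iso_len = max(rna_len - delta, utr5 + MOTIF_LEN + 20, 50)
                transcripts.append(
                    SequenceRecord(
                        id=f"T_{gene}_2", gene_id=gene, kind=Kind.TRANSCRIPT,
                        sequence=rna_seq[:iso_len],
                    )
                )

            # ---- protein ----
            prot_len = int(rng.integers(cfg.protein_len[0], cfg.protein_len[1] + 1))
            prot = _background_protein(rng, prot_len)
            if is_binder:
                slots = []
                for rel, sign in zip(CODE_SLOTS, signs):
                    s = _slot_start(rel + jitter, prot_len, PROTEIN_SLOT_LEN)
                    if sign > 0:
                        comp, mix = HBOND_RICH_AA, _MIX_PLUS
                    else:
                        comp, mix = HBOND_POOR_AA, _MIX_MINUS
                    _mix_segment(rng, prot, s, PROTEIN_SLOT_LEN, comp, alpha * mix)
                    slots.append((s, s + PROTEIN_SLOT_LEN))
                truth.protein_code_intervals[gene] = slots
                p_start = _slot_start(pos_key, prot_len, PATCH_LEN)
                _mix_segment(rng, prot, p_start, PATCH_LEN, HBOND_RICH_AA, alpha * PATCH_MIX)
                truth.protein_patch_intervals[gene] = (p_start, p_start + PATCH_LEN)
            proteins.append(
                SequenceRecord(
                    id=f"P_{gene}", gene_id=gene, kind=Kind.PROTEIN,
                    sequence="".join(prot),
                )
            )

    catalog = GeneCatalog(
        genes=genes,
        proteins=proteins,
        transcripts=transcripts,
        annotation=PathwayAnnotation(
            {g: frozenset(p) for g, p in memberships.items()}
        ),
    )
    if cfg.disorder_link:
        catalog = simulate_disorder_link(catalog, truth, cfg)
    return catalog, truth


def simulate_motif_pair(
    seed: int,
    protein_len: int = 300,
    rna_len: int = 450,
    utr5: int = 100,
    arm_len: int = 28,
    patch_len: int = 32,
) -> tuple[SequenceRecord, SequenceRecord, tuple[int, int]]:
    """One background pair with only the binding motif planted.

    The transcript carries the GC-rich hairpin element at a random position
    inside the 5' UTR and the protein a fully mixed H-bond-rich patch at the
    matched relative position -- no composition code.  Returns the records
    and the planted RNA interval (0-based half-open); used to exercise
    binding-region localization in isolation.
    """
    motif_len = 2 * arm_len + len(HAIRPIN_LOOP)
    if utr5 < motif_len + 6 or rna_len < utr5 + 20:
        raise ValueError("motif does not fit the 5' UTR")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    rna = _background_rna(rng, rna_len)
    m_start = int(rng.integers(3, utr5 - motif_len - 2))
    arm = _draw(rng, "GC", arm_len)
    rna[m_start : m_start + motif_len] = (
        arm + list(HAIRPIN_LOOP) + [_RC[c] for c in reversed(arm)]
    )
    prot = _background_protein(rng, protein_len)
    rel = (m_start + motif_len / 2) / rna_len
    p_start = _slot_start(rel, protein_len, patch_len)
    _mix_segment(rng, prot, p_start, patch_len, HBOND_RICH_AA, 1.0)
    protein = SequenceRecord(
        id="motif_prot", gene_id="motif_gene", kind=Kind.PROTEIN,
        sequence="".join(prot),
    )
    rna_rec = SequenceRecord(
        id="motif_rna", gene_id="motif_gene", kind=Kind.TRANSCRIPT,
        sequence="".join(rna),
    )
    return protein, rna_rec, (m_start, m_start + motif_len)


def simulate_disorder_link(
    catalog: GeneCatalog, truth: SyntheticTruth, cfg: SimulationConfig
) -> GeneCatalog:
    """Bias binder proteins toward charged/hydrophilic composition.

    Residues outside the planted patch and code slots are re-drawn with
    mixing ``cfg.disorder_bias`` toward disorder-promoting residues, so
    surrogate disorder fractions of binder proteins become stochastically
    larger than background.  Bias 0 is a no-op.
    """
    if cfg.disorder_bias <= 0 or not truth.planted_binder_genes:
        return catalog
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    keep: dict[str, set[int]] = {}
    for gene in truth.planted_binder_genes:
        protected: set[int] = set()
        s, e = truth.protein_patch_intervals.get(gene, (0, 0))
        protected.update(range(s, e))
        for s, e in truth.protein_code_intervals.get(gene, []):
            protected.update(range(s, e))
        keep[gene] = protected
    new_proteins = []
    for rec in catalog.proteins:
        if rec.gene_id not in truth.planted_binder_genes:
            new_proteins.append(rec)
            continue
        seq = list(rec.sequence)
        protected = keep[rec.gene_id]
        for i in range(len(seq)):
            if i not in protected and rng.random() < cfg.disorder_bias:
                seq[i] = str(rng.choice(_DIS_AA, p=_DIS_P))
        new_proteins.append(
            SequenceRecord(
                id=rec.id, gene_id=rec.gene_id, kind=rec.kind,
                sequence="".join(seq),
            )
        )
        truth.disorder_enriched_genes.add(rec.gene_id)
    return GeneCatalog(
        genes=catalog.genes,
        proteins=new_proteins,
        transcripts=catalog.transcripts,
        annotation=catalog.annotation,
    )


def simulate_abundances(
    catalog: GeneCatalog, truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein and RNA abundance tables (ppm) with the feedback signature.

    RNA abundance is log-normal across ``n_tissues`` tissue columns with
    zeros injected (to exercise the non-zero-mean rule; at least one tissue
    stays positive).  When ``feedback_link`` is set, binder genes draw a
    translation-efficiency ratio below 1 and the rest above 1; otherwise the
    ratio is independent of binder status.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    genes = sorted(catalog.genes)
    rna_rows = []
    protein_rows = []
    for gene in genes:
        base = float(rng.lognormal(mean=np.log(50.0), sigma=1.0))
        tissues = base * rng.lognormal(mean=0.0, sigma=0.3, size=cfg.n_tissues)
        zero = rng.random(cfg.n_tissues) < cfg.tissue_zero_prob
        zero[int(rng.integers(cfg.n_tissues))] = False  # keep >= 1 non-zero
        tissues[zero] = 0.0
        rna_ppm = tissues[tissues > 0].mean()
        if cfg.feedback_link:
            if gene in truth.planted_binder_genes:
                ratio = float(rng.lognormal(mean=np.log(0.45), sigma=0.3))
            else:
                ratio = float(rng.lognormal(mean=np.log(2.2), sigma=0.4))
        else:
            ratio = float(rng.lognormal(mean=0.0, sigma=0.5))
        rna_rows.append({"gene_id": gene} | {
            f"tissue_{t + 1}": tissues[t] for t in range(cfg.n_tissues)
        })
        protein_rows.append({"gene_id": gene, "ppm": ratio * rna_ppm})
    return pd.DataFrame(protein_rows), pd.DataFrame(rna_rows)


def write_catalog(
    catalog: GeneCatalog, truth: SyntheticTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Serialize a catalog to FASTA/TSV plus the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.fasta",
        "transcripts": out / "transcripts.fasta",
        "gene_map": out / "gene_map.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(catalog.proteins, paths["proteins"])
    write_fasta(catalog.transcripts, paths["transcripts"])
    rows = [
        {"record_id": r.id, "gene_id": r.gene_id}
        for r in (*catalog.proteins, *catalog.transcripts)
    ]
    pd.DataFrame(rows).to_csv(paths["gene_map"], sep="\t", index=False)
    write_annotation(catalog.annotation, paths["annotation"])
    payload = asdict(truth)
    payload["planted_binder_genes"] = sorted(truth.planted_binder_genes)
    payload["planted_pathways"] = sorted(truth.planted_pathways)
    payload["disorder_enriched_genes"] = sorted(truth.disorder_enriched_genes)
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
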