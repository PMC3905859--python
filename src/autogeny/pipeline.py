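"""End-to-end orchestration: score -> partition / strength / fragment ->
disorder / enrichment / feedback, with deterministic per-stage seeding and
provenance headers on every report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defaults import CONFIG_SCHEMA_VERSION, default_model
from .disorder import disorder_scores, disorder_stratification
from .enrichment import (
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    DEFAULT_N_PERM,
    build_ranking,
    enrich_pathways,
    results_table,
    write_results,
)
from .fragmentation import call_binding_regions, interaction_map, make_grid, write_map
from .partition import (
    ScoredPair,
    gene_partition,
    write_partition_report,
    write_scored_pairs,
)
from .propensity import SurrogateScorer, load_score_table
from .sequence_io import (
    GeneCatalog,
    Kind,
    PairClass,
    apply_length_filters,
    enumerate_pairs,
    load_annotation,
    load_fasta,
    load_gene_map,
)
from .strength import ReferenceCache, catalog_composition, interaction_strength
from .synthetic_data import (
    SimulationConfig,
    simulate_abundances,
    simulate_catalog,
    write_catalog,
)
from .translation import feedback_analysis, load_abundances, write_feedback_table

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (50.0, 100.0, 150.0)

#: stable per-stage codes so toggling one stage never shifts another's draws
STAGE_CODES = {
    "simulate": 10,
    "strength": 20,
    "enrich": 30,
}

ALL_STAGES = (
    "score",
    "partition",
    "strength",
    "fragment",
    "disorder",
    "enrich",
    "feedback",
)


@dataclass
class RunConfig:
    out_dir: str = "autogeny_run"
    seed: int = 0
    # either simulate a catalog ...
    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    # ... or load one from files
    proteins: str | None = None
    transcripts: str | None = None
    gene_map: str | None = None
    annotation: str | None = None
    protein_abundance: str | None = None
    rna_abundance: str | None = None
    score_table: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_perm: int = DEFAULT_N_PERM
    min_set_size: int = DEFAULT_MIN_SIZE
    max_set_size: int = DEFAULT_MAX_SIZE
    strength_top_n: int = 2
    fragment_top_n: int = 1
    region_quantile: float = 0.9
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if self.simulate is None:
            for name in ("proteins", "transcripts", "gene_map", "annotation"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} file required: {path!r}")

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        payload = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim = payload.pop("simulate", None)
        cfg = cls(**{k: v for k, v in payload.items() if k in _FIELD_NAMES})
        if isinstance(cfg.thresholds, list):
            cfg.thresholds = tuple(cfg.thresholds)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if sim is not None:
            sim = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            }
            cfg.simulate = SimulationConfig(**sim)
        else:
            cfg.simulate = None
        return cfg


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, independent of stage toggling."""
    code = STAGE_CODES.get(stage, 0)
    digest = hashlib.sha256(f"{master_seed}:{stage}:{code}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(cfg: RunConfig) -> str:
    payload = dataclasses.asdict(cfg)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def score_catalog(
    catalog: GeneCatalog, scorer, mode: str = "all"
) -> list[ScoredPair]:
    """Score every classified protein x transcript pair of the catalog."""
    triples = list(enumerate_pairs(catalog, mode=mode))
    if not triples:
        return []
    if hasattr(scorer, "score_matrix"):
        prots = sorted(catalog.proteins, key=lambda r: r.id)
        rnas = sorted(catalog.transcripts, key=lambda r: r.id)
        matrix = scorer.score_matrix(prots, rnas)
        pi_of = {
            (p.id, r.id): matrix[i, j]
            for i, p in enumerate(prots)
            for j, r in enumerate(rnas)
        }
        get = lambda p, r: float(pi_of[(p.id, r.id)])  # noqa: E731
    else:
        get = lambda p, r: float(scorer(p, r))  # noqa: E731
    return [
        ScoredPair(
            protein_id=p.id,
            rna_id=r.id,
            protein_gene=p.gene_id,
            rna_gene=r.gene_id,
            pair_class=cls,
            pi=get(p, r),
        )
        for p, r, cls in triples
    ]


def load_catalog(cfg: RunConfig) -> GeneCatalog:
    gene_map = load_gene_map(cfg.gene_map)
    proteins = load_fasta(cfg.proteins, Kind.PROTEIN, gene_map)
    transcripts = load_fasta(cfg.transcripts, Kind.TRANSCRIPT, gene_map)
    annotation = load_annotation(cfg.annotation)
    genes = {r.gene_id for r in (*proteins, *transcripts)}
    return GeneCatalog(
        genes=genes, proteins=proteins, transcripts=transcripts,
        annotation=annotation,
    )


def _provenance(cfg: RunConfig, stage: str) -> list[str]:
    return [
        f"autogeny {__version__} (config schema {CONFIG_SCHEMA_VERSION})",
        f"stage: {stage}",
        f"seed: {cfg.seed}",
        f"config: {config_hash(cfg)}",
    ]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a machine-readable summary (also written to ``summary.json``);
    reruns with an identical config reproduce identical outputs.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "stages": {},
    }

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(
                cfg.simulate, seed=stage_seed(cfg.seed, "simulate")
            )
            catalog, truth = simulate_catalog(sim_cfg)
            paths = write_catalog(catalog, truth, out / "inputs")
            prot_ab, rna_ab = simulate_abundances(catalog, truth, sim_cfg)
            prot_ab.to_csv(out / "inputs" / "protein_abundance.tsv", sep="\t", index=False)
            rna_ab.to_csv(out / "inputs" / "rna_abundance.tsv", sep="\t", index=False)
            cfg = dataclasses.replace(
                cfg,
                protein_abundance=str(out / "inputs" / "protein_abundance.tsv"),
                rna_abundance=str(out / "inputs" / "rna_abundance.tsv"),
            )
            summary["stages"]["simulate"] = {
                "n_genes": len(catalog.genes),
                "n_binders": len(truth.planted_binder_genes),
                "paths": {k: str(v) for k, v in paths.items()},
            }
        else:
            catalog = load_catalog(cfg)

        catalog = GeneCatalog(
            genes=catalog.genes,
            proteins=apply_length_filters(catalog.proteins),
            transcripts=apply_length_filters(catalog.transcripts),
            annotation=catalog.annotation,
        )

        stage = "score"
        if cfg.score_table is not None:
            scorer = load_score_table(cfg.score_table)
        else:
            scorer = SurrogateScorer(default_model())
        pairs: list[ScoredPair] = []
        if "score" in cfg.stages:
            pairs = score_catalog(catalog, scorer)
            write_scored_pairs(pairs, out / "scores.tsv", _provenance(cfg, "score"))
            summary["stages"]["score"] = {
                "n_pairs": len(pairs),
                "mean_pi": float(np.mean([p.pi for p in pairs])) if pairs else None,
            }

        if "partition" in cfg.stages and pairs:
            stage = "partition"
            curve = gene_partition(pairs, cfg.thresholds)
            write_partition_report(
                curve, out / "partition.tsv", _provenance(cfg, "partition")
            )
            summary["stages"]["partition"] = {
                "thresholds": list(cfg.thresholds),
                "frac_autogenous": [float(x) for x in curve.fractions[:, 0]],
                "n_genes": [int(x) for x in curve.n_genes],
            }

        auto_pairs = [p for p in pairs if p.pair_class == PairClass.AUTOGENOUS]
        by_id = {r.id: r for r in (*catalog.proteins, *catalog.transcripts)}

        if "strength" in cfg.stages and auto_pairs:
            stage = "strength"
            cache = ReferenceCache(
                composition=catalog_composition(catalog),
                seed=stage_seed(cfg.seed, "strength"),
            )
            top = sorted(auto_pairs, key=lambda p: -p.pi)[: cfg.strength_top_n]
            rows = []
            for p in top:
                prot, rna = by_id[p.protein_id], by_id[p.rna_id]
                ref = cache.get(len(prot), len(rna))
                res = interaction_strength(prot, rna, scorer, ref)
                rows.append(
                    {
                        "protein_id": p.protein_id,
                        "rna_id": p.rna_id,
                        "propensity": p.pi,
                        "strength": res.strength,
                        "n_controls": res.n_controls,
                        "control_mean": res.control_mean,
                        "control_sd": res.control_sd,
                        "control_min": res.control_min,
                        "control_max": res.control_max,
                    }
                )
            with open(out / "strength.tsv", "w") as fh:
                for line in _provenance(cfg, "strength"):
                    fh.write(f"# {line}\n")
                pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
            summary["stages"]["strength"] = rows

        if "fragment" in cfg.stages and auto_pairs:
            stage = "fragment"
            top = sorted(auto_pairs, key=lambda p: -p.pi)[: cfg.fragment_top_n]
            frag_summaries = []
            for p in top:
                prot, rna = by_id[p.protein_id], by_id[p.rna_id]
                imap = interaction_map(
                    prot, rna, scorer, make_grid(len(prot), len(rna))
                )
                prefix = out / f"fragment_{p.protein_id}_{p.rna_id}"
                write_map(imap, prefix)
                regions = call_binding_regions(imap, cfg.region_quantile)
                frag_summaries.append(
                    {
                        "protein_id": p.protein_id,
                        "rna_id": p.rna_id,
                        "rna_regions": regions["rna"],
                        "protein_regions": regions["protein"],
                    }
                )
            summary["stages"]["fragment"] = frag_summaries

        if "disorder" in cfg.stages and pairs:
            stage = "disorder"
            profiles = {rec.id: disorder_scores(rec) for rec in catalog.proteins}
            table = disorder_stratification(pairs, profiles, cfg.thresholds)
            with open(out / "disorder.tsv", "w") as fh:
                for line in _provenance(cfg, "disorder"):
                    fh.write(f"# {line}\n")
                table.to_csv(fh, sep="\t", index=False, na_rep="NA")
            summary["stages"]["disorder"] = table.to_dict("records")

        if "enrich" in cfg.stages and auto_pairs:
            stage = "enrich"
            ranking = build_ranking(auto_pairs)
            results = enrich_pathways(
                ranking,
                catalog.annotation,
                min_size=cfg.min_set_size,
                max_size=cfg.max_set_size,
                n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, "enrich"),
            )
            write_results(results, out / "enrichment.tsv", _provenance(cfg, "enrich"))
            summary["stages"]["enrich"] = results_table(results).to_dict("records")

        if (
            "feedback" in cfg.stages
            and auto_pairs
            and cfg.protein_abundance
            and cfg.rna_abundance
        ):
            stage = "feedback"
            records = load_abundances(cfg.protein_abundance, cfg.rna_abundance)
            table = feedback_analysis(records, auto_pairs)
            write_feedback_table(
                table, out / "feedback.tsv", _provenance(cfg, "feedback")
            )
            summary["stages"]["feedback"] = table.rows.to_dict("records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # digest covers the scientific content only (not filesystem locations),
    # so identical configurations reproduce identical digests anywhere
    content = {
        stage: {k: v for k, v in payload.items() if k != "paths"}
        if isinstance(payload, dict)
        else payload
        for stage, payload in summary["stages"].items()
    }
    digest = hashlib.sha256(
        json.dumps({"seed": cfg.seed, "stages": content}, sort_keys=True,
                   default=str).encode()
    ).hexdigest()[:16]
    summary["digest"] = digest
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
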