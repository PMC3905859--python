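import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from autogeny import (
    GeneCatalog,
    Kind,
    PathwayAnnotation,
    SequenceRecord,
    SurrogateScorer,
    default_model,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_protein(id_, gene, seq):
    return SequenceRecord(id=id_, gene_id=gene, kind=Kind.PROTEIN, sequence=seq)


def make_rna(id_, gene, seq):
    return SequenceRecord(id=id_, gene_id=gene, kind=Kind.TRANSCRIPT, sequence=seq)


def random_protein_seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def random_rna_seq(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def scorer():
    return SurrogateScorer(default_model())


@pytest.fixture()
def toy_catalog():
    """Four genes in three pathways; G4 is unannotated."""
    rng = np.random.default_rng(42)
    annotation = PathwayAnnotation(
        {
            "G1": frozenset({"P1"}),
            "G2": frozenset({"P1", "P2"}),
            "G3": frozenset({"P2"}),
        }
    )
    proteins = [
        make_protein(f"P_{g}", g, random_protein_seq(rng, 80))
        for g in ("G1", "G2", "G3", "G4")
    ]
    transcripts = [
        make_rna(f"T_{g}", g, random_rna_seq(rng, 120))
        for g in ("G1", "G2", "G3", "G4")
    ]
    return GeneCatalog(
        genes={"G1", "G2", "G3", "G4"},
        proteins=proteins,
        transcripts=transcripts,
        annotation=annotation,
    )
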