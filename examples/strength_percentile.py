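"""Interaction-strength specificity of a planted autogenous pair.

The strength of a pair is the percentile of its interaction propensity
within 10^4 random control interactions built from 100 random proteins x
100 random RNAs of exactly the same lengths, so the measure is independent
of molecule size.
"""

from autogeny import (
    SimulationConfig,
    SurrogateScorer,
    default_model,
    interaction_strength,
    sample_reference,
    score_catalog,
    simulate_catalog,
)
from autogeny.strength import catalog_composition

cfg = SimulationConfig(seed=3, n_pathways=6, genes_per_pathway=(5, 7),
                       planted_pathways=(0, 1))
catalog, truth = simulate_catalog(cfg)
scorer = SurrogateScorer(default_model())
pairs = score_catalog(catalog, scorer, mode="autogenous_only")
top = max(pairs, key=lambda p: p.pi)
by_id = {r.id: r for r in (*catalog.proteins, *catalog.transcripts)}
prot, rna = by_id[top.protein_id], by_id[top.rna_id]

ref = sample_reference(len(prot), len(rna),
                       composition=catalog_composition(catalog), seed=0)
res = interaction_strength(prot, rna, scorer, ref)

print(f"pair {top.protein_id} x {top.rna_id}: propensity {top.pi:.1f}")
print(f"controls: {res.n_controls} matched-length random interactions, "
      f"mean {res.control_mean:.1f} +/- {res.control_sd:.1f}")
print(f"interaction strength = {res.strength:.1f}%")
print(
    "\nA strength near 100% means the pair out-scores essentially every"
    "\nrandom protein/RNA control of the same lengths: the predicted"
    "\ninteraction is specific, not a length or composition artifact."
)
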