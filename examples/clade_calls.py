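"""Assign family members to clades against a characterized reference panel.

Simulates a family with known clade labels at two divergence levels and
shows how the relaxed set assigns everything while the conservative
filter (40% identity, 200 aa) leaves strongly diverged members
unassigned — candidate novel clades.
"""

from bahdscape import (
    ReferencePanel,
    SimConfig,
    align_all,
    assign_clades,
    best_hits,
    clade_census,
    simulate_family,
)
from bahdscape.io import fasta_text_to_dict

for divergence in (0.15, 0.75):
    sim = simulate_family(SimConfig(seed=21, protein_divergence=divergence,
                                    clade_labels=("1", "4", "5"),
                                    descendants_per_clade=5))
    panel = ReferencePanel(sim.panel)
    prots = fasta_text_to_dict(sim.protein_fasta)
    queries = {g: prots[g]
               for g in sim.truth[sim.truth.role == "descendant"].gene_id}
    calls = assign_clades(best_hits(align_all(queries, panel)), panel)
    species = {q: "demo_species" for q in queries}
    for mode in ("relaxed", "conservative"):
        table = clade_census([c for c in calls if c.mode == mode], species)
        print(f"divergence {divergence:.0%}, {mode} set:")
        print(table.to_string(), "\n")
# At 15% divergence both sets recover the true clades; at 75% the
# conservative census collapses to "unassigned" (the novel-clade signal)
# while the relaxed set still assigns every query to its best hit.
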