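"""Hypergeometric GO-BP over-representation with BH adjustment and
parent-term redundancy removal.

Builds a small synthetic GO structure containing one term concentrated in
the disease module plus its strict-superset parent, then tests the disease
module's genes against it.
"""

from amelonet import GOStructure, PipelineConfig, SimulationPlan, hypergeom_enrich, nonredundant_filter
from amelonet.simulate import simulate_go

cfg = PipelineConfig()
plan = SimulationPlan(seed=1)
labels = plan.module_labels()

terms, parents = simulate_go(plan, labels, cfg)
structure = GOStructure(term_to_genes=terms, parent_of=parents)
query = [g for g, m in labels.items() if m == plan.disease_module]

rows = nonredundant_filter(hypergeom_enrich(query, structure, cfg), structure, cfg)
print(rows.to_string(index=False))
# k of n query genes fall in a term of K genes out of N annotated; p is the
# upper-tail hypergeometric probability, p_adjust its BH correction.  The
# parent term is significant too but redundant (it subsumes the enriched
# child term), so kept_nonredundant is False for it.
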