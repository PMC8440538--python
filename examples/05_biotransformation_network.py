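"""Mass-shift biotransformation networking of parent drugs in a cohort.

Simulates a cohort carrying five drug pathways, then builds the
reaction-based network: features correlated with each parent across samples
(|r| > 0.4) are kept only when their mass offset from the parent matches a
known biotransformation or adduct delta (±3 ppm).  The result should fall
into five connected components, each centred on one parent compound, with
edges labelled by the matching reaction.
"""

import networkx as nx

from ebimet import network
from ebimet.chem import default_rules
from ebimet.pathways import drug_pathways
from ebimet.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=3, n_background=60)
tables, truth = simulate_cohort(drug_pathways(), n_samples=120, config=config)
table = tables["plasma"]

parents = {p.precursor: f"{p.precursor}/{p.precursor}" for p in drug_pathways()}
g = network.build_network(
    parents, table, default_rules(phases=None), r_threshold=0.4, ppm_tol=3.0
)

print(f"network: {len(g)} nodes, {g.number_of_edges()} edges, "
      f"{nx.number_connected_components(g)} connected components\n")
for comp in nx.connected_components(g):
    root = next(n for n in comp if g.nodes[n].get("role") == "parent")
    print(f"cluster around {g.nodes[root]['annotation']}:")
    for u, v, attrs in g.edges(comp, data=True):
        child = v if u == root else u
        print(f"  {child:40s} {attrs['rule']:18s} "
              f"delta {attrs['delta_mz']:+9.4f} Da  r = {attrs['r']:.2f}")
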