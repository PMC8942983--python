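"""Topological ranking of lncRNAs and key-lncRNA selection.

Uses the package's built-in CN-AML top-10 lncRNA degree profile to show
the pair-count arithmetic: for each lncRNA, total pairs = lncRNA-miRNA
(first) pairs + miRNA-mRNA (secondary) pairs, and the key lncRNAs are
those in the top-3 of both the degree and the total-pairs rankings.
"""

from cernanet.datasets import profile_network
from cernanet.topology import hub_nodes, rank_lncrnas, select_key_lncrnas

net = profile_network()
ranked = rank_lncrnas(net)
print(ranked.to_string(index=False))
keys = select_key_lncrnas(ranked, k=3)
print(f"\nkey lncRNAs (top-3 of both rankings): {', '.join(keys)}")
hubs = hub_nodes(net, threshold=5)
lnc_hubs = hubs[hubs["rna_class"] == "lncRNA"]
print(f"hub lncRNAs (degree > 5): {', '.join(lnc_hubs['node'])}")
# XIST leads with 20 miRNA partners and 58 total pairs; TUG1 and
# GABPB1-AS1 tie on degree 10 and are separated by their total pairs.
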