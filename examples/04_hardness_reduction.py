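"""The max-cut correspondence, executably.

Reduces K4 (complete graph on four vertices) to a mutation-design instance:
wild type AAAA, budget 4, empty functional structure, one single-pair
competing structure per edge.  The brute-force optimum of the mutation
objective equals the brute-force max-cut value (4 for K4), and the explicit
assignment "cut side -> G, other side -> C" achieves it.
"""

from rnadel import (
    Graph,
    brute_force_maxcocycle,
    brute_force_maxdelmuts,
    reduce_graph,
)
from rnadel.hardness import gc_script_for_subset, objective

k4 = Graph.from_edges(4, [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)])
inst = reduce_graph(k4)
print(f"reduced instance: wt={inst.wt}, m={inst.m}, "
      f"{len(inst.competing)} single-pair competing structures")

script, value = brute_force_maxdelmuts(inst)
subset, cut = brute_force_maxcocycle(k4)
print(f"best mutation script: {script.name}  (objective {value})")
print(f"max cut of K4: {sorted(subset)}  (value {cut})")

explicit = gc_script_for_subset(k4, subset)
print(f"explicit G/C script:  {explicit.name}  "
      f"(objective {objective(explicit, inst)})")
print(f"objective == cut: {value == cut}")
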