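"""Why report transfer distance: RF saturates on near-misses.

Moving a single leaf across a caterpillar tree makes almost every
bipartition differ (RF near 1) even though each bipartition is one taxon
move away from correct (transfer stays small).
"""

from sparsenj import rf_distance, transfer_distance, quartet_distance
from sparsenj.tree import from_newick


def caterpillar(labels):
    core = f"({labels[0]},{labels[1]})"
    for lab in labels[2:-1]:
        core = f"({core},{lab})"
    return from_newick(f"({core},{labels[-1]});")


labels = [f"a{i:02d}" for i in range(20)]
reference = caterpillar(labels)
mangled = caterpillar(labels)
edge = mangled.remove_leaf(labels[0])
far = mangled.leaf_node(labels[-1])
mangled.insert_leaf(tuple(sorted((far, mangled.neighbors(far)[0]))), labels[0])

rf = rf_distance(reference, mangled)
td = transfer_distance(reference, mangled)
qd = quartet_distance(reference, mangled, mode="exact")
print(f"one leaf moved end-to-end on a 20-taxon caterpillar:")
print(f"  RF distance:       {rf:.3f}  (most splits no longer identical)")
print(f"  transfer distance: {td:.3f}  (each split needs ~1 taxon moved)")
print(f"  quartet distance:  {qd.value:.3f}  (proportion of 4-taxon "
      "subsets disagreeing)")
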