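"""Build a clonality network from a hand-written clonotype table.

Three clonotypes: a dominant clone, its 1-bp CDR3 variant (an SHM
subclone, same V and J), and one unrelated small clone. The variant links
to the major clone; the unrelated clone stays a separate cluster.
"""

from bcrnet import (
    ClonotypeRecord,
    build_network,
    classify_sample,
    clones_from_records,
    find_clusters,
    filter_singleton_clusters,
    score_dominance,
    shm_branching_metrics,
)

records = [
    ClonotypeRecord("demo", "IGH", frozenset({"IGHV1"}), frozenset({"IGHJ4"}),
                    "TGTGCAAGA", 90),
    ClonotypeRecord("demo", "IGH", frozenset({"IGHV1"}), frozenset({"IGHJ4"}),
                    "TGTGCAAGG", 6),   # one substitution away: subclone
    ClonotypeRecord("demo", "IGH", frozenset({"IGHV3"}), frozenset({"IGHJ2"}),
                    "TGTACCGGTACA", 4),  # different rearrangement
]

clones = clones_from_records(records)["IGH"]
net = build_network(clones, "IGH")
clusters = score_dominance(filter_singleton_clusters(find_clusters(net)))

print(f"{net.graph.number_of_nodes()} nodes, {net.graph.number_of_edges()} edge(s)")
for i, cluster in enumerate(clusters):
    metrics = shm_branching_metrics(cluster, net)
    print(f"cluster {i}: {len(cluster.clones)} clone(s), "
          f"{cluster.cluster_reads} reads, fraction {cluster.fraction:.2f}, "
          f"dominant={cluster.dominant} ({cluster.color}), "
          f"subclones={metrics['subclone_count']}")
print("sample label:", classify_sample({"IGH": clusters}).sample_label)
# Expected: the 96-read cluster (fraction 0.96, red) makes the sample
# monoclonal; its one subclone signals somatic hypermutation.
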