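"""From overlapper output (PAF) to a cluster file.

Builds a miniature PAF file of seven reads from two genes, parses it,
clusters the similarity graph and writes the cluster file plus the
read-name sidecar — the same flow as `lrclust cluster overlaps.paf -o
clusters.txt` from the shell.
"""

import itertools
import tempfile
from pathlib import Path

from lrclust import build_graph, cluster_graph, parse_paf, write_clusters
from lrclust.graph_io import write_name_table

gene_a = [f"geneA_read{i}" for i in range(4)]
gene_b = [f"geneB_read{i}" for i in range(3)]


def paf(q, t):  # minimal 12-column overlap record
    return f"{q}\t1200\t0\t800\t+\t{t}\t1100\t50\t850\t600\t800\t60\n"


workdir = Path(tempfile.mkdtemp())
paf_path = workdir / "overlaps.paf"
with open(paf_path, "w") as fh:
    for group in (gene_a, gene_b):
        for q, t in itertools.combinations(group, 2):
            fh.write(paf(q, t))

records = parse_paf(paf_path, min_block_len=100)
sim = build_graph(records)
print(f"{len(records)} overlap records -> graph with "
      f"{sim.graph.number_of_nodes()} reads, {sim.graph.number_of_edges()} edges")

assignment = cluster_graph(sim)
clusters_path = workdir / "clusters.txt"
write_clusters(assignment, clusters_path)
write_name_table(sim.name_to_index, workdir / "clusters.txt.names.tsv")

index_to_name = sim.index_to_name
print(f"\n{clusters_path} (one line per cluster, read indexes):")
print(clusters_path.read_text(), end="")
print("decoded via the name sidecar:")
for cluster in assignment.clusters:
    print("  " + " ".join(index_to_name[i] for i in sorted(cluster)))
# Each gene's reads overlap each other, form a clique in the similarity
# graph, and come back as one cluster per gene.
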