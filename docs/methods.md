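# Methods

## Model and assumptions

The package clusters long transcriptomic reads by gene from a
read-similarity graph alone. The underlying model: every expressed gene
contributes a set of reads that pairwise overlap (shared exons), so in
an ideal similarity graph each gene is a clique; sequencing error makes
the overlapper miss edges, and repeats/paralogy add edges between
unrelated reads. The method therefore scores candidate communities by
*cliqueness* — the local clustering coefficient (ClCo) — rather than
modularity, which is known to struggle with the very heterogeneous
cluster sizes of expression data. Formally it approximates a minimum
k-cut: partition each connected component while removing as few edges as
possible, with the number of communities k and the cliqueness cutoff θ
both estimated from the data by sweeping θ over the observed ClCo values
and keeping the partition of minimal cut.

Key structural assumptions: overlap detection is specific (few spurious
edges, so most edges should survive the cut); a single read should never
be the sole link between two read groups (such articulation points are
treated as suspect bridges and disconnected up front); and all isoforms
of a gene belong in one cluster, so no attempt is made to separate
transcripts within a community.

## Pipeline and parameters

`cluster_graph` runs: optional articulation-point disconnection → per
connected component: node statistics → seed thresholds → cutoff schedule
→ partition sweep → minimum-cut choice. Parameters (all exposed through
`ClusterConfig` and the CLI):

- `rounding` (decimal places, default 2): ClCo values are rounded before
  they define cutoffs, collapsing noise-level differences; the mechanism
  matters more than the value, and 2 dp keeps at most 100 non-zero
  cutoffs without a cap in practice.
- `max_cutoffs` (default 100): upper bound on cutoffs per component;
  when exceeded, ranks are subsampled uniformly keeping both endpoints.
- `preprocess` (default on): disconnect all articulation points of the
  input graph in one pass (no recursion on newly created ones); the
  nodes stay and are reported as singleton clusters. "Disconnect, don't
  delete" preserves the contract that the output partitions every read.
- `percentile_scope` (default `component`): the seed-guard percentiles
  θ₁ (99th of degree) and θ₂ (1st of ClCo) are nearest-rank percentiles
  of the observed values, computed per component since components are
  clustered independently; a global mode exists.
- `threads`: components are independent; the output is identical for any
  thread count.
- `per_node_split` (default off): move intersection nodes one by one
  instead of as a block when splitting.

## Numerical and tie-break choices

Decisions the problem statement leaves open are fixed as follows, in one
place, and deterministically:

- Seed eligibility at cutoff θ: ClCo ≥ θ, with the star guard applied on
  the open interval (θ, θ₂) exactly — a node whose ClCo equals θ or θ₂
  is never guard-excluded.
- The aggregated coefficient for a merge test is computed on the two
  communities' member sets (seed plus neighbourhood at creation, as
  mutated by refinement); sets with fewer than two nodes have
  coefficient 1 by the same convention as degree-≤1 nodes.
- Split side choice: the intersection block goes to the side with more
  edges into its remainder (fewer removals); ties are broken by the
  larger cliqueness gain ΔCC = CC(side) − CC(side minus intersection),
  then by the smaller seed index. If a community's seed is split away,
  the smallest remaining member becomes the seed.
- Pair-resolution order: communities are ranked by decreasing seed
  degree, then decreasing seed ClCo, then increasing index; the best
  community resolves against the next intersecting one in rank order,
  is updated, and continues until it intersects nothing.
- Cut ties across cutoffs go to the larger cutoff — the more
  conservative partition, consistent with the precision-first design.
- Nodes no seed neighbourhood covers become singletons in that
  partition and their severed edges count toward its cut.
- An all-zero ClCo component (e.g. a long cycle) has an empty cutoff
  schedule and is returned as a single community with cut 0.

The refinement engine represents node sets as big-integer bitmasks over
component-local ids (ascending node order), so intersections,
differences and edge counts run at machine-word speed; community edge
counts are maintained incrementally and severed edges are restored
between cutoffs. The bitset engine and a reference implementation over
hash sets produce identical partitions on thousands of randomised
checks; all orderings are explicit, so repeated runs are byte-identical
regardless of thread count.

## Synthetic instances

`simulate` generates planted-partition graphs that emulate the noise
structure the algorithm assumes, with ground truth:

- Cluster sizes are drawn from four bins mirroring expression quartiles
  (≤5, 5–10, 10–50, ≥50 reads; the top bin capped, default 200), a bin
  chosen by weight and the size uniformly within it. The default low
  bin starts at 2 reads; singleton truth clusters can be configured.
- Each intra-cluster edge of the clique is kept independently with
  probability `p_within` (missed overlaps; default 0.9).
- Spurious edges are added between uniformly chosen nodes of distinct
  clusters until they form `spurious_edge_fraction` of all edges
  (repeats/paralogy; default 0.01).
- Optional hub reads attach by a single edge to each of ≥2 clusters,
  reproducing exactly the articulation-point pathology preprocessing
  targets; hubs are singletons in the truth.

What the generator does *not* emulate: sequence content and error
profiles (noise is edge-level i.i.d., whereas real missed overlaps
correlate with read length and position), overlap scores, isoform
structure within a gene, and the component-size distribution of real
data — node-uniform spurious edges concentrate between highly expressed
genes and readily fuse everything into one giant component, which is
harsher than typical post-preprocessing overlap graphs. Passing tests
on these instances therefore demonstrate the algorithm's graph-level
behaviour, not end-to-end accuracy on any particular sequencing run.

## Known limitations

- **Unequal-size absorption.** The aggregated coefficient of the union
  of one large and one small community is dominated by the large side,
  so a small cluster tied to a large one by a few spurious edges can be
  absorbed at cutoffs that the large cluster itself survives; the
  minimum-cut rule then prefers that partition because it avoids cutting
  the spurious edges. On noisy synthetic instances this is the main
  precision cost (the acceptance script computes the resulting
  recall/precision trade-off at the reference conditions), and it grows
  with the density of inter-cluster edges between highly expressed
  genes.
- Articulation-point disconnection sheds the bridging read — and, for
  stars, its satellites — as singletons; on very small true clusters
  this is the main recall cost.
- The cutoff sweep evaluates up to `max_cutoffs` full refinements per
  component; runtime is dominated by the largest component.
- Exact minimum k-cut is NP-hard; the sweep-and-refine procedure is a
  heuristic with no optimality guarantee beyond minimality over the
  generated schedule (which the test suite verifies exhaustively on
  small graphs).

## Test and acceptance problem sizes

The test suite validates the statistics against brute-force oracles on
graphs of up to 12 nodes (ClCo, articulation points) and 30 nodes
(pair-counting metrics, cut accounting, schedule minimality), checks the
hand-derived butterfly example exactly, and runs the full pipeline on
planted instances of 50 noise-free and 100 noisy clusters (about 2,500
and 4,400 reads). `scripts/acceptance.py` re-runs the two pipeline-scale
instances from a user-supplied seed and writes the computed metrics to
JSON; these sizes keep a complete run in tens of seconds on one CPU
while exercising every code path at realistic cluster-size skew.
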