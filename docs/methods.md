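# Methods

This note records the model, the defaults, the numerical conventions and
the deliberate design choices behind `seedext`, in the order the pipeline
runs.

## Weighted network construction

The raw network is an undirected simple graph: self-interactions and
repeated interactions are dropped at load time, and proteins appearing only
in self-loops are not kept as isolated nodes (they can never join a complex
of size ≥ 3).  Identifiers are opaque, case-sensitive strings; no
identifier mapping is attempted.

Edge weights combine two independent evidence channels:

* **Common neighbors.**  $CN(v,u)=\sqrt{|N(v)\cap N(u)|^2/(|N(v)||N(u)|)}$.
  $N(v)$ is the full adjacency set of $v$ — it includes $u$ when $(v,u)$ is
  an edge — so $|N(v)|$ equals the degree; the intersection never contains
  the endpoints themselves.
* **GO-term overlap.**  Terms are compared as flat opaque sets (no ontology
  traversal, no semantic similarity).  The denominator
  $\max(\min(|GO(v)|,|GO(u)|),\overline{GO})$ uses the network-wide mean
  annotation count $\overline{GO}$, computed **once** over the loaded
  network's annotated proteins before any pruning and never recomputed;
  annotated proteins absent from the network do not contribute.  Proteins
  with no annotation simply score 0 on this channel; if *no* network
  protein is annotated the builder logs a warning and falls back to
  topology-only weights rather than failing.

The weight is the arithmetic mean of the two channels.  A zero weight means
neither channel supports the interaction; such edges are deleted as noise
and nodes isolated by the deletion are removed.  Weights are never rounded
and comparisons use exact floating arithmetic with no epsilon — the
algorithm only ever tests strict inequalities on sums of weights, and ties
in *priorities* are broken lexicographically by node id, not by tolerance.

To make results independent of input file line order, the weighted graph is
assembled in sorted node and edge order, fixing the order of every later
floating-point accumulation.  This is what makes detection output
byte-identical under shuffled inputs.

## Seed queue

$Score(v)=d_w(v)\cdot NGCC(v)$ is computed exactly once per node on the
initial weighted network; detection never rescores.  $NGCC$ sums the
weights of all edges among $V_v=\{v\}\cup N(v)$ (each edge once) and
divides by $\binom{|V_v|}{2}$; it is 0 when $|V_v|<2$.  Nodes are queued by
non-increasing score with lexicographic tie-breaking, so the queue is a
deterministic permutation of the nodes.

## Cluster model and growth

A cluster caches its internal and external weighted degrees; single-node
updates adjust both in O(degree) and the test suite verifies the caches
against full recomputation after arbitrary mutation sequences.  Degenerate
cases are pinned: $D$ and $F$ of a singleton are 0, and $M$ is 0 when the
cluster touches no weight at all (both are 0/0 in the defining formulas).
Pinning to 0 makes the first expansion from a seed well defined: any
positive-weight neighbor raises $F$ above 0 and trivially passes the
expectation-edge test, since $F\cdot|SG|=0$.

Growth alternates extend and correct phases until a full pass changes
nothing.  Both phases evaluate the *post-move* cluster for priority
(`weight_avg` of $SG\cup\{p\}$ or $SG\setminus\{p\}$) — the add and remove
phases are treated symmetrically — and both phases stop at the first
failure of the current top-priority candidate rather than falling through
to the next candidate.  Acceptance always requires a strict fitness
increase, with fitness and size taken **before** the move in the
expectation-edge comparison.

The direction of the correct phase's connectivity test is configurable.
The default (`literal`) requires the removed node's actual edges into the
remainder to *exceed* the expectation edge — the same direction as the add
test — and an `inverted` mode requires them to fall short.  Both are
provided because either direction is defensible (the literal form
preferentially removes well-connected nodes, which reads oddly, but the
dominant fitness-increase condition makes the two modes rarely differ in
practice); the package does not guess beyond exposing the switch.

Strict fitness increase over the finite lattice of node subsets guarantees
termination; `max_passes` (default 100) is a pure safety valve and hitting
it logs a warning.  In practice growth converges in 2–3 passes.

Seeds inside an already-kept complex are skipped, but clusters discarded
for being smaller than `min_size` (default 3) do not mark their members
visited — only saved complexes do.  Nodes are never removed from the graph,
so complexes may overlap.  The "fake complex" filter is exactly the size
filter plus exact-duplicate elimination; no further heuristic is applied
because none is defined.  Finally, near-duplicates are suppressed by a
pairwise overlap-score scan in non-increasing fitness order (ties: detection
order): a complex is kept iff its OS with every already-kept complex is
below `redundancy_threshold` (default 0.8).  The OS-based criterion and the
0.8 default are this package's documented convention for the redundancy
step.

## Evaluation

Matching is one-to-many: a predicted complex counts as matched if *any*
reference reaches $OS\ge\omega$ (inclusive boundary), and symmetrically for
references; no bipartite assignment is computed.  Defaults: $\omega=0.2$.
The Jaccard measures weight each complex's best Jaccard coefficient by
complex size and take the harmonic mean of the predicted-side and
reference-side averages.  The reference loader can drop complexes smaller
than 3 (`--min-ref-size`) and removes exact duplicates only.

Enrichment tests each (complex, term) pair with the hypergeometric tail
$P(X\ge k)$, computed via the survival function for numerical stability.
The background $N$ is the analyzed network's protein count (not the
annotation universe), $F$ counts a term's carriers within the network, and
complex members outside the network are excluded from the urn.  Bonferroni
correction is applied per complex over that complex's tested terms,
mirroring per-query web-tool practice; a complex is significant when its
minimum corrected p falls below $\alpha=0.01$.  Summary bins at 1e-15,
1e-10, 1e-5 and $\alpha$ are reported alongside the mean per-complex
minimum p.

## Synthetic benchmark

The generator plants `n_complexes` groups of proteins with internal edge
probability `p_within`, wires all remaining node pairs (including a pool of
background proteins) with probability `p_between`, and gives each complex
`terms_per_complex` private GO terms that each member carries with
probability `annotation_coherence`; background proteins draw 2 terms from a
`noise_terms`-sized noise vocabulary.  With probability `overlap_fraction`
a complex reuses one member of the previously planted complex, producing
overlapping ground truth.  Within-complex edges are resampled until they
connect the complex (a disconnected planted "complex" could never be
recovered as one cluster, so it would measure nothing about the detector);
if 1000 resamples fail, a ring is added — at the default `p_within` this
path is never taken.  All randomness flows through a single seeded numpy
generator, so outputs are byte-identical per seed.

Defaults describe the study conditions used throughout the tests:
10 complexes of 4–8 proteins, `p_within` = 0.9, `p_between` = 0.02,
coherent annotations (coherence 0.9, 3 private terms per complex), 20
background proteins, 15 noise terms, 10% overlap chance.  The density and
coherence values depict a favorable but not degenerate regime — near-clique
complexes, sparse background, most members annotated — chosen to resemble
a small curated interactome rather than to stress the detector.  What the
benchmark does **not** emulate: the heavy-tailed degree distributions of
real interactomes, correlated experimental false positives, incomplete GO
coverage that varies by pathway, and complexes much larger or sparser than
the planted range.  Passing the recovery tests therefore demonstrates
correctness of the machinery under the model's own assumptions, not
field performance on any particular organism's data.

## Problem sizes in the test suite

The formula-oracle comparisons use 100 random graphs of up to 50 nodes
(tolerance 1e-12 against naive reference implementations); hypergeometric
tails are checked against exhaustive subset enumeration for all feasible
arguments with $N\le12$; local optimality of grown clusters is verified by
brute force on graphs of ≤ 12 nodes; recovery is averaged over 20 generator
seeds of the default benchmark.  These sizes keep the full suite to a few
seconds while exercising every code path at scales where independent
enumeration is exact.

## Known limitations

* GO terms are compared as flat sets; no GO-slim mapping or ancestry is
  applied, so annotation granularity directly shapes the GO channel.
* Seed scores are intentionally never refreshed during detection; a node
  absorbed early into a mediocre complex cannot later found a better one
  (only kept complexes block seeds, which limits the effect).
* The greedy growth is locally optimal per seed, not globally optimal; the
  brute-force optimality guarantee in the tests is over single moves.
* The redundancy step is quadratic in the number of candidate complexes.
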