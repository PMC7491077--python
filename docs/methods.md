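# Methods

## Model and procedure

The method treats the cell's interactome as an unweighted mixed graph
`G = (V, E)` with typed edges (PPI, transcriptional, miRNA→mRNA, enzymatic),
directed where the underlying biochemistry is directional.  Given a hit list
`H ⊆ V` and a final-implementer list `F ⊆ V`, it assumes that the molecular
program connecting a perturbation to its phenotype is enriched along *short*
routes from hits to implementers, and that route segments shared by many
(hit, implementer) pairs are the specific backbone of that program.

The pipeline is:

1. **Merge** the input edge tables into one network, removing duplicates and
   applying direction precedence: if any directed edge exists between a node
   pair, undirected edges between that pair are dropped (pairwise, regardless
   of interaction type — parallel edges of *different* types between a pair
   are retained, since path typing needs them).
2. **Collect**, for every ordered pair `(h, f)` with `h ≠ f`, all shortest
   simple paths of length ≤ `L_max`, independently per path type class.
   A path is classified by the strongest-ranked edge type it contains
   (enzymatic > miRNA→mRNA > transcriptional > PPI), giving the four classes
   metabolic, miRNA, transcriptional, protein-protein.  Direction is
   respected during the search; edge type matters only through the class.
3. **Score** node centralities `c(v)` and, over a configured length window,
   subpath centralities `c(q)`, with the degenerate collapse of `c(q)` to 1
   when all support shares one anchor pair and one class.
4. **Permute**: re-run steps 2–3 for `N` random hit lists (implementers held
   fixed), form per-entity empirical p-values `r/N` where `r` counts
   replicates with centrality ≥ observed, BH-adjust nodes and subpaths as two
   separate families, and flag entities with `c ≥ min_centrality` and
   adjusted `p ≤ FDR`.

## Per-class minimality and the search algorithm

The minimum path length is computed independently for each class: a length-1
transcriptional edge between a pair does not suppress that pair's length-4
metabolic route.  Each class corresponds to a cumulative admissible edge-type
subset (PPI; +transcriptional; +miRNA→mRNA; +enzymatic) together with the
constraint that the class's distinguishing type occurs at least once.  For
each implementer and class the engine precomputes two reverse-BFS maps on the
admissible subgraph: the plain walk distance to the implementer and the
shortest walk distance that still has to cross one distinguishing edge (a
layered BFS over states `(node, still-needed)`).  Both are walk distances,
hence admissible lower bounds on the remaining *simple*-path length, and they
prune a depth-first enumeration of all simple paths of an exact target
length.  The target length starts at the lower bound and increases until a
class-exact simple path is found or `L_max` is passed; the first non-empty
level is provably the class minimum, and the enumeration at that level is
exhaustive.  The test suite checks exact set equality against an independent
brute-force enumerator on random mixed graphs.

Because the reverse maps depend only on (network, implementers, `L_max`),
they are computed once and shared across all permutation replicates, which is
what makes 10⁴-replicate runs practical in pure Python.

Degenerate inputs: pairs with `h = f` are skipped (a path has ≥ 1 edge);
identifiers absent from the network are dropped with a warning, and a run
aborts only when *no* hit or no implementer remains.  Ties between
equal-length shortest paths are all kept; output ordering is the total order
(hit, implementer, class, length, node sequence, edge types), so all tables
are deterministic and diffable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `l_max` | 5 interactions | search bound for integrated networks; 4 is customary for PPI-only networks, roughly the network's mean shortest-path length |
| `len_min`–`len_max` | 3–4 | subpath window examined, one to two interactions below `l_max` (2–3 for PPI-only runs) |
| `min_centrality` | 3 | reporting floor; avoids flagging pairs connected only to each other |
| `n_replicates` | 10,000 | permutation count (tests and examples use fewer) |
| `degree_preserving` | true | replace each hit by a node of approximately equal degree |
| `fdr_threshold` | 0.25 | exploratory BH threshold, as in gene-set enrichment practice |
| `count_endpoints` | true | hits/implementers count as lying on their paths |
| `pseudocount` | false | optional `(r+1)/(N+1)` p-values |
| `pool_bh` | false | optional single BH family for nodes + subpaths |

Replicate RNG streams are derived from `(seed, replicate_index)`, so
significance tables are independent of execution order and reproducible
bit-for-bit from the run manifest.

## Degree-preserving sampling

Candidates for a hit of degree `d` are the nodes with exactly degree `d`.  A
bin with fewer than 5 candidates widens symmetrically in increments of
`max(step, round(0.1·step·d))` for up to five steps (≈ ±50% of `d`; the
`max(step, …)` floor lets small degrees, where 10% of `d` rounds to zero,
widen at all).  An empty bin at the cap is fatal.  Replicate lists contain
distinct nodes and may re-draw original hits.  The degree-2 neighbourhood of
a power-law network keeps bins well-populated; exact-degree behaviour (for
tests) is available by constructing `DegreeBins(min_bin=1, max_steps=0)`.

## Empirical p-values and their calibration

`p = r/N` with the ≥ comparison is conservative (super-uniform) for any fixed
entity when the observed hit list is exchangeable with the sampled ones.  Two
subtleties matter when *checking* this by simulation:

- Pooling p-values only over entities that appear in the observed subnetwork
  conditions on appearance and is anti-conservative by construction; the
  calibration therefore tracks **all** network nodes, entities absent from
  the observed path set scoring 0 (p = 1).
- The p-value distribution is discrete and conservative, so a two-sided KS
  test against U(0,1) would reject for the harmless reason that too much mass
  sits at 1.  Calibration uses the one-sided KS statistic D⁺, which detects
  exactly the harmful direction (empirical CDF above the uniform CDF).

Calibration runs use uniform (non-degree-preserving) hit sampling so that
"observed" lists are drawn from precisely the replicate distribution.

## Synthetic data

`generate_network` draws a zipf degree sequence (exponent 2.5, clipped to
`[min_degree, n/10]`), builds a configuration-model graph, simplifies it, and
assigns edge types by a fixed mixture (defaults: 70% PPI, 15% transcriptional,
5% miRNA→mRNA, 10% enzymatic; 30% of PPI edges directed, all other types
directed, miRNA edges re-typed to PPI unless they originate at a
miRNA-labelled node).  These defaults mimic the proportions and direction
semantics of curated interaction databases at desk scale.

`plant_backbone` inserts a directed chain of `backbone_len` edges, wires
`k_hits` random hits to its head and its tail to `n_implementers` random
implementers, and *verifies against the path engine* that the chain route is
a shortest protein-protein path for every pair, re-drawing on bypasses.  With
8 hits and 2 implementers every chain node lies on ≥ 16 anchored shortest
paths, the situation the centrality statistic is designed to reward.

What the synthetic fixtures do **not** emulate: biological edge correlations
(pathway co-membership, date-hub structure), database ascertainment bias,
confidence scores, and identifier noise.  Passing the planted-recovery and
calibration tests therefore demonstrates the statistical machinery — not that
any particular biological interactome meets the method's assumptions.

## Known limitations

- All shortest paths of a class are enumerated; on dense graphs with heavy
  degree ties the number of co-minimal paths (and hence runtime/memory) can
  grow quickly with `L_max`.  The design targets the sparse regime of curated
  interactomes (`L_max ≤ 5`).
- The collapse rule tests the (anchor, class) signature only; two genuinely
  distinct routes between the *same* anchor still collapse to 1.
- Subpath identity is orientation-sensitive as traversed; an optional
  canonicalization of undirected segments is deliberately not applied by
  default, since the two traversal directions of an undirected fragment are
  distinct mechanistic hypotheses.
- An incomplete hit list biases p-values upward for genuinely involved nodes
  (they keep appearing in random lists), so non-significant does not mean
  uninvolved — the FDR 0.25 reporting threshold is exploratory by design.
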