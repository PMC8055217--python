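# Methods

## Tree model

A tumor phylogeny is a rooted, unordered tree whose nodes carry *sets* of
mutation labels; a label may occur on more than one node (poly-occurring),
modeling recurrent acquisition or loss of the same mutation.  Labels are
opaque byte strings compared exactly — no case folding — so a loss event
written with a minus suffix remains distinct from the corresponding gain.
Nodes with an empty label set are permitted with a warning: real inferred
trees frequently have an unlabeled (germline) root, and such nodes shape the
topology — they can serve as LCA points — while contributing no label
occurrences.  Trees are exchanged as GraphViz DOT digraphs (one per file,
edges parent → child, node attribute `label="m1,m2,..."`); a node without a
`label` attribute uses its id as its single label, which matches mutation-tree
files in the wild.  The parser is a small hand-written reader for exactly this
dialect (undirected graphs, forests, and multi-parent nodes are rejected with
diagnostics naming the offending nodes).

## Triple configurations

For an ordered triple of occurrence nodes (u, v, z), the minimal tree
topology is the subtree spanning {u, v, z} and their three pairwise LCAs,
with uninformative degree-2 nodes contracted.  Enumerating every rooted tree
with up to 7 nodes shows there are exactly **5** such configurations for
distinct nodes and **9** when occurrences may coincide — provided one
identification is made: when one of the three nodes strictly dominates the
other two and those two are incomparable, the configuration does not record
whether the lower pair's LCA coincides with the dominating node or lies
strictly below it (the in-between LCA is absorbed into the dominating node).
Without that identification a sixth distinct-node class appears.  The
catalog of five requires it, and it is the natural reading: the in-between
node adds no ancestry information about the three marked occurrences.

Rather than building contracted subtrees, the implementation classifies a
triple in O(1) from three LCA queries as a `TripleSignature`: the three
ordered pairwise ancestry relations (same node / first strictly above /
second strictly above / incomparable) plus the coincidence partition of the
three pairwise LCAs, normalized per the identification above.  The test
suite proves this encoding faithful by exhaustive comparison against an
independent oracle that does materialize the annotated contracted subtree,
over every rooted tree with ≤ 8 nodes and every ordered node triple
(coincidences included): signature equality and subtree isomorphism induce
identical partitions.

Signatures are **slot-ordered**: the signature of (a, b, c) records which
label sits where, because scoring intersects the configuration multisets of
the *same* label triple across two trees.  Quotienting by slot permutation
happens only when counting the unlabeled catalog.

LCA preprocessing is an Euler tour with a sparse-table range-minimum
structure — O(n log n) preprocessing, O(1) per query, vectorized over numpy
index arrays.  Trees in this domain have at most a few thousand nodes, so
preprocessing cost is negligible; the vectorization matters because scoring
touches every label triple.

## Scores

Per label triple, each tree contributes the multiset of signatures over the
full Cartesian product of the three labels' occurrence nodes (no symmetric
deduplication — a label with k occurrences weighs k-fold).  N is the
multiset-intersection cardinality, D the larger multiset's cardinality.
MP3∩ sums N/D-wise over unordered triples of three *distinct* shared labels;
MP3∪ extends the denominator sum to triples from the combined label set,
where a triple containing a label absent from a tree has an empty multiset
on that side (a triple realized in neither tree is 0/0 and skipped).  The
geometric mean and the sigmoid blend (μ = 10 default; μ tunes how sharply
the blend switches between the union- and intersection-dominated regimes)
are derived from the two ratios.  When MP3∪ = 0 but MP3∩ > 0 the blend
formula yields MP3σ = 0; the formula is implemented literally.

ΣN and ΣD are exact integer sums; each score is one floating division, so
invariants (symmetry, MP3∪ ≤ MP3σ ≤ MP3∩, geometric mean between the two)
hold to 1e−12 relative tolerance and symmetry holds exactly.  Fewer than
three shared labels leaves MP3∩ undefined and raises a dedicated error
(surfaced as exit code 3 in the CLI, and as a NaN entry with a warning in
matrix mode); the choice to raise rather than report 0 keeps "undefined"
distinguishable from "maximally dissimilar".

The common case — all three labels singly occurring in both trees — is
scored in bulk with vectorized signature queries; only triples touching a
poly-occurring label take the explicit multiset path.  Union-only triples
never need LCA work: their contribution is the maximum of the two occurrence
products.

## Perturbation simulator

Benchmark families are produced by drawing a configured number of actions
i.i.d. from a probability vector over five operations, each with uniformly
drawn targets: label swap (two labels exchange full occurrence sets), label
removal (all occurrences of one label vanish; an emptied node stays in place
— topology edits are reserved to node operations), label duplication (one
label lands on a node not yet carrying it, creating a poly-occurrence), node
swap (two nodes exchange label sets), node removal (a non-root node is
spliced out, children reattached, labels discarded — relocating them would
conflate node and label operations).  The root is never removed, preserving
rootedness.  A single seeded generator drives operation and target selection
in a fixed order (operation, then targets, per action), so a (tree, config)
pair reproduces byte-identical DOT output.  Inapplicable draws (e.g. node
removal on a single-node tree) are resampled up to a cap of 100 consecutive
failures.  "Label swap" is interpreted as exchanging the two labels' entire
occurrence sets rather than relabeling a single occurrence; the full
exchange keeps the operation an involution and preserves the multiset of
node label-set sizes.

The generator of random base trees attaches each new node uniformly to an
earlier node (random recursive tree), giving the broad, shallow shapes
typical of inferred mutation trees, with one unique label per node and
optionally a Poisson number of extra labels per node to emulate
multi-mutation clonal expansions.  What this emulates: families of trees
related by small edit sequences, with class structure controlled by the
base trees.  What it does not: realistic mutation frequencies, error
profiles of particular callers, or biologically structured recurrence —
passing benchmarks here shows the measure's discriminative behavior under
controlled edits, not calibrated performance on any cohort.

## Problem sizes and defaults

The shipped experiments use: the exhaustive catalog over all rooted trees
with ≤ 7 nodes (≤ 8 for the oracle-equivalence test); a benchmark of 5 base
trees of 20 nodes with 6 perturbed copies each at 3 actions per copy,
uniform probability vector; 200 random pairs for the invariant suite; 50
random trees with ≤ 7 labels for the brute-force cross-check; 10,000
realized draws for the operation-frequency calibration.  These sizes make
every distributional property measurable while keeping the whole suite in
the tens of seconds; all randomness flows through explicit integer seeds.

## Known limitations

- Scoring is O(L³) in the union label count with numpy-vectorized constant;
  a few hundred labels per tree is comfortable, many thousands are not.
- The naive same-node pair statistic reports a *candidate* denominator
  (pairs co-located in at least one tree) whose definition is this package's
  own; only the shared-pair numerator should be compared across tools.
- The degenerate-comparison analysis in `scripts/acceptance.py` uses a
  synthetic multilabeled base tree (so labeled in code and output) rather
  than curated patient data; it demonstrates the near-zero regime, not any
  published patient value.
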