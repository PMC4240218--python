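# Methods

## Model

A persistent perfect phylogeny (p-pp) for an n × m binary matrix M is a
rooted tree T with

1. a length-m 0/1 state vector per node, the root all zeroes;
2. every edge labeled by at least one signed character, the labels being
   exactly the characters whose state changes across the edge;
3. per character at most one gain edge (0→1) and at most one loss edge
   (1→0); when both exist they lie on one root-to-leaf path with the gain
   above the loss;
4. every row of M equal to the state vector of exactly one node.

A character whose root-to-s path crosses its gain and then its loss is
*persistent for s*. A constraint (c, s) forbids any gain of c on the path
to s (hence also any loss); the constrained problem is CPPP.

Species are always rows and characters columns; duplicated rows or columns
are legal and never removed silently (deduplication is an explicit flag
with a name mapping). Two species with identical rows label the same tree
node: the model speaks of nodes, not leaves, and nothing distinguishes the
two rows.

## Extended matrix and completion semantics

Each character c is replaced by the conjugate pair (c⁺, c⁻) over {0, 1, ?}:

* M[s,c] = 1 → (1, 0) — gained, not lost;
* M[s,c] = 0, (c, s) ∈ F → (0, 0) — pinned, never completed otherwise;
* M[s,c] = 0 otherwise → (?, ?) — persistence undecided.

A (?, ?) pair completes to (0, 0) (never had it) or (1, 1) (had it, lost
it). M has a solution iff some completion of the 2m-column matrix admits a
directed perfect phylogeny, i.e. no two columns jointly show the
configurations (0,1), (1,0), (1,1) — equivalently the column supports form
a laminar family. `?` is always serialized as the literal character, never
as a sentinel number.

## Red-black graph and realization

The working state is a bipartite graph on species and characters: a black
edge (s, c) while the pair is (1, 0) and c is unrealized, a red edge once a
pair completes to (1, 1). Realizing c⁺ (c inactive): species outside c's
connected component complete to (0, 0), species inside it without an edge
to c gain a red edge and complete to (1, 1), c's black edges are removed
and c becomes active. Realizing c⁻ requires c active and red-adjacent to
every species of its component; the red edges are removed and c becomes
free. Everything else is impossible, including the constrained case: the
set of species that would receive red edges is computed *before* any
mutation, and if any of them is constrained for c the realization fails
atomically. Isolated vertices are pruned after every realization (they
correspond to trivially solved sub-instances). A *successful c-reduction*
is a signed-character sequence whose realization empties the graph.

Solvers append a trailing c⁺ for every character never realized during the
search (all-zero columns, characters isolated before their gain). Those
realizations find an empty component, complete all remaining pairs to
(0, 0), and keep the "successful reduction ⇒ fully completed matrix"
invariant purely through realization semantics.

Outcome reasons are `free-character`, `active-not-covering`,
`constraint-violation`, plus `sign-mismatch` for a gain of a non-inactive
or a loss of an inactive character (the three canonical reasons do not
cover sign/status disagreement, which sequence replay must reject).

## Red-sigma certificate

A red-sigma — a red path s1–a–s2–b–s3 on two characters and three species —
certifies that no completion of the current state admits a directed perfect
phylogeny. It is detected as two active characters whose red neighborhoods
*properly cross* (nonempty intersection, both differences nonempty): the
crossing of the two loss columns then exhibits the forbidden triple
regardless of any extra 1-entries in the gain columns. The naive "any
4-edge red path" reading would also fire on nested-plus-shared
neighborhoods, which is not a valid certificate; the crossing formulation
is the sound one and is what the tests and the solver use.

## Greedy algorithm (edgeless conflict graph)

The conflict graph joins two characters when their columns induce all four
configurations. When it is edgeless, a solution (if any) is found
greedily. Per iteration, for every nontrivial connected component of the
red-black graph, the maximal *inactive* characters of the containment
order (c < c' iff column(c) ⊆ column(c') with inequality somewhere) are
computed against the poset of the matrix as it stood when the procedure
started; those whose realization is possible are realized. If a component
offers none, the branch has no solution. Afterwards every active character
red-adjacent to its whole component is freed, repeatedly. With F = ∅ a
solution always exists and is found.

Deterministic choices, fixed once:

* realization order inside a batch: decreasing 1-count, equal columns
  consecutive (they are tied in the poset and have identical effects),
  then name;
* components processed in order of their smallest species name;
* maximality is evaluated among characters still inactive *within the
  component*, using the entry-time poset.

Invoked from an interior search state (red edges present), a `None` answer
triggers backtracking in the caller rather than a global "unsat": the
completeness argument starts from a fresh, red-free state and does not
cover arbitrary interior states.

The residual conflict graph at a state is computed from the species and
inactive characters *still present in the graph*, with a 1 exactly where a
black edge remains. A consequence worth knowing: a species whose row is
entirely explained (e.g. an all-zero row) is pruned and stops contributing
the (0, 0) configuration, so a residual can be conflict-free even when the
input matrix was not — that is harmless (the greedy path is validated by
the oracle-agreement tests) and lets the solver take the polynomial route
earlier.

## Search-tree solver

Depth-first over feasible prefixes (at most (2m)! leaves). At a node:
empty graph → solution; red-sigma → prune; residual conflict graph
edgeless → run the greedy solver from the node's state and splice on
success, expand normally on failure; otherwise expand the feasible signed
characters. Child order (our choice; nothing canonical exists): losses
first (they only shrink the graph), then gains with containment-maximal
characters first, then decreasing 1-count, then name. The search stops at
the first solution; no criterion ranks solutions. State is copied per
child — instances here are small and correctness beats cleverness; an
undo-log would be the next step if profiling ever demanded it.
Memoization of visited states is deliberately absent for the same reason.
The node budget defaults to 10⁶; exceeding it returns a distinct
`budget-exceeded` status rather than an answer.

## Tree construction and verification

Construction goes through the completed matrix, not through replaying the
label sequence: group the 2m signed columns by identical support, order
groups by decreasing support size (gains before losses, then name, within
a group), and walk each species' chain through a trie of group prefixes —
the classical all-zero-root construction. Gain columns become gain edges,
loss columns loss edges; node vectors collapse to m states (present =
gained and not lost on the path). The degenerate case where c⁺ and c⁻
share a support (gained and lost "on the same edge", net zero change)
is contracted away: the canceling labels are dropped and label-less edges
merged. Species attach to whichever node matches their row — internal
nodes included, and duplicate rows share one node.

The verifier recomputes everything from the node vectors (root zero, label
sets versus actual state changes, gain/loss counts and their path order,
species placement, constraint paths) and returns violations as data, never
exceptions.

Newick serialization writes edge labels as `[&gains=...,losses=...]` node
comments and species as node names (`|`-separated when a node carries
several); parsing goes through dendropy, and node vectors are reconstructed
from the annotations, making the format lossless for verification.

## Oracle

The oracle enumerates all 2^q completions of the q remaining (?, ?) pairs
(in species/character name order, vectorized in blocks of 4096) and tests
each with the pairwise-column criterion; default limit q ≤ 20. It shares
only the extended-matrix type with the solvers — no red-black machinery —
so agreement between the two is a genuine two-route check. The pairwise
criterion itself is validated in the tests against an exhaustive
forest-enumeration oracle on small matrices.

## Simulator

`generate_pp_matrix` draws a random genealogy by uniform pairwise
coalescence of n lineages and drops each of m mutations on a uniformly
random branch; a column is the clade below its mutation, so the matrix
always admits a directed perfect phylogeny. Duplicated rows and columns
arise naturally (and can be forced with the `duplicate_row_rate` /
`duplicate_col_rate` knobs, which overwrite trailing rows/columns with
copies — the matrix stays conflict-free). `inject_back_mutations` flips
exactly one uniformly chosen entry of every row that repeats an earlier
row (a probabilistic "at most one" variant exists behind a flag; the
strict default maximizes the back-mutation signal). Constraints are
sampled uniformly from the zero cells.

What the generator does *not* emulate: recombination, recurrent mutation
beyond the single flip per duplicated row, mutation-rate heterogeneity,
and real haplotype ascertainment. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
goodness-of-fit of the persistent model to any particular biological data
set.

## Problem sizes and determinism

All randomized components take explicit integer seeds; sub-seeds are
derived arithmetically so one integer reproduces an entire experiment.
The shipped experiment sizes are chosen for a desk-scale run: oracle
cross-checks at n, m ≤ 5 with up to 2 constraints (where exhaustive
enumeration is exact and fast), greedy/lemma checks at n ≈ 7–8, m ≈ 8–10,
and the protocol harness at n = 10, m ∈ {5, 7, 10} with 20 replicates and
a 200 000-node budget. Larger runs only need larger arguments.

## Known limitations

* The search tree is exponential in m in the worst case; the node budget
  makes that explicit rather than hiding it.
* The oracle refuses instances with more than `limit` incomplete pairs; it
  exists to test, not to solve.
* The greedy algorithm's completeness from interior search states is not
  established; the solver treats its interior failures conservatively
  (expand normally), trading speed for completeness.
* Multi-state characters and general set-valued compatibility are out of
  scope; only the {1}/{0}/{0,2} export with transitions 0→1, 1→2 is
  provided (`cppp.io.export_gcc`), without a solver for it.
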