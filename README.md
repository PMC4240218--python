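# cppp — constrained persistent perfect phylogeny

Tools for explaining binary character data with a **persistent perfect
phylogeny**: a rooted tree in which every character is gained on at most one
edge (0 → 1) and lost on at most one edge (1 → 0), the loss lying below the
gain on the same root-to-leaf path. The model relaxes the infinite-sites
assumption just enough to absorb back mutations — the situation faced with
protein-domain evolution (a domain acquired and later shed), tumor marker
data, and haplotype matrices that fail the classical perfect-phylogeny test.

On top of the plain model, *forbidden-persistence constraints* can be
imposed: a pair (c, s) demands that neither species s nor any of its
ancestors ever carried character c. The resulting decision/construction
problem is the **Constrained Persistent Perfect Phylogeny (CPPP)** problem,
equivalent to the open {1}/{0}/{0,2} case of general character
compatibility with transitions 0→1 and 1→2.

## What is inside

Given an n × m binary matrix M (rows = species, columns = characters) and a
constraint set F:

* **Extended matrix** — each character c becomes a conjugate column pair
  (c⁺, c⁻) over {0, 1, ?}; M[s,c] = 1 ↦ (1, 0), a constrained 0 ↦ (0, 0),
  any other 0 ↦ (?, ?). M has a (constrained) persistent phylogeny iff the
  ? pairs can be completed so that the 2m-column matrix admits a directed
  perfect phylogeny (`cppp.matrix`).
* **Red-black graph and realization** — the solver's working state: black
  edges record unresolved 1-entries, red edges persistence completions.
  Realizing c⁺/c⁻ is the paper-and-pencil graph operation made executable;
  a sequence of signed characters that empties the graph (a *successful
  c-reduction*) is exactly an edge-label DFS of a solution tree
  (`cppp.graphs`).
* **Greedy polynomial solver** for instances whose conflict graph (an edge
  when two columns exhibit all four configurations 00, 01, 10, 11) is
  edgeless: realize the maximal characters of the containment order
  component by component, then free saturated actives (`cppp.edgeless`).
  Unconstrained conflict-free instances are *always* solvable.
* **Search-tree solver** for the general case: DFS over feasible
  c-reduction prefixes, pruned by the red-sigma certificate (two active
  characters with properly crossing red neighborhoods) and short-circuited
  through the greedy solver when the residual conflict graph becomes
  edgeless; fixed-parameter in m (`cppp.search`).
* **Tree builder + verifier** — construct the phylogeny from the completed
  matrix, check any tree against the model axioms and the constraints,
  round-trip through annotated Newick (`cppp.phylogeny`).
* **Exhaustive oracle** — decides small instances by enumerating all 2^q
  completions; fully independent of the graph machinery (`cppp.oracle`).
* **Simulator** — coalescent-style infinite-sites matrices, back-mutation
  injection on duplicated rows, random constraints (`cppp.simulate`).
* **CLI** — `cppp solve | verify | simulate | oracle | conflicts`.

## Worked example

The smallest interesting instance is the "sigma" matrix — three species,
two characters, no directed perfect phylogeny because the two columns
cross:

```
1 0        s1 has c1
1 1        s2 has c1 and c2
0 1        s3 has c2
```

```sh
$ cppp solve sigma.txt
status: solution
nodes explored: 1
c-reduction: c1+ c2+ c1-
(((s3[&losses=c1])s2[&gains=c2])s1[&gains=c1]);
```

The c-reduction says: gain c1, gain c2, then lose c1. The Newick output is
the chain root —c1⁺→ s1(10) —c2⁺→ s2(11) —c1⁻→ s3(01): character c1 is
*persistent* for s3 — s3 descends from ancestors that carried c1 and lost
it. Forbid exactly that (and the symmetric option for c2) and the instance
becomes infeasible:

```sh
$ cat sigma.f
s3 c1
s1 c2
$ cppp solve sigma.txt --constraints sigma.f
status: no-solution
```

The same instance through the library:

```python
from cppp import BinaryMatrix, ConstraintSet, solve_cppp, to_newick, verify

M = BinaryMatrix([[1, 0], [1, 1], [0, 1]])
res = solve_cppp(M)
print(res.status)                      # solution
print([str(x) for x in res.reduction])  # ['c1+', 'c2+', 'c1-']
print(res.completed.pair("s3", "c1"))  # (1, 1)  <- persistence completion
print(verify(res.tree, M))             # []      <- no violations
```

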