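# Methods

## Model

A design problem is a tuple (residues, E_template, E_i, E_ij, d_min): an
ordered list of mutable positions with ≥ 1 rotamers each, a constant
template energy, one-body energies per rotamer (rotamer-internal plus
rotamer-to-template contributions folded together), and a pairwise energy
matrix per residue pair, all in kcal/mol. Rotamer-to-template terms live in
the one-body vector deliberately: edge cutoffs apply only to residue-pair
edges, never to one-body or template terms. The optional distance matrix
stores d_min(i, j), the minimum Euclidean distance between any atoms of the
two residues over all allowed rotamer pairs; when absent it is computed
from per-rotamer pseudo-atom coordinates (whatever atoms are provided —
the model is agnostic about hydrogens). Conformations are tuples of
rotamer indices; the full energy sums all n(n−1)/2 pairwise terms, the
sparse energy only those on the edges of an interaction graph. With the
full graph the two coincide to machine precision.

## Graph cutoffs

Both cutoffs use strict inequalities, keeping boundary-equal pairs: a
distance cutoff δ deletes edge (i, j) iff d_min(i, j) > δ; an energy cutoff
α deletes it iff max_{r,s} |E_ij(r, s)| < α. Consequences: δ = ∞ and α = 0
both return the full graph, edges are monotone in either cutoff, and every
energy-deleted edge has per-edge max |E| < α by construction. Per-edge
extrema for cutoffs and statistics are computed over **all** rotamers at
graph-construction time (before any pruning), so a graph is a function of
the problem and the cutoff alone; the gap bound below optionally tightens
its extrema to unpruned rotamers.

## Dead-end elimination

Goldstein singles with an energy window E_w ≥ 0, iterated to fixpoint with
a deterministic sweep (residues ascending, rotamers ascending): rotamer r
at residue i is pruned when some unpruned competitor t satisfies

    E_i(r) − E_i(t) + Σ_{j≠i, (i,j)∈G} min_{s unpruned} [E_ij(r,s) − E_ij(t,s)] > E_w.

The sum runs over the edges of the graph G the subsequent search will use.
Guarantee (oracle-tested): no conformation with G-energy within E_w of the
G-GMEC uses a pruned rotamer, so a window-E_w gap-free enumeration over the
unpruned space is still exhaustive. Singles-only is the minimal variant
that preserves this window guarantee; pairs/splits pruning, DACS and
continuous-rotamer criteria are out of scope. A residue can never lose all
rotamers: its current best rotamer scores ≤ 0 against every competitor.

## Gap-free enumeration

A* over rotamer assignments with a static ascending residue order. For a
prefix of length m, g is the exact energy of the assigned interactions
(template counted once at the root) and the admissible completion bound is

    h = Σ_{j≥m} min_s [ E_j(s) + Σ_{i<m, (i,j)∈G} E_ij(r_i, s)
                        + Σ_{m≤k<j, (k,j)∈G} min_t E_kj(t, s) ],

the classical one-position relaxation: each unassigned residue pays its
best one-body term, exact interactions to the assigned prefix, and
optimistic minima to unassigned partners (each such edge charged once, at
its larger endpoint). The heap key is (f, assignment-prefix); tuple
comparison breaks f-ties lexicographically on the rotamer-index vector,
which makes equal-energy conformations emerge in lexicographic order and
the stream fully deterministic. Because prefixes of a lex-smaller
equal-energy conformation are themselves lex-smaller and admissibly
bounded, the tie order is global, and the same (energy, lexicographic)
comparator in the brute-force oracle makes the two streams element-wise
comparable — the basis of the oracle-equivalence tests. Window semantics:
enumeration is exhaustive up to (first energy + window); the window is
measured from the stream's first conformation, i.e. the graph's GMEC.
Since suffix minima only depend on the prefix *length* under a static
order, the per-(k, j) minima are pre-accumulated once per search.

## Bounding the sparse gap and recovering both GMECs

For omitted edge set Ω, let Ω_min = Σ min_{r,s} E_ij and
Ω_max = Σ max_{r,s} E_ij, and B = Ω_max − Ω_min ≥ 0. For the sparse GMEC
c_s and full GMEC c_f:

    E_sparse(c_f) = E_full(c_f) − Ω(c_f)
                 ≤ E_full(c_s) − Ω_min
                 = E_sparse(c_s) + Ω(c_s) − Ω_min
                 ≤ E_sparse(c_s) + B.

So a gap-free sparse enumeration with window B contains both GMECs, and
the lowest-full-energy member of that list is provably the full GMEC.
Re-ranking k conformations costs exactly k(n(n−1)/2 + n) energy-term
evaluations (an instrumented counter verifies this in the tests).
Energy-bounding enumeration runs Sparse A* with window B and a conformation
cap (default 1000 — in practice the full GMEC surfaces far earlier than the
bound requires, a looseness the experiment reports quantify as observed gap
versus B); `window_covered` records whether the window was exhausted before
the cap, i.e. whether the returned full GMEC is certified or best-so-far.
When a pruning state is supplied the per-edge extrema are taken over
unpruned rotamers only — tighter and still sound, since pruning soundness
keeps every conformation the bound argument touches in the search space.

## Pipeline modes

* **standard** (default): DEE on the full graph, then sparse-graph
  construction, then Sparse A*. This mirrors common practice but does not
  by itself guarantee the sparse GMEC survives full-graph pruning.
* **provable**: DEE w.r.t. the sparse graph with window
  E_w ≥ B, which guarantees neither GMEC is pruned.

Every experiment row records which mode produced it.

## Synthetic problems

The generator emulates the geometry that makes cutoffs interesting, not
protein physics. Residue centres are scattered uniformly in a cube sized so
the expected nearest-neighbour spacing matches the regime preset — core
5 Å / 10% charged rotamers, boundary 7 Å / 30%, surface 9 Å / 60% — echoing
how buried, interfacial and solvent-exposed design positions differ in
packing and polarity. Each rotamer is 1–4 pseudo-atoms jittered
(sd 1.2 Å) about its centre; charged rotamers carry ±0.4–0.8 e split across
atoms. Pairwise energies are a Lennard-Jones-like 4ε[(σ/r)¹² − (σ/r)⁶] term
(ε = 0.15, σ = 3.2 Å, distances floored at 0.5 Å, per-pair sum capped at
+10 kcal/mol so clashes do not dominate DEE) plus a Coulomb-like k·q₁q₂/r
term with k = 20 kcal·Å/mol, chosen so typical charged long-range terms
fall in ≈ 0.05–0.9 kcal/mol. One-body energies are Gaussian noise with
sd 1.0 kcal/mol — the scale of rotamer self-energy spreads, and large
enough that omitted tenths-of-kcal/mol interactions flip optima only
sometimes, which is the regime where full-vs-sparse comparisons are
informative. What the generator does **not** emulate: force-field
energetics, rotamer libraries, amino-acid-specific chemistry beyond a
charge flag, backbone context. Passing tests therefore certify the
*algorithms* (ordering, gap-freeness, pruning soundness, bound validity —
which hold for arbitrary finite energy tables) on this family, and the
regime trends are qualitative statements about the generator, not about
proteins.

## Numerical conventions

Energies are float64 kcal/mol; comparisons in tests use absolute tolerance
1e-9. The enumeration window accepts energies up to threshold + 1e-12 so a
conformation exactly at the bound is never dropped to rounding. Equal-energy
orderings are lexicographic in rotamer indices everywhere (A*, oracle);
full-energy re-rank ties go to the earlier stream position. Residue indices
are 0-based in code and JSON; report writers echo the informational residue
labels. JSON serialisation writes floats at repr precision, so a round trip
reproduces energies bit-identically. Problem sizes in the shipped test and
acceptance runs (≤ 8 residues, ≤ 6 rotamers per residue, 20 problems per
regime) are chosen so brute-force oracles can verify every claim
exhaustively; all algorithms accept larger instances unchanged.

## Known limitations

Singles-only DEE can leave large unpruned spaces on frustrated instances;
A* memory grows with the heap (no memory-bounded variant); the omitted-edge
bound is often loose (by design it is a worst case over rotamer pairs), so
certified windows can be much larger than the rank at which the full GMEC
actually appears; the standard mode's full-graph pruning can in
principle remove the sparse GMEC (use provable mode when that matters).
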