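"""Design-problem data model and the two conformation energy functions.

A design problem fixes, for each mutable residue position, a discrete set of
rotamers (side-chain conformations, each labelled with an amino-acid identity
and optionally carrying pseudo-atom coordinates), together with a pairwise
energy function in kcal/mol:

    E(c) = E_template + sum_i E_i(r_i) + sum_{i<j} E_ij(r_i, r_j)

The *full* energy sums pairwise terms over all residue pairs; the *sparse*
energy restricts the pairwise sum to the edges of a residue interaction
graph.  The Global Minimum Energy Conformation (GMEC) of either energy is
the rotamer assignment minimising it.

Conformations are plain tuples of per-residue rotamer indices; sequences are
tuples of 3-letter amino-acid codes derived from the chosen rotamers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import DistanceUnavailableError, InvalidConformationError

Conformation = Tuple[int, ...]
AminoSequence = Tuple[str, ...]

STANDARD_AMINO_ACIDS = frozenset(
    [
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    ]
)


@dataclass(frozen=True)
class Rotamer:
    """One discrete side-chain conformation with an amino-acid identity.

    ``atoms`` is an (m, 3) array of pseudo-atom coordinates in Angstrom and
    may be empty when the problem supplies a precomputed distance matrix.
    """

    id: str
    amino_acid: str
    atoms: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "atoms", atoms)


@dataclass(frozen=True)
class Residue:
    """A mutable design position: an informational label plus >= 1 rotamers."""

    label: str
    rotamers: Tuple[Rotamer, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotamers", tuple(self.rotamers))


class EnergyTermCounter:
    """Counts one-body and pairwise energy-term evaluations.

    Used to verify the O(k n^2) cost accounting of full-energy re-ranking:
    each full-energy evaluation touches exactly n one-body terms and
    n(n-1)/2 pairwise terms.
    """

    def __init__(self) -> None:
        self.one_body = 0
        self.pairwise = 0

    def reset(self) -> None:
        self.one_body = 0
        self.pairwise = 0

    @property
    def total(self) -> int:
        return self.one_body + self.pairwise


class DesignProblem:
    """A rotamer-based protein design problem.

    Parameters
    ----------
    residues:
        Ordered residue positions, each with at least one rotamer.
    e_template:
        Constant backbone/template energy in kcal/mol, added once to every
        conformation energy.
    one_body:
        Per-residue vectors of one-body energies ``E_i(r)`` (rotamer-internal
        plus rotamer-to-template terms folded together), kcal/mol.
    pairwise:
        Mapping ``(i, j) -> matrix`` for every ordered pair ``i < j``; entry
        ``[r, s]`` is ``E_ij(r, s)`` in kcal/mol.  Lookups with ``j > i``
        transpose indices.
    d_min:
        Optional symmetric matrix of minimum inter-residue distances in
        Angstrom.  When absent, distances are computed from rotamer atoms.
    """

    def __init__(
        self,
        residues: Sequence[Residue],
        e_template: float,
        one_body: Sequence[np.ndarray],
        pairwise: dict,
        d_min: Optional[np.ndarray] = None,
    ) -> None:
        self.residues: Tuple[Residue, ...] = tuple(residues)
        self.e_template = float(e_template)
        self.one_body = [np.asarray(v, dtype=float) for v in one_body]
        self.pairwise = {
            (int(i), int(j)): np.asarray(m, dtype=float) for (i, j), m in pairwise.items()
        }
        self.d_min = None if d_min is None else np.asarray(d_min, dtype=float)
        self.counter = EnergyTermCounter()

    # -- basic structure ---------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def n_rotamers(self, i: int) -> int:
        return len(self.residues[i].rotamers)

    def rotamer_counts(self) -> Tuple[int, ...]:
        return tuple(self.n_rotamers(i) for i in range(self.n_residues))

    def conformation_count(self) -> int:
        return math.prod(self.rotamer_counts())

    def all_pairs(self) -> Iterable[Tuple[int, int]]:
        n = self.n_residues
        return ((i, j) for i in range(n) for j in range(i + 1, n))

    def pair_energy(self, i: int, r: int, j: int, s: int) -> float:
        """E_ij(r, s); symmetric in the residue arguments."""
        if i < j:
            return float(self.pairwise[(i, j)][r, s])
        return float(self.pairwise[(j, i)][s, r])

    def validate_conformation(self, conf: Conformation) -> None:
        if len(conf) != self.n_residues:
            raise InvalidConformationError(
                f"conformation length {len(conf)} != {self.n_residues} residues"
            )
        for i, r in enumerate(conf):
            if not 0 <= r < self.n_rotamers(i):
                raise InvalidConformationError(
                    f"rotamer index {r} out of range for residue {i}"
                )

    # -- energies ----------------------------------------------------------
    def full_energy(self, conf: Conformation) -> float:
        """Total energy over the complete interaction graph (Eq. above).

        Exactly n one-body and n(n-1)/2 pairwise terms are summed; the
        instrumented counts accumulate in ``self.counter``.
        """
        self.validate_conformation(conf)
        e = self.e_template
        n = self.n_residues
        for i in range(n):
            e += self.one_body[i][conf[i]]
        self.counter.one_body += n
        for i in range(n):
            for j in range(i + 1, n):
                e += self.pairwise[(i, j)][conf[i], conf[j]]
        self.counter.pairwise += n * (n - 1) // 2
        return float(e)

    def sparse_energy(self, conf: Conformation, graph) -> float:
        """Energy with the pairwise sum restricted to the graph's edges.

        With the full graph this equals :meth:`full_energy` exactly.
        """
        from .graph import InteractionGraph  # local import to avoid cycle

        if not isinstance(graph, InteractionGraph):
            raise TypeError("graph must be an InteractionGraph")
        graph.check_problem(self)
        self.validate_conformation(conf)
        e = self.e_template
        for i in range(self.n_residues):
            e += self.one_body[i][conf[i]]
        self.counter.one_body += self.n_residues
        for i, j in graph.edges:
            e += self.pairwise[(i, j)][conf[i], conf[j]]
        self.counter.pairwise += len(graph.edges)
        return float(e)

    def sequence(self, conf: Conformation) -> AminoSequence:
        """Amino-acid sequence encoded by a conformation."""
        self.validate_conformation(conf)
        return tuple(self.residues[i].rotamers[r].amino_acid for i, r in enumerate(conf))

    # -- geometry ----------------------------------------------------------
    def min_pairwise_distance(self, i: int, j: int) -> float:
        """d_min(i, j): minimum distance between any atoms of residues i and
        j over all allowed rotamer pairs, in Angstrom.

        Uses the precomputed matrix when supplied, else the rotamer atom
        coordinates; symmetric by construction.
        """
        if i == j:
            raise ValueError("d_min is defined for distinct residues only")
        if self.d_min is not None:
            return float(self.d_min[i, j])
        atoms_i = [rot.atoms for rot in self.residues[i].rotamers]
        atoms_j = [rot.atoms for rot in self.residues[j].rotamers]
        if any(a.shape[0] == 0 for a in atoms_i) or any(a.shape[0] == 0 for a in atoms_j):
            raise DistanceUnavailableError(
                f"residues {i},{j}: no distance matrix and a rotamer without atoms"
            )
        ai = np.concatenate(atoms_i, axis=0)
        aj = np.concatenate(atoms_j, axis=0)
        diff = ai[:, None, :] - aj[None, :, :]
        return float(np.sqrt((diff * diff).sum(axis=2)).min())


# -- module-level operation aliases ----------------------------------------

def full_energy(conf: Conformation, problem: DesignProblem) -> float:
    return problem.full_energy(conf)


def sparse_energy(conf: Conformation, problem: DesignProblem, graph) -> float:
    return problem.sparse_energy(conf, graph)


def conformation_sequence(conf: Conformation, problem: DesignProblem) -> AminoSequence:
    return problem.sequence(conf)


def min_pairwise_distance(problem: DesignProblem, i: int, j: int) -> float:
    return problem.min_pairwise_distance(i, j)


def validate_problem(problem: DesignProblem) -> list:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    report: list[str] = []
    n = problem.n_residues
    if n < 1:
        report.append("problem has no residues")
        return report
    for i, res in enumerate(problem.residues):
        if len(res.rotamers) < 1:
            report.append(f"residue {i} has no rotamers")
        for rot in res.rotamers:
            if not rot.id:
                report.append(f"residue {i}: rotamer with empty id")
            if rot.amino_acid not in STANDARD_AMINO_ACIDS:
                report.append(
                    f"residue {i}: unknown amino-acid code {rot.amino_acid!r}"
                )
            if rot.atoms.size and not np.all(np.isfinite(rot.atoms)):
                report.append(f"residue {i}: rotamer {rot.id} has non-finite coordinates")
        ids = [rot.id for rot in res.rotamers]
        if len(set(ids)) != len(ids):
            report.append(f"residue {i}: duplicate rotamer ids")
    if not np.isfinite(problem.e_template):
        report.append("non-finite energy: e_template")
    if len(problem.one_body) != n:
        report.append("one_body length != residue count")
    else:
        for i, v in enumerate(problem.one_body):
            if v.shape != (problem.n_rotamers(i),):
                report.append(f"one_body[{i}] has wrong shape {v.shape}")
            elif not np.all(np.isfinite(v)):
                report.append(f"non-finite energy: one_body[{i}]")
    for i in range(n):
        for j in range(i + 1, n):
            m = problem.pairwise.get((i, j))
            if m is None:
                report.append(f"missing pairwise term: pair ({i},{j})")
                continue
            want = (problem.n_rotamers(i), problem.n_rotamers(j))
            if m.shape != want:
                report.append(
                    f"missing pairwise term: pair ({i},{j}) has shape {m.shape}, want {want}"
                )
            elif not np.all(np.isfinite(m)):
                report.append(f"non-finite energy: pairwise ({i},{j})")
    extra = set(problem.pairwise) - {(i, j) for i in range(n) for j in range(i + 1, n)}
    for pair in sorted(extra):
        report.append(f"unexpected pairwise entry {pair} (need i < j within range)")
    if problem.d_min is not None:
        d = problem.d_min
        if d.shape != (n, n):
            report.append(f"d_min matrix has wrong shape {d.shape}")
        else:
            if not np.allclose(d, d.T):
                report.append("d_min matrix not symmetric")
            off = d[~np.eye(n, dtype=bool)] if n > 1 else np.zeros(0)
            if off.size and (np.any(off < 0) or not np.all(np.isfinite(off))):
                report.append("d_min matrix has negative or non-finite entries")
    return report
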