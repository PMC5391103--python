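"""Residue interaction graphs and the distance / energy edge cutoffs.

The *full* graph is the complete graph over design positions: every pairwise
energy term is part of the energy function.  A *sparse* graph drops edges,
either because the two residues are geometrically distant in every allowed
rotamer pair (distance cutoff delta) or because no rotamer pair interacts
strongly (energy cutoff alpha).  Both cutoffs use strict inequalities:
an edge is deleted iff d_min(i, j) > delta, or iff max_{r,s} |E_ij(r, s)| <
alpha; boundary-equal pairs are kept.  Cutoffs only ever remove pairwise
edges — one-body and template terms are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Tuple

import numpy as np
import pandas as pd

from .errors import GraphMismatchError
from .problem import DesignProblem

Edge = Tuple[int, int]


@dataclass(frozen=True)
class InteractionGraph:
    """A set of unordered residue pairs (i < j) over ``n`` residues."""

    n: int
    edges: FrozenSet[Edge]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < self.n):
                raise ValueError(f"bad edge ({i},{j}) for n={self.n}")
        object.__setattr__(self, "edges", frozenset(self.edges))

    @classmethod
    def full(cls, n: int) -> "InteractionGraph":
        return cls(n, frozenset((i, j) for i in range(n) for j in range(i + 1, n)))

    @property
    def n_possible_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def is_full(self) -> bool:
        return len(self.edges) == self.n_possible_edges

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def deleted_edges(self) -> FrozenSet[Edge]:
        all_pairs = frozenset(
            (i, j) for i in range(self.n) for j in range(i + 1, self.n)
        )
        return all_pairs - self.edges

    def neighbors(self, i: int) -> Tuple[int, ...]:
        return tuple(
            sorted(j for j in range(self.n) if j != i and self.has_edge(i, j))
        )

    def check_problem(self, problem: DesignProblem) -> None:
        if self.n != problem.n_residues:
            raise GraphMismatchError(
                f"graph has {self.n} vertices but problem has {problem.n_residues} residues"
            )

    def to_json_dict(self) -> dict:
        return {"n": self.n, "edges": sorted(list(e) for e in self.edges)}

    @classmethod
    def from_json_dict(cls, doc: dict) -> "InteractionGraph":
        return cls(int(doc["n"]), frozenset((int(i), int(j)) for i, j in doc["edges"]))


@dataclass
class EdgeStats:
    """Edge-deletion statistics for a sparse graph.

    ``per_edge`` maps each deleted edge to its signed min, signed max and
    max-absolute pairwise energy over all rotamer pairs.
    """

    pct_deleted: float
    per_deleted_edge_min_e: Dict[Edge, float] = field(default_factory=dict)
    per_deleted_edge_max_e: Dict[Edge, float] = field(default_factory=dict)
    per_deleted_edge_max_abs_e: Dict[Edge, float] = field(default_factory=dict)


def build_full_graph(problem: DesignProblem) -> InteractionGraph:
    return InteractionGraph.full(problem.n_residues)


def apply_distance_cutoff(problem: DesignProblem, delta: float) -> InteractionGraph:
    """Delete every edge whose minimum inter-residue distance exceeds delta (Angstrom)."""
    n = problem.n_residues
    kept = frozenset(
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if problem.min_pairwise_distance(i, j) <= delta
    )
    return InteractionGraph(n, kept)


def apply_energy_cutoff(problem: DesignProblem, alpha: float) -> InteractionGraph:
    """Delete every edge whose max absolute pairwise energy is below alpha (kcal/mol)."""
    n = problem.n_residues
    kept = frozenset(
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.abs(problem.pairwise[(i, j)]).max() >= alpha
    )
    return InteractionGraph(n, kept)


def edge_deletion_stats(problem: DesignProblem, graph: InteractionGraph) -> EdgeStats:
    """Percentage of deleted edges plus per-deleted-edge energy extrema."""
    graph.check_problem(problem)
    n = problem.n_residues
    if n < 2:
        raise ValueError("edge-deletion percentage undefined for n < 2")
    deleted = sorted(graph.deleted_edges())
    stats = EdgeStats(pct_deleted=100.0 * len(deleted) / graph.n_possible_edges)
    for e in deleted:
        m = problem.pairwise[e]
        stats.per_deleted_edge_min_e[e] = float(m.min())
        stats.per_deleted_edge_max_e[e] = float(m.max())
        stats.per_deleted_edge_max_abs_e[e] = float(np.abs(m).max())
    return stats


def edge_stats_table(problem: DesignProblem, graph: InteractionGraph) -> pd.DataFrame:
    """Per-edge CSV-ready table: (i, j, deleted, d_min, min_e, max_e, max_abs_e)."""
    rows = []
    for i, j in sorted(
        (i, j) for i in range(problem.n_residues) for j in range(i + 1, problem.n_residues)
    ):
        m = problem.pairwise[(i, j)]
        try:
            d = problem.min_pairwise_distance(i, j)
        except Exception:
            d = np.nan
        rows.append(
            {
                "i": i,
                "j": j,
                "deleted": not graph.has_edge(i, j),
                "d_min": d,
                "min_e": float(m.min()),
                "max_e": float(m.max()),
                "max_abs_e": float(np.abs(m).max()),
            }
        )
    return pd.DataFrame(rows)


def save_edge_stats_csv(problem: DesignProblem, graph: InteractionGraph, path) -> None:
    edge_stats_table(problem, graph).to_csv(Path(path), index=False, float_format="%.6f")
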