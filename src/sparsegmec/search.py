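"""Gap-free, in-order conformation enumeration by A* over rotamer assignments.

The same search runs under any residue interaction graph: with the full
graph it is classic protein-design A* whose first solution is the full GMEC;
with a sparse graph it is Sparse A*, whose first solution is the sparse
GMEC and whose stream is gap-free and non-decreasing in *sparse* energy.

Residues are assigned in static ascending order, so a search node is a
prefix of rotamer choices.  Node cost f = g + h, with g the exact energy of
the assigned prefix (template + assigned one-body + assigned-pair edges in
the graph) and h the classical admissible completion bound

    h = sum_{unassigned j} min_s [ E_j(s)
          + sum_{assigned i, (i,j) in G} E_ij(r_i, s)
          + sum_{unassigned k < j, (k,j) in G} min_t E_kj(t, s) ]

Ties in f are broken lexicographically on the rotamer-index prefix (tuple
comparison in the heap), which makes equal-energy conformations emerge in
lexicographic order and the whole stream deterministic.

``brute_force_enumerate`` is the exhaustive oracle with the identical
(energy, lexicographic) order, used to verify the A* stream element-wise.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import EmptySearchSpaceError, OracleTooLargeError
from .graph import InteractionGraph
from .problem import Conformation, DesignProblem
from .pruning import PruningState

TERMINATION_WINDOW = "window_exhausted"
TERMINATION_COUNT = "count_cap"
TERMINATION_EXHAUSTED = "space_exhausted"


@dataclass
class EnumerationStream:
    """An in-order, gap-free list of (conformation, graph-energy) pairs."""

    items: List[Tuple[Conformation, float]]
    termination: str
    graph: InteractionGraph

    def __len__(self) -> int:
        return len(self.items)

    def conformations(self) -> List[Conformation]:
        return [c for c, _ in self.items]

    def energies(self) -> List[float]:
        return [e for _, e in self.items]


class _AstarContext:
    """Per-search precomputation: unpruned rotamer lists, pairwise lookup
    tables restricted to graph edges, and suffix-cumulated pair minima for
    the heuristic."""

    def __init__(
        self,
        problem: DesignProblem,
        graph: InteractionGraph,
        pruning: Optional[PruningState],
    ) -> None:
        graph.check_problem(problem)
        if pruning is None:
            pruning = PruningState.empty()
        n = problem.n_residues
        self.problem = problem
        self.graph = graph
        self.n = n
        self.unpruned: List[List[int]] = [pruning.unpruned(problem, i) for i in range(n)]
        if any(not u for u in self.unpruned):
            raise EmptySearchSpaceError("a residue has no unpruned rotamers")
        self.one_body = [
            [float(problem.one_body[i][r]) for r in self.unpruned[i]] for i in range(n)
        ]
        # pair[i][j][ri][sj]: E_ij over unpruned rotamers, None if edge absent
        self.pair: List[List[Optional[List[List[float]]]]] = [
            [None] * n for _ in range(n)
        ]
        for i, j in graph.edges:
            m = problem.pairwise[(i, j)]
            block = [
                [float(m[r, s]) for s in self.unpruned[j]] for r in self.unpruned[i]
            ]
            self.pair[i][j] = block
            self.pair[j][i] = [list(col) for col in zip(*block)]
        # tail[j][m][s]: sum over k in [m, j) with (k,j) an edge of
        # min_t E_kj(t, s); used by h for a prefix of length m.
        self.tail: List[List[List[float]]] = []
        for j in range(n):
            nrot = len(self.unpruned[j])
            rows = [[0.0] * nrot for _ in range(j + 1)]
            acc = [0.0] * nrot
            for k in range(j - 1, -1, -1):
                block = self.pair[k][j]
                if block is not None:
                    mins = [min(col) for col in zip(*block)]
                    acc = [a + b for a, b in zip(acc, mins)]
                rows[k] = list(acc)
            self.tail = self.tail + [rows]

    def heuristic(self, prefix: Tuple[int, ...]) -> float:
        """Admissible lower bound on the best completion of ``prefix``
        (indices into the unpruned lists)."""
        n = self.n
        m = len(prefix)
        h = 0.0
        for j in range(m, n):
            best = None
            tail_j = self.tail[j][m]
            for s in range(len(self.unpruned[j])):
                val = self.one_body[j][s] + tail_j[s]
                for i in range(m):
                    block = self.pair[i][j]
                    if block is not None:
                        val += block[prefix[i]][s]
                if best is None or val < best:
                    best = val
            h += best
        return h

    def prefix_g(self, prefix: Tuple[int, ...]) -> float:
        g = self.problem.e_template
        for i, ri in enumerate(prefix):
            g += self.one_body[i][ri]
            for k in range(i):
                block = self.pair[k][i]
                if block is not None:
                    g += block[prefix[k]][ri]
        return g

    def to_conformation(self, prefix: Tuple[int, ...]) -> Conformation:
        return tuple(self.unpruned[i][ri] for i, ri in enumerate(prefix))


def heuristic_lower_bound(
    problem: DesignProblem,
    graph: InteractionGraph,
    partial: Tuple[int, ...],
    pruning: Optional[PruningState] = None,
) -> float:
    """g + h for a partial assignment over the first ``len(partial)`` residues.

    ``partial`` holds actual rotamer indices; the returned value is a lower
    bound on the graph-energy of every completion.
    """
    ctx = _AstarContext(problem, graph, pruning)
    prefix = tuple(ctx.unpruned[i].index(r) for i, r in enumerate(partial))
    return ctx.prefix_g(prefix) + ctx.heuristic(prefix)


def _astar_iter(ctx: _AstarContext) -> Iterator[Tuple[Conformation, float]]:
    n = ctx.n
    root: Tuple[int, ...] = ()
    heap: List[Tuple[float, Tuple[int, ...]]] = [
        (ctx.problem.e_template + ctx.heuristic(root), root)
    ]
    while heap:
        f, prefix = heapq.heappop(heap)
        m = len(prefix)
        if m == n:
            yield ctx.to_conformation(prefix), f
            continue
        g = ctx.prefix_g(prefix)
        pair_row = [ctx.pair[i][m] for i in range(m)]
        for ri in range(len(ctx.unpruned[m])):
            child = prefix + (ri,)
            g_child = g + ctx.one_body[m][ri]
            for i in range(m):
                block = pair_row[i]
                if block is not None:
                    g_child += block[prefix[i]][ri]
            heapq.heappush(heap, (g_child + ctx.heuristic(child), child))


def astar_enumerate(
    problem: DesignProblem,
    graph: InteractionGraph,
    pruning: Optional[PruningState] = None,
    window: Optional[float] = None,
    max_count: Optional[int] = None,
) -> EnumerationStream:
    """Enumerate unpruned conformations in non-decreasing graph-energy order.

    The first conformation is the graph's GMEC over the unpruned space.
    Enumeration stops when the energy exceeds (first energy + window), when
    ``max_count`` conformations have been produced, or when the space is
    exhausted — whichever comes first; the stream records which.
    """
    if window is not None and window < 0:
        raise ValueError("window must be non-negative")
    ctx = _AstarContext(problem, graph, pruning)
    items: List[Tuple[Conformation, float]] = []
    termination = TERMINATION_EXHAUSTED
    threshold = None
    for conf, energy in _astar_iter(ctx):
        if threshold is None and window is not None:
            threshold = energy + window
        if threshold is not None and energy > threshold + 1e-12:
            termination = TERMINATION_WINDOW
            break
        items.append((conf, energy))
        if max_count is not None and len(items) >= max_count:
            termination = TERMINATION_COUNT
            break
    if not items:
        raise EmptySearchSpaceError("no conformations to enumerate")
    return EnumerationStream(items, termination, graph)


def brute_force_enumerate(
    problem: DesignProblem,
    graph: InteractionGraph,
    pruning: Optional[PruningState] = None,
    cap: int = 10**6,
) -> EnumerationStream:
    """Exhaustive oracle: all unpruned conformations stably sorted by
    (graph-energy, lexicographic rotamer vector)."""
    graph.check_problem(problem)
    if pruning is None:
        pruning = PruningState.empty()
    choices = [pruning.unpruned(problem, i) for i in range(problem.n_residues)]
    if any(not c for c in choices):
        raise EmptySearchSpaceError("a residue has no unpruned rotamers")
    total = int(np.prod([len(c) for c in choices]))
    if total > cap:
        raise OracleTooLargeError(f"{total} conformations exceed the oracle cap {cap}")
    confs = [tuple(c) for c in itertools.product(*choices)]
    arr = np.array(confs, dtype=np.intp)
    energies = np.full(len(confs), problem.e_template)
    for i in range(problem.n_residues):
        energies += problem.one_body[i][arr[:, i]]
    for i, j in graph.edges:
        energies += problem.pairwise[(i, j)][arr[:, i], arr[:, j]]
    order = sorted(range(len(confs)), key=lambda k: (energies[k], confs[k]))
    items = [(confs[k], float(energies[k])) for k in order]
    return EnumerationStream(items, TERMINATION_EXHAUSTED, graph)


def stream_table(stream: EnumerationStream, problem: DesignProblem) -> pd.DataFrame:
    """TSV-ready view of a stream: rank, energy, rotamer vector, sequence."""
    rows = []
    for rank, (conf, energy) in enumerate(stream.items, start=1):
        rows.append(
            {
                "rank": rank,
                "energy": energy,
                "rotamers": " ".join(
                    problem.residues[i].rotamers[r].id for i, r in enumerate(conf)
                ),
                "sequence": "-".join(problem.sequence(conf)),
            }
        )
    return pd.DataFrame(rows, columns=["rank", "energy", "rotamers", "sequence"])


def save_stream_tsv(stream: EnumerationStream, problem: DesignProblem, path) -> None:
    stream_table(stream, problem).to_csv(
        Path(path), sep="\t", index=False, float_format="%.6f"
    )
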