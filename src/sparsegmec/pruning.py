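"""Goldstein dead-end elimination (singles criterion) with an energy window.

A rotamer r at residue i is eliminated when some competitor t at the same
residue satisfies

    E_i(r) - E_i(t) + sum_{j != i, (i,j) in G} min_s [E_ij(r,s) - E_ij(t,s)] > E_w

with the min over unpruned rotamers s of residue j and the sum over the
edges of the interaction graph G the search will use.  The criterion is
iterated to fixpoint with a deterministic sweep order (residues ascending,
rotamers ascending).  Soundness guarantee: no conformation whose G-energy is
within E_w of the G-GMEC uses a pruned rotamer, so a subsequent gap-free
enumeration up to window E_w over the unpruned space is still exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, List, Tuple

import pandas as pd

from .graph import InteractionGraph
from .problem import DesignProblem


@dataclass(frozen=True)
class PruningState:
    """Set of (residue, rotamer) pairs eliminated by DEE at window ``e_w``."""

    pruned: FrozenSet[Tuple[int, int]]
    e_w: float

    @classmethod
    def empty(cls) -> "PruningState":
        return cls(frozenset(), math.inf)

    def is_pruned(self, i: int, r: int) -> bool:
        return (i, r) in self.pruned

    def unpruned(self, problem: DesignProblem, i: int) -> List[int]:
        return [r for r in range(problem.n_rotamers(i)) if (i, r) not in self.pruned]


@dataclass
class PruningRecord:
    """One elimination event, for the pruning report."""

    residue: int
    rotamer: int
    pruned_by_competitor: int
    goldstein_score: float


def _goldstein_score(
    problem: DesignProblem,
    graph: InteractionGraph,
    unpruned: List[List[int]],
    i: int,
    r: int,
    t: int,
) -> float:
    score = problem.one_body[i][r] - problem.one_body[i][t]
    for j in graph.neighbors(i):
        if i < j:
            m = problem.pairwise[(i, j)]
            diffs = (m[r, s] - m[t, s] for s in unpruned[j])
        else:
            m = problem.pairwise[(j, i)]
            diffs = (m[s, r] - m[s, t] for s in unpruned[j])
        score += min(diffs)
    return float(score)


def goldstein_prune(
    problem: DesignProblem,
    graph: InteractionGraph,
    e_w: float = 0.0,
    records: List[PruningRecord] | None = None,
) -> PruningState:
    """Run Goldstein singles DEE to fixpoint w.r.t. ``graph`` and window ``e_w``.

    Pass a list as ``records`` to collect per-elimination diagnostics.
    """
    if e_w < 0:
        raise ValueError("energy window must be non-negative")
    graph.check_problem(problem)
    n = problem.n_residues
    unpruned: List[List[int]] = [list(range(problem.n_rotamers(i))) for i in range(n)]
    pruned: set[Tuple[int, int]] = set()
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for r in list(unpruned[i]):
                for t in unpruned[i]:
                    if t == r:
                        continue
                    score = _goldstein_score(problem, graph, unpruned, i, r, t)
                    if score > e_w:
                        unpruned[i].remove(r)
                        pruned.add((i, r))
                        if records is not None:
                            records.append(PruningRecord(i, r, t, score))
                        changed = True
                        break
        # Goldstein always keeps the residue's best rotamer: its score vs any
        # competitor is <= 0 <= e_w, so a residue can never empty out.
        assert all(unpruned[i] for i in range(n))
    return PruningState(frozenset(pruned), float(e_w))


def pruning_report(records: List[PruningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue": rec.residue,
                "rotamer": rec.rotamer,
                "pruned_by_competitor": rec.pruned_by_competitor,
                "goldstein_score": rec.goldstein_score,
            }
            for rec in records
        ],
        columns=["residue", "rotamer", "pruned_by_competitor", "goldstein_score"],
    )


def save_pruning_csv(records: List[PruningRecord], path) -> None:
    pruning_report(records).to_csv(Path(path), index=False, float_format="%.6f")
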