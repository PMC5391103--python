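"""Shared fixtures: toy problems and random-instance factories.

Random instances use plain Gaussian (or integer, for exact-tie tests)
energies rather than the geometric synthetic generator: the search, pruning
and bounding guarantees must hold for arbitrary finite energy tables, so
the oracle tests draw from the widest distribution.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparsegmec.fixtures import toy_t1, toy_t2
from sparsegmec.graph import InteractionGraph
from sparsegmec.problem import DesignProblem, Residue, Rotamer

_AAS = ("ALA", "SER", "LYS", "GLU", "VAL", "TRP")


def make_random_problem(
    rng: np.random.Generator,
    n_max: int = 6,
    rot_max: int = 4,
    integer_energies: bool = False,
    with_atoms: bool = False,
) -> DesignProblem:
    n = int(rng.integers(2, n_max + 1))
    counts = [int(rng.integers(1, rot_max + 1)) for _ in range(n)]
    residues = []
    for i in range(n):
        rots = []
        for r in range(counts[i]):
            atoms = (
                rng.uniform(0, 20, size=(int(rng.integers(1, 4)), 3))
                if with_atoms
                else np.zeros((0, 3))
            )
            rots.append(Rotamer(f"r{i}_{r}", _AAS[int(rng.integers(0, len(_AAS)))], atoms))
        residues.append(Residue(f"R{i}", tuple(rots)))

    def draw(shape):
        if integer_energies:
            return rng.integers(-3, 4, size=shape).astype(float)
        return rng.normal(0.0, 2.0, size=shape)

    one_body = [draw(counts[i]) for i in range(n)]
    pairwise = {
        (i, j): draw((counts[i], counts[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    e_template = float(draw(())) if not integer_energies else float(rng.integers(-2, 3))
    d_min = None
    if not with_atoms:
        d = rng.uniform(2.0, 15.0, size=(n, n))
        d_min = (d + d.T) / 2.0
        np.fill_diagonal(d_min, 0.0)
    return DesignProblem(residues, e_template, one_body, pairwise, d_min)


def make_random_graph(rng: np.random.Generator, n: int, keep_prob: float = 0.5) -> InteractionGraph:
    edges = frozenset(
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < keep_prob
    )
    return InteractionGraph(n, edges)


@pytest.fixture
def t1() -> DesignProblem:
    return toy_t1()


@pytest.fixture
def t2() -> DesignProblem:
    return toy_t2()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
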