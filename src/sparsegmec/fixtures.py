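"""Canonical hand-checkable toy problems.

T1 is the two-residue worked example used throughout the docs and tests:

* residue 0: rotamers A0 (ALA, E=0) and S0 (SER, E=1)
* residue 1: rotamers A1 (ALA, E=0) and K1 (LYS, E=2)
* e_template = 0; the only non-zero pairwise term is E_01(A0, A1) = 5.

With the full graph the GMEC is (S0, A1) at 1.0 kcal/mol; deleting edge
(0, 1) makes (A0, A1) the sparse GMEC at 0.0 kcal/mol — a minimal example of
a sparse graph changing both sequence and conformation.

T2 extends T1 with a third rotamer X1 (LYS, E=10, no pairwise interactions)
at residue 1, which Goldstein DEE with a zero window provably eliminates.
"""

from __future__ import annotations

import numpy as np

from .problem import DesignProblem, Residue, Rotamer


def toy_t1() -> DesignProblem:
    residues = [
        Residue("R0", (Rotamer("A0", "ALA"), Rotamer("S0", "SER"))),
        Residue("R1", (Rotamer("A1", "ALA"), Rotamer("K1", "LYS"))),
    ]
    one_body = [np.array([0.0, 1.0]), np.array([0.0, 2.0])]
    pairwise = {(0, 1): np.array([[5.0, 0.0], [0.0, 0.0]])}
    return DesignProblem(residues, 0.0, one_body, pairwise)


def toy_t2() -> DesignProblem:
    residues = [
        Residue("R0", (Rotamer("A0", "ALA"), Rotamer("S0", "SER"))),
        Residue("R1", (Rotamer("A1", "ALA"), Rotamer("K1", "LYS"), Rotamer("X1", "LYS"))),
    ]
    one_body = [np.array([0.0, 1.0]), np.array([0.0, 2.0, 10.0])]
    pairwise = {(0, 1): np.array([[5.0, 0.0, 0.0], [0.0, 0.0, 0.0]])}
    return DesignProblem(residues, 0.0, one_body, pairwise)


# rotamer indices by id, for readable tests
T1_A0, T1_S0 = 0, 1
T1_A1, T1_K1 = 0, 1
T2_X1 = 2
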