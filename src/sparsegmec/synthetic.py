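"""Random design problems with pseudo-rotamer geometry and toy energetics.

The generator stands in for structure-derived design problems so the whole
pipeline is testable without external data.  Residue centres are scattered
in a cube sized to hit a regime-dependent mean nearest-neighbour spacing;
each rotamer is a small cluster of pseudo-atoms jittered around its
residue's centre, optionally carrying a partial charge.  Pairwise energies
combine a capped Lennard-Jones-like r^-12/r^-6 term with a Coulomb-like
q1 q2 / r term, so interaction magnitude decays with distance — the premise
that makes distance cutoffs meaningful.  One-body energies are Gaussian
noise standing in for rotamer-internal and rotamer-template terms.

The three regimes mimic where a design's mutable residues sit in a protein:

* ``core``     — tightly packed, mostly apolar:  ~5 A spacing, 10% charged
* ``boundary`` — intermediate:                   ~7 A spacing, 30% charged
* ``surface``  — solvent-exposed, polar:         ~9 A spacing, 60% charged

A fixed seed reproduces a problem bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .problem import DesignProblem, Residue, Rotamer

_AA_POOL = (
    "ALA", "VAL", "LEU", "ILE", "PHE", "MET", "SER", "THR", "TYR", "TRP",
    "ASN", "GLN", "GLY", "PRO", "CYS", "HIS", "LYS", "ARG", "ASP", "GLU",
)

#: regime presets: (mean nearest-neighbour spacing in A, charged-rotamer fraction)
REGIMES: Dict[str, Tuple[float, float]] = {
    "core": (5.0, 0.1),
    "boundary": (7.0, 0.3),
    "surface": (9.0, 0.6),
}

# toy potential constants (kcal/mol, Angstrom)
_LJ_EPS = 0.15
_LJ_SIGMA = 3.2
_LJ_CAP = 10.0
_COULOMB_K = 20.0
_ATOM_JITTER_SD = 1.2


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic-problem generator.

    ``charge_fraction`` and the spacing default to the regime preset;
    ``box_scale`` multiplies the placement box, ``noise_sd`` is the one-body
    Gaussian sd in kcal/mol.
    """

    n_residues: int = 6
    n_amino_acids: int = 2
    n_rotamers: int = 2
    regime: str = "boundary"
    box_scale: float = 1.0
    charge_fraction: Optional[float] = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if min(self.n_residues, self.n_amino_acids, self.n_rotamers) < 1:
            raise ValueError("all counts must be >= 1")
        if self.box_scale <= 0 or self.noise_sd < 0:
            raise ValueError("box_scale must be positive, noise_sd non-negative")
        if self.charge_fraction is not None and not 0 <= self.charge_fraction <= 1:
            raise ValueError("charge_fraction must be in [0, 1]")

    @property
    def effective_charge_fraction(self) -> float:
        return (
            REGIMES[self.regime][1]
            if self.charge_fraction is None
            else self.charge_fraction
        )

    @property
    def spacing(self) -> float:
        return REGIMES[self.regime][0]


def _pair_energy(
    atoms_a: np.ndarray, q_a: np.ndarray, atoms_b: np.ndarray, q_b: np.ndarray
) -> float:
    diff = atoms_a[:, None, :] - atoms_b[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=2))
    r = np.maximum(r, 0.5)  # avoid the singularity; the cap handles clashes
    sr6 = (_LJ_SIGMA / r) ** 6
    lj = float((4.0 * _LJ_EPS * (sr6 * sr6 - sr6)).sum())
    lj = min(lj, _LJ_CAP)
    coulomb = float((_COULOMB_K * np.outer(q_a, q_b) / r).sum())
    return lj + coulomb


def generate_problem(params: GeneratorParams) -> DesignProblem:
    """Deterministically generate a design problem from ``params``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_residues
    # cube side targeting the regime's mean nearest-neighbour spacing: for a
    # Poisson scatter, E[d_NN] ~= 0.554 (V / n)^(1/3)
    side = params.spacing / 0.554 * n ** (1.0 / 3.0) * params.box_scale
    centers = rng.uniform(0.0, side, size=(n, 3))

    residues: List[Residue] = []
    atom_sets: List[List[np.ndarray]] = []
    charge_sets: List[List[np.ndarray]] = []
    cf = params.effective_charge_fraction
    for i in range(n):
        aa_codes = rng.choice(len(_AA_POOL), size=params.n_amino_acids, replace=False)
        rotamers: List[Rotamer] = []
        res_atoms: List[np.ndarray] = []
        res_charges: List[np.ndarray] = []
        for a in range(params.n_amino_acids):
            aa = _AA_POOL[aa_codes[a]]
            for t in range(params.n_rotamers):
                n_atoms = int(rng.integers(1, 5))
                atoms = centers[i] + rng.normal(0.0, _ATOM_JITTER_SD, size=(n_atoms, 3))
                if rng.random() < cf:
                    q_total = rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.8)
                else:
                    q_total = 0.0
                charges = np.full(n_atoms, q_total / n_atoms)
                rotamers.append(Rotamer(f"{aa}_{t}", aa, atoms))
                res_atoms.append(atoms)
                res_charges.append(charges)
        residues.append(Residue(f"X{i}", tuple(rotamers)))
        atom_sets.append(res_atoms)
        charge_sets.append(res_charges)

    one_body = [
        rng.normal(0.0, params.noise_sd, size=len(res.rotamers)) for res in residues
    ]
    pairwise = {}
    d_min = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = len(residues[i].rotamers), len(residues[j].rotamers)
            m = np.zeros((ki, kj))
            dmin = np.inf
            for r in range(ki):
                for s in range(kj):
                    m[r, s] = _pair_energy(
                        atom_sets[i][r], charge_sets[i][r],
                        atom_sets[j][s], charge_sets[j][s],
                    )
                    diff = atom_sets[i][r][:, None, :] - atom_sets[j][s][None, :, :]
                    dmin = min(dmin, float(np.sqrt((diff * diff).sum(axis=2)).min()))
            pairwise[(i, j)] = m
            d_min[i, j] = d_min[j, i] = dmin
    return DesignProblem(residues, 0.0, one_body, pairwise, d_min)


@dataclass
class SuiteManifest:
    """Record of how a problem batch was generated."""

    regime: str
    n_problems: int
    size_range: Tuple[int, int]
    seed: int
    per_problem: List[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "regime": self.regime,
            "n_problems": self.n_problems,
            "size_range": list(self.size_range),
            "seed": self.seed,
            "per_problem": self.per_problem,
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")


def generate_suite(
    regime: str,
    n_problems: int,
    size_range: Tuple[int, int] = (4, 8),
    seed: int = 0,
    base_params: Optional[GeneratorParams] = None,
) -> Tuple[List[DesignProblem], SuiteManifest]:
    """A deterministic batch of problems with per-problem derived seeds."""
    if n_problems < 1:
        raise ValueError("n_problems must be >= 1")
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid size range")
    master = np.random.default_rng(seed)
    base = base_params if base_params is not None else GeneratorParams(regime=regime)
    manifest = SuiteManifest(regime, n_problems, (lo, hi), seed)
    problems = []
    for k in range(n_problems):
        n_res = int(master.integers(lo, hi + 1))
        child_seed = int(master.integers(0, 2**31 - 1))
        params = replace(base, regime=regime, n_residues=n_res, seed=child_seed)
        problems.append(generate_problem(params))
        manifest.per_problem.append(
            {
                "index": k,
                "n_residues": n_res,
                "seed": child_seed,
                "n_amino_acids": params.n_amino_acids,
                "n_rotamers": params.n_rotamers,
                "charge_fraction": params.effective_charge_fraction,
                "noise_sd": params.noise_sd,
            }
        )
    return problems, manifest
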