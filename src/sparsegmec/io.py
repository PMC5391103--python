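"""JSON serialization of design problems.

Format (all energies kcal/mol, distances Angstrom, residue indices 0-based):

    {
      "residues": [{"label": str,
                    "rotamers": [{"id": str, "amino_acid": str,
                                  "atoms": [[x, y, z], ...]}]}, ...],
      "e_template": float,
      "one_body": [[E_i(r) ...] per residue],
      "pairwise": [{"i": int, "j": int, "r": int, "s": int, "e": float}, ...],
      "d_min": [[...]] | absent
    }

Floats are written with ``repr`` precision, so a serialize -> parse round
trip reproduces every energy bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .errors import InvalidProblemError
from .problem import DesignProblem, Residue, Rotamer, validate_problem

PROBLEM_SCHEMA = {
    "type": "object",
    "required": ["residues", "e_template", "one_body", "pairwise"],
    "properties": {
        "residues": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["label", "rotamers"],
                "properties": {
                    "label": {"type": "string"},
                    "rotamers": {
                        "type": "array",
                        "minItems": 1,
                        "items": {
                            "type": "object",
                            "required": ["id", "amino_acid"],
                            "properties": {
                                "id": {"type": "string"},
                                "amino_acid": {"type": "string"},
                                "atoms": {"type": "array"},
                            },
                        },
                    },
                },
            },
        },
        "e_template": {"type": "number"},
        "one_body": {"type": "array"},
        "pairwise": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["i", "j", "r", "s", "e"],
            },
        },
        "d_min": {"type": "array"},
    },
}
"""Published structural schema of the design-problem JSON format."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidProblemError(f"design-problem JSON: {msg}")


def problem_to_dict(problem: DesignProblem) -> dict:
    doc = {
        "residues": [
            {
                "label": res.label,
                "rotamers": [
                    {
                        "id": rot.id,
                        "amino_acid": rot.amino_acid,
                        "atoms": [[float(x) for x in atom] for atom in rot.atoms],
                    }
                    for rot in res.rotamers
                ],
            }
            for res in problem.residues
        ],
        "e_template": float(problem.e_template),
        "one_body": [[float(e) for e in v] for v in problem.one_body],
        "pairwise": [
            {"i": i, "j": j, "r": r, "s": s, "e": float(m[r, s])}
            for (i, j), m in sorted(problem.pairwise.items())
            for r in range(m.shape[0])
            for s in range(m.shape[1])
        ],
    }
    if problem.d_min is not None:
        doc["d_min"] = [[float(x) for x in row] for row in problem.d_min]
    return doc


def problem_from_dict(doc: dict) -> DesignProblem:
    _check(isinstance(doc, dict), "top level must be an object")
    for key in ("residues", "e_template", "one_body", "pairwise"):
        _check(key in doc, f"missing key {key!r}")
    residues = []
    for k, rdoc in enumerate(doc["residues"]):
        _check(isinstance(rdoc, dict) and "rotamers" in rdoc, f"residue {k} malformed")
        rots = []
        for tdoc in rdoc["rotamers"]:
            _check(
                isinstance(tdoc, dict) and "id" in tdoc and "amino_acid" in tdoc,
                f"residue {k}: rotamer missing id/amino_acid",
            )
            atoms = np.asarray(tdoc.get("atoms", []), dtype=float).reshape(-1, 3)
            rots.append(Rotamer(str(tdoc["id"]), str(tdoc["amino_acid"]), atoms))
        residues.append(Residue(str(rdoc.get("label", str(k))), tuple(rots)))
    n = len(residues)
    one_body_doc = doc["one_body"]
    _check(len(one_body_doc) == n, "one_body length != residue count")
    one_body = [np.asarray(v, dtype=float) for v in one_body_doc]
    pairwise = {
        (i, j): np.full(
            (len(residues[i].rotamers), len(residues[j].rotamers)), np.nan
        )
        for i in range(n)
        for j in range(i + 1, n)
    }
    for entry in doc["pairwise"]:
        _check(
            isinstance(entry, dict) and {"i", "j", "r", "s", "e"} <= set(entry),
            "pairwise entry missing keys",
        )
        i, j, r, s = (int(entry[k]) for k in ("i", "j", "r", "s"))
        _check(0 <= i < j < n, f"pairwise entry has bad residue pair ({i},{j})")
        m = pairwise[(i, j)]
        _check(0 <= r < m.shape[0] and 0 <= s < m.shape[1],
               f"pairwise entry ({i},{j},{r},{s}) out of rotamer range")
        m[r, s] = float(entry["e"])
    d_min = None
    if "d_min" in doc and doc["d_min"] is not None:
        d_min = np.asarray(doc["d_min"], dtype=float)
    problem = DesignProblem(residues, float(doc["e_template"]), one_body, pairwise, d_min)
    report = validate_problem(problem)
    if report:
        raise InvalidProblemError("; ".join(report))
    return problem


def save_problem(problem: DesignProblem, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(problem_to_dict(problem)) + "\n")


def load_problem(path: Union[str, Path]) -> DesignProblem:
    return problem_from_dict(json.loads(Path(path).read_text()))
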