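"""Design-problem model: energies, sequences, distances, validation, JSON."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sparsegmec as sg
from sparsegmec.problem import Residue, Rotamer

from conftest import make_random_graph, make_random_problem


class TestEnergies:
    @pytest.mark.parametrize(
        "conf,expected",
        [((1, 0), 1.0), ((0, 0), 5.0), ((0, 1), 2.0), ((1, 1), 3.0)],
    )
    def test_full_energy_t1_hand_sums(self, t1, conf, expected):
        assert t1.full_energy(conf) == pytest.approx(expected, abs=1e-9)

    def test_full_energy_single_residue_has_no_pair_terms(self):
        p = sg.DesignProblem(
            [Residue("R0", (Rotamer("a", "ALA"), Rotamer("b", "SER")))],
            e_template=1.5,
            one_body=[np.array([0.25, -1.0])],
            pairwise={},
        )
        assert p.full_energy((1,)) == pytest.approx(0.5)

    def test_full_energy_rejects_out_of_range_rotamer(self, t1):
        with pytest.raises(sg.InvalidConformationError):
            t1.full_energy((0, 2))

    def test_sparse_energy_omits_deleted_edge_terms(self, t1):
        empty = sg.InteractionGraph(2, frozenset())
        assert t1.sparse_energy((0, 0), empty) == pytest.approx(0.0)
        # one-body + template only
        assert t1.sparse_energy((1, 1), empty) == pytest.approx(3.0)

    def test_sparse_energy_full_graph_equals_full_energy(self, t1):
        g = sg.build_full_graph(t1)
        assert t1.sparse_energy((1, 0), g) == pytest.approx(t1.full_energy((1, 0)), abs=1e-12)

    def test_sparse_energy_rejects_mismatched_graph(self, t1):
        with pytest.raises(sg.GraphMismatchError):
            t1.sparse_energy((0, 0), sg.InteractionGraph(3, frozenset()))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_full_sparse_identity_and_decomposition(self, seed):
        """full == sparse(full graph), and full == sparse + omitted-edge sum."""
        rng = np.random.default_rng(seed)
        p = make_random_problem(rng)
        g = make_random_graph(rng, p.n_residues)
        conf = tuple(int(rng.integers(0, p.n_rotamers(i))) for i in range(p.n_residues))
        full = p.full_energy(conf)
        assert p.sparse_energy(conf, sg.build_full_graph(p)) == pytest.approx(full, abs=1e-9)
        omitted = sum(
            p.pairwise[(i, j)][conf[i], conf[j]] for i, j in g.deleted_edges()
        )
        assert p.sparse_energy(conf, g) + omitted == pytest.approx(full, abs=1e-9)

    def test_term_counter_tracks_full_energy_cost(self, t1):
        t1.counter.reset()
        t1.full_energy((0, 0))
        assert t1.counter.one_body == 2
        assert t1.counter.pairwise == 1


class TestSequence:
    @pytest.mark.parametrize(
        "conf,seq",
        [((1, 0), ("SER", "ALA")), ((0, 0), ("ALA", "ALA")), ((0, 1), ("ALA", "LYS"))],
    )
    def test_sequence_readout(self, t1, conf, seq):
        assert t1.sequence(conf) == seq


class TestDistances:
    def _geom_problem(self, second_residue_atoms):
        residues = [
            Residue("R0", (Rotamer("a", "ALA", np.array([[0.0, 0.0, 0.0]])),)),
            Residue(
                "R1",
                tuple(
                    Rotamer(f"b{k}", "ALA", np.array([atom]))
                    for k, atom in enumerate(second_residue_atoms)
                ),
            ),
        ]
        nrot = len(second_residue_atoms)
        return sg.DesignProblem(
            residues,
            0.0,
            [np.zeros(1), np.zeros(nrot)],
            {(0, 1): np.zeros((1, nrot))},
        )

    def test_single_atom_pair(self):
        p = self._geom_problem([[6.5, 0.0, 0.0]])
        assert p.min_pairwise_distance(0, 1) == pytest.approx(6.5)

    def test_min_over_rotamers(self):
        p = self._geom_problem([[6.5, 0.0, 0.0], [9.0, 0.0, 0.0]])
        assert p.min_pairwise_distance(0, 1) == pytest.approx(6.5)
        assert p.min_pairwise_distance(1, 0) == pytest.approx(6.5)

    def test_matrix_passthrough(self, t1):
        t1.d_min = np.array([[0.0, 7.6], [7.6, 0.0]])
        assert t1.min_pairwise_distance(0, 1) == pytest.approx(7.6)

    def test_unavailable_distance_raises(self, t1):
        assert t1.d_min is None
        with pytest.raises(sg.DistanceUnavailableError):
            t1.min_pairwise_distance(0, 1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetric_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = make_random_problem(rng, n_max=4, rot_max=3, with_atoms=True)
        for i in range(p.n_residues):
            for j in range(i + 1, p.n_residues):
                d = p.min_pairwise_distance(i, j)
                assert d == pytest.approx(p.min_pairwise_distance(j, i), abs=1e-12)
                assert d >= 0


class TestValidation:
    def test_t1_is_valid(self, t1):
        assert sg.validate_problem(t1) == []

    def test_missing_pairwise_entry_reported(self, t1):
        del t1.pairwise[(0, 1)]
        report = sg.validate_problem(t1)
        assert len(report) == 1 and "missing pairwise" in report[0]

    def test_nan_energy_reported(self, t1):
        t1.one_body[0][0] = np.nan
        report = sg.validate_problem(t1)
        assert len(report) == 1 and "non-finite" in report[0]

    def test_bad_amino_acid_code_reported(self):
        res = Residue("R0", (Rotamer("a", "XXX"),))
        p = sg.DesignProblem([res], 0.0, [np.zeros(1)], {})
        assert any("amino-acid" in v for v in sg.validate_problem(p))


class TestJsonRoundTrip:
    def test_t1_round_trip_exact(self, t1):
        doc = sg.problem_to_dict(t1)
        p2 = sg.problem_from_dict(json.loads(json.dumps(doc)))
        assert p2.full_energy((1, 0)) == t1.full_energy((1, 0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_random_round_trip_bit_identical(self, seed):
        rng = np.random.default_rng(seed)
        p = make_random_problem(rng, n_max=4, rot_max=3, with_atoms=True)
        p2 = sg.problem_from_dict(json.loads(json.dumps(sg.problem_to_dict(p))))
        assert p2.e_template == p.e_template
        for a, b in zip(p.one_body, p2.one_body):
            assert np.array_equal(a, b)
        for key in p.pairwise:
            assert np.array_equal(p.pairwise[key], p2.pairwise[key])

    def test_file_round_trip(self, t1, tmp_path):
        path = tmp_path / "t1.json"
        sg.save_problem(t1, path)
        p2 = sg.load_problem(path)
        assert p2.sequence((1, 0)) == ("SER", "ALA")

    def test_invalid_json_rejected(self, t1, tmp_path):
        doc = sg.problem_to_dict(t1)
        doc["pairwise"] = doc["pairwise"][:-1]  # drop one entry
        with pytest.raises(sg.InvalidProblemError):
            sg.problem_from_dict(doc)
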