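"""Sparse-gap bound, full-energy re-ranking and energy-bounding enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sparsegmec as sg
from sparsegmec.problem import Residue, Rotamer

from conftest import make_random_graph, make_random_problem


class TestOmittedEdgeBound:
    def test_t1_omitted_edge(self, t1):
        b = sg.sparse_gap_bound(t1, sg.InteractionGraph(2, frozenset()))
        assert (b.omega_min, b.omega_max, b.bound_b) == (0.0, 5.0, 5.0)

    def test_full_graph_zero_bound(self, t1):
        b = sg.sparse_gap_bound(t1, sg.build_full_graph(t1))
        assert (b.omega_min, b.omega_max, b.bound_b) == (0.0, 0.0, 0.0)

    def test_negative_energy_edge(self):
        residues = [
            Residue("R0", (Rotamer("a", "ALA"),)),
            Residue("R1", (Rotamer("b", "ALA"), Rotamer("c", "SER"))),
        ]
        p = sg.DesignProblem(
            residues, 0.0, [np.zeros(1), np.zeros(2)],
            {(0, 1): np.array([[-2.0, -1.0]])},
        )
        b = sg.sparse_gap_bound(p, sg.InteractionGraph(2, frozenset()))
        assert (b.omega_min, b.omega_max, b.bound_b) == (-2.0, -1.0, 1.0)

    def test_pruning_tightens_bound(self, t1):
        # pruning A0 removes the 5.0 pairwise entry from the extrema scan
        state = sg.PruningState(frozenset({(0, 0)}), 0.0)
        b = sg.sparse_gap_bound(t1, sg.InteractionGraph(2, frozenset()), state)
        assert b.bound_b == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_soundness_against_oracle_gmecs(self, seed):
        """sparse(full GMEC) - sparse(sparse GMEC) <= B on random instances."""
        rng = np.random.default_rng(seed)
        p = make_random_problem(rng, n_max=5, rot_max=4)
        g = make_random_graph(rng, p.n_residues)
        full_gmec = sg.brute_force_enumerate(p, sg.build_full_graph(p)).items[0][0]
        sparse_gmec, sparse_e = sg.brute_force_enumerate(p, g).items[0]
        gap = p.sparse_energy(full_gmec, g) - sparse_e
        b = sg.sparse_gap_bound(p, g)
        assert gap <= b.bound_b + 1e-9
        assert b.bound_b >= -1e-12


class TestRerank:
    def test_t1_sparse_stream_rerank(self, t1):
        stream = sg.astar_enumerate(t1, sg.InteractionGraph(2, frozenset()))
        conf, rank, table = sg.rerank_full_energy(stream, t1)
        assert conf == (1, 0)
        assert rank == 2
        assert list(table["full_energy"]) == pytest.approx([5.0, 1.0, 2.0, 3.0])

    def test_length_one_stream(self, t1):
        stream = sg.astar_enumerate(t1, sg.build_full_graph(t1), max_count=1)
        conf, rank, _ = sg.rerank_full_energy(stream, t1)
        assert (conf, rank) == ((1, 0), 1)

    def test_full_graph_stream_rank_one(self, rng):
        p = make_random_problem(rng)
        stream = sg.astar_enumerate(p, sg.build_full_graph(p))
        _, rank, _ = sg.rerank_full_energy(stream, p)
        assert rank == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_term_evaluation_accounting(self, seed):
        """Re-ranking k conformations costs exactly k (n(n-1)/2 + n) terms."""
        rng = np.random.default_rng(seed)
        p = make_random_problem(rng, n_max=6, rot_max=3)
        g = make_random_graph(rng, p.n_residues)
        k = int(rng.integers(1, 9))
        stream = sg.astar_enumerate(p, g, max_count=k)
        k = len(stream)
        n = p.n_residues
        p.counter.reset()
        sg.rerank_full_energy(stream, p)
        assert p.counter.total == k * (n * (n - 1) // 2 + n)


class TestEnergyBoundingEnumeration:
    def test_t1_recovers_both_gmecs(self, t1):
        res = sg.energy_bounding_enumeration(t1, sg.InteractionGraph(2, frozenset()))
        assert res.sparse_gmec == (0, 0)
        assert res.sparse_gmec_sparse_energy == pytest.approx(0.0)
        assert res.full_gmec == (1, 0)
        assert res.full_gmec_full_energy == pytest.approx(1.0)
        assert res.full_gmec_rank == 2
        assert res.bound_b == pytest.approx(5.0)
        assert res.window_covered
        assert res.conformations_enumerated == 4

    def test_full_graph_input_is_trivial(self, t1):
        res = sg.energy_bounding_enumeration(t1, sg.build_full_graph(t1))
        assert res.sparse_gmec == res.full_gmec == (1, 0)
        assert res.full_gmec_rank == 1
        assert res.bound_b == 0.0

    def test_count_cap_flags_uncovered_window(self, t1):
        res = sg.energy_bounding_enumeration(
            t1, sg.InteractionGraph(2, frozenset()), max_count=1
        )
        assert res.sparse_gmec == res.full_gmec == (0, 0)
        assert not res.window_covered
        assert res.conformations_enumerated == 1

    def test_json_report_round_trips(self, t1, tmp_path):
        import json

        res = sg.energy_bounding_enumeration(t1, sg.InteractionGraph(2, frozenset()))
        path = tmp_path / "dual.json"
        res.save_json(path)
        doc = json.loads(path.read_text())
        assert doc["full_gmec"]["sequence"] == ["SER", "ALA"]
        assert doc["full_gmec_rank"] == 2

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_certified_recovery_matches_oracle(self, seed):
        """When the window is covered the returned full GMEC is the oracle's,
        conformation-identical; the observed gap never exceeds the bound."""
        rng = np.random.default_rng(seed)
        p = make_random_problem(rng, n_max=5, rot_max=4)
        g = make_random_graph(rng, p.n_residues)
        res = sg.energy_bounding_enumeration(p, g, max_count=2000)
        oracle_full = sg.brute_force_enumerate(p, sg.build_full_graph(p)).items[0][0]
        gap = res.full_gmec_sparse_energy - res.sparse_gmec_sparse_energy
        assert gap <= res.bound_b + 1e-9
        if res.window_covered:
            assert res.full_gmec == oracle_full


class TestCompareGmecs:
    def test_t1_differences(self, t1):
        cmp = sg.compare_gmecs((0, 0), (1, 0), t1)
        assert (cmp.seq_diff_count, cmp.rot_diff_count) == (1, 1)
        assert cmp.delta_full_energy == pytest.approx(4.0)

    def test_identical_conformations(self, t1):
        cmp = sg.compare_gmecs((1, 0), (1, 0), t1, sg.build_full_graph(t1))
        assert (cmp.seq_diff_count, cmp.rot_diff_count) == (0, 0)
        assert cmp.delta_full_energy == 0.0
        assert cmp.delta_sparse_energy == 0.0

    def test_same_sequence_different_rotamer(self):
        residues = [
            Residue("R0", (Rotamer("a1", "ALA"), Rotamer("a2", "ALA"))),
        ]
        p = sg.DesignProblem(residues, 0.0, [np.array([0.0, 1.0])], {})
        cmp = sg.compare_gmecs((0,), (1,), p)
        assert (cmp.seq_diff_count, cmp.rot_diff_count) == (0, 1)
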