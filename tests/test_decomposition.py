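"""Core/neighbor decomposition: primitives, algorithm, verification."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from boolcarve import (
    BooleanNetwork,
    LogicTable,
    decompose,
    decomposition_overlap_test,
    delete_edge,
    enumerate_attractors,
    is_insignificant,
    node_scores,
    perturbation_novelty,
    preserves_primary,
    primary,
    reduced_table,
    sample_basin_states,
    verify_decomposition,
)
from boolcarve.decomposition import Decomposition, core_network
from boolcarve.dynamics import compile_network
from conftest import random_networks

OR2 = LogicTable("B", ("A", "C"), (0, 1, 1, 1))


class TestReducedTable:
    def test_or_fixed_at_zero_projects_to_copy(self):
        t = reduced_table(OR2, "A", 0)
        assert t.inputs == ("C",) and t.outputs == (0, 1)

    def test_fix_only_input_gives_constant(self):
        t = LogicTable("B", ("A",), (0, 1))
        r = reduced_table(t, "A", 1)
        assert r.inputs == () and r.outputs == (1,)

    def test_reductions_commute(self):
        t = LogicTable("D", ("X", "Y", "Z"), (0, 1, 1, 0, 1, 0, 0, 1))
        a = reduced_table(reduced_table(t, "X", 0), "Y", 1)
        b = reduced_table(reduced_table(t, "Y", 1), "X", 0)
        assert a == b

    def test_unknown_input_raises(self):
        with pytest.raises(KeyError):
            reduced_table(OR2, "Z", 0)


class TestInsignificant:
    def test_fictitious_input_insignificant(self):
        net = BooleanNetwork(
            ["A", "B", "C"],
            {"C": LogicTable("C", ("A", "B"), (0, 0, 1, 1))},  # f_C = A
        )
        assert is_insignificant(net, ("B", "C"))
        assert not is_insignificant(net, ("A", "C"))

    def test_or_edges_significant(self, toy3):
        assert not is_insignificant(toy3, ("A", "B"))
        assert not is_insignificant(toy3, ("C", "B"))

    def test_xor_edges_significant(self):
        net = BooleanNetwork(
            ["A", "B", "C"], {"C": LogicTable("C", ("A", "B"), (0, 1, 1, 0))}
        )
        assert not is_insignificant(net, ("A", "C"))
        assert not is_insignificant(net, ("B", "C"))


def transition_map(net):
    c = compile_network(net)
    free = [c.n - 1 - net.index(v) for v in net.free_nodes]
    out = []
    for i in range(2 ** len(free)):
        s = c.clamp_bits
        for j, p in enumerate(free):
            if (i >> j) & 1:
                s |= 1 << p
        out.append(c.step(s))
    return out


class TestDeleteEdge:
    def test_silent_edge_deletion_keeps_map(self, toy3):
        # A clamped 0 makes (A,B) dynamically silent
        assert transition_map(delete_edge(toy3, ("A", "B"))) == transition_map(toy3)

    def test_insignificant_deletion_keeps_full_map(self):
        # planted fictitious inputs on random networks; exhaustive n<=12 check
        rng = np.random.default_rng(0)
        for net in random_networks(10, n_nodes=8):
            target = net.free_nodes[int(rng.integers(len(net.free_nodes)))]
            t = net.tables[target]
            extra = next(
                (v for v in net.nodes if v not in t.inputs and v != target), None
            )
            if extra is None or t.k >= 6:
                continue
            doubled = LogicTable(target, (extra,) + t.inputs, t.outputs * 2)
            bigger = net.with_table(doubled)
            assert is_insignificant(bigger, (extra, target))
            assert transition_map(delete_edge(bigger, (extra, target))) == transition_map(bigger)

    def test_last_input_becomes_constant(self, toy3):
        net = delete_edge(toy3, ("B", "C"))
        assert net.tables["C"].inputs == ()
        assert net.tables["C"].outputs == (0,)

    def test_absent_edge_raises(self, toy3):
        with pytest.raises(KeyError):
            delete_edge(toy3, ("C", "A"))


class TestPreservesPrimary:
    def _basin(self, toy3):
        prim = primary(enumerate_attractors(toy3))
        return prim, sample_basin_states(toy3, prim, 20, seed=0)

    def test_identity_preserves(self, toy3):
        prim, states = self._basin(toy3)
        assert preserves_primary(toy3, states, prim)

    def test_breaking_feedback_fails(self, toy3):
        prim, states = self._basin(toy3)
        assert not preserves_primary(delete_edge(toy3, ("C", "B")), states, prim)

    def test_silent_edge_preserves(self, toy3):
        prim, states = self._basin(toy3)
        assert preserves_primary(delete_edge(toy3, ("A", "B")), states, prim)


class TestDecompose:
    @pytest.mark.parametrize("seed_order", [0, 1, 2, 3, 4])
    def test_toy3_ground_truth_every_seed(self, toy3, seed_order):
        dec = decompose(toy3, n_samples=40, seed_init=1, seed_order=seed_order)
        assert dec.core_edges == {("C", "B"), ("B", "C")}
        assert dec.neighbor_edges == {("A", "B")}
        assert dec.provenance[("A", "B")] == "candidate_deleted"

    def test_insignificant_provenance(self):
        net = BooleanNetwork(
            ["A", "B", "C"],
            {
                "B": LogicTable("B", ("C",), (0, 1)),
                "C": LogicTable("C", ("A", "B"), (0, 0, 1, 1)),  # ignores B? no: f_C=A
            },
        )
        # f_C(A,B) = A: edge (B,C) is insignificant
        dec = decompose(net, n_samples=20, seed_init=0, seed_order=0)
        assert dec.provenance[("B", "C")] == "insignificant"
        assert ("B", "C") in dec.neighbor_edges

    def test_ffwd5_everything_deletable(self, ffwd5):
        dec = decompose(ffwd5, n_samples=16, seed_init=0, seed_order=0)
        assert dec.core_edges == frozenset()
        assert dec.neighbor_edges == ffwd5.edges

    def test_redundant4_partition(self, redundant4):
        dec = decompose(redundant4, n_samples=30, seed_init=0, seed_order=0)
        assert dec.neighbor_edges == {("A", "D")}
        assert dec.core_edges == {("B", "C"), ("C", "B"), ("C", "D")}

    def test_partition_invariant_random_networks(self):
        for net in random_networks(6, n_nodes=9):
            dec = decompose(net, n_samples=100, seed_init=0, seed_order=0)
            assert dec.core_edges | dec.neighbor_edges == net.edges
            assert not dec.core_edges & dec.neighbor_edges

    def test_seed_stability_core_nondegenerate(self):
        # feedback-sustained primary cycle => core never empty, sizes similar
        net = random_networks(1, n_nodes=10, plant=(3, 1))[0]
        land = enumerate_attractors(net)
        if primary(land).length > 1:
            sizes = [
                len(decompose(net, n_samples=100, seed_init=0, seed_order=s).core_edges)
                for s in range(5)
            ]
            assert min(sizes) >= 1


class TestNodeScores:
    def test_toy3_scores(self, toy3):
        dec = decompose(toy3, n_samples=40, seed_init=0, seed_order=0)
        ns = node_scores(toy3, dec)
        assert ns.evolvability["B"] == pytest.approx(2 / 3)
        assert ns.robustness["B"] == pytest.approx(1 / 3)
        assert ns.evolvability["A"] == 0.0
        assert ns.evolvability["C"] == 1.0

    def test_scores_sum_to_one(self):
        for net in random_networks(3, n_nodes=8):
            dec = decompose(net, n_samples=60, seed_init=0, seed_order=0)
            ns = node_scores(net, dec)
            for v in ns.evolvability:
                assert ns.evolvability[v] + ns.robustness[v] == pytest.approx(1.0)

    def test_isolated_node_absent(self):
        net = BooleanNetwork(
            ["A", "B", "Z"], {"B": LogicTable("B", ("A", "B"), (0, 1, 1, 1))}
        )
        dec = decompose(net, n_samples=10, seed_init=0, seed_order=0)
        ns = node_scores(net, dec)
        assert "Z" not in ns.evolvability


class TestVerify:
    def test_passes_on_decompose_output(self, toy3):
        dec = decompose(toy3, n_samples=40, seed_init=0, seed_order=0)
        prim = dec.primary
        states = sample_basin_states(toy3, prim, 20, seed=0)
        assert verify_decomposition(toy3, dec, states).passed

    def test_hand_broken_decomposition_fails_preservation(self, toy3):
        dec = decompose(toy3, n_samples=40, seed_init=0, seed_order=0)
        broken = Decomposition(
            core_edges=frozenset({("B", "C")}),
            neighbor_edges=frozenset({("A", "B"), ("C", "B")}),
            provenance={
                ("B", "C"): "retained",
                ("A", "B"): "candidate_deleted",
                ("C", "B"): "candidate_deleted",
            },
            deletion_order=[],
            seeds=dec.seeds,
            sample_size=dec.sample_size,
            primary=dec.primary,
            landscape=dec.landscape,
        )
        states = sample_basin_states(toy3, dec.primary, 20, seed=0)
        report = verify_decomposition(toy3, broken, states)
        assert not report.core_preserves
        assert not report.passed

    def test_empty_neighbor_flags_deletable_edge(self):
        net = BooleanNetwork(
            ["A", "B", "C"],
            {
                "B": LogicTable("B", ("C",), (0, 1)),
                "C": LogicTable("C", ("A", "B"), (0, 0, 1, 1)),  # f_C = A (B fictitious)
            },
        )
        land = enumerate_attractors(net)
        prim = primary(land)
        lazy = Decomposition(
            core_edges=net.edges,
            neighbor_edges=frozenset(),
            provenance={e: "retained" for e in net.edges},
            deletion_order=[],
            seeds={},
            sample_size=4,
            primary=prim,
            landscape=land,
        )
        states = sample_basin_states(net, prim, 10, seed=0)
        report = verify_decomposition(net, lazy, states)
        assert not report.minimal
        assert any("('B', 'C')" in f for f in report.failures)

    def test_soundness_small_ensemble(self):
        for net in random_networks(6, n_nodes=9):
            for s1, s2 in [(0, 0), (1, 2)]:
                dec = decompose(net, n_samples=100, seed_init=s1, seed_order=s2)
                states = sample_basin_states(net, dec.primary, 100, seed=s1 + 1)
                assert verify_decomposition(net, dec, states).passed


def _fake_decomposition(core, neighbor):
    return Decomposition(
        core_edges=frozenset(core),
        neighbor_edges=frozenset(neighbor),
        provenance={},
        deletion_order=[],
        seeds={},
        sample_size=0,
    )


class TestOverlap:
    def test_self_overlap_jaccard_one(self, toy3):
        dec = decompose(toy3, n_samples=40, seed_init=0, seed_order=0)
        res = decomposition_overlap_test(dec, dec)
        assert res["jaccard"] == 1.0

    def test_perfect_agreement_chi_square_closed_form(self):
        edges = [("u%d" % i, "v%d" % i) for i in range(100)]
        d1 = _fake_decomposition(edges[:50], edges[50:])
        res = decomposition_overlap_test(d1, d1)
        assert res["chi2"] == pytest.approx(100.0)
        assert (res["table"] == np.array([[50, 0], [0, 50]])).all()
        assert res["p"] < 1e-20

    def test_independent_partitions_hypergeometric(self):
        # 575 edges split 408/167 independently twice: overlap ~ hypergeometric
        rng = np.random.default_rng(0)
        edges = [("s%d" % i, "t%d" % i) for i in range(575)]
        p_values = []
        overlaps = []
        for rep in range(5):
            picks = [set(rng.choice(575, size=408, replace=False)) for _ in range(2)]
            ds = [
                _fake_decomposition(
                    [e for i, e in enumerate(edges) if i in pick],
                    [e for i, e in enumerate(edges) if i not in pick],
                )
                for pick in picks
            ]
            res = decomposition_overlap_test(ds[0], ds[1])
            overlaps.append(res["table"][0, 0])
            p_values.append(res["p"])
        expected = 408 * 408 / 575
        sd = np.sqrt(sps.hypergeom(575, 408, 408).var())
        assert abs(np.mean(overlaps) - expected) < 3 * sd
        assert max(p_values) > 0.05  # independent partitions: not all small

    def test_universe_mismatch_raises(self, toy3):
        d1 = _fake_decomposition([("A", "B")], [])
        d2 = _fake_decomposition([("X", "Y")], [])
        with pytest.raises(ValueError):
            decomposition_overlap_test(d1, d2)


class TestPerturbationNovelty:
    def test_toy3_outcomes_are_original_attractors(self, toy3):
        dec = decompose(toy3, n_samples=40, seed_init=0, seed_order=0)
        states = sample_basin_states(toy3, dec.primary, 20, seed=0)
        res = perturbation_novelty(toy3, dec, states, enumerate_attractors(toy3))
        # deleting (C,B) collapses basin states to (0,0,0) - an ORIGINAL attractor
        assert res["fraction_novel"] == 0.0
        assert res["total_new_attractors"] >= 1

    def test_constructed_novel_fixed_point(self):
        # B<->C 2-cycle plus D = B XOR C: primary has D oscillating... deleting
        # (B,D) makes D copy C, creating cycles absent from the original list
        net = BooleanNetwork(
            ["A", "B", "C", "D"],
            {
                "B": LogicTable("B", ("C",), (0, 1)),
                "C": LogicTable("C", ("B",), (0, 1)),
                "D": LogicTable("D", ("B", "C"), (0, 1, 1, 0)),
            },
        )
        land = enumerate_attractors(net)
        prim = primary(land)
        assert prim.length == 2
        states = sample_basin_states(net, prim, 20, seed=0)
        dec = Decomposition(
            core_edges=frozenset({("B", "D")}),
            neighbor_edges=net.edges - {("B", "D")},
            provenance={},
            deletion_order=[],
            seeds={},
            sample_size=20,
            primary=prim,
            landscape=land,
        )
        res = perturbation_novelty(net, dec, states)
        assert res["total_new_attractors"] == 1
        assert res["fraction_novel"] == 1.0

    def test_neighbor_edge_sanity_empty(self, toy3):
        land = enumerate_attractors(toy3)
        prim = primary(land)
        states = sample_basin_states(toy3, prim, 20, seed=0)
        sanity = Decomposition(
            core_edges=frozenset({("A", "B")}),  # actually a neighbor edge
            neighbor_edges=toy3.edges - {("A", "B")},
            provenance={},
            deletion_order=[],
            seeds={},
            sample_size=20,
            primary=prim,
            landscape=land,
        )
        res = perturbation_novelty(toy3, sanity, states)
        assert res["per_edge"][("A", "B")] == set()
        assert res["total_new_attractors"] == 0
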