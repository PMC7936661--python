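import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_4cycles, brute_triangles
from shortloop.motifs import (
    enumerate_short_loops,
    loop_profile,
    loop_ratio,
    partner_pairs,
)
from shortloop.netio import Network
from shortloop.synthdata import gen_er_network
from conftest import complete_graph


def relabelled(network: Network, perm: dict) -> Network:
    return Network.from_edges(
        [(perm[a], perm[b]) for a, b in network.graph.edges],
        nodes=[perm[n] for n in network.graph.nodes],
    )


class TestEnumeration:
    def test_k3_single_triangle(self, k3):
        assert enumerate_short_loops(k3, 3) == {("A", "B", "C")}

    def test_k4_counts(self, k4):
        assert len(enumerate_short_loops(k4, 3)) == 4
        assert len(enumerate_short_loops(k4, 4)) == 3

    def test_chordless_excludes_k4_cycles(self, k4):
        assert enumerate_short_loops(k4, 4, chordless=True) == set()

    def test_plain_4cycle_is_chordless(self):
        c4 = Network.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        assert enumerate_short_loops(c4, 4) == {("A", "B", "C", "D")}
        assert enumerate_short_loops(c4, 4, chordless=True) == {("A", "B", "C", "D")}

    def test_invalid_length(self, k3):
        with pytest.raises(ValueError):
            enumerate_short_loops(k3, 5)

    def test_empty_network(self):
        assert enumerate_short_loops(Network(), 3) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_er_matches_exhaustive_triple_scan(self, seed):
        net = gen_er_network(60, 0.15, seed=seed)
        assert enumerate_short_loops(net, 3) == brute_triangles(net)

    @pytest.mark.parametrize("seed", range(5))
    def test_4cycles_match_exhaustive_quad_scan(self, seed):
        net = gen_er_network(14, 0.35, seed=seed)
        assert enumerate_short_loops(net, 4) == brute_4cycles(net)

    @given(st.integers(0, 10_000), st.floats(0.05, 0.6))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_property(self, seed, p):
        net = gen_er_network(15, p, seed=seed)
        assert enumerate_short_loops(net, 3) == brute_triangles(net)

    def test_edge_deletion_monotone(self):
        net = gen_er_network(20, 0.4, seed=11)
        count = len(enumerate_short_loops(net, 3))
        for a, b in list(net.graph.edges)[:10]:
            smaller = net.copy()
            smaller.graph.remove_edge(a, b)
            assert len(enumerate_short_loops(smaller, 3)) <= count

    def test_relabel_invariance(self):
        net = gen_er_network(20, 0.3, seed=12)
        nodes = sorted(net.nodes)
        rng = np.random.default_rng(0)
        shuffled = [nodes[i] for i in rng.permutation(len(nodes))]
        perm = dict(zip(nodes, shuffled))
        inv = {v: k for k, v in perm.items()}
        once = enumerate_short_loops(net, 3)
        back = {
            tuple(sorted(inv[x] for x in loop))
            for loop in enumerate_short_loops(relabelled(net, perm), 3)
        }
        assert once == back
        assert enumerate_short_loops(net, 3) == once  # deterministic re-run


class TestLoopRatio:
    @pytest.mark.parametrize(
        "n_loops,n_edges,expected",
        [(17443, 14119, 1.24), (228, 367, 0.62), (0, 10, 0.00)],
    )
    def test_printed_precision(self, n_loops, n_edges, expected):
        assert round(loop_ratio(n_loops, n_edges), 2) == expected

    def test_zero_edges_undefined(self):
        with pytest.raises(ValueError):
            loop_ratio(5, 0)


class TestPartnerPairs:
    def test_fan_topology(self, fig_fan):
        loops = enumerate_short_loops(fig_fan, 3)
        pairs = partner_pairs(loops)
        expected = {frozenset("AB"), frozenset("BC"), frozenset("CD")}
        assert pairs["X"] == expected
        assert pairs["Y"] == expected

    def test_k3_each_node_owns_single_pair(self, k3):
        pairs = partner_pairs(enumerate_short_loops(k3, 3))
        assert pairs == {
            "A": {frozenset("BC")},
            "B": {frozenset("AC")},
            "C": {frozenset("AB")},
        }

    def test_counting_identity(self):
        net = gen_er_network(40, 0.2, seed=3)
        loops = enumerate_short_loops(net, 3)
        pairs = partner_pairs(loops)
        assert sum(len(v) for v in pairs.values()) == 3 * len(loops)

    def test_rejects_length4_loops(self):
        with pytest.raises(ValueError):
            partner_pairs({("A", "B", "C", "D")})


class TestLoopProfile:
    def test_k5_closed_form(self, k5):
        prof = loop_profile(k5)
        assert (prof.n_loops, prof.n_edges) == (10, 10)
        assert round(prof.ratio, 2) == 1.00

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_complete_graph_ratio_closed_form(self, n):
        net = complete_graph([f"N{i}" for i in range(n)])
        prof = loop_profile(net)
        assert prof.ratio == pytest.approx((n - 2) / 3)

    def test_consensus_present_only_with_annotations(self, k3):
        assert loop_profile(k3).consensus_pct is None
        prof = loop_profile(k3, annotations={"A": {"T"}, "B": {"T"}, "C": {"T"}})
        assert prof.consensus_pct == 100.0


def test_er_mean_triangle_count_matches_binomial_moment():
    """Over many seeds the mean triangle count of G(n, p) must match the
    closed form C(n,3) p^3 within 3 standard errors."""
    n, p, n_rep = 18, 0.3, 250
    counts = [
        len(enumerate_short_loops(gen_er_network(n, p, seed=s), 3)) for s in range(n_rep)
    ]
    arr = np.asarray(counts, dtype=float)
    expected = (n * (n - 1) * (n - 2) / 6) * p**3
    se = arr.std(ddof=1) / np.sqrt(n_rep)
    assert abs(arr.mean() - expected) <= 3 * se
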