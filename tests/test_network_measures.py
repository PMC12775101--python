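"""Node measures against independent brute-force and igraph oracles."""

import numpy as np
import pandas as pd
import pytest

from oncnet.errors import InvalidConfigError, InvalidInputError, MissingNodeError
from oncnet.network_builder import AnnualNetwork, classify_ties
from oncnet.network_measures import (
    compute_constraint,
    compute_linchpin,
    compute_local_transitivity,
    compute_strength,
    decompose_strength,
    flag_linchpins,
)

# ---------------------------------------------------------------------------
# brute-force oracles on the dense weight matrix


def brute_strength(W, i):
    return W[i].sum()


def brute_transitivity(W, i):
    A = (W > 0).astype(int)
    nbrs = np.flatnonzero(A[i])
    k = len(nbrs)
    if k < 2:
        return None
    closed = sum(
        A[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:]
    )
    return 2 * closed / (k * (k - 1))


def brute_constraint(W, i):
    A = (W > 0).astype(int)
    deg = A.sum(axis=1)
    nbrs = np.flatnonzero(A[i])
    if len(nbrs) == 0:
        return None
    total = 0.0
    for j in nbrs:
        p_ij = 1.0 / deg[i]
        indirect = sum(
            (1.0 / deg[i]) * (1.0 / deg[q])
            for q in nbrs
            if q != j and A[q, j]
        )
        total += (p_ij + indirect) ** 2
    return total


def brute_linchpin(W, spec, i, weighted=True):
    A = W > 0
    nbrs = np.flatnonzero(A[i])
    if len(nbrs) == 0:
        return None
    num = den = 0.0
    for j in nbrs:
        wt = W[i, j] if weighted else 1.0
        den += wt
        if spec[j] == spec[i]:
            continue
        has_alt = any(q != i and spec[q] == spec[i] for q in np.flatnonzero(A[j]))
        if not has_alt:
            num += wt
    return num / den


def random_graph(rng, n=None):
    n = n or int(rng.integers(2, 13))
    W = np.zeros((n, n), dtype=int)
    p = rng.uniform(0.15, 0.7)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                W[a, b] = W[b, a] = int(rng.integers(1, 6))
    specs = rng.choice(
        ["medical oncology", "radiation oncology", "surgery", "other"], size=n
    )
    return W, specs


def to_net(W, year=2017):
    n = len(W)
    edges = [
        (f"N{a:02d}", f"N{b:02d}", W[a, b])
        for a in range(n)
        for b in range(a + 1, n)
        if W[a, b]
    ]
    net = AnnualNetwork.from_edges(year, edges)
    net.add_isolates([f"N{a:02d}" for a in range(n)])
    return net


class TestStrength:
    def test_isolated_node_zero(self):
        net = to_net(np.zeros((3, 3), dtype=int))
        assert compute_strength(net, "N00") == 0.0

    def test_sums_weights(self):
        net = AnnualNetwork.from_edges(
            2017, [("A", "B", 3), ("A", "C", 1), ("A", "D", 2)]
        )
        assert compute_strength(net, "A") == 6.0

    def test_matches_matrix_row_sum(self):
        rng = np.random.default_rng(1)
        W, _ = random_graph(rng, n=8)
        net = to_net(W)
        for i in range(8):
            assert compute_strength(net, f"N{i:02d}") == brute_strength(W, i)

    def test_missing_node_raises(self):
        with pytest.raises(MissingNodeError):
            compute_strength(AnnualNetwork(2017), "X")


class TestTransitivity:
    def test_triangle_is_one(self):
        net = AnnualNetwork.from_edges(
            2017, [("A", "B", 1), ("B", "C", 1), ("A", "C", 1)]
        )
        assert compute_local_transitivity(net, "A") == 1.0

    def test_star_center_is_zero(self):
        net = AnnualNetwork.from_edges(
            2017, [("A", c, 1) for c in "BCDE"]
        )
        assert compute_local_transitivity(net, "A") == 0.0

    def test_degree_below_two_undefined(self):
        net = AnnualNetwork.from_edges(2017, [("A", "B", 1)])
        assert compute_local_transitivity(net, "A") is None


class TestConstraint:
    def test_single_neighbor_gives_one(self):
        net = AnnualNetwork.from_edges(2017, [("A", "B", 5)])
        assert compute_constraint(net, "A") == pytest.approx(1.0)

    def test_complete_triad_value(self):
        net = AnnualNetwork.from_edges(
            2017, [("A", "B", 1), ("B", "C", 1), ("A", "C", 1)]
        )
        # each tie: (1/2 + 1/2 * 1/2)^2 = 0.5625, twice
        assert compute_constraint(net, "A") == pytest.approx(1.125)

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_star_center_closed_form(self, k):
        net = AnnualNetwork.from_edges(
            2017, [("A", f"L{i}", 1) for i in range(k)]
        )
        assert compute_constraint(net, "A") == pytest.approx(1.0 / k)

    def test_isolated_undefined(self):
        net = to_net(np.zeros((2, 2), dtype=int))
        assert compute_constraint(net, "N00") is None


class TestLinchpin:
    def specs(self, net, mapping):
        return mapping

    def test_all_neighbors_dependent_scores_one(self):
        net = AnnualNetwork.from_edges(2017, [("A", "B", 2), ("A", "C", 1)])
        spec = {"A": "medical oncology", "B": "surgery", "C": "other"}
        assert compute_linchpin(net, "A", spec) == 1.0

    def test_all_neighbors_have_alternatives_scores_zero(self):
        net = AnnualNetwork.from_edges(
            2017,
            [("A", "B", 2), ("A", "C", 1), ("B", "M", 1), ("C", "M", 1)],
        )
        spec = {"A": "medical oncology", "B": "surgery", "C": "other",
                "M": "medical oncology"}
        assert compute_linchpin(net, "A", spec) == 0.0

    def test_weighted_mix(self):
        # j1 (w=3) dependent, j2 (w=1) has an alternative -> 3/4
        net = AnnualNetwork.from_edges(
            2017, [("A", "J1", 3), ("A", "J2", 1), ("J2", "M", 1)]
        )
        spec = {"A": "medical oncology", "J1": "surgery", "J2": "surgery",
                "M": "medical oncology"}
        assert compute_linchpin(net, "A", spec) == pytest.approx(0.75)

    def test_unweighted_form_and_unit_weight_agreement(self):
        rng = np.random.default_rng(3)
        W, specs = random_graph(rng, n=9)
        W01 = (W > 0).astype(int)
        net = to_net(W01)
        smap = {f"N{i:02d}": s for i, s in enumerate(specs)}
        for i in range(9):
            name = f"N{i:02d}"
            if net.degree(name) == 0:
                continue
            assert compute_linchpin(net, name, smap, weighted=True) == (
                compute_linchpin(net, name, smap, weighted=False)
            )

    def test_missing_specialty_label_rejected(self):
        net = AnnualNetwork.from_edges(2017, [("A", "B", 1)])
        with pytest.raises(InvalidInputError):
            compute_linchpin(net, "A", {"B": "surgery"})


class TestLinchpinFlags:
    def test_top_three_of_twenty_distinct(self):
        scores = pd.Series(np.linspace(0.01, 0.96, 20))
        specs = pd.Series(["medical oncology"] * 20)
        flags = flag_linchpins(scores, specs, pct=0.15)
        assert flags.sum() == 3
        assert flags[scores.nlargest(3).index].all()

    def test_all_tied_scores_all_flagged(self):
        scores = pd.Series([0.4] * 7)
        specs = pd.Series(["surgery"] * 7)
        assert flag_linchpins(scores, specs, pct=0.15).all()

    def test_pct_one_rejected(self):
        with pytest.raises(InvalidConfigError):
            flag_linchpins(pd.Series([0.1, 0.2]), pd.Series(["a", "a"]), pct=1.0)

    def test_small_specialty_never_flagged(self):
        scores = pd.Series([0.9, np.nan, 0.2, 0.3])
        specs = pd.Series(["surgery", "surgery", "medical oncology",
                           "medical oncology"])
        flags = flag_linchpins(scores, specs, pct=0.15)
        assert not flags[specs == "surgery"].any()


class TestDecomposition:
    def test_all_persistent(self):
        prev = AnnualNetwork.from_edges(2017, [("A", "B", 1), ("A", "C", 1)])
        cur = AnnualNetwork.from_edges(2018, [("A", "B", 4), ("A", "C", 2)])
        ties = classify_ties(cur, prev)
        assert decompose_strength(cur, ties, "A") == (6.0, 0.0)

    def test_empty_prior_all_new(self):
        cur = AnnualNetwork.from_edges(2018, [("A", "B", 4)])
        ties = classify_ties(cur, AnnualNetwork(2017))
        assert decompose_strength(cur, ties, "A") == (0.0, 4.0)

    def test_conserves_total_strength(self):
        rng = np.random.default_rng(11)
        W1, _ = random_graph(rng, n=10)
        W2, _ = random_graph(rng, n=10)
        prev, cur = to_net(W1, 2017), to_net(W2, 2018)
        ties = classify_ties(cur, prev)
        for i in range(10):
            name = f"N{i:02d}"
            pers, new = decompose_strength(cur, ties, name)
            assert pers + new == compute_strength(cur, name)


class TestOracleEquivalence:
    """Systematic agreement with brute force and igraph on random graphs."""

    def test_bruteforce_agreement(self):
        rng = np.random.default_rng(2024)
        for _ in range(250):
            W, specs = random_graph(rng)
            net = to_net(W)
            smap = {f"N{i:02d}": s for i, s in enumerate(specs)}
            for i in range(len(W)):
                name = f"N{i:02d}"
                assert compute_strength(net, name) == brute_strength(W, i)
                bt = brute_transitivity(W, i)
                ct = compute_local_transitivity(net, name)
                assert (ct is None) == (bt is None)
                if bt is not None:
                    assert ct == pytest.approx(bt, abs=1e-12)
                bc = brute_constraint(W, i)
                cc = compute_constraint(net, name)
                assert (cc is None) == (bc is None)
                if bc is not None:
                    assert cc == pytest.approx(bc, abs=1e-12)
                if specs[i] != "other" and W[i].sum() > 0:
                    assert compute_linchpin(net, name, smap) == pytest.approx(
                        brute_linchpin(W, specs, i), abs=1e-12
                    )

    def test_igraph_agreement(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(7)
        for _ in range(40):
            W, _ = random_graph(rng)
            n = len(W)
            edges = [(a, b) for a in range(n) for b in range(a + 1, n) if W[a, b]]
            g = igraph.Graph(n=n, edges=edges)
            net = to_net(W)
            trans = g.transitivity_local_undirected(mode="nan")
            cons = g.constraint()
            for i in range(n):
                name = f"N{i:02d}"
                ct = compute_local_transitivity(net, name)
                if ct is not None and not np.isnan(trans[i]):
                    assert ct == pytest.approx(trans[i], abs=1e-9)
                cc = compute_constraint(net, name)
                if cc is not None and not np.isnan(cons[i]):
                    assert cc == pytest.approx(cons[i], abs=1e-9)

    def test_measure_ranges_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(150):
            W, specs = random_graph(rng)
            net = to_net(W)
            smap = {f"N{i:02d}": s for i, s in enumerate(specs)}
            for i in range(len(W)):
                name = f"N{i:02d}"
                t = compute_local_transitivity(net, name)
                if t is not None:
                    assert 0.0 <= t <= 1.0
                c = compute_constraint(net, name)
                if c is not None:
                    assert c > 0.0
                if specs[i] != "other" and net.degree(name) > 0:
                    ell = compute_linchpin(net, name, smap)
                    assert 0.0 <= ell <= 1.0
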