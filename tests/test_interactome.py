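import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import lower_tail, upper_tail
from bloodsig.errors import ValidationError
from bloodsig.interactome import (ConnectivityStats, connectivity_stats,
                                  map_genes_to_objects, overconnected_pairs,
                                  overconnected_set, regulator_enrichment,
                                  topology_summary)
from bloodsig.io_formats import InteractionNetwork
from bloodsig.synthetic import simulate_expression, simulate_network
from conftest import small_config

# Published reference rows for the over-connectivity statistic:
# (object, A, n, R, N, E, ratio, z, p) as printed.
REFERENCE_ROWS = [
    ("IRF9",     7, 102,  60, 26494, "0.231", "30.3", "14.1", "3.32e-09"),
    ("STAT1",   22, 102, 575, 26494, "2.21",  "9.9",  "13.5", "4.04e-16"),
    ("FCGR2B",   2, 102,  35, 26494, "0.135", "14.8", "5.1",  "0.0080"),
    ("PKC-delta", 8, 102, 386, 26494, "1.486", "5.4", "5.4",  "0.0001"),
    ("PSMB9",    3, 102,  38, 26494, "0.146", "20.5", "7.5",  "0.0004"),
    ("PSMB8",    2, 102,  30, 26494, "0.115", "17.3", "5.6",  "0.0059"),
    ("SHP-1",    5, 102, 200, 26494, "0.770", "6.5",  "4.8",  "0.0010"),
    ("MxA",      3, 102,  57, 26494, "0.219", "13.7", "6.0",  "0.0013"),
    ("IFIT1",    4, 102,  15, 26494, "0.058", "69.3", "16.4", "2.74e-07"),
    ("TOM34",    2, 102,  21, 26494, "0.081", "24.7", "6.8",  "0.0029"),
    ("RIG-G",    6, 102,  66, 26494, "0.254", "23.6", "11.4", "2.11e-07"),
    ("C1-inh",   2, 102,  23, 26494, "0.089", "22.6", "6.4",  "0.0035"),
    ("p40-phox", 2, 102,  23, 26494, "0.089", "22.6", "6.4",  "0.0035"),
    ("TAP1",     4, 102,  51, 26494, "0.196", "20.4", "8.6",  "4.5e-05"),
    ("ISG15",    8, 102, 256, 26494, "0.986", "8.1",  "7.1",  "6.83e-06"),
]


def assert_printed(value: float, printed: str):
    """Agreement with a printed number to one unit in its last digit
    (covers both rounding and truncation in the source table)."""
    mantissa = printed.lower().split("e")[0]
    decimals = len(mantissa.split(".")[1]) if "." in mantissa else 0
    exponent = int(printed.lower().split("e")[1]) if "e" in printed.lower() else 0
    ulp = 10.0 ** (exponent - decimals)
    assert abs(value - float(printed)) <= ulp, (value, printed)


def star_network(center="HUB", n_leaves=4, extra_nodes=0):
    g = nx.DiGraph()
    leaves = [f"L{i}" for i in range(n_leaves)]
    for leaf in leaves:
        g.add_edge(center, leaf, sign=1)
    for i in range(extra_nodes):
        g.add_node(f"X{i}")
    return InteractionNetwork(g, {f"gene_{x}": x for x in [center] + leaves})


class TestConnectivityFormulas:
    @pytest.mark.parametrize("name,A,n,R,N,E,ratio,z,p", REFERENCE_ROWS)
    def test_reference_rows_reproduced(self, name, A, n, R, N, E, ratio, z, p):
        s = ConnectivityStats.from_counts(name, A=A, n=n, R=R, N=N)
        assert_printed(s.E, E)
        assert_printed(s.ratio, ratio)
        assert_printed(s.z, z)
        assert_printed(s.p, p)
        assert s.direction == "over"

    def test_exact_toy_tail(self):
        # N=10, n=5, R=2, A=1: E=1, z=0, upper tail 1 - C(8,5)/C(10,5)
        s = ConnectivityStats.from_counts("t", A=1, n=5, R=2, N=10)
        assert s.E == pytest.approx(1.0)
        assert s.z == pytest.approx(0.0)
        assert s.p == pytest.approx(1 - math.comb(8, 5) / math.comb(10, 5))
        assert s.p == pytest.approx(0.7778, abs=1e-4)

    def test_under_connected_uses_lower_tail(self):
        s = ConnectivityStats.from_counts("t", A=0, n=50, R=40, N=100)
        assert s.z < 0
        assert s.p == pytest.approx(lower_tail(0, 100, 40, 50), rel=1e-9)
        assert s.direction == "under"

    def test_isolated_object_flagged(self):
        s = ConnectivityStats.from_counts("t", A=0, n=5, R=0, N=10)
        assert s.direction == "isolated"
        assert math.isnan(s.z)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_tails_match_enumeration_oracle(self, data):
        N = data.draw(st.integers(2, 500))
        n = data.draw(st.integers(1, N))
        R = data.draw(st.integers(1, N))
        A = data.draw(st.integers(0, min(n, R)))
        if n - A > N - R:      # impossible configuration
            A = n - (N - R)
        s = ConnectivityStats.from_counts("x", A=A, n=n, R=R, N=N)
        expect = (upper_tail(A, N, R, n) if s.z >= 0
                  else lower_tail(A, N, R, n))
        assert s.p == pytest.approx(expect, rel=1e-9, abs=1e-300)

    def test_upper_tail_monotone_in_A(self):
        n, R, N = 40, 30, 300
        ps = [ConnectivityStats.from_counts("x", A=a, n=n, R=R, N=N).p
              for a in range(int(n * R / N) + 1, min(n, R) + 1)]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_z_antisymmetric_about_expectation(self):
        n, R, N = 50, 20, 200      # E = 5
        E = n * R / N
        for d in (1, 2, 3):
            up = ConnectivityStats.from_counts("x", A=int(E + d), n=n, R=R, N=N)
            dn = ConnectivityStats.from_counts("x", A=int(E - d), n=n, R=R, N=N)
            assert up.z == pytest.approx(-dn.z)


class TestMapping:
    def test_gene_family_maps_to_one_object(self):
        g = nx.DiGraph()
        g.add_edge("MxA", "OBJ2", sign=1)
        net = InteractionNetwork(g, {"MX1": "MxA", "MX2": "MxA"})
        mapping = map_genes_to_objects(["MX1", "MX2"], net)
        assert mapping.objects == {"MxA"}

    def test_empty_gene_list(self):
        net = star_network()
        assert map_genes_to_objects([], net).objects == set()

    def test_shared_objects_reduce_n(self):
        g = nx.DiGraph()
        for o in ("O1", "O2", "O3"):
            g.add_node(o)
        net = InteractionNetwork(
            g, {"a": "O1", "b": "O1", "c": "O2", "d": "O2", "e": "O3"})
        mapping = map_genes_to_objects(["a", "b", "c", "d", "e", "zz"], net)
        assert len(mapping.objects) == 3
        assert mapping.unmapped == ["zz"]


class TestSelfExclusion:
    def test_object_in_dataset_not_its_own_neighbor(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", sign=1)
        g.add_edge("C", "A", sign=1)
        for i in range(20):
            g.add_node(f"N{i}")
        net = InteractionNetwork(g, {})
        s = connectivity_stats("A", {"A", "B"}, net)
        assert s.A == 1      # B only; A itself excluded
        assert s.R == 2


class TestOverconnectedSet:
    def test_planted_hubs_recovered(self):
        cfg = small_config(seed=7, hub_neighborhood_deg_frac=0.8)
        _, _, truth = simulate_expression(cfg)
        net, truth = simulate_network(cfg, truth)
        dataset = {net.gene_to_object[g] for g in truth.deg_genes}
        result = overconnected_set(dataset, net)
        over_ids = [s.object_id for s in result.over]
        assert truth.hub_objects <= set(over_ids)
        # strongly rewired hubs rank at the top by z
        by_z = sorted(result.over, key=lambda s: -s.z)
        top = {s.object_id for s in by_z[:len(truth.hub_objects)]}
        assert truth.hub_objects == top

    def test_alpha_zero_empty(self):
        cfg = small_config(seed=7)
        _, _, truth = simulate_expression(cfg)
        net, truth = simulate_network(cfg, truth)
        dataset = {net.gene_to_object[g] for g in truth.deg_genes}
        result = overconnected_set(dataset, net, alpha=0.0)
        assert result.over == [] and result.under == []

    def test_null_false_positive_rate_bounded(self):
        # no planted hubs, random dataset objects: P(p < alpha) stays at
        # or below alpha (exact discrete tails are conservative)
        cfg = small_config(seed=9, n_hub_plants=0)
        _, _, truth = simulate_expression(cfg)
        net, _ = simulate_network(cfg, truth)
        rng = np.random.default_rng(0)
        objs = sorted(net.objects)
        flagged, total = 0, 0
        for _ in range(30):
            dataset = set(rng.choice(objs, size=40, replace=False))
            res = overconnected_set(dataset, net)
            flagged += len(res.over) + len(res.under)
            total += len(objs) - len(res.isolated)
        rate = flagged / total
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestPairs:
    def test_isolated_over_set_no_pairs(self):
        net = star_network(extra_nodes=3)
        report = overconnected_pairs(["X0", "X1", "X2"], net)
        assert report.pairs == []
        assert all(c == 0 for _, c in report.counts)

    def test_triangle(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", sign=1)
        g.add_edge("B", "C", sign=1)
        g.add_edge("C", "A", sign=-1)
        net = InteractionNetwork(g, {})
        report = overconnected_pairs(["A", "B", "C"], net)
        assert len(report.pairs) == 3
        assert all(c == 2 for _, c in report.counts)

    def test_planted_clique_top_count(self):
        g = nx.DiGraph()
        clique = ["H1", "H2", "H3", "H4"]
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v, sign=1)
        g.add_edge("H1", "OUT", sign=1)
        g.add_node("LONER")
        net = InteractionNetwork(g, {})
        report = overconnected_pairs(clique + ["LONER"], net)
        assert report.counts[0][1] == 3
        assert dict(report.counts)["LONER"] == 0


class TestRegulatorEnrichment:
    def test_tf_covering_deg_set_dominates(self):
        uni = [f"g{i}" for i in range(200)]
        degs = uni[:20]
        tfs = {"TF_exact": degs,
               "TF_half": degs[:10] + uni[100:110],
               "TF_null": uni[100:120]}
        ranked = regulator_enrichment(tfs, degs, uni)
        assert ranked[0].object_id == "TF_exact"
        assert [s.object_id for s in ranked][-1] == "TF_null"

    def test_hidden_regulator_recovered(self):
        # planted regulator with 70% DEG targets ranks top-3 of 50 TFs
        rng = np.random.default_rng(5)
        uni = [f"g{i}" for i in range(1000)]
        degs = set(uni[i] for i in rng.choice(1000, 100, replace=False))
        deg_list = sorted(degs)
        other = [g for g in uni if g not in degs]
        tfs = {}
        for i in range(49):
            tfs[f"TF{i:02d}"] = [uni[j] for j in
                                 rng.choice(1000, 30, replace=False)]
        tfs["PLANTED"] = (deg_list[:21]
                          + [other[j] for j in rng.choice(len(other), 9,
                                                          replace=False)])
        ranked = regulator_enrichment(tfs, deg_list, uni)
        assert "PLANTED" in [s.object_id for s in ranked[:3]]
        # the planted TF is "hidden": it needs no entry in the DEG list

    def test_zero_overlap_large_target_set_is_under(self):
        uni = [f"g{i}" for i in range(300)]
        ranked = regulator_enrichment({"TF": uni[100:250]}, uni[:50], uni)
        assert ranked[0].z < 0
        assert ranked[0].direction == "under"

    def test_empty_target_set_skipped(self, caplog):
        uni = [f"g{i}" for i in range(50)]
        with caplog.at_level("WARNING"):
            ranked = regulator_enrichment({"TF_e": [], "TF_ok": uni[:5]},
                                          uni[:10], uni)
        assert [s.object_id for s in ranked] == ["TF_ok"]
        assert "empty target set" in caplog.text


class TestTopology:
    def test_star_center_degree_split(self):
        net = star_network(n_leaves=5)
        topo = topology_summary({"HUB"}, net)
        row = topo.degrees.loc["HUB"]
        assert row["out_within"] == 0
        assert row["out_to_background"] == 5
        assert row["in_within"] == 0 and row["in_from_background"] == 0

    def test_triangle_clustering_is_one(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", sign=1)
        g.add_edge("B", "C", sign=1)
        g.add_edge("C", "A", sign=1)
        g.add_edge("A", "D", sign=1)   # background appendage
        net = InteractionNetwork(g, {})
        topo = topology_summary({"A", "B", "C"}, net)
        assert topo.mean_clustering_dataset == pytest.approx(1.0)

    def test_mean_clustering_matches_brute_force(self):
        cfg = small_config(seed=13)
        _, _, truth = simulate_expression(cfg)
        net, _ = simulate_network(cfg, truth)
        und = net.undirected()
        topo = topology_summary(set(), net)

        def local_cc(g, v):
            nbrs = list(g.neighbors(v))
            k = len(nbrs)
            if k < 2:
                return 0.0
            links = sum(1 for i in range(k) for j in range(i + 1, k)
                        if g.has_edge(nbrs[i], nbrs[j]))
            return 2 * links / (k * (k - 1))

        brute = np.mean([local_cc(und, v) for v in und.nodes])
        assert topo.mean_clustering_background == pytest.approx(brute)
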