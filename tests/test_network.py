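"""Ortholog mapping, regulome projection, direction annotation, exports."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lazpipe.network import (
    ProjectedNetwork,
    annotate_directions,
    export_network,
    load_edges,
    load_ortholog_map,
    load_table1,
    map_to_regulome,
    project_network,
)

FIG5_EDGES = pd.DataFrame(
    [("ANT", "X", "activation"), ("AIL6", "X", "activation"),
     ("X", "GNC", "repression"), ("X", "GNL", "repression")],
    columns=["regulator", "target", "mode"],
)


def _map(pairs):
    return load_ortholog_map(
        pd.DataFrame(pairs, columns=["soy_id", "at_id"]).assign(score=90.0)
    )


class TestOrthologMap:
    def test_best_match_tie_breaking(self):
        df = pd.DataFrame(
            {"soy_id": ["s1", "s1", "s1"], "at_id": ["AT3", "AT1", "AT2"],
             "score": [80.0, 95.0, 95.0]}
        )
        best = load_ortholog_map(df)
        assert len(best) == 1
        assert best.loc[0, "at_id"] == "AT1"  # highest score, then lexicographic


class TestMapping:
    def test_table1_fixture_yields_40_distinct(self):
        t1 = load_table1()
        assert len(t1) == 58
        edges = pd.DataFrame(
            {"regulator": t1["at_id"], "target": t1["at_id"], "mode": "unknown"}
        )
        res = map_to_regulome(set(t1["soy_id"]), load_ortholog_map(t1), edges)
        assert res.n_distinct == 40

    def test_empty_soy_set(self):
        res = map_to_regulome(set(), _map([("s1", "A")]), FIG5_EDGES)
        assert res.matched == set() and res.n_distinct == 0

    def test_shared_at_id_multiplicity(self):
        res = map_to_regulome(
            {"s1", "s2"}, _map([("s1", "ANT"), ("s2", "ANT")]), FIG5_EDGES
        )
        assert res.n_distinct == 1
        assert res.soy_members["ANT"] == ["s1", "s2"]

    def test_missing_soy_reported_not_fatal(self):
        res = map_to_regulome({"s1", "ghost"}, _map([("s1", "ANT")]), FIG5_EDGES)
        assert res.missing_soy == ["ghost"]
        assert res.matched == {"ANT"}


class TestProjection:
    def test_bridge_connects_matched_quartet(self):
        net = project_network({"ANT", "AIL6", "GNC", "GNL"}, FIG5_EDGES, bridge=True)
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 4
        assert net.graph.nodes["X"]["role"] == "bridge"
        assert len(net.components) == 1

    def test_without_bridge_nodes_are_isolated(self):
        net = project_network({"ANT", "AIL6", "GNC", "GNL"}, FIG5_EDGES, bridge=False)
        assert net.graph.number_of_nodes() == 4
        assert net.graph.number_of_edges() == 0
        assert len(net.components) == 4

    def test_bridge_needs_two_matched_neighbors(self):
        net = project_network({"ANT"}, FIG5_EDGES, bridge=True)
        assert set(net.graph.nodes) == {"ANT"}

    def test_projection_monotone(self):
        small = project_network({"ANT", "AIL6"}, FIG5_EDGES, bridge=True)
        big = project_network({"ANT", "AIL6", "GNC", "GNL"}, FIG5_EDGES, bridge=True)
        assert set(small.graph.nodes) <= set(big.graph.nodes)
        assert set(small.graph.edges) <= set(big.graph.edges)

    def test_induced_subgraph_matches_bruteforce_filter(self):
        rng = np.random.default_rng(4)
        ids = [f"AT{i}" for i in range(12)]
        edges = pd.DataFrame(
            {"regulator": rng.choice(ids, 40), "target": rng.choice(ids, 40),
             "mode": rng.choice(["activation", "repression"], 40)}
        ).drop_duplicates(["regulator", "target"])
        matched = set(rng.choice(ids, 5, replace=False))
        net = project_network(matched, edges, bridge=False)
        brute = {
            (u, v) for u, v in zip(edges["regulator"], edges["target"])
            if u in matched and v in matched
        }
        assert set(net.graph.edges) == brute
        assert set(net.graph.nodes) == matched

    def test_synthetic_truth_recovered(self, bundle):
        mapping = map_to_regulome(
            bundle.planted_specific_tfs, load_ortholog_map(bundle.ortholog_map), bundle.edges
        )
        net = project_network(mapping.matched, bundle.edges, bridge=True,
                              soy_members=mapping.soy_members)
        expected_nodes = dict(zip(bundle.truth_network_nodes["at_id"],
                                  bundle.truth_network_nodes["role"]))
        assert {n: d["role"] for n, d in net.graph.nodes(data=True)} == expected_nodes
        expected_edges = set(bundle.truth_network_edges.itertuples(index=False, name=None))
        assert {(u, v, d["mode"]) for u, v, d in net.graph.edges(data=True)} == expected_edges


def _diff_for(genes_s):
    times = (0, 12, 24, 48, 72)
    rows = {}
    for g, s12 in genes_s.items():
        row = {}
        for t in times:
            row[f"S_{t}"] = s12 if t == 12 else 0.0
            row[f"p_S_{t}"] = 0.001
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class TestDirections:
    def test_up_down_mixed_none(self):
        edges = pd.DataFrame(
            [("A", "B", "activation"), ("A", "X", "activation"), ("X", "B", "repression")],
            columns=["regulator", "target", "mode"],
        )
        members = {"A": ["s_up"], "B": ["s_up2", "s_down"]}
        net = project_network({"A", "B"}, edges, bridge=True, soy_members=members)
        diff = _diff_for({"s_up": 4.1, "s_up2": 3.5, "s_down": -4.0})
        annotate_directions(net, diff)
        assert net.graph.nodes["A"]["direction_class"] == "up"
        assert net.graph.nodes["B"]["direction_class"] == "mixed"
        assert net.graph.nodes["X"]["direction_class"] == "none"

    def test_down_and_no_signal(self):
        edges = pd.DataFrame([("A", "B", "activation")],
                             columns=["regulator", "target", "mode"])
        net = project_network({"A", "B"}, edges, bridge=False,
                              soy_members={"A": ["s1"], "B": ["s2"]})
        diff = _diff_for({"s1": -4.0, "s2": 1.0})
        annotate_directions(net, diff)
        assert net.graph.nodes["A"]["direction_class"] == "down"
        assert net.graph.nodes["B"]["direction_class"] == "none"


class TestExport:
    def test_sif_line(self):
        edges = pd.DataFrame([("A", "B", "activation")],
                             columns=["regulator", "target", "mode"])
        net = project_network({"A", "B"}, edges, bridge=False)
        assert export_network(net, "sif").splitlines()[0] == "A activation B"

    def test_empty_network_is_valid(self):
        net = project_network(set(), FIG5_EDGES, bridge=False)
        assert export_network(net, "sif") == ""
        table = export_network(net, "nodes")
        assert table.splitlines()[0].startswith("at_id")

    def test_graphml_roundtrip(self, bundle):
        mapping = map_to_regulome(
            bundle.planted_specific_tfs, load_ortholog_map(bundle.ortholog_map), bundle.edges
        )
        net = project_network(mapping.matched, bundle.edges, bridge=True,
                              soy_members=mapping.soy_members)
        text = export_network(net, "graphml")
        g = nx.parse_graphml(text)
        assert set(g.nodes) == set(net.graph.nodes)
        assert {(u, v) for u, v in g.edges} == set(net.graph.edges)
        assert g.nodes[sorted(g.nodes)[0]]["role"] in {"matched", "bridge"}

    def test_export_is_byte_stable(self, bundle):
        mapping = map_to_regulome(
            bundle.planted_specific_tfs, load_ortholog_map(bundle.ortholog_map), bundle.edges
        )
        nets = [
            project_network(mapping.matched, bundle.edges, bridge=True,
                            soy_members=mapping.soy_members)
            for _ in range(2)
        ]
        for fmt in ("sif", "graphml", "nodes", "edges"):
            assert export_network(nets[0], fmt) == export_network(nets[1], fmt)

    def test_unsupported_format(self):
        net = project_network(set(), FIG5_EDGES, bridge=False)
        with pytest.raises(ValueError, match="unsupported"):
            export_network(net, "xgmml")

    def test_mode_normalization(self):
        df = pd.DataFrame([("A", "B", "binds")], columns=["regulator", "target", "mode"])
        assert load_edges(df)["mode"].iloc[0] == "unknown"
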