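"""Cross-species projection of abscission-specific TFs onto a signed regulome.

Soybean TF genes are mapped through a best-match ortholog table to
Arabidopsis identifiers, intersected with the vocabulary of a curated
directed, signed (activation/repression) TF-target edge table in the style
of the Arabidopsis Transcriptional Regulatory Map, and the induced subgraph
is extracted.  Optionally, "bridge" nodes — regulome genes with no soybean
member but adjacent to at least two matched nodes — are admitted so that
indirect matched-matched connections are visible.  Nodes carry the tissue
direction of their soybean members (up = LAZ-high, down = NAZ-high) and the
result exports to SIF, GraphML, and node/edge TSVs for Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

EDGE_MODES = ("activation", "repression", "unknown")


def load_ortholog_map(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Best-match map (soy_id, at_id, score); ties resolved by highest score
    then lexicographically smallest at_id, leaving one at_id per soy_id."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    df = df.rename(columns={df.columns[0]: "soy_id", df.columns[1]: "at_id"})
    if "score" not in df.columns:
        df["score"] = 0.0
    df = df.sort_values(["soy_id", "score", "at_id"], ascending=[True, False, True])
    return df.drop_duplicates("soy_id", keep="first").reset_index(drop=True)


def load_edges(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["regulator", "target", "mode"]))
    )
    df["mode"] = df["mode"].where(df["mode"].isin(EDGE_MODES), "unknown")
    return df[["regulator", "target", "mode"]]


def load_table1() -> pd.DataFrame:
    """Packaged transcription of the study's soy TF -> Arabidopsis best-match table."""
    with resources.files("lazpipe.data").joinpath("table1_orthologs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class MappingResult:
    matched: set[str]  # at_ids present in the edge-table vocabulary
    n_distinct: int
    soy_members: dict[str, list[str]]  # at_id -> soy genes (multiplicity retained)
    missing_soy: list[str]  # soy genes absent from the map


def map_to_regulome(soy_set, ortholog_map: pd.DataFrame, edges: pd.DataFrame) -> MappingResult:
    """Intersect the soy set's best matches with the regulome vocabulary."""
    soy_set = set(soy_set)
    mapping = ortholog_map.set_index("soy_id")["at_id"]
    missing = sorted(soy_set - set(mapping.index))
    vocab = set(edges["regulator"]) | set(edges["target"])
    members: dict[str, list[str]] = {}
    for soy in sorted(soy_set & set(mapping.index)):
        at = mapping[soy]
        members.setdefault(at, []).append(soy)
    matched = {at for at in members if at in vocab}
    return MappingResult(
        matched=matched,
        n_distinct=len(matched),
        soy_members={at: soys for at, soys in members.items() if at in matched},
        missing_soy=missing,
    )


@dataclass
class ProjectedNetwork:
    graph: nx.DiGraph
    components: list[set[str]] = field(default_factory=list)

    @property
    def largest_component(self) -> set[str]:
        return self.components[0] if self.components else set()

    def nodes_table(self) -> pd.DataFrame:
        rows = [
            {
                "at_id": n,
                "role": d["role"],
                "direction_class": d.get("direction_class", "none"),
                "soy_members": ",".join(d.get("soy_members", [])),
                "in_largest_component": n in self.largest_component,
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["at_id", "role", "direction_class", "soy_members", "in_largest_component"])

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"regulator": u, "target": v, "mode": d["mode"], "self_loop": u == v}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "mode", "self_loop"])


def project_network(
    matched,
    edges: pd.DataFrame,
    bridge: bool = True,
    soy_members: dict[str, list[str]] | None = None,
    min_bridge_degree: int = 2,
) -> ProjectedNetwork:
    """Induced subgraph of the regulome on the matched set, plus optional bridges.

    A bridge is an unmatched regulome node adjacent (either direction) to at
    least `min_bridge_degree` distinct matched nodes.
    """
    matched = set(matched)
    nodes = set(matched)
    if bridge:
        neighbor_count: dict[str, set[str]] = {}
        for u, v in zip(edges["regulator"], edges["target"]):
            if u in matched and v not in matched:
                neighbor_count.setdefault(v, set()).add(u)
            if v in matched and u not in matched:
                neighbor_count.setdefault(u, set()).add(v)
        nodes |= {n for n, adj in neighbor_count.items() if len(adj) >= min_bridge_degree}

    g = nx.DiGraph()
    for n in sorted(nodes):
        role = "matched" if n in matched else "bridge"
        g.add_node(
            n,
            role=role,
            soy_members=sorted((soy_members or {}).get(n, [])),
            direction_class="none",
        )
    mask = edges["regulator"].isin(nodes) & edges["target"].isin(nodes)
    for row in edges[mask].itertuples(index=False):
        g.add_edge(row.regulator, row.target, mode=row.mode)
    components = sorted(
        (set(c) for c in nx.weakly_connected_components(g)),
        key=lambda c: (-len(c), sorted(c)),
    )
    return ProjectedNetwork(graph=g, components=components)


def annotate_directions(
    net: ProjectedNetwork,
    diff: pd.DataFrame,
    fold_log2: float = 3.0,
    p_threshold: float = 0.015,
) -> ProjectedNetwork:
    """Attach direction_class per node from its soy members' specificity ratios.

    A member is "up" if some S_t > fold_log2 with p < p_threshold (LAZ-high),
    "down" for S_t < -fold_log2.  Nodes are up/down when all members agree,
    mixed when both occur, none for bridges or members without signal.
    """
    times = sorted(int(c[2:]) for c in diff.columns if c.startswith("S_"))
    S = diff[[f"S_{t}" for t in times]]
    P = diff[[f"p_S_{t}" for t in times]]
    for node, data in net.graph.nodes(data=True):
        members = data.get("soy_members") or []
        dirs: set[str] = set()
        for soy in members:
            if soy not in diff.index:
                continue
            s = S.loc[soy].to_numpy()
            p = P.loc[soy].to_numpy()
            if ((s > fold_log2) & (p < p_threshold)).any():
                dirs.add("up")
            if ((s < -fold_log2) & (p < p_threshold)).any():
                dirs.add("down")
        if data["role"] == "bridge" or not dirs:
            data["direction_class"] = "none"
        elif dirs == {"up"}:
            data["direction_class"] = "up"
        elif dirs == {"down"}:
            data["direction_class"] = "down"
        else:
            data["direction_class"] = "mixed"
    return net


def export_network(net: ProjectedNetwork, fmt: str) -> str:
    """Serialize to `sif`, `graphml`, `nodes` or `edges` (TSV); byte-stable ordering."""
    fmt = fmt.lower()
    if fmt == "sif":
        lines = [
            f"{u} {d['mode']} {v}" for u, v, d in sorted(net.graph.edges(data=True))
        ]
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
        lines += isolated
        return "\n".join(lines) + ("\n" if lines else "")
    if fmt == "graphml":
        g = nx.DiGraph()
        for n, d in sorted(net.graph.nodes(data=True)):
            g.add_node(
                n,
                role=d["role"],
                direction_class=d.get("direction_class", "none"),
                soy_members=",".join(d.get("soy_members", [])),
            )
        for u, v, d in sorted(net.graph.edges(data=True)):
            g.add_edge(u, v, mode=d["mode"])
        return "\n".join(nx.generate_graphml(g)) + "\n"
    if fmt == "nodes":
        return net.nodes_table().to_csv(sep="\t", index=False)
    if fmt == "edges":
        return net.edges_table().to_csv(sep="\t", index=False)
    raise ValueError(f"unsupported export format: {fmt!r} (use sif, graphml, nodes, edges)")
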