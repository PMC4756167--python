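"""GO over-representation: ontology loading, true-path propagation, hypergeometric tests.

The test follows the classic over-representation recipe: with N background
genes of which K carry a term, and a test set of n genes of which k carry it,
p is the hypergeometric upper tail P(X >= k).  Annotations are first closed
under the true-path rule (a gene annotated to a term is annotated to every
is_a / part_of ancestor), the tested universe is restricted to background
genes with at least one propagated annotation, only terms present in the
test set (k >= 1) are tested, and Benjamini-Hochberg adjustment is applied
within the tested terms at FDR 0.05.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
RELATIONS = ("is_a", "part_of")


def load_ontology(obo: str | Path) -> nx.MultiDiGraph:
    """Parse OBO text or a path into a child -> parent DAG (is_a, part_of only).

    Obsolete terms are dropped; a cycle is an error.
    """
    if isinstance(obo, Path) or (isinstance(obo, str) and "\n" not in obo and Path(obo).exists()):
        graph = obonet.read_obo(str(obo))
    else:
        graph = obonet.read_obo(io.StringIO(obo))
    keep = [
        (u, v, k)
        for u, v, k in graph.edges(keys=True)
        if k in RELATIONS
    ]
    dag = nx.MultiDiGraph()
    dag.add_nodes_from(graph.nodes(data=True))
    dag.add_edges_from(keep)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return dag


def term_depths(dag: nx.MultiDiGraph) -> dict[str, int]:
    """Shortest child->parent path length to a root (term with no parents)."""
    roots = [n for n in dag.nodes if dag.out_degree(n) == 0]
    depths = {}
    for node in dag.nodes:
        depths[node] = min(
            nx.shortest_path_length(dag, node, r) for r in roots if nx.has_path(dag, node, r)
        )
    return depths


def propagate_annotations(
    dag: nx.MultiDiGraph, direct: dict[str, set]
) -> dict[str, set]:
    """Close each gene's term set under ancestors (true-path rule). Idempotent."""
    known = set(dag.nodes)
    ancestors: dict[str, set] = {}
    out = {}
    for gene, terms in direct.items():
        unknown = set(terms) - known
        if unknown:
            raise ValueError(f"unknown term(s) for gene {gene}: {sorted(unknown)}")
        closed = set()
        for t in terms:
            if t not in ancestors:
                ancestors[t] = nx.descendants(dag, t)  # edges point child -> parent
            closed |= {t} | ancestors[t]
        out[gene] = closed
    return out


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"infeasible hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving on input positions."""
    import numpy as np

    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Two-column (gene, term) TSV, or GAF 2.x (columns 2 and 5, comment lines '!')."""
    first = Path(path).open().readline()
    if first.startswith("!") or first.count("\t") >= 10:
        gaf = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        return pd.DataFrame({"gene": gaf[1], "term": gaf[4]})
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "term"]:
        df = df.iloc[:, :2]
        df.columns = ["gene", "term"]
    return df


def enrich(
    test_set,
    background,
    dag: nx.MultiDiGraph,
    annotations: pd.DataFrame,
    fdr: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Hypergeometric over-representation of propagated terms in `test_set`.

    Universe = background genes with >= 1 propagated annotation; only terms
    with k >= 1 in the test set are tested; BH across tested terms.  Rows are
    sorted by (q, p, term) and flagged `significant` at q < fdr.
    """
    test_set = set(test_set)
    background = set(background)
    if not test_set <= background:
        raise ValueError("test_set must be a subset of background")
    if not test_set:
        warnings.warn("empty test set; returning empty enrichment table", stacklevel=2)
        return pd.DataFrame(
            columns=["term", "name", "k", "n", "K", "N", "p", "q", "significant"]
        )
    direct = (
        annotations[annotations["gene"].isin(background)]
        .groupby("gene")["term"]
        .apply(set)
        .to_dict()
    )
    closed = propagate_annotations(dag, direct)
    universe = set(closed)
    N = len(universe)
    test_in = test_set & universe
    n = len(test_in)

    term_bg: dict[str, int] = {}
    term_test: dict[str, int] = {}
    for gene, terms in closed.items():
        in_test = gene in test_in
        for t in terms:
            term_bg[t] = term_bg.get(t, 0) + 1
            if in_test:
                term_test[t] = term_test.get(t, 0) + 1

    rows = []
    for term, k in sorted(term_test.items()):
        K = term_bg[term]
        rows.append(
            {
                "term": term,
                "name": dag.nodes[term].get("name", ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeometric_tail(k, n, K, N),
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"])
    result["significant"] = result["q"] < fdr
    return result.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)
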