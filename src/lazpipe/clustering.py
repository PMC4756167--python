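"""Consecutive-window expression clusters and multiscale-bootstrap dendrogram support.

Window rule: a gene joins the `up` cluster of window Wk = (t_k, t_{k+1}) when
its specificity ratio S_t exceeds 2 (more than four-fold LAZ/NAZ) with
p < 0.015 at BOTH timepoints of the window; `down` uses S_t < -2.  The
primary cluster label is the earliest qualifying window, C1..C4 for up-W1..W4
and C5..C8 for down-W1..W4; genes passing at three or more consecutive
timepoints qualify in several windows and are flagged `multi_window` with
their run length recorded.

Dendrogram support follows the multiscale-bootstrap recipe: bootstrap the
condition columns at several scale factors r, record per-edge bootstrap
probabilities BP(r), fit Phi^-1(1 - BP(r)) = d*sqrt(r) + c/sqrt(r) by
weighted least squares, and report AU = 1 - Phi(d - c) (approximately
unbiased) alongside BP_fitted = 1 - Phi(d + c).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4
DEFAULT_NBOOT = 1000


# ---------------------------------------------------------------------------
# window clusters


def assign_window_clusters(
    diff: pd.DataFrame,
    times=None,
    fold_log2: float = 2.0,
    p_threshold: float = 0.015,
) -> pd.DataFrame:
    """Direction x consecutive-window cluster assignment from a differential table.

    Returns one row per gene with columns `windows` (list of "up_Wk"/"down_Wk"),
    `primary_cluster` (C1..C{2k} or None), `direction`, `run_length`, and
    `multi_window`.
    """
    if times is None:
        times = diff.attrs.get(
            "times", sorted(int(c[2:]) for c in diff.columns if c.startswith("S_"))
        )
    for t in times:
        if f"S_{t}" not in diff.columns or f"p_S_{t}" not in diff.columns:
            raise ValueError(f"missing S_{t} / p_S_{t} for timepoint {t}")
    S = diff[[f"S_{t}" for t in times]].to_numpy()
    P = diff[[f"p_S_{t}" for t in times]].to_numpy()
    with np.errstate(invalid="ignore"):
        up_pass = (S > fold_log2) & (P < p_threshold)
        down_pass = (S < -fold_log2) & (P < p_threshold)
    n_windows = len(times) - 1

    rows = []
    for i, gene in enumerate(diff.index):
        wins: list[str] = []
        for w in range(n_windows):
            if up_pass[i, w] and up_pass[i, w + 1]:
                wins.append(f"up_W{w+1}")
            if down_pass[i, w] and down_pass[i, w + 1]:
                wins.append(f"down_W{w+1}")
        primary = None
        direction = None
        if wins:
            # earliest window; up/down cannot collide in one window
            order = sorted(wins, key=lambda s: (int(s.rsplit("W", 1)[1]), s))
            direction, wnum = order[0].split("_W")
            k = int(wnum)
            primary = f"C{k}" if direction == "up" else f"C{n_windows + k}"
        run = max(_longest_run(up_pass[i]), _longest_run(down_pass[i]))
        rows.append(
            {
                "gene": gene,
                "windows": wins,
                "primary_cluster": primary,
                "direction": direction,
                "run_length": run,
                "multi_window": len(wins) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def cluster_sizes(assign: pd.DataFrame) -> dict[str, int]:
    counts = assign["primary_cluster"].value_counts()
    return {k: int(v) for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# correlation dendrogram


def correlation_distance(profiles: pd.DataFrame) -> np.ndarray:
    """1 - Pearson correlation across columns; zero-variance rows get distance 1."""
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance profile(s); correlation undefined, "
            "assigning distance 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def correlation_dendrogram(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree on 1 - Pearson distance over condition columns.

    Genes are sorted lexicographically first so ties break deterministically.
    Returns (scipy linkage matrix, leaf labels in input order of the matrix).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if not np.isfinite(profiles.to_numpy(dtype=float)).all():
        raise ValueError("profiles must be finite")
    profiles = profiles.sort_index()
    dist = correlation_distance(profiles)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, list(profiles.index)


def tree_bipartitions(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf set under each internal node, root (trivial full set) excluded."""
    n = len(labels)
    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _h, _c) in enumerate(Z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + k] = merged
        if len(merged) < n:
            out.append(merged)
    return out


# ---------------------------------------------------------------------------
# multiscale bootstrap


def multiscale_bootstrap(
    profiles: pd.DataFrame,
    scales=DEFAULT_SCALES,
    nboot: int = 100,
    seed: int = 0,
) -> dict[frozenset, dict[float, float]]:
    """BP(r) per tree edge: resample condition columns at each scale factor r.

    At scale r, ceil(r*m) of the m columns are drawn with replacement, the
    tree is rebuilt, and BP(r) is the fraction of `nboot` replicates whose
    tree contains the edge's leaf set.
    """
    scales = [float(r) for r in scales]
    if any(r < 0.3 or r > 2.0 for r in scales):
        raise ValueError("scales must lie in [0.3, 2]")
    if nboot < 10:
        raise ValueError("nboot must be >= 10")
    profiles = profiles.sort_index()
    Z, labels = correlation_dendrogram(profiles)
    edges = tree_bipartitions(Z, labels)
    rng = np.random.Generator(np.random.PCG64(seed))
    m = profiles.shape[1]
    bp: dict[frozenset, dict[float, float]] = {e: {} for e in edges}
    for r in scales:
        size = math.ceil(r * m)
        hits = {e: 0 for e in edges}
        for _ in range(nboot):
            cols = rng.integers(0, m, size=size)
            boot = profiles.iloc[:, cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Zb, lb = correlation_dendrogram(boot)
            present = set(tree_bipartitions(Zb, lb))
            for e in edges:
                if e in present:
                    hits[e] += 1
        for e in edges:
            bp[e][r] = hits[e] / nboot
    return bp


@dataclass
class EdgeSupport:
    au: float
    bp_fitted: float
    d: float
    c: float
    bp_raw: dict[float, float]
    degenerate: bool = False


def au_from_bp(bp_curve: dict[float, float], nboot: int) -> EdgeSupport:
    """AU and fitted BP from a per-scale BP curve.

    Weighted least squares fit of z(r) = Phi^-1(1 - BP(r)) = d*sqrt(r) +
    c/sqrt(r), with the standard binomial weights nboot * phi(z)^2 /
    (BP * (1 - BP)).  AU = 1 - Phi(d - c); BP_fitted = 1 - Phi(d + c).
    Curves clipped entirely to one extreme give AU 0 or 1 with a flag.
    """
    lo, hi = 1.0 / (nboot + 1), nboot / (nboot + 1)
    rs = np.array(sorted(bp_curve))
    raw = np.array([bp_curve[r] for r in rs])
    clipped = np.clip(raw, lo, hi)
    interior = (raw > 0) & (raw < 1)
    if interior.sum() < 2:
        au = 1.0 if raw.mean() >= 0.5 else 0.0
        return EdgeSupport(au=au, bp_fitted=au, d=np.nan, c=np.nan, bp_raw=dict(bp_curve), degenerate=True)
    z = stats.norm.ppf(1.0 - clipped)
    X = np.column_stack([np.sqrt(rs), 1.0 / np.sqrt(rs)])
    w = nboot * stats.norm.pdf(z) ** 2 / (clipped * (1.0 - clipped))
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
    d, c = float(coef[0]), float(coef[1])
    au = float(1.0 - stats.norm.cdf(d - c))
    bpf = float(1.0 - stats.norm.cdf(d + c))
    return EdgeSupport(au=au, bp_fitted=bpf, d=d, c=c, bp_raw=dict(bp_curve))


@dataclass
class SupportedDendrogram:
    """Merge tree plus per-edge AU/BP support values."""

    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset, EdgeSupport]
    scales: tuple[float, ...]
    nboot: int

    def support_table(self) -> pd.DataFrame:
        rows = [
            {
                "edge": ",".join(sorted(e)),
                "size": len(e),
                "au": s.au,
                "bp": s.bp_fitted,
                "bp_raw_1": s.bp_raw.get(1.0, np.nan),
                "degenerate": s.degenerate,
            }
            for e, s in sorted(self.support.items(), key=lambda kv: ",".join(sorted(kv[0])))
        ]
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick with `au|bp` internal node labels and merge heights as branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            idx = n + k
            members[idx] = members[a] | members[b]
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            sup = self.support.get(members[idx])
            label = f"{sup.au:.3f}|{sup.bp_fitted:.3f}" if sup else ""
            nodes[idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g}){label}"
            heights[idx] = h
        return nodes[len(nodes) - 1] + ";"


def supported_dendrogram(
    profiles: pd.DataFrame,
    scales=DEFAULT_SCALES,
    nboot: int = 100,
    seed: int = 0,
) -> SupportedDendrogram:
    """Cluster profiles and attach multiscale-bootstrap AU/BP support per edge."""
    profiles = profiles.sort_index()
    Z, labels = correlation_dendrogram(profiles)
    bp = multiscale_bootstrap(profiles, scales=scales, nboot=nboot, seed=seed)
    support = {e: au_from_bp(curve, nboot) for e, curve in bp.items()}
    return SupportedDendrogram(
        linkage=Z, labels=labels, support=support, scales=tuple(float(r) for r in scales), nboot=nboot
    )
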