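"""Seeded synthetic inputs emulating a two-tissue ethylene time-course RNA-seq study.

The generator reproduces the statistical shape of the real experiment — two
tissues (LAZ, the leaf abscission zone, and NAZ, the adjacent petiole), five
timepoints of ethylene exposure (0/12/24/48/72 h), three biological
replicates, ~4 million reads per sample — and plants ground-truth structure
that every downstream stage can be scored against:

* eight "window" archetypes (`up_W1` … `down_W4`): abscission-specific genes
  whose LAZ/NAZ log2 ratio equals ±`effect_log2` at exactly the two
  timepoints of one consecutive-timepoint window and 0 elsewhere;
* `temporal_only` genes that decline identically in both tissues after 0 h,
  like auxin-responsive transcripts after leaf-blade removal (selectable by
  the over-time filter, invisible to the specificity filter in expectation);
* `constitutive` housekeeping-like genes and flat `null` genes;
* a designated GO term enriched in the `up_W1` class, a transcription-factor
  annotation layer with an excluded subclass (DNA-methylation /
  RNA-polymerase-like), a soy→Arabidopsis best-match ortholog map, and a toy
  signed regulome whose projection onto the planted abscission-specific TF
  set is recorded as ground truth.

Counts are gamma-Poisson (negative binomial, variance = mu + dispersion*mu^2);
`dispersion=0` is the noise-free limit in which counts equal their rounded
expectations, which gives exactly reproducible fixtures for unit tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES = ("LAZ", "NAZ")

# synthetic ontology vocabulary (see build_ontology_stanzas)
TERM_ROOT = "ST:0000001"
TERM_REGULATION = "ST:0000010"
TERM_TF_ACTIVITY = "ST:0000011"  # include term for TF calling
TERM_TF_DNA_BINDING = "ST:0000012"  # leaf child; direct annotation target
TERM_CHROMATIN = "ST:0000020"
TERM_DNA_METHYLATION = "ST:0000013"  # exclusion term
TERM_RNA_BIOSYNTH = "ST:0000021"
TERM_RNA_POLYMERASE = "ST:0000014"  # exclusion term
TERM_DEVELOPMENT = "ST:0000031"
TERM_ABSCISSION = "ST:0000030"
TERM_AZ_DEVELOPMENT = "ST:0000033"
TERM_PLANTED = "ST:0000032"  # planted enrichment signal
FILLER_TERMS = tuple(f"ST:00001{i:02d}" for i in range(10))

DEFAULT_INCLUDE_TERMS = (TERM_TF_ACTIVITY,)
DEFAULT_EXCLUDE_TERMS = (TERM_DNA_METHYLATION, TERM_RNA_POLYMERASE)

BRIDGE_AT_ID = "AT9G00001"


@dataclass(frozen=True)
class SimParams:
    """Study-design and noise parameters for the synthetic generator.

    Defaults encode the study conditions: 2 tissues x 5 timepoints x 3
    replicates (30 samples), ~4e6 reads per sample, 8 planted window classes
    of 50 genes each at a 16-fold (log2 = 4) specificity effect, NB
    dispersion 0.05.
    """

    n_genes: int = 2000
    frac_tf: float = 0.10
    n_planted_per_class: int = 50
    effect_log2: float = 4.0
    temporal_log2: float = 4.0
    dispersion: float = 0.05
    depth_mean: float = 4e6
    depth_cv: float = 0.10
    n_reps: int = 3
    times: tuple[int, ...] = (0, 12, 24, 48, 72)
    seed: int = 0
    # annotation / regulome layer
    frac_tf_excluded: float = 0.05
    planted_term_frac_in: float = 0.9
    planted_term_frac_out: float = 0.02
    frac_orthologs_in_regulome: float = 0.8

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_tf <= 1.0:
            raise ValueError("frac_tf must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if len(self.times) < 2:
            raise ValueError("need at least two timepoints")
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError("times must start at 0")

    @property
    def windows(self) -> list[tuple[int, int]]:
        """Consecutive timepoint pairs W1..W{k}, e.g. (0,12), (12,24), ..."""
        return list(zip(self.times[:-1], self.times[1:]))

    @property
    def archetype_classes(self) -> list[str]:
        k = len(self.windows)
        return [f"up_W{i+1}" for i in range(k)] + [f"down_W{i+1}" for i in range(k)]


def generate_design(n_reps: int, times) -> pd.DataFrame:
    """Full-factorial sample design: tissue x time x replicate."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    times = list(times)
    if not times:
        raise ValueError("times must be non-empty")
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate times in design: {times}")
    rows = [
        {
            "sample": f"{tissue}_{t}h_r{r}",
            "tissue": tissue,
            "time": t,
            "replicate": r,
        }
        for tissue in TISSUES
        for t in times
        for r in range(1, n_reps + 1)
    ]
    return pd.DataFrame(rows)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent component streams so adding one layer never perturbs another."""
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_truth(params: SimParams) -> pd.DataFrame:
    """Per-gene ground-truth table (archetype, TF status, baseline, length, terms, ortholog)."""
    p = params
    n_classes = len(p.archetype_classes)
    n_planted = n_classes * p.n_planted_per_class
    n_special = n_planted + 2 * p.n_planted_per_class  # + temporal_only + constitutive
    if n_special > p.n_genes:
        raise ValueError(
            f"infeasible allocation: {n_classes} window classes + temporal_only + "
            f"constitutive x {p.n_planted_per_class} = {n_special} genes > n_genes={p.n_genes}"
        )

    (rng_len, rng_base, rng_tf, rng_assign, rng_annot, rng_orth, _rng_reg) = _substreams(p.seed, 7)

    width = max(4, len(str(p.n_genes)))
    gene_ids = [f"gene{i:0{width}d}" for i in range(1, p.n_genes + 1)]

    lengths = np.clip(rng_len.lognormal(math.log(1500.0), 0.6, p.n_genes), 200, 20000).astype(int)

    # wide baseline distribution so the 0.1 floor and the RPKM>=1 expression
    # call both bite on a realistic minority of genes
    baseline = rng_base.lognormal(math.log(5.0), 2.3, p.n_genes)

    # TF labels first; planted classes are then stratified across both pools
    is_tf = rng_tf.random(p.n_genes) < p.frac_tf

    archetype = np.array(["null"] * p.n_genes, dtype=object)
    tf_idx = np.flatnonzero(is_tf)
    non_tf_idx = np.flatnonzero(~is_tf)
    rng_assign.shuffle(tf_idx)
    rng_assign.shuffle(non_tf_idx)
    n_tf_per_class = int(round(p.frac_tf * p.n_planted_per_class))
    if p.frac_tf > 0 and p.n_planted_per_class > 0:
        n_tf_per_class = max(1, n_tf_per_class)
    classes = list(p.archetype_classes) + ["temporal_only", "constitutive"]
    need_tf = n_tf_per_class * len(classes)
    need_non = (p.n_planted_per_class - n_tf_per_class) * len(classes)
    if need_tf > tf_idx.size or need_non > non_tf_idx.size:
        raise ValueError(
            f"infeasible allocation: need {need_tf} TF and {need_non} non-TF planted genes, "
            f"have {tf_idx.size} TF / {non_tf_idx.size} non-TF"
        )
    ti = ni = 0
    for cls in classes:
        take_tf = tf_idx[ti : ti + n_tf_per_class]
        ti += n_tf_per_class
        take_non = non_tf_idx[ni : ni + (p.n_planted_per_class - n_tf_per_class)]
        ni += p.n_planted_per_class - n_tf_per_class
        archetype[np.concatenate([take_tf, take_non])] = cls

    # planted / special genes get solidly expressed baselines so the truth is
    # recoverable at the study's depth; constitutive mimic housekeeping genes
    special = archetype != "null"
    n_sp = int(special.sum())
    redraw = rng_base.lognormal(math.log(20.0), 0.5, n_sp)
    baseline[special] = redraw
    baseline[archetype == "constitutive"] *= 2.5

    # scale so the all-baseline condition carries 1e6 RPKM*kb total: expected
    # column sums then track the sampled depth and RPKM conservation holds
    baseline *= 1e6 / float(np.sum(baseline * lengths / 1000.0))

    excluded = np.zeros(p.n_genes, dtype=bool)
    excluded[is_tf] = rng_annot.random(int(is_tf.sum())) < p.frac_tf_excluded

    go_terms = []
    up_w1 = archetype == "up_W1"
    for i in range(p.n_genes):
        terms = set(rng_annot.choice(FILLER_TERMS, size=rng_annot.integers(1, 4), replace=False))
        if is_tf[i]:
            terms.add(TERM_TF_DNA_BINDING)
        if excluded[i]:
            terms.add(TERM_DNA_METHYLATION if rng_annot.random() < 0.5 else TERM_RNA_POLYMERASE)
        thr = p.planted_term_frac_in if up_w1[i] else p.planted_term_frac_out
        if rng_annot.random() < thr:
            terms.add(TERM_PLANTED)
        go_terms.append(";".join(sorted(terms)))

    ortholog = np.array([""] * p.n_genes, dtype=object)
    counter = 0
    for i in np.flatnonzero(is_tf):
        counter += 1
        ortholog[i] = f"AT{1 + counter % 5}G{counter * 10:05d}"
    # a couple of shared best matches, as in real best-hit maps
    shared_pool = np.flatnonzero(is_tf)
    if shared_pool.size >= 4:
        pairs = rng_orth.choice(shared_pool, size=4, replace=False)
        ortholog[pairs[1]] = ortholog[pairs[0]]
        ortholog[pairs[3]] = ortholog[pairs[2]]

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": archetype,
            "is_tf": is_tf,
            "excluded_class": excluded,
            "baseline_rpkm": baseline,
            "length_bp": lengths,
            "go_terms": go_terms,
            "ortholog": ortholog,
        }
    ).set_index("gene_id")


def expected_log2_offset(truth: pd.DataFrame, params: SimParams) -> pd.DataFrame:
    """Expected log2 offset from baseline per gene x (tissue, time).

    Window archetypes put the full +/-effect_log2 on the LAZ at exactly the
    archetype's two timepoints with NAZ flat, so planted genes are both
    tissue-specific (|S| = effect) and, for windows away from 0 h, temporal
    (|T| = effect) — mirroring the study's specific-and-temporal overlap.
    `temporal_only` genes drop by temporal_log2 in both tissues at t > 0.
    """
    p = params
    cols = pd.MultiIndex.from_product([TISSUES, p.times], names=["tissue", "time"])
    off = pd.DataFrame(0.0, index=truth.index, columns=cols)
    for w, (t1, t2) in enumerate(p.windows, start=1):
        for direction, sign in (("up", 1.0), ("down", -1.0)):
            genes = truth.index[truth["archetype"] == f"{direction}_W{w}"]
            for t in (t1, t2):
                off.loc[genes, ("LAZ", t)] = sign * p.effect_log2
    temporal = truth.index[truth["archetype"] == "temporal_only"]
    for t in p.times[1:]:
        off.loc[temporal, ("LAZ", t)] = -p.temporal_log2
        off.loc[temporal, ("NAZ", t)] = -p.temporal_log2
    return off


def simulate_counts(
    truth: pd.DataFrame, design: pd.DataFrame, params: SimParams
) -> pd.DataFrame:
    """Gene x sample integer counts under the gamma-Poisson model."""
    p = params
    if (truth["length_bp"] <= 0).any() or (truth["baseline_rpkm"] <= 0).any():
        raise ValueError("all genes need positive length and baseline")
    streams = _substreams(p.seed, 9)
    rng_depth, rng_counts = streams[7], streams[8]

    off = expected_log2_offset(truth, p)
    len_kb = truth["length_bp"].to_numpy() / 1000.0
    base = truth["baseline_rpkm"].to_numpy()

    n_samples = len(design)
    if p.depth_cv > 0:
        sigma = math.sqrt(math.log(1.0 + p.depth_cv**2))
        jitter = rng_depth.lognormal(-0.5 * sigma**2, sigma, n_samples)
    else:
        jitter = np.ones(n_samples)
    depth = p.depth_mean * jitter

    counts = np.empty((len(truth), n_samples), dtype=np.int64)
    for j, row in enumerate(design.itertuples(index=False)):
        rpkm_expected = base * np.power(2.0, off[(row.tissue, row.time)].to_numpy())
        mu = rpkm_expected * len_kb * depth[j] / 1e6
        if p.dispersion == 0 and p.depth_cv == 0:
            counts[:, j] = np.rint(mu).astype(np.int64)
        elif p.dispersion == 0:
            counts[:, j] = rng_counts.poisson(mu)
        else:
            r = 1.0 / p.dispersion
            prob = r / (r + mu)
            counts[:, j] = rng_counts.negative_binomial(r, prob)
    return pd.DataFrame(counts, index=truth.index, columns=design["sample"].tolist())


# ---------------------------------------------------------------------------
# ontology / annotations / regulome


def build_ontology_stanzas() -> str:
    """OBO text for the synthetic ontology: a rooted DAG, >=3 levels, is_a and part_of."""
    terms: list[tuple[str, str, list[str], list[str]]] = [
        (TERM_ROOT, "biological process", [], []),
        (TERM_REGULATION, "regulation of gene expression", [TERM_ROOT], []),
        (TERM_TF_ACTIVITY, "transcription regulator activity", [TERM_REGULATION], []),
        (
            TERM_TF_DNA_BINDING,
            "sequence-specific DNA binding transcription factor activity",
            [TERM_TF_ACTIVITY],
            [],
        ),
        (TERM_CHROMATIN, "chromatin organization", [TERM_ROOT], []),
        (TERM_DNA_METHYLATION, "DNA methylation", [TERM_CHROMATIN], []),
        (TERM_RNA_BIOSYNTH, "RNA biosynthetic process", [TERM_REGULATION], []),
        (TERM_RNA_POLYMERASE, "DNA-directed RNA polymerase activity", [TERM_RNA_BIOSYNTH], []),
        (TERM_DEVELOPMENT, "developmental process", [TERM_ROOT], []),
        (TERM_ABSCISSION, "organ abscission", [TERM_DEVELOPMENT], []),
        (TERM_AZ_DEVELOPMENT, "abscission zone development", [TERM_DEVELOPMENT], []),
        (
            TERM_PLANTED,
            "cell separation during organ abscission",
            [TERM_ABSCISSION],
            [TERM_AZ_DEVELOPMENT],
        ),
    ]
    filler_parents = [TERM_DEVELOPMENT, TERM_CHROMATIN, TERM_REGULATION]
    for i, term in enumerate(FILLER_TERMS):
        terms.append((term, f"synthetic process {i}", [filler_parents[i % 3]], []))

    lines = ["format-version: 1.2", "ontology: synthetic-abscission", ""]
    for tid, name, isa, partof in terms:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        lines.append("namespace: biological_process")
        for parent in isa:
            lines.append(f"is_a: {parent}")
        for parent in partof:
            lines.append(f"relationship: part_of {parent}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the recorded ground truth."""

    params: SimParams
    design: pd.DataFrame
    truth: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    obo_text: str
    annotations: pd.DataFrame  # columns gene, term
    ortholog_map: pd.DataFrame  # columns soy_id, at_id, score
    edges: pd.DataFrame  # columns regulator, target, mode
    truth_network_nodes: pd.DataFrame  # at_id, role
    truth_network_edges: pd.DataFrame  # regulator, target, mode

    @property
    def planted_specific_tfs(self) -> pd.Index:
        """Planted window-archetype genes that are callable abscission-specific TFs."""
        t = self.truth
        window = t["archetype"].str.match(r"(up|down)_W\d+")
        return t.index[window & t["is_tf"] & ~t["excluded_class"]]


def generate_ontology_and_regulome(
    truth: pd.DataFrame, params: SimParams
) -> tuple[str, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(OBO text, annotations, ortholog map, edge table, truth nodes, truth edges)."""
    p = params
    rng_reg = _substreams(p.seed, 7)[6]

    obo_text = build_ontology_stanzas()

    rows = [
        {"gene": g, "term": t}
        for g, ts in truth["go_terms"].items()
        for t in ts.split(";")
        if t
    ]
    annotations = pd.DataFrame(rows, columns=["gene", "term"])

    has_orth = truth["ortholog"] != ""
    ortholog_map = pd.DataFrame(
        {
            "soy_id": truth.index[has_orth],
            "at_id": truth.loc[has_orth, "ortholog"].to_numpy(),
            "score": np.round(rng_reg.uniform(60, 100, int(has_orth.sum())), 1),
        }
    ).reset_index(drop=True)

    # planted abscission-specific TF orthologs: a configurable subset enters the regulome
    window = truth["archetype"].str.match(r"(up|down)_W\d+")
    planted_tf = truth.index[window & truth["is_tf"] & ~truth["excluded_class"]]
    planted_at = sorted(set(truth.loc[planted_tf, "ortholog"]) - {""})
    n_in = max(2, int(round(p.frac_orthologs_in_regulome * len(planted_at))))
    in_regulome = sorted(rng_reg.choice(planted_at, size=min(n_in, len(planted_at)), replace=False))

    modes = ("activation", "repression")
    edge_rows: list[tuple[str, str, str]] = []
    # a sparse random regulome among the matched orthologs
    for i, reg in enumerate(in_regulome):
        n_targets = int(rng_reg.integers(1, 3))
        for tgt in rng_reg.choice(in_regulome, size=n_targets, replace=False):
            if tgt != reg:
                edge_rows.append((reg, tgt, modes[int(rng_reg.integers(2))]))
    # bridge node: never assigned to a soy gene, adjacent to >=2 matched nodes
    bridge_neighbors = in_regulome[:2]
    edge_rows.append((bridge_neighbors[0], BRIDGE_AT_ID, "activation"))
    edge_rows.append((BRIDGE_AT_ID, bridge_neighbors[1], "repression"))
    # decoy edges disconnected from the matched set
    for i in range(5):
        edge_rows.append((f"AT8G{i:05d}", f"AT8G{i + 100:05d}", modes[i % 2]))
    # dangling edges touching exactly one matched node via a degree-1 outsider
    edge_rows.append((in_regulome[0], "AT8G00900", "activation"))
    edges = pd.DataFrame(sorted(set(edge_rows)), columns=["regulator", "target", "mode"])

    # ground truth network, constructed directly from what was planted above:
    # matched nodes in the regulome + the bridge, and every edge among them
    node_set = set(in_regulome) | {BRIDGE_AT_ID}
    truth_nodes = pd.DataFrame(
        sorted((a, "matched" if a != BRIDGE_AT_ID else "bridge") for a in node_set),
        columns=["at_id", "role"],
    )
    mask = edges["regulator"].isin(node_set) & edges["target"].isin(node_set)
    truth_edges = edges[mask].reset_index(drop=True)

    return obo_text, annotations, ortholog_map, edges, truth_nodes, truth_edges


def generate_bundle(params: SimParams | None = None) -> SyntheticBundle:
    """Run the full generator: design, truth, counts, annotations, regulome."""
    p = params or SimParams()
    design = generate_design(p.n_reps, p.times)
    truth = generate_truth(p)
    counts = simulate_counts(truth, design, p)
    obo, annot, orth, edges, tnodes, tedges = generate_ontology_and_regulome(truth, p)
    return SyntheticBundle(
        params=p,
        design=design,
        truth=truth,
        counts=counts,
        lengths=truth["length_bp"].rename("length_bp"),
        obo_text=obo,
        annotations=annot,
        ortholog_map=orth,
        edges=edges,
        truth_network_nodes=tnodes,
        truth_network_edges=tedges,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every input file the pipeline stages read; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "lengths": out / "lengths.tsv",
        "ontology": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "orthologs": out / "orthologs.tsv",
        "edges": out / "regulome_edges.tsv",
        "truth": out / "truth.tsv",
        "truth_network_nodes": out / "truth_network_nodes.tsv",
        "truth_network_edges": out / "truth_network_edges.tsv",
    }
    bundle.counts.to_csv(paths["counts"], sep="\t")
    bundle.design.to_csv(paths["design"], sep="\t", index=False)
    bundle.lengths.to_frame().to_csv(paths["lengths"], sep="\t")
    paths["ontology"].write_text(bundle.obo_text)
    bundle.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    bundle.ortholog_map.to_csv(paths["orthologs"], sep="\t", index=False)
    bundle.edges.to_csv(paths["edges"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t")
    bundle.truth_network_nodes.to_csv(paths["truth_network_nodes"], sep="\t", index=False)
    bundle.truth_network_edges.to_csv(paths["truth_network_edges"], sep="\t", index=False)
    return paths
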