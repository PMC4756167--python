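"""End-to-end orchestration: configuration, stage chaining, manifest, validation."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, differential, enrichment, expression, network, simulate

log = logging.getLogger("lazpipe")


@dataclass
class PipelineConfig:
    """Every numeric threshold and knob of the pipeline, with study defaults."""

    outdir: str = "lazpipe_out"
    seed: int = 0
    times: tuple[int, ...] = (0, 12, 24, 48, 72)
    # thresholds
    fold_specific_log2: float = 3.0
    fold_cluster_log2: float = 2.0
    p_threshold: float = 0.015
    fdr: float = 0.05
    expr_min: float = 1.0
    floor: float = 0.1
    # statistical test
    equal_var: bool = False  # False = Welch; True = Student
    # bootstrap
    scales: tuple[float, ...] = clustering.DEFAULT_SCALES
    nboot: int = clustering.DEFAULT_NBOOT
    # network
    bridge: bool = True
    # TF calling
    include_terms: tuple[str, ...] = simulate.DEFAULT_INCLUDE_TERMS
    exclude_terms: tuple[str, ...] = simulate.DEFAULT_EXCLUDE_TERMS
    # input paths (filled by `simulate`, or pointed at user files)
    counts: str | None = None
    design: str | None = None
    lengths: str | None = None
    ontology: str | None = None
    annotations: str | None = None
    orthologs: str | None = None
    edges: str | None = None
    # simulation
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fold_specific_log2", "fold_cluster_log2", "p_threshold", "fdr",
                     "expr_min", "floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["times"] = list(self.times)
        d["scales"] = list(self.scales)
        d["include_terms"] = list(self.include_terms)
        d["exclude_terms"] = list(self.exclude_terms)
        return d


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic bundle and point the config's input paths at it."""
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    sim_kwargs.setdefault("times", tuple(config.times))
    params = simulate.SimParams(**sim_kwargs)
    bundle = simulate.generate_bundle(params)
    paths = simulate.write_bundle(bundle, Path(config.outdir) / "inputs")
    for key in ("counts", "design", "lengths", "ontology", "annotations", "orthologs", "edges"):
        setattr(config, key, str(paths[key]))
    return paths


def run_pipeline(config: PipelineConfig, do_simulate: bool = False) -> dict:
    """simulate? -> normalize -> select -> cluster -> enrich -> network.

    Writes every stage output under `config.outdir` and returns the manifest
    (also written to manifest.json).  Deterministic under a fixed seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "counts": {},
    }
    stage = "simulate"
    try:
        if do_simulate:
            _timed(stage, run_simulate, config)

        stage = "normalize"
        counts = expression.read_counts(_require(config, "counts"))
        design = expression.read_design(_require(config, "design"))
        lengths = expression.read_lengths(_require(config, "lengths"))
        rpkm = _timed(stage, expression.compute_rpkm, counts, lengths)
        summary = expression.summarize_conditions(
            rpkm, design, floor=config.floor, expr_min=config.expr_min
        )
        rpkm.to_csv(out / "rpkm.tsv", sep="\t")
        summary.raw_mean.to_csv(out / "condition_means.tsv", sep="\t")

        stage = "select"
        diff = _timed(stage, differential.compute_differential, summary, config.equal_var)
        dag = enrichment.load_ontology(_require(config, "ontology"))
        annotations = enrichment.read_annotations(_require(config, "annotations"))
        tf_flags = differential.select_tf_genes(
            annotations, dag, config.include_terms, config.exclude_terms, diff.index
        )
        selection = differential.flag_selection(
            diff, tf_flags, fold_log2=config.fold_specific_log2, p_threshold=config.p_threshold
        )
        diff.join(selection.flags.drop(columns=["expressed"])).to_csv(
            out / "differential.tsv", sep="\t"
        )
        (out / "selection_summary.txt").write_text(
            differential.selection_summary_text(selection.counts) + "\n"
        )
        manifest["counts"].update(selection.counts)

        stage = "cluster"
        tf_set = selection.flags.index[selection.flags["abscission_specific_tf"]]
        assign = _timed(
            stage,
            clustering.assign_window_clusters,
            diff.loc[tf_set],
            config.times,
            config.fold_cluster_log2,
            config.p_threshold,
        )
        assign_out = assign.copy()
        assign_out["windows"] = assign_out["windows"].map(";".join)
        assign_out.to_csv(out / "window_clusters.tsv", sep="\t")
        manifest["counts"]["tf_cluster_sizes"] = clustering.cluster_sizes(assign)
        manifest["counts"]["n_tf_clustered"] = int(assign["primary_cluster"].notna().sum())

        clustered = assign.index[assign["primary_cluster"].notna()]
        if len(clustered) >= 2:
            profiles = summary.floored_mean.loc[clustered]
            profiles.columns = [f"{ti}_{t}h" for ti, t in profiles.columns]
            profiles = np.log2(profiles)
            dendro = clustering.supported_dendrogram(
                profiles, scales=config.scales, nboot=config.nboot, seed=config.seed
            )
            (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            dendro.support_table().to_csv(out / "dendrogram_support.tsv", sep="\t", index=False)
            long = (
                summary.floored_mean.loc[clustered]
                .stack(["tissue", "time"], future_stack=True)
                .rename("rpkm")
                .reset_index()
            )
            long = long.merge(
                assign["primary_cluster"], left_on=long.columns[0], right_index=True
            )
            long["log2_rpkm"] = np.log2(long["rpkm"])
            long.to_csv(out / "heatmap_long.tsv", sep="\t", index=False)

        stage = "enrich"
        background = diff.index[diff["expressed"]]
        enr = _timed(
            stage,
            enrichment.enrich,
            set(tf_set) & set(background),
            background,
            dag,
            annotations,
            config.fdr,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["counts"]["n_enriched_terms"] = int(enr["significant"].sum()) if len(enr) else 0

        stage = "network"
        ortho = network.load_ortholog_map(_require(config, "orthologs"))
        edges = network.load_edges(_require(config, "edges"))
        mapping = network.map_to_regulome(tf_set, ortho, edges)
        net = network.project_network(
            mapping.matched, edges, bridge=config.bridge, soy_members=mapping.soy_members
        )
        network.annotate_directions(
            net, diff, fold_log2=config.fold_specific_log2, p_threshold=config.p_threshold
        )
        (out / "network.sif").write_text(network.export_network(net, "sif"))
        (out / "network.graphml").write_text(network.export_network(net, "graphml"))
        (out / "network_nodes.tsv").write_text(network.export_network(net, "nodes"))
        (out / "network_edges.tsv").write_text(network.export_network(net, "edges"))
        manifest["counts"]["n_matched_at_ids"] = mapping.n_distinct
        manifest["counts"]["n_network_nodes"] = net.graph.number_of_nodes()
        manifest["counts"]["n_network_edges"] = net.graph.number_of_edges()
        manifest["counts"]["n_network_components"] = len(net.components)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(config: PipelineConfig, key: str) -> str:
    value = getattr(config, key)
    if not value:
        raise ValueError(f"missing required input path: {key}")
    if not Path(value).exists():
        raise FileNotFoundError(f"{key} file not found: {value}")
    return value


def _timed(stage: str, fn, *args):
    t0 = time.perf_counter()
    result = fn(*args)
    log.info("stage %-10s %.2fs", stage, time.perf_counter() - t0)
    return result


def validate_inputs(config: PipelineConfig) -> dict[str, list[str]]:
    """Cross-file consistency report; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    paths = {
        k: getattr(config, k)
        for k in ("counts", "design", "lengths", "ontology", "annotations", "orthologs", "edges")
    }
    for key, value in paths.items():
        if value and not Path(value).exists():
            errors.append(f"{key}: file not found: {value}")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    counts = expression.read_counts(paths["counts"]) if paths["counts"] else None
    design = expression.read_design(paths["design"]) if paths["design"] else None
    if counts is not None and design is not None:
        missing = set(design["sample"]) - set(counts.columns)
        for s in sorted(missing):
            errors.append(f"sample in design absent from counts: {s}")
        extra = set(counts.columns) - set(design["sample"])
        if extra:
            warnings_.append(f"{len(extra)} count columns not in design")
    if counts is not None and paths["lengths"]:
        lengths = expression.read_lengths(paths["lengths"])
        missing = counts.index.difference(lengths.index)
        if len(missing):
            errors.append(f"{len(missing)} genes missing lengths (e.g. {missing[0]})")
    if paths["ontology"] and paths["annotations"]:
        dag = enrichment.load_ontology(paths["ontology"])
        annot = enrichment.read_annotations(paths["annotations"])
        unknown = set(annot["term"]) - set(dag.nodes)
        if unknown:
            errors.append(f"{len(unknown)} annotation terms absent from ontology")
    if paths["orthologs"] and paths["edges"]:
        ortho = network.load_ortholog_map(paths["orthologs"])
        edges = network.load_edges(paths["edges"])
        vocab = set(edges["regulator"]) | set(edges["target"])
        overlap = set(ortho["at_id"]) & vocab
        if not overlap:
            warnings_.append("no ortholog at_id appears in the edge table vocabulary")
        if counts is not None:
            unmapped = set(counts.index) - set(ortho["soy_id"])
            if unmapped:
                warnings_.append(f"{len(unmapped)} genes without an ortholog best match")
    return {"errors": errors, "warnings": warnings_}
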