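"""RPKM normalization, per-condition replicate summaries, and expressed-gene calls.

RPKM(g, s) = count(g, s) / (length_kb(g) * mapped_millions(s)), with
mapped_millions(s) the sample's column total / 1e6 — the reads mapped to the
genes in the matrix (ribosomal and unmapped reads are assumed removed
upstream).  Condition means are floored at 0.1 before ratio formation so no
ratio ever has a zero numerator or denominator, and a gene counts as
expressed when the replicate-mean RPKM reaches 1.0 in at least one
tissue/timepoint condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RPKM_FLOOR = 0.1
EXPRESSED_MIN_MEAN = 1.0


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Gene x sample RPKM from an integer count matrix and gene lengths in bp."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes missing a length: {', '.join(map(str, missing[:5]))}")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    colsums = counts.sum(axis=0)
    zero = colsums.index[colsums == 0]
    if len(zero):
        raise ValueError(f"zero mapped reads in sample(s): {', '.join(map(str, zero))}")
    len_kb = lengths.to_numpy(dtype=float) / 1000.0
    mapped_millions = colsums.to_numpy(dtype=float) / 1e6
    values = counts.to_numpy(dtype=float) / (len_kb[:, None] * mapped_millions[None, :])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def floor_values(values, floor: float = RPKM_FLOOR):
    """Apply the minimal-value floor; idempotent and monotone."""
    return np.maximum(values, floor)


@dataclass
class ConditionSummary:
    """Replicate-level RPKM plus per-(tissue, time) means and expression calls.

    `raw_mean` and `floored_mean` are gene x condition frames with a
    (tissue, time) column MultiIndex; `expressed` is a per-gene flag, true
    iff any condition's raw mean reaches `expr_min`.
    """

    rpkm: pd.DataFrame
    design: pd.DataFrame
    raw_mean: pd.DataFrame
    floored_mean: pd.DataFrame
    expressed: pd.Series
    floor: float = RPKM_FLOOR
    expr_min: float = EXPRESSED_MIN_MEAN

    def replicate_values(self, tissue: str, time: int) -> pd.DataFrame:
        """Gene x replicate RPKM for one condition (column order = replicate order)."""
        samples = self.design.loc[
            (self.design["tissue"] == tissue) & (self.design["time"] == time), "sample"
        ]
        return self.rpkm[samples.tolist()]


def summarize_conditions(
    rpkm: pd.DataFrame,
    design: pd.DataFrame,
    floor: float = RPKM_FLOOR,
    expr_min: float = EXPRESSED_MIN_MEAN,
) -> ConditionSummary:
    missing = set(design["sample"]) - set(rpkm.columns)
    if missing:
        raise ValueError(f"samples in design missing from matrix: {sorted(missing)}")
    conditions = design[["tissue", "time"]].drop_duplicates().itertuples(index=False)
    means = {}
    for tissue, time in conditions:
        samples = design.loc[
            (design["tissue"] == tissue) & (design["time"] == time), "sample"
        ].tolist()
        means[(tissue, time)] = rpkm[samples].mean(axis=1)
    raw_mean = pd.DataFrame(means)
    raw_mean.columns = pd.MultiIndex.from_tuples(raw_mean.columns, names=["tissue", "time"])
    floored_mean = raw_mean.clip(lower=floor)
    expressed = (raw_mean >= expr_min).any(axis=1)
    return ConditionSummary(
        rpkm=rpkm,
        design=design,
        raw_mean=raw_mean,
        floored_mean=floored_mean,
        expressed=expressed,
        floor=floor,
        expr_min=expr_min,
    )


def gene_lengths_from_gff3(gff3_path: str | Path) -> pd.Series:
    """Gene lengths as the union of exon intervals per gene.

    Coordinates are 1-based inclusive (length = sum of (end - start + 1) over
    the merged exon union); strand is ignored.  Falls back to the gene span
    for genes without exon features.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths = {}
    for gene in db.features_of_type("gene"):
        intervals = sorted(
            (e.start, e.end) for e in db.children(gene, featuretype="exon")
        )
        if not intervals:
            lengths[gene.id] = gene.end - gene.start + 1
            continue
        total = 0
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        total += cur_end - cur_start + 1
        lengths[gene.id] = total
    return pd.Series(lengths, name="length_bp")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("length_bp")
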