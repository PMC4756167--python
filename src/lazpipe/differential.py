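"""Specificity and temporal log2 ratios, replicate tests, and selection flags.

Two ratio families drive gene selection:

* S_t = log2(LAZ mean / NAZ mean) at each timepoint t — tissue specificity;
* T_t = log2(LAZ mean at t / LAZ mean at 0 h) for t > 0 — change over time.

Both use floored condition means so every ratio is finite.  Significance
comes from a two-sided Welch t-test on log2(RPKM + floor) replicate values,
with each group variance floored at 1e-8 so identical groups give p = 1
rather than 0/0.  A gene is "abscission-specific" when some |S_t| exceeds 3
(more than eight-fold) with p < 0.015; the temporal analogue uses T_t.
Transcription-factor status comes from ontology-propagated annotations, with
an exclusion list for DNA-methylation- and RNA-polymerase-like activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FOLD_SPECIFIC_LOG2 = 3.0
FOLD_CLUSTER_LOG2 = 2.0
P_THRESHOLD = 0.015
VAR_FLOOR = 1e-8


def compare_groups(
    a, b, floor: float = 0.1, var_floor: float = VAR_FLOOR, equal_var: bool = False
) -> float:
    """Two-sided t-test on log2(x + floor); Welch by default.

    Each group's variance is floored at `var_floor`, so two identical groups
    yield t = 0 and p = 1 instead of a degenerate 0/0 statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    la, lb = np.log2(a + floor), np.log2(b + floor)
    va = max(la.var(ddof=1), var_floor)
    vb = max(lb.var(ddof=1), var_floor)
    na, nb = la.size, lb.size
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    else:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = (la.mean() - lb.mean()) / np.sqrt(se2)
    return float(2.0 * stats.t.sf(abs(t), df))


def compute_differential(summary, equal_var: bool = False) -> pd.DataFrame:
    """Per-gene table of S_t, T_t and their p-values; NaN for non-expressed genes.

    `summary` is an expression.ConditionSummary.  Columns: S_<t> and p_S_<t>
    for every t, T_<t> and p_T_<t> for t > 0, plus `expressed`.
    """
    times = sorted(summary.raw_mean.columns.get_level_values("time").unique())
    for tissue in ("LAZ", "NAZ"):
        for t in times:
            if (tissue, t) not in summary.raw_mean.columns:
                raise ValueError(f"missing condition ({tissue}, {t}) in summary")
    fl = summary.floored_mean
    out = pd.DataFrame(index=summary.raw_mean.index)
    out["expressed"] = summary.expressed

    laz_reps = {t: summary.replicate_values("LAZ", t) for t in times}
    naz_reps = {t: summary.replicate_values("NAZ", t) for t in times}

    def pvals(reps_a: pd.DataFrame, reps_b: pd.DataFrame) -> np.ndarray:
        return np.array(
            [
                compare_groups(
                    reps_a.iloc[i], reps_b.iloc[i], floor=summary.floor, equal_var=equal_var
                )
                for i in range(len(reps_a))
            ]
        )

    for t in times:
        out[f"S_{t}"] = np.log2(fl[("LAZ", t)] / fl[("NAZ", t)])
        out[f"p_S_{t}"] = pvals(laz_reps[t], naz_reps[t])
    t0 = times[0]
    for t in times[1:]:
        out[f"T_{t}"] = np.log2(fl[("LAZ", t)] / fl[("LAZ", t0)])
        out[f"p_T_{t}"] = pvals(laz_reps[t], laz_reps[t0])

    ratio_cols = [c for c in out.columns if c != "expressed"]
    out.loc[~summary.expressed, ratio_cols] = np.nan
    out.attrs["times"] = times
    return out


def select_tf_genes(
    annotations: pd.DataFrame,
    dag,
    include_terms,
    exclude_terms,
    genes: pd.Index,
) -> pd.DataFrame:
    """is_tf / tf_excluded flags from DAG-propagated annotations.

    A gene is a TF when its propagated term set hits any include term
    (annotation to a descendant suffices); it is excluded when the propagated
    set hits any exclude term.
    """
    from .enrichment import propagate_annotations

    known = set(dag.nodes)
    unknown = [t for t in list(include_terms) + list(exclude_terms) if t not in known]
    if unknown:
        raise ValueError(f"unknown ontology term id(s) in config: {', '.join(unknown)}")
    direct = annotations.groupby("gene")["term"].apply(set).to_dict()
    closed = propagate_annotations(dag, direct)
    include_set, exclude_set = set(include_terms), set(exclude_terms)
    flags = pd.DataFrame(index=genes)
    flags["is_tf"] = [bool(closed.get(g, set()) & include_set) for g in genes]
    flags["tf_excluded"] = [bool(closed.get(g, set()) & exclude_set) for g in genes]
    return flags


@dataclass
class SelectionResult:
    flags: pd.DataFrame
    counts: dict[str, int]


def flag_selection(
    diff: pd.DataFrame,
    tf_flags: pd.DataFrame,
    fold_log2: float = FOLD_SPECIFIC_LOG2,
    p_threshold: float = P_THRESHOLD,
) -> SelectionResult:
    """Eight-fold selection flags for TFs and for all genes.

    Strict inequalities throughout ("more than eight-fold"): |S_t| > fold_log2
    with p_S(t) < p_threshold at some t makes a gene specific; the same rule
    on T_t makes it temporal.
    """
    times = diff.attrs.get(
        "times", sorted(int(c[2:]) for c in diff.columns if c.startswith("S_"))
    )
    S = diff[[f"S_{t}" for t in times]].to_numpy()
    pS = diff[[f"p_S_{t}" for t in times]].to_numpy()
    T = diff[[f"T_{t}" for t in times[1:]]].to_numpy()
    pT = diff[[f"p_T_{t}" for t in times[1:]]].to_numpy()

    with np.errstate(invalid="ignore"):
        specific_any = np.nansum((np.abs(S) > fold_log2) & (pS < p_threshold), axis=1) > 0
        specific_up = np.nansum((S > fold_log2) & (pS < p_threshold), axis=1) > 0
        specific_down = np.nansum((S < -fold_log2) & (pS < p_threshold), axis=1) > 0
        temporal_any = np.nansum((np.abs(T) > fold_log2) & (pT < p_threshold), axis=1) > 0

    flags = pd.DataFrame(index=diff.index)
    flags["expressed"] = diff["expressed"]
    flags["is_tf"] = tf_flags["is_tf"].reindex(diff.index, fill_value=False)
    flags["tf_excluded"] = tf_flags["tf_excluded"].reindex(diff.index, fill_value=False)
    flags["specific_any"] = specific_any & diff["expressed"]
    flags["specific_up"] = specific_up & diff["expressed"]
    flags["specific_down"] = specific_down & diff["expressed"]
    flags["temporal_any"] = temporal_any & diff["expressed"]
    tf_ok = flags["is_tf"] & ~flags["tf_excluded"]
    flags["abscission_specific_tf"] = tf_ok & flags["specific_any"]
    flags["specific_and_temporal"] = flags["abscission_specific_tf"] & flags["temporal_any"]
    flags["deg_specific"] = flags["specific_any"]
    flags["deg_specific_and_temporal"] = flags["specific_any"] & flags["temporal_any"]

    counts = {
        "n_genes": int(len(flags)),
        "n_expressed": int(flags["expressed"].sum()),
        "n_tf": int(flags["is_tf"].sum()),
        "n_tf_expressed": int((flags["is_tf"] & flags["expressed"]).sum()),
        "n_tf_excluded": int(flags["tf_excluded"].sum()),
        "n_abscission_specific_tf": int(flags["abscission_specific_tf"].sum()),
        "n_specific_and_temporal_tf": int(flags["specific_and_temporal"].sum()),
        "n_deg_specific": int(flags["deg_specific"].sum()),
        "n_deg_specific_and_temporal": int(flags["deg_specific_and_temporal"].sum()),
    }
    return SelectionResult(flags=flags, counts=counts)


def selection_summary_text(counts: dict[str, int]) -> str:
    """Human-readable stage summary (expressed / TF / specific set sizes)."""
    lines = [
        f"genes                          {counts['n_genes']}",
        f"expressed (mean RPKM >= 1)     {counts['n_expressed']}",
        f"TF genes                       {counts['n_tf']}",
        f"TF genes expressed             {counts['n_tf_expressed']}",
        f"TF excluded (methylation/pol)  {counts['n_tf_excluded']}",
        f"abscission-specific TFs        {counts['n_abscission_specific_tf']}",
        f"  ... also >8-fold over time   {counts['n_specific_and_temporal_tf']}",
        f"abscission-specific DEGs       {counts['n_deg_specific']}",
        f"  ... also >8-fold over time   {counts['n_deg_specific_and_temporal']}",
    ]
    return "\n".join(lines)
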