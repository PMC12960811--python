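"""Validation-stage RT-qPCR quantification.

Triplicate Ct wells are aggregated with a QC/rescue rule, normalised to the
housekeeping gene by the ΔCt method (relative expression 2^-ΔCt), and
compared between clinical groups with two-tailed Welch t tests on the log2
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohortdata import CtTable, SampleTable

logger = logging.getLogger("swabmark.qpcr")

DEFAULT_MAX_SD = 0.5  # Ct cycles; common triplicate concordance threshold

QC_OK = "ok"
QC_RESCUED = "rescued"
QC_HIGH_SD = "high_sd"
QC_MISSING = "missing"
QC_MISSING_HK = "missing_housekeeping"


@dataclass
class GroupComparison:
    """Welch comparison of one gene between two groups (fold change b/a)."""

    gene: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_log2_a: float
    mean_log2_b: float
    fold_change: float
    t_stat: float
    df: float
    p_value: float


def aggregate_triplicates(
    ct: CtTable, max_sd: float = DEFAULT_MAX_SD, rescue: bool = True
) -> pd.DataFrame:
    """Aggregate replicate wells to one (sample, gene) row with a QC flag.

    Mean/SD over the non-missing replicates.  If the SD exceeds ``max_sd``
    and ``rescue`` is on, the single replicate whose removal minimises the
    SD is dropped; the row is flagged ``rescued`` if the remaining pair
    agrees, else ``high_sd``.  Fewer than two usable replicates leave the
    row ``missing`` with no mean.
    """
    rows = []
    for (sample, gene), grp in ct.table.groupby(["sample_id", "gene"],
                                                sort=False):
        values = grp["ct"].dropna().to_numpy(dtype=float)
        n_used = len(values)
        if n_used < 2:
            rows.append({"sample_id": sample, "gene": gene,
                         "mean_ct": np.nan, "ct_sd": np.nan,
                         "n_used": n_used, "qc_flag": QC_MISSING})
            continue
        sd = float(np.std(values, ddof=1))
        flag = QC_OK
        if sd > max_sd and rescue and n_used >= 3:
            best_idx, best_sd = None, sd
            for i in range(n_used):
                rest_sd = float(np.std(np.delete(values, i), ddof=1))
                if rest_sd < best_sd:
                    best_idx, best_sd = i, rest_sd
            if best_idx is not None and best_sd <= max_sd:
                logger.info("rescued (%s, %s): dropped Ct %.2f",
                            sample, gene, values[best_idx])
                values = np.delete(values, best_idx)
                sd, flag, n_used = best_sd, QC_RESCUED, n_used - 1
            else:
                flag = QC_HIGH_SD
        elif sd > max_sd:
            flag = QC_HIGH_SD
        rows.append({"sample_id": sample, "gene": gene,
                     "mean_ct": float(np.mean(values)), "ct_sd": sd,
                     "n_used": n_used, "qc_flag": flag})
    return pd.DataFrame(rows)


def delta_ct(target_mean_ct: float, housekeeping_mean_ct: float) -> float:
    """ΔCt = target − housekeeping; relative expression is 2^-ΔCt."""
    if not (np.isfinite(target_mean_ct) and np.isfinite(housekeeping_mean_ct)):
        raise ValueError("delta_ct requires finite Ct values")
    return float(target_mean_ct - housekeeping_mean_ct)


def relative_expression(
    aggregated: pd.DataFrame, housekeeping_gene: str
) -> pd.DataFrame:
    """ΔCt-normalised expression table, one row per (sample, target gene).

    Columns: mean_ct, ct_sd, delta_ct, rel_expr (= 2^-ΔCt), log2_rel_expr
    (= -ΔCt), qc_flag.  Samples without an aggregated housekeeping Ct are
    flagged ``missing_housekeeping`` and carry no expression values.
    """
    hk = aggregated[aggregated["gene"] == housekeeping_gene]
    hk_ct = {r["sample_id"]: r["mean_ct"] for _, r in hk.iterrows()
             if np.isfinite(r["mean_ct"])}
    rows = []
    for _, r in aggregated[aggregated["gene"] != housekeeping_gene].iterrows():
        row = {"sample_id": r["sample_id"], "gene": r["gene"],
               "mean_ct": r["mean_ct"], "ct_sd": r["ct_sd"],
               "qc_flag": r["qc_flag"], "delta_ct": np.nan,
               "rel_expr": np.nan, "log2_rel_expr": np.nan}
        if r["sample_id"] not in hk_ct:
            row["qc_flag"] = QC_MISSING_HK
        elif np.isfinite(r["mean_ct"]):
            d = delta_ct(r["mean_ct"], hk_ct[r["sample_id"]])
            row.update(delta_ct=d, rel_expr=2.0 ** -d, log2_rel_expr=-d)
        rows.append(row)
    return pd.DataFrame(rows)


def quantify(ct: CtTable, housekeeping_gene: str,
             max_sd: float = DEFAULT_MAX_SD,
             rescue: bool = True) -> pd.DataFrame:
    """Full Ct → relative-expression pipeline for one Ct table."""
    return relative_expression(aggregate_triplicates(ct, max_sd, rescue),
                               housekeeping_gene)


def _group_values(expr: pd.DataFrame, meta: SampleTable, gene: str,
                  group: str) -> np.ndarray:
    ids = set(meta.sample_ids(group=group))
    sub = expr[(expr["gene"] == gene) & expr["sample_id"].isin(ids)]
    return sub["log2_rel_expr"].dropna().to_numpy(dtype=float)


def group_fold_change(expr: pd.DataFrame, meta: SampleTable, gene: str,
                      group_a: str, group_b: str) -> GroupComparison:
    """Fold change (ratio of mean relative expression, b over a) with a
    two-tailed Welch t test on log2 relative expression."""
    log_a = _group_values(expr, meta, gene, group_a)
    log_b = _group_values(expr, meta, gene, group_b)
    if len(log_a) < 2 or len(log_b) < 2:
        raise ValueError(
            f"{gene}: need >= 2 samples per group "
            f"({group_a}: {len(log_a)}, {group_b}: {len(log_b)})")
    res = stats.ttest_ind(log_b, log_a, equal_var=False)
    fc = float(np.mean(2.0 ** log_b) / np.mean(2.0 ** log_a))
    return GroupComparison(
        gene=gene, group_a=group_a, group_b=group_b,
        n_a=len(log_a), n_b=len(log_b),
        mean_log2_a=float(np.mean(log_a)), mean_log2_b=float(np.mean(log_b)),
        fold_change=fc, t_stat=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue))


DEFAULT_CONTRASTS = (
    ("healthy", "tumour"),
    ("high_risk", "tumour"),
    ("post_therapy", "tumour"),
    ("high_risk", "post_therapy"),
)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cohort_marker_stats(
    expr: pd.DataFrame, meta: SampleTable, genes: list[str],
    contrasts=DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """Welch comparisons for each gene x contrast with significance stars."""
    known = set(meta.table["group"])
    for a, b in contrasts:
        for g in (a, b):
            if g not in known:
                raise ValueError(f"unknown group {g!r} in contrasts")
    rows = []
    for gene in genes:
        for a, b in contrasts:
            cmp_ = group_fold_change(expr, meta, gene, a, b)
            rows.append({
                "gene": gene, "group_a": a, "group_b": b,
                "n_a": cmp_.n_a, "n_b": cmp_.n_b,
                "fold_change": cmp_.fold_change,
                "t_stat": cmp_.t_stat, "df": cmp_.df,
                "p_value": cmp_.p_value,
                "stars": significance_stars(cmp_.p_value),
            })
    columns = ["gene", "group_a", "group_b", "n_a", "n_b", "fold_change",
               "t_stat", "df", "p_value", "stars"]
    return pd.DataFrame(rows, columns=columns)
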