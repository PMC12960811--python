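"""Discovery-stage statistics on the RNA-seq count matrix.

Covers median-of-ratios depth normalisation, merging of technical
replicates, sample QC, a per-gene two-sided Welch test on log2 normalised
counts with Benjamini-Hochberg FDR control, and a PCA variance summary.

The differential test here is deliberately a transparent Welch-on-logs
procedure rather than a negative-binomial Wald model: the discovery
contract of this pipeline is the downstream filter cascade (robust fold
change, base-mean window, outlier rule), which consumes base means and fold
changes and is insensitive to the exact flavour of the per-gene test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohortdata import CountMatrix, SampleTable

logger = logging.getLogger("swabmark.diffexpr")

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class DEResult:
    """Per-gene differential expression result for one contrast (B over A)."""

    group_a: str
    group_b: str
    table: pd.DataFrame = field(repr=False)  # indexed by gene

    def __post_init__(self) -> None:
        required = {"base_mean_all", "base_mean_a", "base_mean_b",
                    "log2fc", "p_value", "p_adj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")


@dataclass
class PcaSummary:
    variance_explained: np.ndarray  # non-increasing, sums to <= 1

    @property
    def pc1_pct(self) -> float:
        return 100.0 * float(self.variance_explained[0])

    @property
    def pc2_pct(self) -> float:
        return 100.0 * float(self.variance_explained[1]) \
            if len(self.variance_explained) > 1 else 0.0


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (DESeq-style).

    Reference per gene = geometric mean across samples, genes containing
    any zero excluded; the factor of a sample is the median ratio of its
    counts to the reference.
    """
    c = counts.counts.astype(float)
    usable = np.all(c > 0, axis=1)
    if not usable.any():
        raise ValueError("no gene without zeros available for the reference")
    ref = np.exp(np.mean(np.log(c[usable]), axis=1))
    factors = np.median(c[usable] / ref[:, None], axis=0)
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        raise ValueError("degenerate size factors; check input counts")
    return factors


def normalized_counts(counts: CountMatrix) -> pd.DataFrame:
    """Counts divided by their sample size factors, as genes x samples."""
    return counts.to_frame() / size_factors(counts)


def merge_technical_replicates(counts: CountMatrix) -> CountMatrix:
    """Sum technical replicate columns into one column per biological sample."""
    if not counts.replicate_of:
        return counts
    for rep, parent in counts.replicate_of.items():
        if parent in counts.replicate_of:
            raise ValueError(f"{rep!r} is a replicate of replicate {parent!r}")
    frame = counts.to_frame()
    parents = [counts.replicate_of.get(s, s) for s in counts.sample_ids]
    merged = frame.T.groupby(pd.Index(parents, name="sample"), sort=False).sum().T
    return CountMatrix.from_frame(merged)


def replicate_dispersion(counts: CountMatrix, subject: str,
                         min_count: int = 5) -> float:
    """Median across expressed genes of the replicate CV of counts.

    Expressed = mean count across the subject's replicates >= ``min_count``.
    Returns 0.0 for subjects without technical replicates.
    """
    cols = [s for s in counts.sample_ids
            if s == subject or (counts.replicate_of or {}).get(s) == subject]
    if len(cols) < 2:
        return 0.0
    sub = counts.to_frame()[cols].to_numpy(dtype=float)
    mean = sub.mean(axis=1)
    expressed = mean >= min_count
    if not expressed.any():
        return np.inf
    cv = sub[expressed].std(axis=1, ddof=1) / mean[expressed]
    return float(np.median(cv))


def sample_qc(
    counts: CountMatrix,
    min_assigned: int = 10_000,
    max_replicate_cv: float = 0.5,
) -> tuple[list[str], dict[str, str]]:
    """Flag biological samples with too few assigned reads or discordant
    technical replicates.

    Returns (kept subject ids, dropped subject id -> reason).  QC never
    raises on content; it only reports.
    """
    rep_of = counts.replicate_of or {}
    subjects = [s for s in counts.sample_ids if s not in rep_of]
    frame = counts.to_frame()
    kept, dropped = [], {}
    for subj in subjects:
        cols = [s for s in counts.sample_ids
                if s == subj or rep_of.get(s) == subj]
        total = int(frame[cols].to_numpy().sum())
        if total < min_assigned:
            dropped[subj] = f"low assigned reads ({total} < {min_assigned})"
            continue
        cv = replicate_dispersion(counts, subj)
        if cv > max_replicate_cv:
            dropped[subj] = f"replicate CV {cv:.3g} > {max_replicate_cv}"
            continue
        kept.append(subj)
    for subj, reason in dropped.items():
        logger.info("sample QC: dropped %s (%s)", subj, reason)
    return kept, dropped


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t test; returns (t, Welch-Satterthwaite df, p)."""
    res = stats.ttest_ind(b, a, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]


def de_test(
    counts: CountMatrix,
    meta: SampleTable | None,
    group_a,
    group_b,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    count_group_outliers: bool = True,
) -> DEResult:
    """Per-gene differential expression of group B over group A.

    ``group_a``/``group_b`` are either explicit sample-id lists or criteria
    dicts resolved against ``meta`` (e.g. ``{"group": "healthy"}``).  Base
    means are arithmetic means of size-factor-normalised counts; log2FC uses
    a pseudocount; p-values come from a two-sided Welch test on
    log2(normalised + pseudocount), adjusted by Benjamini-Hochberg across
    all genes of the contrast.
    """
    def resolve(sel):
        if isinstance(sel, dict):
            if meta is None:
                raise ValueError("criteria selectors require metadata")
            return meta.sample_ids(**sel)
        return list(sel)

    ids_a, ids_b = resolve(group_a), resolve(group_b)
    for name, ids in (("A", ids_a), ("B", ids_b)):
        if len(ids) < 2:
            raise ValueError(f"group {name} has {len(ids)} samples; need >= 2")

    norm = normalized_counts(counts)
    sub_a = norm[ids_a].to_numpy()
    sub_b = norm[ids_b].to_numpy()
    c = pseudocount

    mean_a, mean_b = sub_a.mean(axis=1), sub_b.mean(axis=1)
    base_all = norm[ids_a + ids_b].to_numpy().mean(axis=1)
    log2fc = np.log2((mean_b + c) / (mean_a + c))

    log_a, log_b = np.log2(sub_a + c), np.log2(sub_b + c)
    res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant in both groups give 0/0; they carry no evidence
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = bh_adjust(p)

    table = pd.DataFrame({
        "base_mean_all": base_all,
        "base_mean_a": mean_a,
        "base_mean_b": mean_b,
        "log2fc": log2fc,
        "p_value": p,
        "p_adj": p_adj,
    }, index=pd.Index(counts.gene_ids, name="gene"))

    if count_group_outliers:
        from .shortlist import count_outliers  # local import: no module cycle
        n_out_a = np.empty(len(counts.gene_ids), dtype=int)
        n_out_b = np.empty(len(counts.gene_ids), dtype=int)
        for i in range(len(counts.gene_ids)):
            direction = "up" if log2fc[i] >= 0 else "down"
            n_out_a[i], n_out_b[i] = count_outliers(
                sub_a[i] + c, sub_b[i] + c, direction=direction)
        table["n_outliers_a"] = n_out_a
        table["n_outliers_b"] = n_out_b

    label = (lambda sel: ",".join(f"{k}={v}" for k, v in sel.items())
             if isinstance(sel, dict) else "custom")
    return DEResult(group_a=label(group_a), group_b=label(group_b), table=table)


def pca_summary(counts: CountMatrix,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PcaSummary:
    """Variance explained by the principal components of log2 normalised
    counts (samples as observations, gene-wise centring, no scaling)."""
    if counts.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = np.log2(normalized_counts(counts).to_numpy() + pseudocount)
    centred = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    total = np.sum(centred ** 2)
    if total == 0:
        logger.warning("constant matrix: PCA variance undefined, returning 0s")
        return PcaSummary(np.zeros(counts.n_samples - 1))
    s = np.linalg.svd(centred, compute_uv=False)
    var = s ** 2 / total
    return PcaSummary(var[: counts.n_samples - 1])
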