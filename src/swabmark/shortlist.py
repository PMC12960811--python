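"""Candidate-marker selection: robust fold change and the filter cascade.

Conventional per-gene tests flag genes whose *average* expression differs,
which in a ten-sample discovery cohort tolerates single samples on the
wrong side of the divide — fatal for a diagnostic marker.  The robust
("largest minimum") fold change instead pairs the least-expressing tumour
sample with the highest-expressing healthy sample: a ratio above 1 means
every tumour sample exceeds every healthy sample, i.e. the gene separates
the groups sample-by-sample within the assay's dynamic range.

Candidates significant in the healthy-vs-tumour contrast are then pushed
through a hard filter cascade — overall base mean, log2 fold change, a
window on the tumour-minus-healthy base-mean difference (high enough to
survive RT-qPCR, low enough not to saturate), and an outlier budget of at
most one discordant sample per group — and ranked by robust fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DEResult

CASCADE_RULES = ("significant", "base_mean_gt", "log2fc_gt",
                 "diff_window", "outlier_rule")


@dataclass
class CascadeConfig:
    """Thresholds of the discovery filter cascade (defaults as published:
    base mean > 25, log2FC > 2, base-mean difference in [50, 3500],
    <= 1 outlier per group, adjusted p < 0.05)."""

    min_base_mean: float = 25.0
    min_log2fc: float = 2.0
    diff_min: float = 50.0
    diff_max: float = 3500.0
    max_outliers_per_group: int = 1
    alpha: float = 0.05


@dataclass
class Shortlist:
    """Flags, robust FC and rank per candidate gene, plus the funnel."""

    table: pd.DataFrame = field(repr=False)   # indexed by gene
    funnel: dict[str, int] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        sel = self.table[self.table["shortlisted"]]
        return list(sel.sort_values("rank").index)


def robust_fold_change(healthy: np.ndarray, tumour: np.ndarray,
                       pseudocount: float = 1.0) -> float:
    """Worst-case separation ratio min(tumour) / max(healthy).

    For a tumour-up candidate this matches the lowest tumour sample against
    the highest healthy one; > 1 means perfect sample-wise separation.  A
    pseudocount is applied only if any input value is zero, keeping the
    statistic scale-equivariant on positive data.
    """
    healthy = np.asarray(healthy, dtype=float)
    tumour = np.asarray(tumour, dtype=float)
    if healthy.size == 0 or tumour.size == 0:
        raise ValueError("robust_fold_change needs nonempty groups")
    if np.any(healthy < 0) or np.any(tumour < 0):
        raise ValueError("counts must be >= 0")
    if np.any(healthy == 0) or np.any(tumour == 0):
        healthy = healthy + pseudocount
        tumour = tumour + pseudocount
    return float(tumour.min() / healthy.max())


def significant_in_all_contrasts(
    de_results: list[DEResult] | DEResult, alpha: float = 0.05
) -> set[str]:
    """Genes over-expressed (log2FC > 0) with adjusted p < alpha in every
    supplied contrast.

    Pass a single healthy-vs-tumour contrast for the default selection or
    several contrasts for their intersection.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if isinstance(de_results, DEResult):
        de_results = [de_results]
    if not de_results:
        raise ValueError("no DE results supplied")
    selected: set[str] | None = None
    for de in de_results:
        t = de.table
        hits = set(t.index[(t["p_adj"] < alpha) & (t["log2fc"] > 0)])
        selected = hits if selected is None else selected & hits
    return selected or set()


def count_outliers(values_a: np.ndarray, values_b: np.ndarray,
                   direction: str = "up") -> tuple[int, int]:
    """Count samples on the wrong side of the group separation threshold.

    The threshold t* is the geometric mean of the two group medians.  For an
    up-regulated gene (B above A), a B sample below t* or an A sample above
    t* is discordant; ``direction="down"`` flips the roles.  Values are
    normalised counts with any pseudocount already applied by the caller.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("count_outliers needs nonempty groups")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    t_star = float(np.sqrt(np.median(a) * np.median(b)))
    if direction == "up":
        n_a = int(np.sum(a > t_star))
        n_b = int(np.sum(b < t_star))
    else:
        n_a = int(np.sum(a < t_star))
        n_b = int(np.sum(b > t_star))
    return n_a, n_b


def filter_cascade(
    candidates: set[str] | list[str],
    de: DEResult,
    norm_counts: pd.DataFrame,
    healthy_ids: list[str],
    tumour_ids: list[str],
    config: CascadeConfig | None = None,
    pseudocount: float = 1.0,
) -> Shortlist:
    """Apply the hard filters in order and rank survivors by robust FC.

    ``norm_counts`` is the genes x samples matrix of size-factor-normalised
    counts.  Flags are evaluated for every candidate (so the funnel can be
    reported); a gene is shortlisted iff all flags hold.
    """
    cfg = config or CascadeConfig()
    candidates = sorted(candidates)
    missing = [g for g in candidates
               if g not in de.table.index or g not in norm_counts.index]
    if missing:
        raise KeyError(f"candidate gene(s) missing from inputs: {missing}")

    rows = []
    for g in candidates:
        d = de.table.loc[g]
        h = norm_counts.loc[g, healthy_ids].to_numpy(dtype=float) + pseudocount
        t = norm_counts.loc[g, tumour_ids].to_numpy(dtype=float) + pseudocount
        diff = d["base_mean_b"] - d["base_mean_a"]
        n_out_a, n_out_b = count_outliers(h, t, direction="up")
        flags = {
            "significant": bool(d["p_adj"] < cfg.alpha and d["log2fc"] > 0),
            "base_mean_gt": bool(d["base_mean_all"] > cfg.min_base_mean),
            "log2fc_gt": bool(d["log2fc"] > cfg.min_log2fc),
            "diff_window": bool(cfg.diff_min <= diff <= cfg.diff_max),
            "outlier_rule": bool(max(n_out_a, n_out_b)
                                 <= cfg.max_outliers_per_group),
        }
        rows.append({
            "gene": g,
            "robust_fc": robust_fold_change(h, t),
            "base_mean_all": float(d["base_mean_all"]),
            "log2fc": float(d["log2fc"]),
            "base_mean_diff": float(diff),
            "n_outliers_healthy": n_out_a,
            "n_outliers_tumour": n_out_b,
            **flags,
        })

    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["robust_fc", *CASCADE_RULES, "shortlisted", "rank"])
    if rows:
        table["shortlisted"] = table[list(CASCADE_RULES)].all(axis=1)
        # unique ranks over survivors, by robust FC descending (gene id
        # breaks exact ties deterministically)
        surv = table[table["shortlisted"]].sort_values(
            ["robust_fc", "gene"], ascending=[False, True],
            key=None).index
        table["rank"] = pd.NA
        table.loc[surv, "rank"] = range(1, len(surv) + 1)

    funnel = {"candidates": len(candidates)}
    alive = pd.Series(True, index=table.index)
    for rule in CASCADE_RULES:
        if len(table):
            alive &= table[rule]
        funnel[rule] = int(alive.sum())
    return Shortlist(table=table, funnel=funnel)
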