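"""Diagnostic evaluation: ROC curves, Youden cutoffs and marker panels.

Single markers are scored by their log2 relative expression; panels combine
markers CombiROC-style, by the in-sample predicted probability of a ridge-
penalised logistic model (so the operating cutoff lives on a probability
scale) or by a transparent mean-of-z-scores alternative.  Operating points
maximise the Youden index J = sensitivity + specificity - 1; a sample is
called positive when its score is >= the cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger("swabmark.rocpanel")

DEFAULT_RIDGE = 1e-6


@dataclass
class RocResult:
    """ROC curve with AUC, Youden operating point and confusion counts."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    se_at_cutoff: float
    sp_at_cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def pct_false_pos(self) -> float:
        """False positives as a percentage of the whole evaluated cohort."""
        return 100.0 * self.fp / (self.tp + self.fp + self.tn + self.fn)

    @property
    def pct_false_neg(self) -> float:
        return 100.0 * self.fn / (self.tp + self.fp + self.tn + self.fn)


def _check_classes(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative, ties ½.

    Computed in Mann-Whitney form from midranks, which equals exhaustive
    pair counting with tie correction.
    """
    scores, labels = _check_classes(scores, labels)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> RocResult:
    """Full ROC over the threshold grid of unique scores plus ±inf.

    A sample is called positive when score >= threshold.  The trapezoidal
    area under the curve equals the pair-counting AUC; the Youden point is
    the threshold maximising J, ties resolved toward the smallest cutoff.
    """
    scores, labels = _check_classes(scores, labels)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    thresholds = np.concatenate(
        [[-np.inf], np.unique(scores), [np.inf]])
    se = np.empty(len(thresholds))
    sp = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = scores >= t
        se[i] = (called & labels).sum() / n_pos
        sp[i] = (~called & ~labels).sum() / n_neg

    # Youden scan over the finite grid plus sentinels
    j = se + sp - 1.0
    best = np.flatnonzero(j == j.max())
    cut_idx = best[np.argmin(thresholds[best])]
    cutoff = float(thresholds[cut_idx])
    called = scores >= cutoff
    tp = int((called & labels).sum())
    fp = int((called & ~labels).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    return RocResult(
        thresholds=thresholds, sensitivity=se, specificity=sp,
        auc=auc(scores, labels),
        youden_cutoff=cutoff, youden_j=float(j[cut_idx]),
        se_at_cutoff=float(se[cut_idx]), sp_at_cutoff=float(sp[cut_idx]),
        tp=tp, fp=fp, tn=tn, fn=fn)


def youden_cutoff(scores, labels) -> tuple[float, float, float, float, dict]:
    """(cutoff, J, SE, SP, confusion) at the Youden-optimal threshold."""
    r = roc_curve(scores, labels)
    confusion = {"tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn}
    return r.youden_cutoff, r.youden_j, r.se_at_cutoff, r.sp_at_cutoff, confusion


# ---------------------------------------------------------------------------
# Panel combination
# ---------------------------------------------------------------------------


def _marker_matrix(expr: pd.DataFrame | np.ndarray,
                   markers: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(expr, pd.DataFrame):
        markers = list(dict.fromkeys(markers or expr.columns))
        return expr[markers].to_numpy(dtype=float), markers
    x = np.asarray(expr, dtype=float)
    markers = markers or [f"m{i}" for i in range(x.shape[1])]
    return x, list(markers)


def combo_score(expr, labels, markers: list[str] | None = None,
                method: str = "logistic",
                ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Combined per-sample score of a marker subset.

    ``logistic``: in-sample predicted probability of an L2-penalised
    logistic model on the standardised marker values (penalty weight =
    ``ridge``).  ``mean_z``: mean of the per-marker z-scores.  Constant
    markers are dropped with a warning; an all-constant panel is an error.
    """
    x, markers = _marker_matrix(expr, markers)
    _, y = _check_classes(np.zeros(len(x)), np.asarray(labels).astype(bool))
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(markers, keep) if not k]
        logger.warning("dropping constant marker(s): %s", dropped)
    if not keep.any():
        raise ValueError("all markers are constant; no score possible")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    if method == "mean_z":
        return z.mean(axis=1)
    if method != "logistic":
        raise ValueError(f"unknown method {method!r}")
    # sklearn's C is the inverse penalty weight
    c = 1.0 / ridge if ridge > 0 else 1e12
    model = LogisticRegression(penalty="l2", C=c, solver="lbfgs",
                               max_iter=5000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable fits hit max_iter benignly
        model.fit(z, y.astype(int))
    return model.predict_proba(z)[:, 1]


@dataclass
class PanelResult:
    """Ranked combinatorial panel table (one row per marker subset)."""

    table: pd.DataFrame = field(repr=False)
    score_method: str = "logistic"

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]


def evaluate_combos(expr, labels, markers: list[str],
                    min_size: int = 2, max_size: int | None = None,
                    method: str = "logistic",
                    ridge: float = DEFAULT_RIDGE) -> PanelResult:
    """Enumerate all marker subsets of sizes [min_size, max_size], score
    each, and rank by (AUC desc, Youden J desc, smaller panel first)."""
    if min_size < 2:
        raise ValueError("min_size must be >= 2; single markers have their "
                         "own ROC path")
    markers = list(dict.fromkeys(markers))  # identical sets never recounted
    max_size = max_size or len(markers)
    if max_size > len(markers):
        raise ValueError("max_size exceeds number of distinct markers")
    y = np.asarray(labels).astype(bool)
    rows = []
    for size in range(min_size, max_size + 1):
        for subset in combinations(markers, size):
            s = combo_score(expr, y, list(subset), method=method, ridge=ridge)
            r = roc_curve(s, y)
            rows.append({
                "markers": "+".join(subset), "size": size,
                "auc": r.auc, "youden_cutoff": r.youden_cutoff,
                "youden_j": r.youden_j,
                "sensitivity": r.se_at_cutoff, "specificity": r.sp_at_cutoff,
                "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                "pct_false_pos": r.pct_false_pos,
                "pct_false_neg": r.pct_false_neg,
            })
    table = pd.DataFrame(rows).sort_values(
        ["auc", "youden_j", "size", "markers"],
        ascending=[False, False, True, True]).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return PanelResult(table=table, score_method=method)


def marker_roc_table(expr: pd.DataFrame, labels, markers: list[str]
                     ) -> pd.DataFrame:
    """Single-marker ROC summary (one row per marker)."""
    y = np.asarray(labels).astype(bool)
    rows = []
    for m in markers:
        r = roc_curve(expr[m].to_numpy(dtype=float), y)
        rows.append({"marker": m, "auc": r.auc,
                     "youden_cutoff": r.youden_cutoff,
                     "youden_j": r.youden_j,
                     "sensitivity": r.se_at_cutoff,
                     "specificity": r.sp_at_cutoff,
                     "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                     "pct_false_pos": r.pct_false_pos,
                     "pct_false_neg": r.pct_false_neg})
    return pd.DataFrame(rows)


def stratified_eval(expr: pd.DataFrame, labels, strata,
                    markers: list[str],
                    method: str = "logistic",
                    ridge: float = DEFAULT_RIDGE) -> pd.DataFrame:
    """Single-marker and best-panel AUCs per stratum, with cross-stratum
    differences.

    ``expr`` is samples x markers; ``labels`` and ``strata`` align with its
    rows.  Strata containing only one class are skipped with a warning.
    Returns a long table (stratum, marker-or-panel, auc) plus rows with
    stratum "diff:<a>-<b>" holding pairwise AUC differences.
    """
    y = np.asarray(labels).astype(bool)
    strata = np.asarray(strata)
    rows = []
    per_stratum: dict[str, dict[str, float]] = {}
    for stratum in pd.unique(strata):
        mask = strata == stratum
        if y[mask].all() or not y[mask].any():
            logger.warning("stratum %r has a single class; skipped", stratum)
            continue
        aucs = {}
        for m in markers:
            aucs[m] = auc(expr.loc[mask, m].to_numpy(dtype=float), y[mask])
        if len(markers) >= 2:
            s = combo_score(expr.loc[mask], y[mask], markers,
                            method=method, ridge=ridge)
            aucs["panel:" + "+".join(markers)] = auc(s, y[mask])
        per_stratum[str(stratum)] = aucs
        for name, value in aucs.items():
            rows.append({"stratum": str(stratum), "marker": name,
                         "auc": value, "n": int(mask.sum())})
    names = list(per_stratum)
    for a, b in combinations(names, 2):
        for m in per_stratum[a]:
            if m in per_stratum[b]:
                rows.append({"stratum": f"diff:{a}-{b}", "marker": m,
                             "auc": per_stratum[a][m] - per_stratum[b][m],
                             "n": 0})
    return pd.DataFrame(rows, columns=["stratum", "marker", "auc", "n"])
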