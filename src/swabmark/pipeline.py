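"""Orchestration of the discovery → validation → panel workflow.

``run_all`` ties the stages together on a synthetic cohort (or files on
disk), writes every intermediate table, and renders a run report whose
numbers all trace back to written TSVs.  All randomness flows from the
config seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortdata, diffexpr, qpcr, rocpanel, shortlist, simulate
from .cohortdata import write_table
from .shortlist import CascadeConfig

logger = logging.getLogger("swabmark.pipeline")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of a full run."""

    seed: int = 0
    out_dir: str = "swabmark_run"
    # simulation scale (None fields fall back to the study-scale design)
    n_genes: int = 2000
    n_marker_genes: int = 40
    n_smoking_genes: int = 40
    technical_replicates: int = 2
    # discovery thresholds
    alpha: float = 0.05
    min_base_mean: float = 25.0
    min_log2fc: float = 2.0
    diff_min: float = 50.0
    diff_max: float = 3500.0
    max_outliers_per_group: int = 1
    min_assigned: int = 10_000
    max_replicate_cv: float = 0.5
    # validation / qPCR
    housekeeping_gene: str = simulate.HOUSEKEEPING_GENE
    max_ct_sd: float = 0.5
    rescue: bool = True
    # panel analysis
    markers: list[str] = field(default_factory=lambda: list(simulate.PANEL_GENES))
    min_combo_size: int = 2
    max_combo_size: int = 4
    combo_method: str = "logistic"
    ridge: float = 1e-6
    pos_group: str = "tumour"
    neg_group: str = "healthy"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        """Digest of the analytic configuration (output location excluded:
        where artifacts land does not change what was computed)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def cascade(self) -> CascadeConfig:
        return CascadeConfig(
            min_base_mean=self.min_base_mean, min_log2fc=self.min_log2fc,
            diff_min=self.diff_min, diff_max=self.diff_max,
            max_outliers_per_group=self.max_outliers_per_group,
            alpha=self.alpha)


def _design(config: RunConfig) -> simulate.SimDesign:
    d = simulate.default_design(seed=config.seed)
    d.n_genes = config.n_genes
    d.n_marker_genes = config.n_marker_genes
    d.n_smoking_genes = config.n_smoking_genes
    d.technical_replicates_per_sample = config.technical_replicates
    return d


def stage_simulate(config: RunConfig, out: Path) -> dict:
    design = _design(config)
    params = simulate.default_params()
    params.housekeeping_gene = config.housekeeping_gene
    counts, meta_d, truth = simulate.simulate_counts(design, params)
    ct, meta_v, truth = simulate.simulate_ct(design, params, truth)
    cohortdata.write_counts(counts, out / "counts.tsv")
    cohortdata.write_metadata(meta_d, out / "meta_discovery.csv")
    cohortdata.write_ct(ct, out / "ct.csv")
    cohortdata.write_metadata(meta_v, out / "meta_validation.csv")
    truth.to_json(out / "truth.json")
    return {"counts": counts, "meta_discovery": meta_d, "ct": ct,
            "meta_validation": meta_v, "truth": truth}


def stage_discover(config: RunConfig, counts, meta, out: Path) -> dict:
    merged = diffexpr.merge_technical_replicates(counts)
    kept, dropped = diffexpr.sample_qc(
        counts, min_assigned=config.min_assigned,
        max_replicate_cv=config.max_replicate_cv)
    merged = merged.subset_samples([s for s in merged.sample_ids if s in kept])

    subj = meta.table.drop_duplicates("subject_id")
    groups = dict(zip(subj["subject_id"], subj["group"]))
    smoking = dict(zip(subj["subject_id"], subj["smoking"]))
    tumour = [s for s in merged.sample_ids if groups.get(s) == "tumour"]
    healthy = [s for s in merged.sample_ids if groups.get(s) == "healthy"]
    smokers = [s for s in healthy if smoking.get(s) in ("light", "heavy")]
    nonsmokers = [s for s in healthy if smoking.get(s) == "none"]

    contrasts = {"all_healthy_vs_tumour": (healthy, tumour)}
    if len(smokers) >= 2:
        contrasts["smoker_vs_tumour"] = (smokers, tumour)
    if len(nonsmokers) >= 2:
        contrasts["nonsmoker_vs_tumour"] = (nonsmokers, tumour)

    de_results, de_frames = {}, []
    for name, (a, b) in contrasts.items():
        de = diffexpr.de_test(merged, meta, a, b)
        de_results[name] = de
        frame = de.table.reset_index()
        frame.insert(0, "contrast", name)
        de_frames.append(frame)
    write_table(pd.concat(de_frames, ignore_index=True),
                out / "de_results.tsv")

    pca = diffexpr.pca_summary(merged)
    with open(out / "pca.json", "w", encoding="utf-8") as fh:
        json.dump({"variance_explained": pca.variance_explained.tolist(),
                   "pc1_pct": pca.pc1_pct, "pc2_pct": pca.pc2_pct}, fh)

    de_main = de_results["all_healthy_vs_tumour"]
    candidates = shortlist.significant_in_all_contrasts(de_main, config.alpha)
    norm = diffexpr.normalized_counts(merged)
    sl = shortlist.filter_cascade(candidates, de_main, norm, healthy, tumour,
                                  config.cascade())
    write_table(sl.table.reset_index(), out / "shortlist.tsv")
    with open(out / "cascade_funnel.json", "w", encoding="utf-8") as fh:
        json.dump(sl.funnel, fh)
    logger.info("discovery funnel: %s", sl.funnel)
    return {"de_results": de_results, "pca": pca, "shortlist": sl,
            "qc_dropped": dropped, "candidates": candidates}


def stage_qpcr(config: RunConfig, ct, meta, out: Path) -> dict:
    expr = qpcr.quantify(ct, config.housekeeping_gene,
                         max_sd=config.max_ct_sd, rescue=config.rescue)
    write_table(expr, out / "expression.tsv")
    genes = [g for g in config.markers if g in set(expr["gene"])]
    present_groups = set(meta.table["group"])
    contrasts = [c for c in qpcr.DEFAULT_CONTRASTS
                 if set(c) <= present_groups]
    comparisons = qpcr.cohort_marker_stats(expr, meta, genes, contrasts)
    write_table(comparisons, out / "comparisons.tsv")
    return {"expression": expr, "comparisons": comparisons, "genes": genes}


def _score_frame(expr: pd.DataFrame, meta, genes, pos_group, neg_group,
                 sex=None):
    """Samples x markers matrix of log2 relative expression plus labels."""
    crit = {"group": [neg_group, pos_group]}
    if sex is not None:
        crit["sex"] = sex
    ids = meta.sample_ids(**crit)
    wide = (expr[expr["sample_id"].isin(ids)]
            .pivot(index="sample_id", columns="gene",
                   values="log2_rel_expr")[genes].dropna())
    grp = {s: meta.lookup(s)["group"] for s in wide.index}
    labels = np.array([grp[s] == pos_group for s in wide.index])
    sexes = np.array([meta.lookup(s)["sex"] for s in wide.index])
    return wide, labels, sexes


def stage_roc(config: RunConfig, expr, meta, genes, out: Path) -> dict:
    wide, labels, _ = _score_frame(expr, meta, genes,
                                   config.pos_group, config.neg_group,
                                   sex="male")
    roc = rocpanel.marker_roc_table(wide, labels, genes)
    write_table(roc, out / "roc.tsv")

    wide_all, labels_all, sexes = _score_frame(
        expr, meta, genes, config.pos_group, config.neg_group)
    strat = rocpanel.stratified_eval(wide_all, labels_all, sexes, genes,
                                     method=config.combo_method,
                                     ridge=config.ridge)
    write_table(strat, out / "roc_by_sex.tsv")
    return {"roc": roc, "stratified": strat,
            "wide": wide, "labels": labels}


def stage_combi(config: RunConfig, wide, labels, out: Path) -> dict:
    genes = [g for g in config.markers if g in wide.columns]
    panel = rocpanel.evaluate_combos(
        wide, labels, genes,
        min_size=config.min_combo_size,
        max_size=min(config.max_combo_size, len(genes)),
        method=config.combo_method, ridge=config.ridge)
    write_table(panel.table, out / "combos.tsv")
    best = panel.best
    scores = rocpanel.combo_score(wide, labels, best["markers"].split("+"),
                                  method=config.combo_method,
                                  ridge=config.ridge)
    score_table = pd.DataFrame({
        "sample_id": wide.index, "score": scores,
        "label": np.where(labels, config.pos_group, config.neg_group),
        "cutoff": best["youden_cutoff"],
        "called_positive": scores >= best["youden_cutoff"],
    })
    write_table(score_table, out / "best_combo_scores.tsv")
    return {"panel": panel, "best_scores": score_table}


def make_report(artifacts: dict, config: RunConfig, out: Path) -> dict:
    """Render report.md + report.json from the stage outputs.

    AUCs print to 2 decimals and percentages to 1, matching diagnostic
    reporting convention; missing stages are marked absent, never invented.
    """
    report: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "schema_version": config.schema_version}
    lines = ["# swabmark run report", "",
             f"- config hash: `{config.hash()}`",
             f"- seed: {config.seed}", ""]

    disc = artifacts.get("discover")
    if disc:
        report["funnel"] = disc["shortlist"].funnel
        report["pc1_pct"] = round(disc["pca"].pc1_pct, 1)
        report["pc2_pct"] = round(disc["pca"].pc2_pct, 1)
        lines += ["## Discovery", "",
                  f"- PC1 {report['pc1_pct']}% / PC2 {report['pc2_pct']}% "
                  "of variance",
                  f"- filter funnel: {disc['shortlist'].funnel}", ""]
    else:
        lines += ["## Discovery", "", "not run", ""]

    roc = artifacts.get("roc")
    if roc is not None:
        tab = roc["roc"]
        report["single_markers"] = {
            r["marker"]: {"auc": round(r["auc"], 2),
                          "sensitivity_pct": round(100 * r["sensitivity"], 1),
                          "specificity_pct": round(100 * r["specificity"], 1)}
            for _, r in tab.iterrows()}
        lines += ["## Single markers (male validation cohort)", ""]
        for m, v in report["single_markers"].items():
            lines.append(f"- {m}: AUC {v['auc']:.2f}, "
                         f"SE {v['sensitivity_pct']}%, "
                         f"SP {v['specificity_pct']}%")
        lines.append("")
    else:
        lines += ["## Single markers", "", "not run", ""]

    combi = artifacts.get("combi")
    if combi is not None:
        best = combi["panel"].best
        report["best_combo"] = {
            "markers": best["markers"], "auc": round(best["auc"], 2),
            "sensitivity_pct": round(100 * best["sensitivity"], 1),
            "specificity_pct": round(100 * best["specificity"], 1),
            "cutoff": round(float(best["youden_cutoff"]), 3),
            "pct_false_pos": round(float(best["pct_false_pos"]), 1),
            "pct_false_neg": round(float(best["pct_false_neg"]), 1)}
        report["n_combos"] = int(len(combi["panel"].table))
        b = report["best_combo"]
        lines += ["## Marker panels "
                  "(no multiplicity correction across combinations)", "",
                  f"- {report['n_combos']} combinations evaluated",
                  f"- best: {b['markers']} — AUC {b['auc']:.2f}, "
                  f"SE {b['sensitivity_pct']}%, SP {b['specificity_pct']}%, "
                  f"cutoff {b['cutoff']}, "
                  f"{b['pct_false_pos']}% FP / {b['pct_false_neg']}% FN",
                  ""]
    else:
        lines += ["## Marker panels", "", "not run", ""]

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
    return report


def run_all(config: RunConfig) -> dict:
    """Execute simulate → discover → qpcr → roc → combi → report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    artifacts: dict = {}
    stage = "simulate"
    try:
        sim = stage_simulate(config, out)
        artifacts["simulate"] = sim
        stage = "discover"
        artifacts["discover"] = stage_discover(
            config, sim["counts"], sim["meta_discovery"], out)
        stage = "qpcr"
        q = stage_qpcr(config, sim["ct"], sim["meta_validation"], out)
        artifacts["qpcr"] = q
        stage = "roc"
        r = stage_roc(config, q["expression"], sim["meta_validation"],
                      q["genes"], out)
        artifacts["roc"] = r
        stage = "combi"
        artifacts["combi"] = stage_combi(config, r["wide"], r["labels"], out)
        stage = "report"
        artifacts["report"] = make_report(artifacts, config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return artifacts
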