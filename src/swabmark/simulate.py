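"""Synthetic swab-cohort generator.

Emulates the two data layers of the study so the whole pipeline is testable
without access to the unpublished patient data:

* a discovery RNA-seq cohort (all male: 4 tumour, 3 healthy smokers, 3
  healthy non-smokers, technical replicates per library) with negative-
  binomial counts, tumour-specific marker genes and smoking-responsive
  genes;
* a validation RT-qPCR cohort (four clinical groups x sex, triplicate Ct
  values normalised to the mitochondrial housekeeping gene MT-ATP6) with
  Gaussian cycler noise, subject-level biological variation, a sex-dependent
  attenuation of the tumour effect and sporadic outlier samples.

All randomness flows from a single seed; each artifact (counts, Ct,
outliers) draws from its own child stream so adding one artifact never
perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohortdata import CountMatrix, CtTable, SampleTable

# The validated marker panel and housekeeping gene carry their real names so
# reports read like the study; remaining genes get synthetic identifiers.
PANEL_GENES = ("c-JUN", "SFN", "HSP90AB1", "STARD7")
HOUSEKEEPING_GENE = "MT-ATP6"


@dataclass
class SimDesign:
    """Cohort layout: who is sampled, and how many of each."""

    n_tumour: int = 4
    n_healthy_smoker: int = 3
    n_healthy_nonsmoker: int = 3
    # validation cohort sizes per clinical group, by sex
    validation_males: dict[str, int] = field(default_factory=lambda: {
        "healthy": 12, "tumour": 14, "post_therapy": 12, "high_risk": 11,
    })
    validation_females: dict[str, int] = field(default_factory=lambda: {
        "healthy": 19, "tumour": 11, "post_therapy": 0, "high_risk": 0,
    })
    n_genes: int = 2000
    n_marker_genes: int = 40
    n_smoking_genes: int = 40
    technical_replicates_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_tumour, self.n_healthy_smoker, self.n_healthy_nonsmoker,
                  self.n_genes, self.n_marker_genes, self.n_smoking_genes,
                  self.technical_replicates_per_sample]
        counts += list(self.validation_males.values())
        counts += list(self.validation_females.values())
        if any(c < 0 for c in counts):
            raise ValueError("design counts must be >= 0")
        if self.n_marker_genes + self.n_smoking_genes > self.n_genes:
            raise ValueError("marker + smoking genes exceed n_genes")


@dataclass
class SimParams:
    """Distributional knobs of the generator.

    Count layer: per-gene NB mean mu_g drawn log2-uniformly over
    ``baseline_log2_mean_range``; marker genes are instead drawn from
    ``marker_log2_mean_range`` (biomarker candidates sit in the mid-range of
    qPCR-detectable expression, not at the noise floor or saturation).
    Variance is mu + dispersion * mu^2.

    Ct layer: true Ct = ct_intercept - log2(relative abundance); triplicate
    wells add iid Gaussian noise, subjects add biological log2 noise, and
    tumour effects in females are multiplied by ``female_effect_attenuation``.
    """

    baseline_log2_mean_range: tuple[float, float] = (1.0, 9.0)
    marker_log2_mean_range: tuple[float, float] = (4.5, 7.0)
    nb_dispersion: float = 0.1
    library_size_log_sd: float = 0.2
    marker_log2fc: float = 3.0
    smoking_log2fc: float = 2.0
    female_effect_attenuation: float = 0.3
    biological_log2_sd: float = 1.0
    ct_intercept: float = 20.0
    ct_replicate_sd: float = 0.15
    housekeeping_gene: str = HOUSEKEEPING_GENE
    outlier_rate: float = 0.02
    outlier_log2_shift: float = 4.0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.library_size_log_sd < 0 or self.ct_replicate_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.female_effect_attenuation <= 1.0:
            raise ValueError("female_effect_attenuation must be in [0, 1]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    marker_gene_ids: list[str]
    smoking_gene_ids: list[str]
    true_log2fc: dict[str, float]          # tumour effect per gene (males)
    sample_groups: dict[str, str]
    sample_sex: dict[str, str]
    ct_outliers: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def default_design(seed: int = 0) -> SimDesign:
    """Cohort layout matching the study scale.

    Discovery: 4 male tumour patients, 3 healthy smokers, 3 healthy
    non-smokers.  Validation: males 12 healthy / 14 tumour / 12 post-therapy
    / 11 high-risk, females 19 healthy / 11 tumour (79 samples in total).
    """
    return SimDesign(seed=seed)


def default_params() -> SimParams:
    return SimParams()


def _gene_ids(design: SimDesign) -> tuple[list[str], list[str], list[str]]:
    n_m, n_s = design.n_marker_genes, design.n_smoking_genes
    markers = list(PANEL_GENES[:n_m]) + [
        f"MARK{i:03d}" for i in range(len(PANEL_GENES), n_m)
    ]
    smoking = [f"SMOK{i:03d}" for i in range(n_s)]
    n_null = design.n_genes - n_m - n_s - 1  # one slot for housekeeping
    null = [f"GENE{i:04d}" for i in range(max(n_null, 0))]
    return markers, smoking, null


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_counts(
    design: SimDesign, params: SimParams | None = None
) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Simulate the discovery RNA-seq cohort.

    Counts are NB(mean = L_s * mu_g * 2^effect, dispersion alpha) with
    variance mu + alpha mu^2.  Technical replicates share the biological
    mean but are drawn independently (with their own library size).
    """
    params = params or SimParams()
    if min(design.n_tumour,
           design.n_healthy_smoker + design.n_healthy_nonsmoker) == 0:
        raise ValueError("discovery design needs tumour and healthy samples")
    rng_base, rng_counts = _rng_streams(design.seed, 4)[:2]

    markers, smoking, null = _gene_ids(design)
    genes = markers + smoking + null + [params.housekeeping_gene]

    lo, hi = params.baseline_log2_mean_range
    mu = 2.0 ** rng_base.uniform(lo, hi, size=len(genes))
    m_lo, m_hi = params.marker_log2_mean_range
    mu[: len(markers)] = 2.0 ** rng_base.uniform(m_lo, m_hi, size=len(markers))

    subjects, groups, smoke = [], [], []
    for i in range(design.n_tumour):
        subjects.append(f"T{i+1:02d}"); groups.append("tumour"); smoke.append("heavy")
    for i in range(design.n_healthy_smoker):
        subjects.append(f"HS{i+1:02d}"); groups.append("healthy"); smoke.append("heavy")
    for i in range(design.n_healthy_nonsmoker):
        subjects.append(f"HN{i+1:02d}"); groups.append("healthy"); smoke.append("none")

    marker_set, smoking_set = set(markers), set(smoking)
    effect = np.zeros((len(genes), len(subjects)))
    for j, subj in enumerate(subjects):
        for i, g in enumerate(genes):
            e = 0.0
            if g in marker_set and groups[j] == "tumour":
                e += params.marker_log2fc
            if g in smoking_set and smoke[j] in ("light", "heavy"):
                e += params.smoking_log2fc
            effect[i, j] = e

    n_rep = max(design.technical_replicates_per_sample, 1)
    cols, rep_of, meta_rows = [], {}, []
    col_mats = []
    r = 1.0 / params.nb_dispersion  # NB number-of-failures parameter
    for j, subj in enumerate(subjects):
        bio_mean = mu * 2.0 ** effect[:, j]
        for k in range(n_rep):
            name = subj if k == 0 else f"{subj}_r{k+1}"
            if k > 0:
                rep_of[name] = subj
            lib = np.exp(rng_counts.normal(0.0, params.library_size_log_sd))
            m = np.clip(bio_mean * lib, 1e-12, None)
            p = r / (r + m)
            col_mats.append(rng_counts.negative_binomial(r, p))
            cols.append(name)
            meta_rows.append({
                "sample_id": name, "subject_id": subj, "group": groups[j],
                "sex": "male", "smoking": smoke[j],
                "swab_site": "lesion" if groups[j] == "tumour" else "NA",
            })

    counts = CountMatrix(genes, cols, np.column_stack(col_mats),
                         replicate_of=rep_of or None)
    meta = SampleTable(pd.DataFrame(meta_rows))
    truth = SimTruth(
        marker_gene_ids=markers,
        smoking_gene_ids=smoking,
        true_log2fc={g: (params.marker_log2fc if g in marker_set else 0.0)
                     for g in genes},
        sample_groups={s: g for s, g in zip(subjects, groups)},
        sample_sex={s: "male" for s in subjects},
    )
    return counts, meta, truth


def validation_metadata(design: SimDesign) -> SampleTable:
    """Metadata sheet for the validation RT-qPCR cohort."""
    rows = []
    for sex, sizes in (("male", design.validation_males),
                       ("female", design.validation_females)):
        for group, n in sizes.items():
            for i in range(n):
                sid = f"V{sex[0].upper()}_{group[:4]}{i+1:02d}"
                rows.append({
                    "sample_id": sid, "subject_id": sid, "group": group,
                    "sex": sex,
                    "smoking": "NA",
                    "swab_site": "NA" if group == "healthy" else "lesion",
                })
    return SampleTable(pd.DataFrame(rows))


def simulate_ct(
    design: SimDesign,
    params: SimParams | None = None,
    truth: SimTruth | None = None,
    genes: list[str] | None = None,
) -> tuple[CtTable, SampleTable, SimTruth]:
    """Simulate the validation cohort's triplicate Ct table.

    Per subject and gene the true Ct is ``ct_intercept - log2(abundance)``
    where abundance multiplies a per-gene baseline, the group/sex effect and
    subject-level biological noise; the housekeeping gene has constant unit
    abundance.  Triplicate wells add iid N(0, ct_replicate_sd).  With
    probability ``outlier_rate`` a (sample, target gene) pair is shifted by
    +-``outlier_log2_shift`` cycles (sign at random) and recorded in the
    truth.
    """
    params = params or SimParams()
    if truth is None:
        markers, smoking, _ = _gene_ids(design)
        truth = SimTruth(
            marker_gene_ids=markers, smoking_gene_ids=smoking,
            true_log2fc={g: params.marker_log2fc for g in markers},
            sample_groups={}, sample_sex={},
        )
    if genes is None:
        genes = list(truth.marker_gene_ids[: max(len(PANEL_GENES), 1)])
    if params.housekeeping_gene in genes:
        genes = [g for g in genes if g != params.housekeeping_gene]
    all_genes = genes + [params.housekeeping_gene]

    _, _, rng_ct, rng_out = _rng_streams(design.seed, 4)
    meta = validation_metadata(design)
    if meta.table.empty:
        raise ValueError("validation design has no samples")

    marker_set = set(truth.marker_gene_ids)
    baseline_log2 = {g: rng_ct.uniform(-8.0, -3.0) for g in genes}
    outliers: list[tuple[str, str]] = []
    rows = []
    for _, s in meta.table.iterrows():
        sid, group, sex = s["sample_id"], s["group"], s["sex"]
        for g in all_genes:
            if g == params.housekeeping_gene:
                log2_ab = 0.0
            else:
                eff = truth.true_log2fc.get(g, 0.0) if (
                    group == "tumour" and g in marker_set) else 0.0
                if sex == "female":
                    eff *= params.female_effect_attenuation
                log2_ab = (baseline_log2[g] + eff
                           + rng_ct.normal(0.0, params.biological_log2_sd))
            true_ct = params.ct_intercept - log2_ab
            if g != params.housekeeping_gene and (
                    rng_out.random() < params.outlier_rate):
                true_ct += rng_out.choice([-1.0, 1.0]) * params.outlier_log2_shift
                outliers.append((sid, g))
            for rep in (1, 2, 3):
                ct = true_ct + rng_ct.normal(0.0, params.ct_replicate_sd)
                rows.append({"sample_id": sid, "gene": g,
                             "replicate": rep, "ct": float(np.clip(ct, 0.0, 45.0))})

    truth.ct_outliers = outliers
    truth.sample_groups.update(dict(zip(meta.table["sample_id"],
                                        meta.table["group"])))
    truth.sample_sex.update(dict(zip(meta.table["sample_id"],
                                     meta.table["sex"])))
    return CtTable(pd.DataFrame(rows)), meta, truth
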