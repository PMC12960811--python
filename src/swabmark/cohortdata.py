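"""Data model and file I/O for the swab-cohort study artifacts.

Four tabular artifacts flow through the pipeline:

* a gene x sample RNA-seq count matrix (TSV, genes in rows),
* a per-sample clinical/lifestyle metadata sheet (CSV),
* a long-format RT-qPCR Ct table (CSV, one row per replicate well),
* generic result tables (TSV) written by the analysis stages.

Readers validate against the domain invariants (unique identifiers,
non-negative integer counts, Ct within the instrument range) and log every
normalisation or rejection with its source line; nothing is dropped
silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("swabmark.cohortdata")

GROUPS = ("healthy", "tumour", "post_therapy", "high_risk")
SEXES = ("male", "female")
SMOKING_LEVELS = ("none", "light", "heavy", "NA")
SWAB_SITES = ("lesion", "contralateral_normal", "NA")
P16_STATUSES = ("pos", "neg", "NA")

# Clinical sheets are inconsistently cased and hyphenated; map the common
# spellings onto the canonical enum values instead of rejecting them.
_GROUP_SYNONYMS = {
    "healthy": "healthy",
    "tumour": "tumour",
    "tumor": "tumour",
    "post_therapy": "post_therapy",
    "post-therapy": "post_therapy",
    "post therapy": "post_therapy",
    "high_risk": "high_risk",
    "high-risk": "high_risk",
    "high risk": "high_risk",
}

CT_MIN, CT_MAX = 0.0, 45.0


class FormatError(ValueError):
    """Structurally malformed input file (duplicates, ragged rows, bad types)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with optional technical-replicate map.

    ``replicate_of`` maps a replicate column to its parent sample column;
    the parent is itself a column of the matrix (first replicate by
    convention).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    replicate_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.replicate_of:
            known = set(self.sample_ids)
            for rep, parent in self.replicate_of.items():
                if rep not in known:
                    raise ValidationError(f"replicate sample {rep!r} not in matrix")
                if parent not in known:
                    raise ValidationError(
                        f"replicate parent {parent!r} of {rep!r} not in matrix"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, replicate_of: dict[str, str] | None = None
    ) -> "CountMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            counts=frame.to_numpy(),
            replicate_of=replicate_of,
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        rep = None
        if self.replicate_of:
            keep = set(sample_ids)
            rep = {r: p for r, p in self.replicate_of.items()
                   if r in keep and p in keep} or None
        return CountMatrix(self.gene_ids, list(sample_ids),
                           self.counts[:, idx], rep)


def read_counts(path, replicate_of: dict[str, str] | None = None) -> CountMatrix:
    """Read a genes-in-rows TSV count matrix (first column ``gene_id``)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected a gene_id column plus >=1 sample")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicated sample ids in header")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing count values")
    frame.columns = sample_ids  # undo pandas' duplicate-mangling safety net
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ValidationError(f"{path}: non-numeric counts in column {col!r}")
    return CountMatrix.from_frame(frame, replicate_of=replicate_of)


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_DEFAULTS = {
    "subject_id": None,  # defaults to sample_id
    "smoking": "NA",
    "swab_site": "NA",
    "p16_status": "NA",
}


@dataclass
class SampleTable:
    """Per-sample clinical and lifestyle metadata.

    Required columns: ``sample_id``, ``group``, ``sex``.  Optional clinical
    columns (staging, grading, localisation, ...) are preserved verbatim.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "group", "sex"):
            if col not in t.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if t["sample_id"].isna().any():
            row = int(t.index[t["sample_id"].isna()][0])
            raise ValidationError(f"metadata row {row}: missing sample_id")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
        for col, default in _META_DEFAULTS.items():
            if col not in t.columns:
                t[col] = t["sample_id"] if col == "subject_id" else default
        t["subject_id"] = t["subject_id"].fillna(t["sample_id"])
        for col, allowed in (("group", GROUPS), ("sex", SEXES),
                             ("smoking", SMOKING_LEVELS),
                             ("swab_site", SWAB_SITES),
                             ("p16_status", P16_STATUSES)):
            bad = ~t[col].isin(allowed)
            if bad.any():
                row = int(t.index[bad][0])
                raise ValidationError(
                    f"metadata row {row}: invalid {col} {t.loc[t.index[bad][0], col]!r}"
                )
        healthy_lesion = (t["group"] == "healthy") & (t["swab_site"] == "lesion")
        if healthy_lesion.any():
            row = int(t.index[healthy_lesion][0])
            raise ValidationError(
                f"metadata row {row}: healthy subjects cannot have a lesion swab"
            )
        self.table = t.reset_index(drop=True)

    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids matching all column=value (or column=list) criteria."""
        mask = pd.Series(True, index=self.table.index)
        for col, want in criteria.items():
            if isinstance(want, (list, tuple, set, frozenset)):
                mask &= self.table[col].isin(list(want))
            else:
                mask &= self.table[col] == want
        return self.table.loc[mask, "sample_id"].tolist()

    def lookup(self, sample_id: str) -> pd.Series:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]


def _normalise_group(value, row_number: int) -> str:
    key = str(value).strip().lower()
    if key not in _GROUP_SYNONYMS:
        raise ValidationError(
            f"metadata row {row_number}: unknown group label {value!r}"
        )
    canonical = _GROUP_SYNONYMS[key]
    if str(value) != canonical:
        logger.info("metadata row %d: normalised group %r -> %r",
                    row_number, value, canonical)
    return canonical


def read_metadata(path) -> SampleTable:
    """Read the sample metadata CSV, normalising enum spellings."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.replace({"": None, "NA": "NA"})
    if "group" in frame.columns:
        frame["group"] = [
            _normalise_group(v, i + 2) for i, v in enumerate(frame["group"])
        ]
    if "sex" in frame.columns:
        frame["sex"] = frame["sex"].astype(str).str.strip().str.lower()
    for col in ("smoking", "swab_site", "p16_status"):
        if col in frame.columns:
            frame[col] = frame[col].fillna("NA")
    return SampleTable(frame)


def write_metadata(meta: SampleTable, path) -> None:
    meta.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RT-qPCR Ct table
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Replicate-level Ct values, long format.

    Columns: ``sample_id``, ``gene``, ``replicate`` (1-based), ``ct``
    (float; NaN encodes a well that did not amplify — never a sentinel
    number, since e.g. Ct 40 is a legitimate measurement).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "gene", "replicate", "ct"):
            if col not in t.columns:
                raise ValidationError(f"Ct table missing column {col!r}")
        key = t[["sample_id", "gene", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise FormatError(
                "duplicate Ct record "
                f"({dup['sample_id']}, {dup['gene']}, {dup['replicate']})"
            )
        if (t["replicate"] < 1).any():
            raise ValidationError("replicate index must be >= 1")
        finite = t["ct"].dropna()
        out = (finite < CT_MIN) | (finite > CT_MAX)
        if out.any():
            raise ValidationError(
                f"Ct value {finite[out].iloc[0]} outside [{CT_MIN}, {CT_MAX}]"
            )
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.table["sample_id"]))


def read_ct(path) -> CtTable:
    """Read a long-format Ct CSV; "NA"/empty cells are missing values."""
    frame = pd.read_csv(path, dtype={"sample_id": str, "gene": str},
                        na_values=["NA", ""])
    frame["replicate"] = frame["replicate"].astype(int)
    frame["ct"] = pd.to_numeric(frame["ct"], errors="raise")
    n_missing = int(frame["ct"].isna().sum())
    if n_missing:
        logger.info("Ct table %s: %d missing wells", path, n_missing)
    return CtTable(frame)


def write_ct(ct: CtTable, path) -> None:
    ct.table.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a result table as TSV (row order preserved, no index column)."""
    if frame.columns.duplicated().any():
        raise FormatError("result table has duplicated column names")
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
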