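"""Readers, writers and validation for the pipeline's tabular and tree formats.

Canonical interchange is dense UTF-8 TSV (header row = taxon ids, first
column = sample ids); sparse ``(sample, taxon, count)`` triplets are accepted
for large simulated tables.  Trees are Newick, handled by scikit-bio.
Missing taxonomy ranks are encoded as the empty string, SILVA-style: a taxon
assignable at level L must have every rank above and including L present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("microsev")

#: Taxonomic ranks, highest to lowest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Clinical severity groups, ordered.  HC = healthy control; ASYM_UAS =
#: asymptomatic or undifferentiated autoimmune syndrome; SS_SLE = Sjögren's
#: syndrome or systemic lupus erythematosus.
GROUPS = ("HC", "ASYM_UAS", "SS_SLE")

#: Ordinal severity score used by the trend contrast.
GROUP_SCORE = {"HC": -1.0, "ASYM_UAS": 0.0, "SS_SLE": 1.0}

HLA_COLUMNS = ("hla_drb1_0301", "hla_drb1_1501", "hla_dqb1_0201", "hla_dqb1_0602")
TITER_COLUMNS = ("ro52_iga", "ro52_igg", "ro60_iga", "ro60_igg")

METADATA_COLUMNS = ("sample_id", "group", "batch") + HLA_COLUMNS + TITER_COLUMNS


class ValidationError(ValueError):
    """Malformed or internally inconsistent input."""


class CrossReferenceError(ValidationError):
    """Ids in one input do not match the object they must refer to."""


@dataclass
class CountTable:
    """Samples x taxa table of non-negative integer counts.

    ``data`` is a pandas DataFrame indexed by sample id with taxon-id
    columns; row order is authoritative for all downstream matrices.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r}")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(vals != np.floor(vals)):
            i, j = np.argwhere(vals != np.floor(vals))[0]
            raise ValidationError(
                f"non-integer count {vals[i, j]!r} at sample "
                f"{df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count {vals[i, j]!r} at sample "
                f"{df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"count table needs >= 2 samples and >= 2 taxa, got {df.shape}"
            )
        df = df.astype(np.int64)
        df.index.name = "sample_id"
        df.columns.name = None
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class TaxonomyTable:
    """Per-taxon 7-rank lineage (kingdom..species), '' marking missing.

    Invariant: a missing rank implies every lower rank is missing too.
    """

    data: pd.DataFrame  # index = taxon_id, columns = RANKS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if list(df.columns) != list(RANKS):
            raise ValidationError(
                f"taxonomy columns must be {list(RANKS)}, got {list(df.columns)}"
            )
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r} in taxonomy")
        df = df.fillna("").astype(str)
        present = df.to_numpy() != ""
        # once a rank is missing, all lower ranks must be missing
        bad = present[:, 1:] & ~present[:, :-1]
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"taxon {df.index[i]!r}: rank {RANKS[j + 1]!r} present but "
                f"{RANKS[j]!r} missing (gap in lineage)"
            )
        df.index.name = "taxon_id"
        self.data = df

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        return tuple(self.data.loc[taxon_id])

    def assignable_at(self, level: str) -> pd.Index:
        """Taxon ids with a non-missing lineage value at ``level``."""
        j = RANKS.index(level)
        mask = (self.data.iloc[:, : j + 1] != "").all(axis=1)
        return self.data.index[mask]


def _parse_flag(x) -> float:
    if pd.isna(x) or x == "":
        return np.nan
    v = float(x)
    if v not in (0.0, 1.0):
        raise ValidationError(f"HLA carrier flag must be 0, 1 or missing, got {x!r}")
    return v


@dataclass
class SampleMetadata:
    """Per-sample clinical metadata: severity group, sequencing batch, four
    HLA class II carrier flags and four anti-Ro titers (possibly missing)."""

    data: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in metadata")
        required = [c for c in METADATA_COLUMNS if c != "sample_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns {missing}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"unknown group label(s) {sorted(bad)}; allowed: {list(GROUPS)}"
            )
        for c in HLA_COLUMNS:
            df[c] = df[c].map(_parse_flag)
        for c in TITER_COLUMNS:
            df[c] = pd.to_numeric(df[c], errors="raise")
            if (df[c].dropna() < 0).any():
                sid = df.index[df[c] < 0][0]
                raise ValidationError(f"negative titer {c} for sample {sid!r}")
        df["batch"] = df["batch"].astype(str)
        df = df[list(required)]
        df.index.name = "sample_id"
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    @property
    def batch(self) -> pd.Series:
        return self.data["batch"]

    def severity_score(self) -> pd.Series:
        """Ordinal contrast score: HC=-1, ASYM_UAS=0, SS_SLE=+1."""
        return self.data["group"].map(GROUP_SCORE)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, dialect: str = "tsv_dense") -> CountTable:
    """Read a count table, either dense TSV or sparse triplets.

    Dense: header row of taxon ids, first column sample ids.  Triplet:
    3 columns (sample_id, taxon_id, count); absent cells are zero.
    """
    path = Path(path)
    if dialect == "tsv_dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountTable(df)
    if dialect == "triplet_sparse":
        trip = pd.read_csv(
            path, sep="\t", header=0,
            names=["sample_id", "taxon_id", "count"],
            dtype={"sample_id": str, "taxon_id": str},
        )
        dup = trip.duplicated(["sample_id", "taxon_id"])
        if dup.any():
            r = trip[dup].iloc[0]
            raise ValidationError(
                f"duplicate triplet for sample {r.sample_id!r}, taxon {r.taxon_id!r}"
            )
        dense = trip.pivot(index="sample_id", columns="taxon_id", values="count")
        dense = dense.fillna(0)
        dense = dense.loc[
            pd.unique(trip["sample_id"]), pd.unique(trip["taxon_id"])
        ]
        dense.columns.name = None
        return CountTable(dense)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_table(ct: CountTable, path) -> None:
    ct.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = [c.lower() for c in df.columns]
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=True,
                     na_values=[""])
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path) -> None:
    md.data.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path, taxonomy: TaxonomyTable | None = None) -> TreeNode:
    """Read a Newick tree; if a taxonomy is given, leaves must be known taxa."""
    tree = TreeNode.read(str(path), format="newick")
    if taxonomy is not None:
        known = set(taxonomy.data.index)
        for tip in tree.tips():
            if tip.name not in known:
                raise CrossReferenceError(
                    f"tree leaf {tip.name!r} not present in taxonomy"
                )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# alignment


def align(
    ct: CountTable, tax: TaxonomyTable, md: SampleMetadata
) -> tuple[CountTable, TaxonomyTable, SampleMetadata]:
    """Restrict all three inputs to their shared sample and taxon ids.

    Count-table order is preserved; dropped ids are logged at INFO.
    """
    samples = [s for s in ct.sample_ids if s in set(md.sample_ids)]
    taxa = [t for t in ct.taxon_ids if t in set(tax.data.index)]
    if not samples:
        raise CrossReferenceError("no samples shared between counts and metadata")
    if not taxa:
        raise CrossReferenceError("no taxa shared between counts and taxonomy")
    dropped_s = sorted(set(ct.sample_ids) - set(samples))
    dropped_t = sorted(set(ct.taxon_ids) - set(taxa))
    if dropped_s:
        logger.info("align: dropped %d sample(s): %s", len(dropped_s), dropped_s)
    if dropped_t:
        logger.info("align: dropped %d taxon/taxa: %s", len(dropped_t), dropped_t)
    ct2 = CountTable(ct.data.loc[samples, taxa])
    tax2 = TaxonomyTable(tax.data.loc[taxa])
    md2 = SampleMetadata(md.data.loc[samples].copy())
    return ct2, tax2, md2
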