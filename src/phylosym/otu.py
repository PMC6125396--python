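"""OTU table data model and text IO.

The central exchange object is :class:`OtuTable`: an integer count matrix
(samples x OTUs) carrying per-OTU taxonomy strings and per-sample host
metadata. Readers accept both the QIIME-classic orientation (OTUs as rows,
first header cell ``#OTU ID``, optional trailing ``taxonomy`` column) and a
plain samples-as-rows TSV; the orientation is detected from the header
sentinel and normalized to samples x OTUs.

Depth normalization (:func:`rarefy`) is sampling without replacement — a
multivariate hypergeometric draw per sample — so it matches classical
rarefaction semantics exactly and is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ranks of a seven-level semicolon-delimited lineage string.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

METADATA_COLUMNS = ("host_species", "genus", "tribe", "replicate")


class OtuTableError(ValueError):
    """Raised for malformed tables, metadata mismatches, or bad counts."""


@dataclass
class OtuTable:
    """Integer OTU counts with taxonomy and host metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = sample ids,
        columns = OTU ids.
    taxonomy
        Series mapping each OTU id to a semicolon-delimited lineage string
        (up to seven ranks; may be truncated when unassigned).
    metadata
        DataFrame indexed by sample id with at least a ``host_species``
        column; ``genus``, ``tribe`` and ``replicate`` are carried when
        present.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            raise OtuTableError("duplicated sample ids in count table")
        if self.counts.columns.has_duplicates:
            raise OtuTableError("duplicated OTU ids in count table")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise OtuTableError(
                    "non-integer count at sample "
                    f"{self.counts.index[bad[0]]!r}, OTU "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if arr.size and (self.counts.to_numpy() < 0).any():
            raise OtuTableError("negative counts are not allowed")
        missing_meta = set(self.counts.index) - set(self.metadata.index)
        if missing_meta:
            raise OtuTableError(
                "samples missing from metadata: " + ", ".join(sorted(missing_meta))
            )
        self.metadata = self.metadata.loc[self.counts.index]
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise OtuTableError(
                f"{len(missing_tax)} OTUs missing from taxonomy map "
                f"(e.g. {sorted(missing_tax)[:3]})"
            )
        self.taxonomy = self.taxonomy.loc[self.counts.columns]

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence matrix (samples x OTUs)."""
        return self.counts > 0

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized counts; empty samples stay all-zero."""
        totals = self.counts.sum(axis=1).replace(0, 1)
        return self.counts.div(totals, axis=0)

    def select_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(
            counts=self.counts.loc[sample_ids],
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[sample_ids],
        )

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return OtuTable(self.counts[keep], self.taxonomy.loc[keep], self.metadata)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
            and self.metadata.loc[:, list(self.metadata.columns)].equals(
                other.metadata.loc[:, list(other.metadata.columns)]
            )
        )


# -- readers / writers ---------------------------------------------------------


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise OtuTableError("metadata must have a 'sample_id' column")
    if "host_species" not in meta.columns:
        raise OtuTableError("metadata must have a 'host_species' column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise OtuTableError(f"duplicated sample id in metadata: {dup!r}")
    return meta.set_index("sample_id")


def read_otu_table(table_path, metadata_path) -> OtuTable:
    """Read a tab-separated OTU table plus its sample metadata.

    Both the QIIME-classic dialect (OTU rows, ``#OTU ID`` sentinel,
    optional trailing ``taxonomy`` column) and plain samples-as-rows TSV
    are accepted; orientation is normalized to samples x OTUs.
    """
    meta = read_metadata(metadata_path)
    with open(table_path) as fh:
        header = fh.readline()
    first_cell = header.rstrip("\n").split("\t")[0].strip()
    raw = pd.read_csv(table_path, sep="\t", index_col=0)
    if first_cell == "#OTU ID":  # QIIME classic: OTUs as rows
        if "taxonomy" in raw.columns:
            taxonomy = raw["taxonomy"].astype(str)
            raw = raw.drop(columns="taxonomy")
        else:
            taxonomy = pd.Series("", index=raw.index, dtype=str)
        counts = raw.T
    else:  # samples as rows
        if "taxonomy" in raw.index:
            taxonomy = raw.loc["taxonomy"].astype(str)
            raw = raw.drop(index="taxonomy")
        else:
            taxonomy = pd.Series("", index=raw.columns, dtype=str)
        counts = raw
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    taxonomy.index = taxonomy.index.astype(str)
    taxonomy.name = "taxonomy"

    unknown = set(counts.index) - set(meta.index)
    if unknown:
        raise OtuTableError(
            "samples in table but not in metadata: " + ", ".join(sorted(unknown))
        )
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            raise OtuTableError(
                f"non-numeric count in OTU {col!r}, sample {bad.index[0]!r}"
            )
    return OtuTable(counts=counts, taxonomy=taxonomy, metadata=meta)


def write_otu_table(table: OtuTable, table_path, metadata_path=None) -> None:
    """Write in the QIIME-classic dialect (round-trips with the reader)."""
    out = table.counts.T.copy()
    out.index.name = "#OTU ID"
    out["taxonomy"] = table.taxonomy
    out.to_csv(table_path, sep="\t")
    if metadata_path is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


# -- filtering / normalization -------------------------------------------------


def filter_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples is exactly 1."""
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals != 1]
    return OtuTable(table.counts[keep], table.taxonomy.loc[keep], table.metadata)


def rarefy(table: OtuTable, depth: int, seed, prune: bool = True) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Each retained row is an independent multivariate hypergeometric draw,
    so no OTU absent before subsampling can appear after, and row sums are
    exactly ``depth``. With ``prune`` (default) OTUs reduced to zero total
    are removed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    kept = totals.index[totals >= depth]
    dropped = sorted(set(totals.index) - set(kept))
    if dropped:
        logger.warning(
            "dropping %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    if not len(kept):
        raise ValueError(f"no sample has at least depth {depth} reads")
    rows = []
    for sid in kept:
        row = table.counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=list(kept), columns=table.counts.columns
    )
    out = OtuTable(counts, table.taxonomy, table.metadata.loc[list(kept)])
    return out.drop_empty_otus() if prune else out


# -- taxonomic aggregation -----------------------------------------------------


def split_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage, trimming rank prefixes like ``p__``.

    Empty or placeholder fields (``p__``, ``unclassified``, ``NA``) end the
    assigned part of the lineage.
    """
    parts = []
    for token in str(lineage).split(";"):
        token = token.strip()
        if "__" in token:
            token = token.split("__", 1)[1]
        if token in {"", "unclassified", "Unclassified", "NA", "nan"}:
            break
        parts.append(token)
    return parts


def lineage_at_rank(lineage: str, rank_idx: int) -> str:
    """Taxon label at rank ``rank_idx`` (0 = kingdom), pooling unassigned
    OTUs into ``unclassified_<deepest assigned parent>``."""
    parts = split_lineage(lineage)
    if len(parts) > rank_idx:
        return parts[rank_idx]
    parent = parts[-1] if parts else "root"
    return f"unclassified_{parent}"


def aggregate_by_rank(table: OtuTable, rank: str) -> pd.DataFrame:
    """Relative-abundance table (samples x taxa) at a taxonomic rank.

    Rows sum to 1 (empty samples excepted); columns are ordered by
    grand-mean abundance descending. OTUs unassigned at ``rank`` are pooled
    under ``unclassified_<deepest assigned parent>``.
    """
    if rank not in RANKS[:6]:
        raise ValueError(f"rank must be one of {RANKS[:6]}, got {rank!r}")
    rank_idx = RANKS.index(rank)
    labels = table.taxonomy.map(lambda s: lineage_at_rank(s, rank_idx))
    rel = table.relative_abundance()
    agg = rel.T.groupby(labels.values).sum().T
    order = agg.mean(axis=0).sort_values(ascending=False).index
    return agg[order]
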