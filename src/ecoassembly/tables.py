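"""Core data containers and OTU-table preprocessing.

The universal input for every analysis in this package is an OTU count
table: a samples x taxa matrix of non-negative integer read counts with
unique sample and taxon identifiers.  Tables are stored as pandas
DataFrames inside a thin validating wrapper, together with an optional
per-taxon domain tag (bacteria / fungi / unknown) used to extract
domain-specific subnetworks.

Preprocessing follows common amplicon practice: drop OTUs with fewer
than a minimum number of reads summed over all samples, rarefy every
sample to a common depth by sampling reads without replacement, and
optionally drop taxa below a relative-abundance floor before network
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "read_otu_table",
    "read_metadata",
    "filter_min_total_count",
    "filter_rare_relative",
    "rarefy",
    "to_relative_abundance",
]

VALID_DOMAINS = ("bacteria", "fungi", "unknown")


@dataclass
class OtuTable:
    """Samples x taxa integer count matrix with identifiers.

    Parameters
    ----------
    counts :
        DataFrame with sample ids as index and taxon ids as columns.
        Values must be non-negative integers.
    domain :
        Optional per-taxon domain tag, one of ``bacteria``, ``fungi``
        or ``unknown``.  Defaults to ``unknown`` for every taxon.
    """

    counts: pd.DataFrame
    domain: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise ValueError("duplicate taxon ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.domain is None:
            self.domain = pd.Series("unknown", index=c.columns)
        else:
            self.domain = self.domain.reindex(c.columns).fillna("unknown")
            bad = set(self.domain.unique()) - set(VALID_DOMAINS)
            if bad:
                raise ValueError(f"invalid domain tags: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_empty_taxa(self) -> "OtuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return OtuTable(self.counts[keep], self.domain[keep])

    def subset_taxa(self, taxa) -> "OtuTable":
        return OtuTable(self.counts[list(taxa)], self.domain[list(taxa)])

    def subset_samples(self, samples) -> "OtuTable":
        return OtuTable(self.counts.loc[list(samples)], self.domain)

    def to_tsv(self, path, orientation: str = "samples") -> None:
        """Write as dense TSV; first column holds ids."""
        if orientation == "samples":
            self.counts.rename_axis("sample_id").to_csv(path, sep="\t")
        elif orientation == "taxa":
            self.counts.T.rename_axis("taxon_id").to_csv(path, sep="\t")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")

    def __eq__(self, other) -> bool:  # noqa: D105
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.domain.equals(other.domain)


def read_otu_table(path, orientation: str = "samples", domain=None) -> OtuTable:
    """Read a dense TSV count table.

    ``orientation='samples'`` expects samples as rows; ``'taxa'``
    expects taxa as rows (the table is transposed on read so the
    in-memory orientation is always samples x taxa).  Non-integer cells
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric cells in count table")
    if not np.allclose(arr, np.round(arr), atol=0):
        raise ValueError("counts must be integers")
    dom = None
    if domain is not None:
        dom = pd.Series(domain, index=df.columns) if np.isscalar(domain) else pd.Series(domain)
    return OtuTable(df.astype(np.int64), dom)


def read_metadata(path, index_col: str | int = 0) -> pd.DataFrame:
    """Read per-sample metadata CSV (coordinates + environmental variables)."""
    md = pd.read_csv(path, index_col=index_col)
    md.index = md.index.astype(str)
    if "latitude" in md.columns:
        lat = md["latitude"].dropna()
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
    if "longitude" in md.columns:
        lon = md["longitude"].dropna()
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
    return md


def filter_min_total_count(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Drop taxa whose total read count over all samples is below ``min_total``.

    The boundary is strict: a taxon with exactly ``min_total`` reads is
    retained.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = table.taxon_totals()
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        raise ValueError("all taxa removed by min-total filter")
    return table.subset_taxa(keep)


def filter_rare_relative(table: OtuTable, min_rel: float = 1e-4) -> OtuTable:
    """Drop taxa whose overall relative abundance is below ``min_rel``.

    Overall relative abundance is the taxon total divided by the grand
    total across all samples; taxa at exactly ``min_rel`` are kept.
    """
    totals = table.taxon_totals()
    grand = totals.sum()
    if grand == 0:
        raise ValueError("empty table")
    keep = totals.index[totals / grand >= min_rel]
    if len(keep) == 0:
        raise ValueError("all taxa removed by rare filter")
    return table.subset_taxa(keep)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses multivariate-hypergeometric draws, so a rarefied sample is a
    uniformly random subset of its reads.  Per-sample substreams are
    derived deterministically from the single ``seed``.
    """
    totals = table.sample_totals()
    low = totals[totals < depth]
    if len(low):
        raise ValueError(
            f"sample {low.index[0]!r} has {low.iloc[0]} reads, fewer than depth {depth}"
        )
    root = np.random.default_rng(seed)
    streams = root.spawn(table.n_samples)
    out = np.empty_like(table.counts.to_numpy())
    for i, rng in enumerate(streams):
        row = table.counts.to_numpy()[i]
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns),
        table.domain,
    )


def to_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    totals = table.sample_totals()
    if (totals == 0).any():
        empty = totals.index[totals == 0][0]
        raise ValueError(f"sample {empty!r} has zero total count")
    return table.counts.div(totals, axis=0)
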