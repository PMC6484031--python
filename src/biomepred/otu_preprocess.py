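"""OTU-table quality control and design-matrix construction.

The 16S pipeline upstream of this package produces an integer OTU count
table (samples x OTUs).  This module reproduces the tabular QC applied
before modelling: abundance filtering of sparse OTUs, rarefaction to a
common sequencing depth, conversion to relative abundances, construction
of the centered/scaled count matrix ``W`` used as the regression design,
and Good's coverage as a per-sample completeness diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "ScaledMatrix",
    "filter_otus",
    "rarefy",
    "to_relative",
    "build_W",
    "goods_coverage",
]

METADATA_COLUMNS = ("animal", "timepoint")


@dataclass
class OTUTable:
    """Integer OTU counts with sample-level metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, index = sample ids,
        columns = OTU ids.
    metadata
        DataFrame indexed by the same sample ids with at least the
        columns ``animal`` and ``timepoint``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate sample ids in OTU table")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate OTU ids in OTU table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts in OTU table")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if not self.counts.index.equals(self.metadata.index):
            # allow metadata given in any order but require same sample set
            if set(self.counts.index) != set(self.metadata.index):
                raise ValueError("metadata sample ids do not match count table")
            self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "OTUTable":
        ids = pd.Index(sample_ids)
        return OTUTable(self.counts.loc[ids], self.metadata.loc[ids])

    def to_tsv(self, counts_path, metadata_path) -> None:
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "OTUTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        bad = counts.columns[
            [not np.issubdtype(dt, np.integer) for dt in counts.dtypes]
        ]
        if len(bad):
            raise TypeError(f"non-integer counts in OTU columns: {list(bad)[:5]}")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        return cls(counts, meta)


def filter_otus(table: OTUTable, min_total: int = 1200) -> OTUTable:
    """Drop OTUs whose total count across all samples is below ``min_total``.

    The boundary is inclusive: an OTU with total exactly ``min_total`` is
    retained.  The sample set is unchanged.
    """
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        warnings.warn("abundance filter removed every OTU", stacklevel=2)
    return OTUTable(table.counts.loc[:, keep], table.metadata)


def rarefy(table: OTUTable, depth: int = 10000, seed: int | None = None) -> OTUTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Uses multivariate-hypergeometric draws (equivalent to drawing reads
    uniformly without replacement).  Samples with fewer than ``depth``
    total reads are dropped with a warning; samples at exactly ``depth``
    are returned unchanged.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep_mask = totals >= depth
    dropped = table.sample_ids[~keep_mask]
    if len(dropped):
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) with < {depth} reads",
            stacklevel=2,
        )
    rows = []
    kept_ids = table.sample_ids[keep_mask]
    for i in np.flatnonzero(keep_mask):
        if totals[i] == depth:
            rows.append(counts[i])
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth))
    new_counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64) if rows else np.empty((0, table.n_otus), int),
        index=kept_ids,
        columns=table.otu_ids,
    )
    return OTUTable(new_counts, table.metadata.loc[kept_ids])


def to_relative(table: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances; rows sum to 1, zeros preserved."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero-total sample(s): {bad[:5]}")
    return table.counts.div(totals, axis=0)


@dataclass
class ScaledMatrix:
    """Centered/scaled OTU count matrix with its fitting statistics.

    Centering means and scale factors are computed on a declared
    reference subset (the training fold in cross-validation) and applied
    to every sample, so held-out samples never inform the scaling.
    Zero-variance columns on the reference are scaled by 1 and flagged.
    """

    W: pd.DataFrame
    means: pd.Series
    scales: pd.Series
    zero_variance: pd.Series
    reference_ids: pd.Index = field(repr=False)

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return (counts[self.means.index] - self.means) / self.scales


def build_W(table: OTUTable, reference=None) -> ScaledMatrix:
    """Build the centered/scaled count matrix ``W``.

    Parameters
    ----------
    reference
        Sample ids on which the per-OTU means and standard deviations
        are estimated.  Defaults to all samples.
    """
    ref_ids = table.sample_ids if reference is None else pd.Index(reference)
    if len(ref_ids) == 0:
        raise ValueError("reference subset is empty")
    ref = table.counts.loc[ref_ids]
    means = ref.mean(axis=0)
    sds = ref.std(axis=0, ddof=1) if len(ref_ids) > 1 else ref.std(axis=0, ddof=0)
    zero_var = sds.fillna(0.0) <= 0.0
    scales = sds.where(~zero_var, 1.0)
    W = (table.counts - means) / scales
    return ScaledMatrix(
        W=W,
        means=means,
        scales=scales,
        zero_variance=zero_var,
        reference_ids=ref_ids,
    )


def goods_coverage(table: OTUTable) -> pd.Series:
    """Good's coverage 1 - singletons/total per sample.

    A singleton is an OTU observed exactly once in that sample.
    """
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-total sample in Good's coverage")
    singletons = (counts == 1).sum(axis=1)
    return pd.Series(1.0 - singletons / totals, index=table.sample_ids, name="goods_coverage")
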