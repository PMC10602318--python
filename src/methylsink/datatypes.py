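"""Core containers shared across the pipeline.

Matrices are pandas DataFrames oriented genes (or regions, metabolites)
as rows and samples as columns.  Sample metadata is a DataFrame indexed
by sample ID whose rows align 1:1 with the matrix columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class MethylsinkError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(MethylsinkError):
    """An invalid configuration value; the message names the field."""


class NormalizationError(MethylsinkError):
    pass


class DimensionError(MethylsinkError):
    pass


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups[:5]}")


@dataclass
class CountMatrix:
    """Raw gene x sample counts with per-sample metadata.

    ``metadata`` must be indexed by sample ID and contain at least a
    ``cohort`` column; ``donor``, ``mutation_status`` and arbitrary
    covariate columns are optional.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        if not self.counts.columns.equals(self.metadata.index):
            if set(self.counts.columns) != set(self.metadata.index):
                raise DimensionError(
                    "metadata rows do not align 1:1 with count-matrix samples"
                )
            self.metadata = self.metadata.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """Transformed expression values with provenance.

    ``transform`` is one of ``pseudocount``, ``log10``, ``zscore``,
    ``rank_percentile`` or ``residual``.  ``size_factors`` carries the
    per-sample normalization factors when the values derive from a
    median-ratio normalization.
    """

    values: pd.DataFrame
    transform: str = "pseudocount"
    size_factors: Optional[pd.Series] = None
    metadata: Optional[pd.DataFrame] = None

    _TRANSFORMS = ("pseudocount", "log10", "zscore", "rank_percentile", "residual")

    def __post_init__(self) -> None:
        if self.transform not in self._TRANSFORMS:
            raise ValueError(f"unknown transform tag {self.transform!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise NormalizationError("size factors must be strictly positive")
        if self.transform == "rank_percentile":
            v = self.values.to_numpy()
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("rank_percentile values must lie in (0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSet:
    """A named list of gene IDs with an optional per-gene classification."""

    name: str
    members: list[str]
    classification: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def require_in(self, genes: Sequence[str]) -> None:
        missing = sorted(set(self.members) - set(genes))
        if missing:
            raise KeyError(
                f"gene set {self.name!r} members absent from matrix: {missing[:10]}"
            )


@dataclass
class SignalMatrix:
    """Regions x samples mean log2 fold-change-over-input signal."""

    values: pd.DataFrame
    mark: str = ""
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "region")
        _check_unique(self.values.columns, "sample")

    @property
    def region_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


REGION_COLUMNS = ["chrom", "start", "end", "strand", "id"]


def make_regions(
    chrom: Sequence[str],
    start: Sequence[int],
    end: Sequence[int],
    strand: Optional[Sequence[str]] = None,
    ids: Optional[Sequence[str]] = None,
    region_class: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Build a 0-based half-open region table and validate coordinates."""
    n = len(chrom)
    df = pd.DataFrame(
        {
            "chrom": list(chrom),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": list(strand) if strand is not None else ["."] * n,
            "id": list(ids) if ids is not None else [f"region_{i}" for i in range(n)],
        }
    )
    if region_class is not None:
        df["class"] = list(region_class)
    if (df["start"] < 0).any():
        raise ValueError("region start must be non-negative")
    if (df["start"] >= df["end"]).any():
        raise ValueError("regions must satisfy start < end")
    _check_unique(pd.Index(df["id"]), "region")
    return df
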