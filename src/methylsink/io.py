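"""Plain-text readers and writers for the formats the pipeline consumes.

Matrices are TSV with feature IDs in the first column and sample IDs in
the header row; metadata TSV is keyed by sample ID; gene sets are
one-ID-per-line text or two-column (gene, class) TSV; peaks and regions
are BED (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, GeneSet, make_regions

PathLike = Union[str, Path]

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_counts",
    "read_gene_set",
    "write_gene_set",
    "read_bed",
    "write_bed",
]


def read_matrix_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: PathLike, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_counts(counts_path: PathLike, metadata_path: PathLike) -> CountMatrix:
    counts = read_matrix_tsv(counts_path)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, metadata=metadata)


def read_gene_set(path: PathLike, name: str | None = None) -> GeneSet:
    """One gene ID per line, or two tab-separated columns (gene, class)."""
    path = Path(path)
    members: list[str] = []
    classification: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        members.append(parts[0])
        if len(parts) > 1:
            classification[parts[0]] = parts[1]
    return GeneSet(
        name=name or path.stem,
        members=members,
        classification=classification or None,
    )


def write_gene_set(gene_set: GeneSet, path: PathLike) -> None:
    lines = []
    for m in gene_set.members:
        if gene_set.classification and m in gene_set.classification:
            lines.append(f"{m}\t{gene_set.classification[m]}")
        else:
            lines.append(m)
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: PathLike) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end and optional name, score, strand."""
    names = ["chrom", "start", "end", "id", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if "id" in df.columns and "strand" in df.columns:
        return make_regions(
            df["chrom"], df["start"], df["end"], df["strand"], df["id"]
        )
    return df


def write_bed(regions: pd.DataFrame, path: PathLike) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("id", "score", "strand"):
        if extra in regions.columns:
            cols.append(extra)
        elif extra in ("id", "score") and "strand" in regions.columns:
            # BED columns are positional: pad name/score when strand is kept
            regions = regions.assign(**{extra: "." if extra == "id" else 0})
            cols.append(extra)
    regions[cols].to_csv(path, sep="\t", header=False, index=False)
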