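"""RPKM quantification of screened genes from metatranscriptome count tables.

Read trimming, alignment and feature counting happen upstream; this module
consumes a featureCounts-style table (gene_id, genome_id, gene length in bp,
one count column per sample) plus per-sample library sizes, computes

    RPKM[s] = count[s] * 1e9 / (library_size[s] * gene_length)

and summarises which genes/genomes are expressed and the mean expression per
taxon and gene family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import RANKS, UNKNOWN, GenomeRecord


def rpkm(count: float, gene_length: float, library_size: float) -> float:
    """Reads per kilobase per million mapped reads for one gene in one sample."""
    if gene_length <= 0:
        raise ValueError(f"gene_length must be positive, got {gene_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count * 1e9 / (library_size * gene_length)


@dataclass
class ExpressionRecord:
    """Counts and RPKM values of one gene across all samples."""

    gene_id: str
    genome_id: str
    gene_length: int
    counts: np.ndarray
    library_sizes: np.ndarray
    rpkm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != self.library_sizes.shape:
            raise ValueError("counts and library_sizes must have the same length")
        if self.gene_length <= 0:
            raise ValueError(f"gene {self.gene_id}: non-positive length")
        if (self.library_sizes <= 0).any():
            raise ValueError(f"gene {self.gene_id}: non-positive library size")
        if (self.counts < 0).any():
            raise ValueError(f"gene {self.gene_id}: negative count")
        self.rpkm = self.counts * 1e9 / (self.library_sizes * self.gene_length)


def load_counts(
    counts_path: str | Path, libsizes_path: str | Path
) -> list[ExpressionRecord]:
    """Read a counts TSV (gene_id, genome_id, length, S1..Sn) and a library-size TSV
    (sample, library_size) into :class:`ExpressionRecord` objects."""
    counts = pd.read_csv(counts_path, sep="\t")
    libs = pd.read_csv(libsizes_path, sep="\t")
    sample_cols = [c for c in counts.columns if c not in ("gene_id", "genome_id", "length")]
    lib_by_sample = dict(zip(libs["sample"], libs["library_size"]))
    missing = [s for s in sample_cols if s not in lib_by_sample]
    if missing:
        raise ValueError(f"library sizes missing for samples: {missing}")
    libsizes = np.array([lib_by_sample[s] for s in sample_cols], dtype=float)
    return [
        ExpressionRecord(
            gene_id=row["gene_id"],
            genome_id=row["genome_id"],
            gene_length=int(row["length"]),
            counts=row[sample_cols].to_numpy(dtype=float),
            library_sizes=libsizes,
        )
        for _, row in counts.iterrows()
    ]


def expression_flags(
    records: Sequence[ExpressionRecord], min_rpkm: float | None = None
) -> dict[str, bool]:
    """Per-gene expressed flag.

    Default rule: a gene is expressed when its raw count is > 0 in at least
    one sample.  With ``min_rpkm`` set, at least one sample must instead reach
    that RPKM value.
    """
    flags = {}
    for rec in records:
        if min_rpkm is None:
            flags[rec.gene_id] = bool((rec.counts > 0).any())
        else:
            flags[rec.gene_id] = bool((rec.rpkm >= min_rpkm).any())
    return flags


def genome_expression(
    records: Sequence[ExpressionRecord],
    gene_families: Mapping[str, str],
    min_rpkm: float | None = None,
) -> pd.DataFrame:
    """Per-genome, per-family expressed flags.

    A genome expresses a family when at least one of its genes assigned to
    that family is expressed.  ``gene_families`` maps gene_id to a family
    label (e.g. ``luxS`` / ``lsrB`` / ``cahR``).
    """
    flags = expression_flags(records, min_rpkm=min_rpkm)
    rows: dict[tuple[str, str], bool] = {}
    for rec in records:
        family = gene_families.get(rec.gene_id)
        if family is None:
            continue
        key = (rec.genome_id, family)
        rows[key] = rows.get(key, False) or flags[rec.gene_id]
    df = pd.DataFrame(
        [(g, f, v) for (g, f), v in sorted(rows.items())],
        columns=["genome_id", "family", "expressed"],
    )
    return df


def mean_expression(
    records: Sequence[ExpressionRecord],
    genomes: Sequence[GenomeRecord],
    gene_families: Mapping[str, str],
    rank: str = "genus",
) -> pd.DataFrame:
    """Mean RPKM per taxon per gene family.

    Aggregation order is fixed: arithmetic mean over samples within a gene,
    then over genes within the (taxon, family) group.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown lineage rank {rank!r}")
    taxon_of = {g.genome_id: g.lineage.get(rank, UNKNOWN) for g in genomes}
    unknown_ids = sorted({r.genome_id for r in records} - set(taxon_of))
    if unknown_ids:
        raise ValueError(f"genomes absent from the genome table: {unknown_ids}")
    rows = []
    for rec in records:
        family = gene_families.get(rec.gene_id)
        if family is None:
            continue
        rows.append(
            {
                "taxon": taxon_of[rec.genome_id],
                "family": family,
                "gene_mean_rpkm": float(rec.rpkm.mean()),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["taxon", "family", "mean_rpkm", "n_genes"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["taxon", "family"], as_index=False)
        .agg(mean_rpkm=("gene_mean_rpkm", "mean"), n_genes=("gene_mean_rpkm", "size"))
        .sort_values(["taxon", "family"])
        .reset_index(drop=True)
    )
    return out
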