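"""Genome tables, proteomes and the completeness/contamination filter.

The screening pipeline starts from (i) a genome quality/taxonomy table with
CheckM-style completeness and contamination percentages and (ii) per-genome
predicted proteomes (protein FASTA) with product-name annotations from a
PROKKA-style annotator, supplied either as GFF3 (``product=`` attribute) or
as a plain two-column ``protein_id<TAB>product`` table.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Lineage ranks carried for every genome, in hierarchical order.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNKNOWN = "unknown"

_REQUIRED_COLUMNS = ("genome_id", "completeness", "contamination")


@dataclass
class GenomeRecord:
    """One genome with its lineage and CheckM-style quality metrics."""

    genome_id: str
    lineage: dict[str, str] = field(default_factory=dict)
    completeness: float = 0.0
    contamination: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        self.lineage = {r: (self.lineage.get(r) or UNKNOWN) for r in RANKS}

    def rank(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown lineage rank {rank!r}; expected one of {RANKS}")
        return self.lineage[rank]


@dataclass
class ProteinRecord:
    """One predicted protein: sequence plus free-text product name."""

    protein_id: str
    genome_id: str
    sequence: str
    product_name: str = ""


def load_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read a genome quality/taxonomy TSV into :class:`GenomeRecord` objects.

    The header must name ``genome_id``, ``completeness`` and ``contamination``;
    lineage rank columns and ``source`` are optional.  Empty or missing ranks
    become ``"unknown"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"genome table {path} is missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        gid = row["genome_id"]
        metrics = {}
        for col in ("completeness", "contamination"):
            try:
                metrics[col] = float(row[col])
            except ValueError:
                raise ValueError(
                    f"genome {gid!r}: non-numeric {col} value {row[col]!r}"
                ) from None
        lineage = {r: row.get(r, UNKNOWN) or UNKNOWN for r in RANKS}
        records.append(
            GenomeRecord(
                genome_id=gid,
                lineage=lineage,
                completeness=metrics["completeness"],
                contamination=metrics["contamination"],
                source=row.get("source", ""),
            )
        )
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genome ids in {path}: {dupes}")
    return records


def write_genome_table(genomes: list[GenomeRecord], path: str | Path) -> None:
    """Write genomes back to the TSV dialect read by :func:`load_genome_table`."""
    rows = []
    for g in genomes:
        row = {"genome_id": g.genome_id}
        row.update({r: g.lineage[r] for r in RANKS})
        row["completeness"] = g.completeness
        row["contamination"] = g.contamination
        row["source"] = g.source
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def qc_filter(
    genomes: list[GenomeRecord],
    min_completeness: float = 80.0,
    max_contamination: float = 10.0,
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Split genomes into (kept, dropped) by the quality rule.

    A genome is kept iff ``completeness >= min_completeness`` and
    ``contamination <= max_contamination``; both boundaries are inclusive.
    Input order is preserved in both lists.
    """
    if not 0 <= min_completeness <= 100 or not 0 <= max_contamination <= 100:
        raise ValueError("QC thresholds must lie in [0, 100]")
    kept, dropped = [], []
    for g in genomes:
        if g.completeness >= min_completeness and g.contamination <= max_contamination:
            kept.append(g)
        else:
            dropped.append(g)
    return kept, dropped


def _products_from_gff3(path: Path) -> dict[str, str]:
    products: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                continue
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    key, value = item.split("=", 1)
                    attrs[key.strip()] = urllib.parse.unquote(value.strip())
            pid = attrs.get("ID") or attrs.get("locus_tag")
            if pid and "product" in attrs:
                products[pid] = attrs["product"]
    return products


def _products_from_table(path: Path) -> dict[str, str]:
    products: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno + 1}: expected 2 tab-separated columns")
            if lineno == 0 and parts[0].lower() in ("protein_id", "id"):
                continue
            products[parts[0]] = parts[1]
    return products


def load_proteome(
    faa_path: str | Path,
    annotation_path: str | Path | None = None,
    genome_id: str = "",
) -> list[ProteinRecord]:
    """Read one genome's protein FASTA plus its product-name annotations.

    Annotations may be GFF3 (``product`` attribute of records whose ``ID``
    matches the FASTA id) or a two-column ``protein_id<TAB>product`` table.
    Sequences are upper-cased and a trailing stop symbol ``*`` is stripped.
    FASTA entries without an annotation row get an empty product name and a
    logged warning.
    """
    faa_path = Path(faa_path)
    products: dict[str, str] = {}
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if annotation_path.suffix.lower() in (".gff", ".gff3"):
            products = _products_from_gff3(annotation_path)
        else:
            products = _products_from_table(annotation_path)

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(faa_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {faa_path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        if len(seq) < 1:
            raise ValueError(f"empty sequence for protein {rec.id!r} in {faa_path}")
        if annotation_path is not None and rec.id not in products:
            logger.warning("protein %s in %s has no annotation row", rec.id, faa_path)
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                genome_id=genome_id,
                sequence=seq,
                product_name=products.get(rec.id, ""),
            )
        )
    if not records:
        raise ValueError(f"no sequences found in FASTA {faa_path}")
    return records
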