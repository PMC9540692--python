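"""Prevalence percentages, the AI-2 role partition, and the run report.

All headline numbers of a screening run are derived here: what fraction of
genomes carry any QS family, how AI-2-positive genomes split into producers
(synthase only), sensors (receptor only) and both, and per-taxon rollups of
component carriage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ingest import RANKS, UNKNOWN, GenomeRecord

logger = logging.getLogger(__name__)


def prevalence(n_hit: int, n_total: int, decimals: int = 2) -> float:
    """``100 * n_hit / n_total`` rounded half-up to ``decimals`` places."""
    if n_total <= 0:
        raise ValueError("prevalence denominator must be positive")
    if not 0 <= n_hit <= n_total:
        raise ValueError(f"n_hit {n_hit} outside [0, {n_total}]")
    pct = Decimal(100) * Decimal(n_hit) / Decimal(n_total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class RolePartition:
    """AI-2-positive genomes split by role, with a receptor-only breakdown."""

    synthase_only: set[str] = field(default_factory=set)
    receptor_only: set[str] = field(default_factory=set)
    both: set[str] = field(default_factory=set)
    lsrb_only: set[str] = field(default_factory=set)
    cahr_only: set[str] = field(default_factory=set)
    lsrb_and_cahr: set[str] = field(default_factory=set)

    @property
    def positives(self) -> set[str]:
        return self.synthase_only | self.receptor_only | self.both

    def sizes(self) -> dict[str, int]:
        return {
            "synthase_only": len(self.synthase_only),
            "receptor_only": len(self.receptor_only),
            "both": len(self.both),
            "lsrb_only": len(self.lsrb_only),
            "cahr_only": len(self.cahr_only),
            "lsrb_and_cahr": len(self.lsrb_and_cahr),
        }


def partition_ai2_roles(component_table: pd.DataFrame) -> RolePartition:
    """Partition genomes by AI-2 role from the component table.

    ``component_table`` is indexed by genome_id with boolean columns
    ``has_luxS``, ``has_lsrB``, ``has_luxP`` and ``has_cahR``.  A known
    periplasmic receptor (LsrB or LuxP) counts on the LsrB side of the
    receptor-only breakdown.
    """
    part = RolePartition()
    for genome_id, row in component_table.iterrows():
        synthase = bool(row["has_luxS"])
        pbp = bool(row.get("has_lsrB", False)) or bool(row.get("has_luxP", False))
        cahr = bool(row.get("has_cahR", False))
        receptor = pbp or cahr
        if synthase and receptor:
            part.both.add(genome_id)
        elif synthase:
            part.synthase_only.add(genome_id)
        elif receptor:
            part.receptor_only.add(genome_id)
            if pbp and cahr:
                part.lsrb_and_cahr.add(genome_id)
            elif pbp:
                part.lsrb_only.add(genome_id)
            else:
                part.cahr_only.add(genome_id)
    return part


def taxon_rollup(
    component_table: pd.DataFrame,
    genomes: Sequence[GenomeRecord],
    rank: str = "genus",
) -> pd.DataFrame:
    """Per-taxon genome counts and component carriage counts.

    One row per taxon at ``rank`` with the number of genomes and, per
    component, the number of genomes carrying it (a genome counts once per
    component regardless of gene copies).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown lineage rank {rank!r}")
    taxon_of = {g.genome_id: g.lineage.get(rank, UNKNOWN) for g in genomes}
    rows: dict[str, dict[str, int]] = {}
    for genome_id, row in component_table.iterrows():
        taxon = taxon_of.get(genome_id, UNKNOWN)
        agg = rows.setdefault(
            taxon, {"n_genomes": 0, "luxS": 0, "lsrB": 0, "luxP": 0, "cahR": 0}
        )
        agg["n_genomes"] += 1
        agg["luxS"] += bool(row["has_luxS"])
        agg["lsrB"] += bool(row.get("has_lsrB", False))
        agg["luxP"] += bool(row.get("has_luxP", False))
        agg["cahR"] += bool(row.get("has_cahR", False))
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = rank
    return df


def family_prevalence(name_calls, n_genomes: int, decimals: int = 2) -> pd.DataFrame:
    """Per-family genome counts and prevalence percentages from name calls."""
    genomes_per_family: dict[str, set[str]] = {}
    for call in name_calls:
        genomes_per_family.setdefault(call.qs_family, set()).add(call.genome_id)
    rows = [
        {
            "qs_family": fam,
            "n_genomes": len(gset),
            "prevalence_pct": prevalence(len(gset), n_genomes, decimals)
            if n_genomes
            else 0.0,
        }
        for fam, gset in sorted(genomes_per_family.items())
    ]
    return pd.DataFrame(rows, columns=["qs_family", "n_genomes", "prevalence_pct"])


def summary_report(
    genomes_kept: Sequence[GenomeRecord],
    genomes_dropped: Sequence[GenomeRecord],
    name_calls,
    component_table: pd.DataFrame,
    partition: RolePartition,
    expression_table: pd.DataFrame | None = None,
    network_stats: Mapping | None = None,
) -> dict:
    """Assemble every headline statistic into one JSON-serialisable report."""
    for label, value in (
        ("component_table", component_table),
        ("partition", partition),
    ):
        if value is None:
            raise ValueError(f"missing stage output: {label}")
    n_total = len(genomes_kept)
    qs_positive = sorted({c.genome_id for c in name_calls} | partition.positives)
    ai2_positive = partition.positives
    if n_total == 0:
        logger.warning("empty community: all percentages reported as 0")

    def pct(n: int) -> float:
        return prevalence(n, n_total) if n_total else 0.0

    report = {
        "genomes": {
            "total_input": n_total + len(genomes_dropped),
            "kept": n_total,
            "dropped": len(genomes_dropped),
        },
        "qs_positive": {"n": len(qs_positive), "pct": pct(len(qs_positive))},
        "ai2_positive": {"n": len(ai2_positive), "pct": pct(len(ai2_positive))},
        "ai2_components": {
            "luxS_genomes": int(component_table["has_luxS"].sum()),
            "lsrB_genomes": int(component_table["has_lsrB"].sum()),
            "luxP_genomes": int(component_table["has_luxP"].sum()),
            "cahR_genomes": int(component_table["has_cahR"].sum())
            if "has_cahR" in component_table
            else 0,
        },
        "role_partition": partition.sizes(),
    }
    if expression_table is not None and len(expression_table):
        per_family = {}
        for family, group in expression_table.groupby("family"):
            n_with = group["genome_id"].nunique()
            n_expr = group.loc[group["expressed"], "genome_id"].nunique()
            per_family[family] = {
                "genomes_with_gene": int(n_with),
                "genomes_expressing": int(n_expr),
                "pct": prevalence(n_expr, n_with, 0) if n_with else 0.0,
            }
        expressing = expression_table.loc[
            expression_table["expressed"], "genome_id"
        ].nunique()
        with_any = expression_table["genome_id"].nunique()
        report["expression"] = {
            "genomes_expressing_ai2": int(expressing),
            "genomes_with_ai2_genes": int(with_any),
            "pct": prevalence(expressing, with_any, 0) if with_any else 0.0,
            "per_family": per_family,
        }
    if network_stats is not None:
        report["network"] = dict(network_stats)
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
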