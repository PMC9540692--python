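"""End-to-end orchestration: QC -> screening -> CahR calls -> partition -> network."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .cahr import CahRCall, CahRReference, classify_dcache_domains
from .ingest import GenomeRecord, ProteinRecord, qc_filter
from .network import build_network, network_stats, receptor_class_table
from .screen import (
    DomainHit,
    QSCatalog,
    QSGeneCall,
    ThresholdPolicy,
    call_ai2_components,
    hmm_scan,
    load_catalog,
    name_match,
)
from .summary import RolePartition, partition_ai2_roles, summary_report


@dataclass
class ScreenResult:
    """All stage outputs of one screening run."""

    kept: list[GenomeRecord]
    dropped: list[GenomeRecord]
    name_calls: list[QSGeneCall]
    domain_hits: list[DomainHit]
    component_table: pd.DataFrame
    cahr_calls: list[CahRCall]
    partition: RolePartition
    receptor_classes: dict[str, set[str]]
    network: nx.Graph
    network_stats: dict
    report: dict


def analyze_community(
    genomes: list[GenomeRecord],
    proteins: list[ProteinRecord],
    profiles,
    reference: CahRReference,
    catalog: QSCatalog | None = None,
    policy: ThresholdPolicy = ThresholdPolicy(),
    min_completeness: float = 80.0,
    max_contamination: float = 10.0,
    collapse_classes: bool = False,
) -> ScreenResult:
    """Run the whole screening pipeline on an in-memory community."""
    catalog = catalog or load_catalog()
    kept, dropped = qc_filter(genomes, min_completeness, max_contamination)
    kept_ids = {g.genome_id for g in kept}
    proteins = [p for p in proteins if p.genome_id in kept_ids]

    calls = name_match(proteins, catalog)
    hits = hmm_scan(proteins, profiles, policy)
    component_table = call_ai2_components(proteins, calls, hits)
    cahr_calls = classify_dcache_domains(proteins, hits, reference)

    passing_genomes = {c.genome_id for c in cahr_calls if c.passed}
    component_table["has_cahR"] = [
        gid in passing_genomes for gid in component_table.index
    ]
    partition = partition_ai2_roles(component_table)
    receptor_classes = receptor_class_table(component_table, cahr_calls)
    taxonomy = {g.genome_id: g.lineage.get("phylum", "unknown") for g in kept}
    network = build_network(
        partition, receptor_classes, taxonomy, collapse_classes=collapse_classes
    )
    stats = network_stats(network)
    report = summary_report(
        genomes_kept=kept,
        genomes_dropped=dropped,
        name_calls=calls,
        component_table=component_table,
        partition=partition,
        network_stats=stats,
    )
    return ScreenResult(
        kept=kept,
        dropped=dropped,
        name_calls=calls,
        domain_hits=hits,
        component_table=component_table,
        cahr_calls=cahr_calls,
        partition=partition,
        receptor_classes=receptor_classes,
        network=network,
        network_stats=stats,
        report=report,
    )
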