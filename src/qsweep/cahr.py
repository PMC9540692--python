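"""CahR-type AI-2 receptor classification of dCache_1 sensor domains.

A dCache_1 domain is called a CahR-type AI-2 receptor when five binding-pocket
residues are conserved at the positions of the reference ligand-binding domain
(PctA-LBD numbering): R126, W128, Y144, D146 and D173.  Candidate domains are
mapped onto the reference by a deterministic global alignment (see
:mod:`qsweep.align`); a candidate passes iff every one of the five reference
positions aligns to a candidate residue and that residue equals the required
one exactly.

The host protein's signal-transduction module (MCP, histidine kinase, ...) is
then typed from its domain architecture using the canonical Pfam marker
domains of each transmembrane signalling class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import ALPHABET, Alignment, global_align
from .ingest import ProteinRecord
from .screen import PFAM_DCACHE1, DomainHit

#: Default conserved positions (1-based in the reference) and required residues.
DEFAULT_CONSERVED = ((126, "R"), (128, "W"), (144, "Y"), (146, "D"), (173, "D"))

#: Candidates shorter than this are auto-failed without alignment.
MIN_DOMAIN_LENGTH = 30

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Marker domains of each signal-transduction class, and the precedence used
#: when a hybrid architecture matches several classes.
FUNCTIONAL_MODULE_MARKERS: dict[str, frozenset[str]] = {
    "MCP": frozenset({"MCPsignal"}),
    "HK": frozenset(
        {
            "HisKA",
            "HisKA_2",
            "HisKA_3",
            "HWE_HK",
            "HATPase_c",
            "HATPase_c_2",
            "HATPase_c_3",
            "HATPase_c_5",
        }
    ),
    "GCD": frozenset({"GGDEF", "EAL", "HD-GYP"}),
    "SP": frozenset({"SpoIIE", "PP2C", "PP2C_2"}),
    "STK": frozenset({"Pkinase"}),
    "ACGC": frozenset({"guanylate_cyc"}),
}

CLASS_PRECEDENCE = ("MCP", "HK", "GCD", "SP", "STK", "ACGC")

FUNCTIONAL_CLASSES = CLASS_PRECEDENCE + ("HP",)


@dataclass(frozen=True)
class CahRReference:
    """Reference ligand-binding domain with its conserved-position screen."""

    sequence: str
    reference_id: str = "PctA-LBD"
    conserved_positions: tuple[tuple[int, str], ...] = DEFAULT_CONSERVED

    def __post_init__(self) -> None:
        for pos, residue in self.conserved_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"conserved position {pos} outside reference of length {len(self.sequence)}"
                )
            if self.sequence[pos - 1] != residue:
                raise ValueError(
                    f"reference residue at {pos} is {self.sequence[pos - 1]}, "
                    f"screen requires {residue}"
                )

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "CahRReference":
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(sequence=str(rec.seq).upper().rstrip("*"), reference_id=rec.id, **kwargs)


@dataclass(frozen=True)
class ResidueState:
    """Observed candidate state at one conserved reference position."""

    candidate_index: int | None  # 1-based into the candidate; None = unmapped
    residue: str | None

    @property
    def mapped(self) -> bool:
        return self.candidate_index is not None


def _validate_candidate(candidate: str) -> None:
    bad = set(candidate) - set(ALPHABET)
    if bad:
        raise ValueError(f"candidate contains non-amino-acid letters: {sorted(bad)}")


def map_reference_positions(
    candidate: str, reference: CahRReference
) -> dict[int, ResidueState]:
    """Map the reference's conserved positions onto a candidate domain.

    The candidate is globally aligned against the reference; each conserved
    reference position reports the aligned candidate index and residue, or an
    unmapped state when the position falls on a gap, when the candidate
    residue is the ambiguity code X, or when the candidate is shorter than
    ``MIN_DOMAIN_LENGTH`` (fragments are auto-failed).
    """
    _validate_candidate(candidate)
    if len(candidate) < MIN_DOMAIN_LENGTH:
        return {pos: ResidueState(None, None) for pos, _ in reference.conserved_positions}
    alignment = global_align(candidate, reference.sequence)
    ref_to_cand = alignment.reference_to_candidate()
    states = {}
    for pos, _required in reference.conserved_positions:
        idx = ref_to_cand.get(pos)
        if idx is None:
            states[pos] = ResidueState(None, None)
        else:
            residue = candidate[idx - 1]
            if residue == "X":
                states[pos] = ResidueState(None, residue)
            else:
                states[pos] = ResidueState(idx, residue)
    return states


def screen_five_residues(
    residue_states: Mapping[int, ResidueState], reference: CahRReference
) -> bool:
    """True iff every conserved position is mapped to exactly the required residue."""
    for pos, required in reference.conserved_positions:
        if pos not in residue_states:
            raise ValueError(f"residue_states lacks conserved position {pos}")
        state = residue_states[pos]
        if not state.mapped or state.residue != required:
            return False
    return True


def classify_functional_module(domain_architecture: Iterable[str]) -> str:
    """Type a receptor protein from its ordered domain-model list.

    Returns the first class in precedence order (MCP > HK > GCD > SP > STK >
    ACGC) whose marker set intersects the architecture, or ``"HP"``
    (hypothetical protein) when none does.  Total: every architecture gets
    exactly one class.
    """
    arch = set(domain_architecture)
    for cls in CLASS_PRECEDENCE:
        if arch & FUNCTIONAL_MODULE_MARKERS[cls]:
            return cls
    return "HP"


@dataclass
class CahRCall:
    """Screen verdict and functional typing for one dCache_1 domain."""

    protein_id: str
    genome_id: str
    env_start: int
    env_end: int
    residue_states: dict[int, ResidueState]
    passed: bool
    functional_class: str
    architecture: tuple[str, ...] = ()


def classify_dcache_domains(
    proteins: Sequence[ProteinRecord],
    domain_hits: Sequence[DomainHit],
    reference: CahRReference,
) -> list[CahRCall]:
    """Run the five-residue screen on every dCache_1 domain hit.

    Each dCache_1 domain is screened independently on its envelope
    subsequence; the host protein's architecture (all of its domain hits,
    ordered by start coordinate) determines the functional class.
    """
    by_protein = {p.protein_id: p for p in proteins}
    hits_per_protein: dict[str, list[DomainHit]] = {}
    for hit in domain_hits:
        hits_per_protein.setdefault(hit.protein_id, []).append(hit)

    calls: list[CahRCall] = []
    for protein_id in sorted(hits_per_protein):
        hits = sorted(hits_per_protein[protein_id], key=lambda h: h.env_start)
        architecture = tuple(h.model_id for h in hits)
        dcache_hits = [h for h in hits if h.model_id == PFAM_DCACHE1]
        if not dcache_hits:
            continue
        protein = by_protein[protein_id]
        functional_class = classify_functional_module(architecture)
        for hit in dcache_hits:
            subsequence = protein.sequence[hit.env_start - 1 : hit.env_end]
            states = map_reference_positions(subsequence, reference)
            calls.append(
                CahRCall(
                    protein_id=protein_id,
                    genome_id=protein.genome_id,
                    env_start=hit.env_start,
                    env_end=hit.env_end,
                    residue_states=states,
                    passed=screen_five_residues(states, reference),
                    functional_class=functional_class,
                    architecture=architecture,
                )
            )
    return calls


@dataclass
class ConservationProfile:
    """Reference-anchored per-column amino-acid frequencies."""

    columns: tuple[int, ...]  # reference positions retained (all ungapped columns)
    frequencies: pd.DataFrame  # index = columns, columns = 20 residues, rows sum to 1
    n_sequences: int

    def to_tsv(self, path: str | Path) -> None:
        self.frequencies.to_csv(path, sep="\t", index_label="reference_position")


def reference_column_map(candidate: str, reference: CahRReference) -> dict[int, str | None]:
    """Candidate residue observed at every reference position (None on a gap)."""
    _validate_candidate(candidate)
    alignment = global_align(candidate, reference.sequence)
    ref_to_cand = alignment.reference_to_candidate()
    return {
        pos: (candidate[ref_to_cand[pos] - 1] if pos in ref_to_cand else None)
        for pos in range(1, len(reference.sequence) + 1)
    }


def conservation_profile(
    passing_domains: Sequence[str], reference: CahRReference
) -> ConservationProfile:
    """Position-frequency matrix of passing domains in reference coordinates.

    Columns gapped in the reference (candidate insertions) are discarded;
    each retained column's distribution is normalised over the sequences
    contributing a standard residue there.
    """
    if not passing_domains:
        raise ValueError("conservation profile requires at least one passing domain")
    positions = tuple(range(1, len(reference.sequence) + 1))
    counts = pd.DataFrame(0.0, index=list(positions), columns=list(AA20))
    for domain in passing_domains:
        for pos, residue in reference_column_map(domain, reference).items():
            if residue is not None and residue in counts.columns:
                counts.loc[pos, residue] += 1.0
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.where(totals > 0, 1.0), axis=0)
    return ConservationProfile(
        columns=positions, frequencies=freqs, n_sequences=len(passing_domains)
    )


def _merge_alignments(alignments: Sequence[Alignment], reference: CahRReference):
    """Merge reference-anchored pairwise alignments into one multiple alignment."""
    m = len(reference.sequence)
    # Per sequence: insertions[k] = run of candidate residues between reference
    # positions k and k+1 (k = 0..m), and residue_at[pos] for matched columns.
    parsed = []
    max_insert = [0] * (m + 1)
    for aln in alignments:
        inserts: dict[int, list[str]] = {k: [] for k in range(m + 1)}
        residue_at: dict[int, str] = {}
        last_ref = 0
        for i, j in aln.columns:
            if j is None:
                inserts[last_ref].append(aln.candidate[i - 1])
            else:
                if i is not None:
                    residue_at[j] = aln.candidate[i - 1]
                last_ref = j
        parsed.append((inserts, residue_at))
        for k in range(m + 1):
            max_insert[k] = max(max_insert[k], len(inserts[k]))

    def render(inserts, residue_at) -> str:
        out = []
        for k in range(m + 1):
            run = inserts[k]
            out.append("".join(run) + "-" * (max_insert[k] - len(run)))
            if k < m:
                out.append(residue_at.get(k + 1, "-"))
        return "".join(out)

    ref_inserts = {k: [] for k in range(m + 1)}
    ref_residues = {pos: reference.sequence[pos - 1] for pos in range(1, m + 1)}
    rows = [render(ref_inserts, ref_residues)]
    rows.extend(render(ins, res) for ins, res in parsed)
    return rows


def export_domain_alignment(
    domains: Mapping[str, str] | Sequence[tuple[str, str]],
    reference: CahRReference,
    path: str | Path,
) -> None:
    """Write a reference-anchored multiple alignment as aligned FASTA.

    ``domains`` maps sequence ids to unaligned domain sequences; each is
    pairwise-aligned to the reference and the alignments are merged on
    reference coordinates (suitable for external tree/logo software).  Output
    order is the reference followed by the domains in input order.
    """
    items = list(domains.items()) if isinstance(domains, Mapping) else list(domains)
    if len(items) < 2:
        raise ValueError("alignment export needs at least 2 sequences")
    alignments = [global_align(seq, reference.sequence) for _, seq in items]
    rows = _merge_alignments(alignments, reference)
    with open(path, "w") as fh:
        fh.write(f">{reference.reference_id}\n{rows[0]}\n")
        for (seq_id, _), row in zip(items, rows[1:]):
            fh.write(f">{seq_id}\n{row}\n")
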