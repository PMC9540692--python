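"""Detection of quorum-sensing signal-molecule genes.

Two complementary lines of evidence are combined, mirroring how large genome
collections are screened in practice:

* **name matching** — product names from the annotator are matched against a
  per-family keyword catalog (case-insensitive, whole-word);
* **profile-HMM search** — protein sequences are scanned with profile HMMs
  for the AI-2 components: the LuxS synthase (PF02664), the LsrB/LuxP
  periplasmic binding proteins (PF13407) and the dCache_1 sensor domain
  (PF02743), plus any extra domain models supplied (e.g. a Pfam-A subset for
  architecture typing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyhmmer
import yaml

from .ingest import ProteinRecord

#: The 15 signal families screened.
FAMILIES = (
    "AHL",
    "AIP",
    "AI-2",
    "AI-3",
    "CAI-1",
    "DSF/BDSF",
    "indole",
    "DKP",
    "PQS/HHQ",
    "IQS",
    "PPY",
    "DAR/CHD",
    "CSP",
    "DPO",
    "3-OH-PAME/3-OH-MAME",
)

ROLES = ("synthase", "receptor", "regulator", "degradation")

#: Pfam accessions of the AI-2 component models.
PFAM_LUXS = "PF02664"
PFAM_LSRB_LUXP = "PF13407"
PFAM_DCACHE1 = "PF02743"

#: Product-name keywords that pick LuxP over LsrB for a PF13407 hit.
LUXP_KEYWORDS = ("LuxP", "autoinducer 2-binding periplasmic protein")
LSRB_KEYWORDS = ("LsrB", "autoinducer 2-binding protein")


@dataclass(frozen=True)
class CatalogEntry:
    family: str
    role: str
    keywords: tuple[str, ...]


@dataclass
class QSCatalog:
    """Keyword catalog covering all 15 signal families."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        covered = {e.family for e in self.entries}
        missing = [f for f in FAMILIES if f not in covered]
        if missing:
            raise ValueError(f"catalog lacks entries for families: {missing}")
        for e in self.entries:
            if e.family not in FAMILIES:
                raise ValueError(f"unknown QS family {e.family!r}")
            if e.role not in ROLES:
                raise ValueError(f"unknown role {e.role!r} for family {e.family}")
            if not e.keywords:
                raise ValueError(f"empty keyword list for {e.family}/{e.role}")


def load_catalog(path: str | Path | None = None) -> QSCatalog:
    """Load a keyword catalog; the packaged default when ``path`` is None."""
    if path is None:
        text = resources.files("qsweep.data").joinpath("qs_catalog.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    entries = []
    for family, groups in raw["families"].items():
        for group in groups:
            entries.append(
                CatalogEntry(
                    family=family,
                    role=group["role"],
                    keywords=tuple(group["keywords"]),
                )
            )
    return QSCatalog(entries=entries)


@dataclass(frozen=True)
class QSGeneCall:
    """One protein assigned to one signal family with a role."""

    protein_id: str
    genome_id: str
    qs_family: str
    role: str
    evidence: str  # name_match | hmm | residue_screen
    detail: str  # matched keyword or profile model id


@dataclass(frozen=True)
class DomainHit:
    """One profile-model match on a protein (envelope coordinates, 1-based)."""

    protein_id: str
    model_id: str
    env_start: int
    env_end: int
    bit_score: float
    e_value: float


def _keyword_pattern(keyword: str) -> re.Pattern:
    # Whole-word: no letter/digit directly abutting the keyword.  Hyphens and
    # underscores therefore act as boundaries.
    return re.compile(
        rf"(?<![A-Za-z0-9]){re.escape(keyword)}(?![A-Za-z0-9])", re.IGNORECASE
    )


def name_match(proteins: Iterable[ProteinRecord], catalog: QSCatalog) -> list[QSGeneCall]:
    """Match product names against the catalog.

    One call is emitted per (protein, matching catalog entry); a protein may
    be called in several families.  Empty product names never match.
    """
    compiled = [
        (entry, [(kw, _keyword_pattern(kw)) for kw in entry.keywords])
        for entry in catalog.entries
    ]
    calls: list[QSGeneCall] = []
    for protein in proteins:
        name = protein.product_name
        if not name:
            continue
        for entry, patterns in compiled:
            for kw, pattern in patterns:
                if pattern.search(name):
                    calls.append(
                        QSGeneCall(
                            protein_id=protein.protein_id,
                            genome_id=protein.genome_id,
                            qs_family=entry.family,
                            role=entry.role,
                            evidence="name_match",
                            detail=kw,
                        )
                    )
                    break  # one call per matching entry
    return calls


@dataclass(frozen=True)
class ThresholdPolicy:
    """Hit-reporting policy for :func:`hmm_scan`.

    The model's gathering cutoff is used when present; otherwise domains must
    reach ``max_evalue`` (independent e-value).
    """

    use_gathering: bool = True
    max_evalue: float = 1e-5


def _load_profiles(profiles) -> list[pyhmmer.plan7.HMM]:
    hmms: list[pyhmmer.plan7.HMM] = []
    items = [profiles] if isinstance(profiles, (str, Path)) else list(profiles)
    for item in items:
        if isinstance(item, pyhmmer.plan7.HMM):
            hmms.append(item)
            continue
        path = Path(item)
        if path.is_dir():
            files = sorted(path.glob("*.hmm"))
            if not files:
                raise ValueError(f"no .hmm files found in directory {path}")
            for f in files:
                hmms.extend(_load_profiles(f))
            continue
        try:
            with pyhmmer.plan7.HMMFile(str(path)) as fh:
                hmms.extend(fh)
        except Exception as exc:  # noqa: BLE001 - surface the file name
            raise ValueError(f"unreadable profile HMM file {path}: {exc}") from exc
    return hmms


def _as_str(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def model_id_of(hmm: pyhmmer.plan7.HMM) -> str:
    """Stable model identifier: versionless accession if set, else the name."""
    if hmm.accession:
        return _as_str(hmm.accession).split(".")[0]
    return _as_str(hmm.name)


def hmm_scan(
    proteins: Sequence[ProteinRecord],
    profiles,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> list[DomainHit]:
    """Search every protein with every profile HMM.

    ``profiles`` may be paths to HMMER3 files/directories or in-memory
    ``pyhmmer.plan7.HMM`` objects.  Returns domain hits passing the threshold
    policy, sorted by (protein_id, env_start).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("no proteins to scan")
    hmms = _load_profiles(profiles)
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(name=p.protein_id.encode(), sequence=p.sequence).digitize(alphabet)
        for p in proteins
    ]
    block = pyhmmer.easel.DigitalSequenceBlock(alphabet, seqs)

    hits: list[DomainHit] = []
    for hmm in hmms:
        gathering = policy.use_gathering and hmm.cutoffs.gathering_available()
        pipeline = pyhmmer.plan7.Pipeline(
            alphabet, bit_cutoffs="gathering" if gathering else None
        )
        top = pipeline.search_hmm(hmm, block)
        mid = model_id_of(hmm)
        for hit in top:
            if not hit.included:
                continue
            for dom in hit.domains.included:
                if not gathering and dom.i_evalue > policy.max_evalue:
                    continue
                hits.append(
                    DomainHit(
                        protein_id=_as_str(hit.name),
                        model_id=mid,
                        env_start=dom.env_from,
                        env_end=dom.env_to,
                        bit_score=float(dom.score),
                        e_value=float(dom.i_evalue),
                    )
                )
    hits.sort(key=lambda h: (h.protein_id, h.env_start, h.model_id))
    return hits


def _name_has(product: str, keywords: Iterable[str]) -> bool:
    return any(_keyword_pattern(kw).search(product) for kw in keywords)


def call_ai2_components(
    proteins: Sequence[ProteinRecord],
    name_calls: Sequence[QSGeneCall],
    domain_hits: Sequence[DomainHit],
) -> pd.DataFrame:
    """Per-genome AI-2 component table.

    Columns: ``has_luxS``, ``has_lsrB``, ``has_luxP`` (booleans) and
    ``dcache1_proteins`` (list of dCache_1 :class:`DomainHit`).  ``has_luxS``
    is true on a PF02664 hit or an AI-2 synthase name match; PF13407 hits are
    split LuxP vs LsrB by product-name evidence (LuxP only on an explicit
    LuxP keyword, LsrB otherwise).
    """
    by_protein = {p.protein_id: p for p in proteins}
    genomes = sorted({p.genome_id for p in proteins})
    table = {
        g: {"has_luxS": False, "has_lsrB": False, "has_luxP": False, "dcache1_proteins": []}
        for g in genomes
    }

    for call in name_calls:
        if call.qs_family != "AI-2" or call.genome_id not in table:
            continue
        if call.role == "synthase":
            table[call.genome_id]["has_luxS"] = True
        elif call.role == "receptor":
            if call.detail in LUXP_KEYWORDS:
                table[call.genome_id]["has_luxP"] = True
            else:
                table[call.genome_id]["has_lsrB"] = True

    for hit in domain_hits:
        protein = by_protein.get(hit.protein_id)
        if protein is None:
            continue
        row = table[protein.genome_id]
        if hit.model_id == PFAM_LUXS:
            row["has_luxS"] = True
        elif hit.model_id == PFAM_LSRB_LUXP:
            if _name_has(protein.product_name, LUXP_KEYWORDS):
                row["has_luxP"] = True
            else:
                row["has_lsrB"] = True
        elif hit.model_id == PFAM_DCACHE1:
            row["dcache1_proteins"].append(hit)

    df = pd.DataFrame.from_dict(table, orient="index")
    df.index.name = "genome_id"
    return df
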