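"""Self-contained synthetic communities with a ground-truth manifest.

Real screening runs consume hundreds of downloaded genomes plus Pfam; every
stage of the pipeline is instead testable on communities generated here:
per-genome protein FASTA + GFF3 annotations, a quality/taxonomy table,
profile HMMs built from synthetic consensus alignments, and
negative-binomial count matrices — all determined byte-for-byte by a seed
and accompanied by a manifest recording what was planted where.

Planted receptors are copies of a synthetic reference scaffold (a ~250-aa
sequence, labelled synthetic, standing in for the PctA ligand-binding domain)
mutated only outside the five conserved positions; decoys differ at exactly
one conserved position, so the screen's decision boundary is the thing under
test.  Role fractions default to the producer/sensor/both ratios observed in
the rumen study system (357:122:201 of 981).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pyhmmer

from .cahr import DEFAULT_CONSERVED
from .ingest import RANKS, GenomeRecord, ProteinRecord, write_genome_table
from .screen import PFAM_DCACHE1, PFAM_LSRB_LUXP, PFAM_LUXS

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate background amino-acid frequencies (Robinson & Robinson order AA20).
_BACKGROUND = np.array(
    [
        0.078, 0.019, 0.053, 0.063, 0.039, 0.072, 0.022, 0.053, 0.059, 0.091,
        0.022, 0.043, 0.052, 0.042, 0.051, 0.068, 0.059, 0.066, 0.014, 0.032,
    ]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

REFERENCE_LENGTH = 250

#: Default role fractions: producers : sensors : both of the full collection.
DEFAULT_FRACTIONS = {
    "synthase_only": 357 / 981,
    "receptor_only": 122 / 981,
    "both": 201 / 981,
}

#: Functional-class mix of planted receptors (MCPs and HKs dominate).
CLASS_WEIGHTS = {
    "MCP": 0.50,
    "HK": 0.35,
    "GCD": 0.085,
    "SP": 0.044,
    "STK": 0.002,
    "ACGC": 0.005,
    "HP": 0.014,
}

#: Marker co-domains appended per functional class.
CLASS_CODOMAINS = {
    "MCP": ("MCPsignal",),
    "HK": ("HisKA", "HATPase_c"),
    "GCD": ("GGDEF",),
    "SP": ("SpoIIE",),
    "STK": ("Pkinase",),
    "ACGC": ("guanylate_cyc",),
    "HP": (),
}

#: Profile families: name -> (consensus length, accession or None).
FAMILY_SPECS = {
    "LuxS": (160, PFAM_LUXS),
    "LsrB": (330, PFAM_LSRB_LUXP),
    "dCache_1": (REFERENCE_LENGTH, PFAM_DCACHE1),
    "MCPsignal": (70, None),
    "HisKA": (66, None),
    "HATPase_c": (110, None),
    "GGDEF": (160, None),
    "SpoIIE": (90, None),
    "Pkinase": (130, None),
    "guanylate_cyc": (120, None),
}

#: A small pool of realistic rumen lineages to draw taxonomy labels from.
LINEAGES = [
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Butyrivibrio"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Oribacterium"),
    ("Bacteria", "Firmicutes", "Negativicutes", "Selenomonadales", "Selenomonadaceae", "Selenomonas"),
    ("Bacteria", "Spirochaetes", "Spirochaetia", "Spirochaetales", "Treponemataceae", "Treponema"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Succinivibrio"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    ("Bacteria", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", "Fibrobacter"),
    ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "unknown", "unknown"),
]


def _family_rng(name: str) -> np.random.Generator:
    # Family consensus sequences are fixtures: seeded by name, not by the run seed.
    return np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=_BACKGROUND))


def synthetic_reference() -> str:
    """The shipped synthetic reference scaffold (fixed, seed-independent).

    A 250-residue background-composition sequence with the five required
    residues R/W/Y/D/D planted at positions 126/128/144/146/173.
    """
    rng = _family_rng("PctA-LBD-synthetic")
    seq = list(_random_sequence(REFERENCE_LENGTH, rng))
    for pos, residue in DEFAULT_CONSERVED:
        seq[pos - 1] = residue
        # keep the flanks distinct from the required residue so that a
        # single-residue indel cannot produce a score-tied alignment that
        # still places the required residue at the conserved column
        for flank in (pos - 2, pos):
            if 0 <= flank < len(seq) and seq[flank] == residue:
                seq[flank] = "A" if residue != "A" else "G"
    return "".join(seq)


def family_consensus(name: str) -> str:
    """Deterministic consensus sequence of one synthetic profile family."""
    if name == "dCache_1":
        return synthetic_reference()
    length, _ = FAMILY_SPECS[name]
    return _random_sequence(length, _family_rng(name))


def mutate(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    frozen_positions: Sequence[int] = (),
) -> str:
    """Substitute residues at ``rate`` per site, never touching frozen (1-based) positions."""
    frozen = set(frozen_positions)
    out = list(sequence)
    hits = rng.random(len(sequence)) < rate
    for i in np.flatnonzero(hits):
        if i + 1 in frozen:
            continue
        choices = [aa for aa in AA20 if aa != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def build_profiles(families: Sequence[str] | None = None) -> list[pyhmmer.plan7.HMM]:
    """Build profile HMMs for the synthetic families from consensus MSAs.

    Each profile is trained on 12 sequences mutated at 8% per site from the
    family consensus (the five conserved positions stay frozen for the
    dCache_1 family).  Accessions are set to the corresponding Pfam ids where
    the pipeline keys on them.
    """
    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmms = []
    for name in families or FAMILY_SPECS:
        consensus = family_consensus(name)
        frozen = [p for p, _ in DEFAULT_CONSERVED] if name == "dCache_1" else []
        rng = _family_rng(name + "/msa")
        seqs = [
            pyhmmer.easel.TextSequence(
                name=f"{name}_{i:02d}".encode(),
                sequence=mutate(consensus, 0.08, rng, frozen),
            )
            for i in range(12)
        ]
        msa = pyhmmer.easel.TextMSA(name=name.encode(), sequences=seqs).digitize(alphabet)
        hmm, _, _ = builder.build_msa(msa, background)
        _, accession = FAMILY_SPECS[name]
        hmm.accession = accession
        hmms.append(hmm)
    return hmms


def write_profiles(hmms: Sequence[pyhmmer.plan7.HMM], path: str | Path) -> None:
    """Write profiles to a single HMMER3 text file."""
    with open(path, "wb") as fh:
        for hmm in hmms:
            hmm.write(fh)


@dataclass
class CahRTruth:
    protein_id: str
    functional_class: str
    n_domains: int


@dataclass
class DecoyTruth:
    protein_id: str
    mutated_position: int


@dataclass
class GenomeTruth:
    genome_id: str
    role: str  # synthase_only | receptor_only | both | none
    qc_pass: bool
    completeness: float
    contamination: float
    lineage: dict[str, str]
    luxs_proteins: list[str] = field(default_factory=list)
    lsrb_proteins: list[str] = field(default_factory=list)
    cahr_proteins: list[CahRTruth] = field(default_factory=list)
    decoys: list[DecoyTruth] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: fully determines every stage's expected output."""

    seed: int
    params: dict
    genomes: dict[str, GenomeTruth]
    expression: dict[str, bool] = field(default_factory=dict)

    def kept(self) -> list[GenomeTruth]:
        return [g for g in self.genomes.values() if g.qc_pass]

    def expected_component_table(self) -> pd.DataFrame:
        rows = {}
        for g in self.kept():
            rows[g.genome_id] = {
                "has_luxS": bool(g.luxs_proteins),
                "has_lsrB": bool(g.lsrb_proteins),
                "has_luxP": False,
                "has_cahR": bool(g.cahr_proteins),
            }
        df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        df.index.name = "genome_id"
        return df

    def expected_role(self, g: GenomeTruth) -> str:
        synthase = bool(g.luxs_proteins)
        receptor = bool(g.lsrb_proteins) or bool(g.cahr_proteins)
        if synthase and receptor:
            return "both"
        if synthase:
            return "synthase_only"
        if receptor:
            return "receptor_only"
        return "none"

    def expected_partition_sizes(self) -> dict[str, int]:
        sizes = {"synthase_only": 0, "receptor_only": 0, "both": 0}
        for g in self.kept():
            role = self.expected_role(g)
            if role in sizes:
                sizes[role] += 1
        return sizes

    def expected_passing_domains(self) -> dict[str, int]:
        """protein_id -> number of dCache_1 domains expected to pass the screen."""
        return {
            c.protein_id: c.n_domains for g in self.kept() for c in g.cahr_proteins
        }

    def expected_failing_proteins(self) -> set[str]:
        return {d.protein_id for g in self.kept() for d in g.decoys}

    def expected_receptor_classes(self) -> dict[str, set[str]]:
        classes: dict[str, set[str]] = {}
        for g in self.kept():
            for c in g.cahr_proteins:
                classes.setdefault(g.genome_id, set()).add(c.functional_class)
            if g.lsrb_proteins:
                classes.setdefault(g.genome_id, set()).add("LsrB")
        return classes

    def expected_edge_counts(self) -> dict[str, int]:
        """Edge counts by type for the full (class-materialised) network."""
        sizes = self.expected_partition_sizes()
        classes = self.expected_receptor_classes()
        receptor_species = [
            g for g in self.kept() if self.expected_role(g) in ("receptor_only", "both")
        ]
        class_links = sum(len(classes.get(g.genome_id, set())) for g in receptor_species)
        classes_present = set().union(
            *(classes.get(g.genome_id, set()) for g in receptor_species), set()
        )
        return {
            "produce": sizes["synthase_only"],
            "produce_and_sense": sizes["both"],
            "sense": sizes["receptor_only"] + class_links + len(classes_present),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "genomes": {gid: asdict(g) for gid, g in sorted(self.genomes.items())},
            "expression": dict(sorted(self.expression.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genomes = {}
        for gid, g in payload["genomes"].items():
            genomes[gid] = GenomeTruth(
                genome_id=g["genome_id"],
                role=g["role"],
                qc_pass=g["qc_pass"],
                completeness=g["completeness"],
                contamination=g["contamination"],
                lineage=g["lineage"],
                luxs_proteins=g["luxs_proteins"],
                lsrb_proteins=g["lsrb_proteins"],
                cahr_proteins=[CahRTruth(**c) for c in g["cahr_proteins"]],
                decoys=[DecoyTruth(**d) for d in g["decoys"]],
            )
        return cls(
            seed=payload["seed"],
            params=payload["params"],
            genomes=genomes,
            expression=payload.get("expression", {}),
        )


@dataclass
class SyntheticCommunity:
    genomes: list[GenomeRecord]
    proteins: list[ProteinRecord]
    truth: SyntheticTruth


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    quotas = {k: n * v for k, v in fractions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_community(
    n_genomes: int = 40,
    fractions: dict[str, float] | None = None,
    decoy_rate: float = 0.5,
    qc_fail_fraction: float = 0.1,
    lsrb_rate: float = 0.15,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticCommunity:
    """Generate a synthetic community and its ground-truth manifest.

    ``fractions`` gives the share of genomes per role (synthase_only /
    receptor_only / both); the remainder carries no AI-2 component.
    ``decoy_rate`` is the per-genome probability of planting a dCache_1 decoy
    that fails the screen at exactly one conserved position;
    ``qc_fail_fraction`` of genomes get quality metrics below threshold.
    With ``out_dir`` set, FASTA/GFF3/TSV/JSON files are written (byte-identical
    across runs with the same seed).
    """
    if n_genomes < 4:
        raise ValueError("n_genomes must be at least 4")
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError(f"role fractions sum to {sum(fractions.values()):.3f} > 1")
    allocation = dict(fractions)
    allocation["none"] = 1.0 - sum(fractions.values())
    counts = _largest_remainder(n_genomes, allocation)

    rng = np.random.default_rng(seed)
    roles = [role for role in ("synthase_only", "receptor_only", "both", "none") for _ in range(counts.get(role, 0))]
    roles = [roles[i] for i in rng.permutation(len(roles))]
    n_fail = int(round(qc_fail_fraction * n_genomes))
    fail_idx = set(rng.choice(n_genomes, size=n_fail, replace=False).tolist())

    reference = synthetic_reference()
    conserved = dict(DEFAULT_CONSERVED)
    conserved_positions = [p for p, _ in DEFAULT_CONSERVED]
    luxs_consensus = family_consensus("LuxS")
    lsrb_consensus = family_consensus("LsrB")
    codomain_consensus = {name: family_consensus(name) for name in FAMILY_SPECS if name not in ("LuxS", "LsrB", "dCache_1")}
    class_names = list(CLASS_WEIGHTS)
    class_p = np.array([CLASS_WEIGHTS[c] for c in class_names])
    class_p = class_p / class_p.sum()

    genomes: list[GenomeRecord] = []
    proteins: list[ProteinRecord] = []
    truth_genomes: dict[str, GenomeTruth] = {}

    for idx in range(n_genomes):
        genome_id = f"G{idx + 1:04d}"
        role = roles[idx]
        lineage_tuple = LINEAGES[rng.integers(len(LINEAGES))]
        lineage = dict(zip(RANKS[:-1], lineage_tuple))
        lineage["species"] = f"{lineage_tuple[-1]} sp. {genome_id}"
        qc_pass = idx not in fail_idx
        if qc_pass:
            completeness = round(float(rng.uniform(80.0, 100.0)), 2)
            contamination = round(float(rng.uniform(0.0, 10.0)), 2)
        elif rng.random() < 0.5:
            completeness = round(float(rng.uniform(50.0, 79.9)), 2)
            contamination = round(float(rng.uniform(0.0, 10.0)), 2)
        else:
            completeness = round(float(rng.uniform(80.0, 100.0)), 2)
            contamination = round(float(rng.uniform(10.5, 25.0)), 2)

        gtruth = GenomeTruth(
            genome_id=genome_id,
            role=role,
            qc_pass=qc_pass,
            completeness=completeness,
            contamination=contamination,
            lineage=lineage,
        )
        gproteins: list[ProteinRecord] = []
        counter = 0

        def add_protein(sequence: str, product: str) -> str:
            nonlocal counter
            counter += 1
            pid = f"{genome_id}_P{counter:04d}"
            gproteins.append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=genome_id,
                    sequence=sequence,
                    product_name=product,
                )
            )
            return pid

        if role in ("synthase_only", "both"):
            seq = mutate(luxs_consensus, 0.05, rng)
            gtruth.luxs_proteins.append(add_protein(seq, "S-ribosylhomocysteine lyase"))
        if role in ("receptor_only", "both"):
            plant_lsrb = rng.random() < lsrb_rate
            plant_cahr = (rng.random() < 0.95) or not plant_lsrb
            if plant_lsrb:
                seq = mutate(lsrb_consensus, 0.05, rng)
                gtruth.lsrb_proteins.append(
                    add_protein(seq, "Autoinducer 2-binding protein LsrB")
                )
            if plant_cahr:
                for _ in range(1 + int(rng.random() < 0.3)):  # some genomes carry 2 receptors
                    functional_class = class_names[
                        rng.choice(len(class_names), p=class_p)
                    ]
                    n_domains = 1 + int(rng.random() < 0.15)  # tandem dCache_1 occurs
                    domain_rate = float(rng.uniform(0.03, 0.12))
                    parts = [
                        mutate(reference, domain_rate, rng, conserved_positions)
                        for _ in range(n_domains)
                    ]
                    for codomain in CLASS_CODOMAINS[functional_class]:
                        parts.append(mutate(codomain_consensus[codomain], 0.05, rng))
                    pid = add_protein("".join(parts), "dCache_1 domain-containing protein")
                    gtruth.cahr_proteins.append(
                        CahRTruth(
                            protein_id=pid,
                            functional_class=functional_class,
                            n_domains=n_domains,
                        )
                    )
        if rng.random() < decoy_rate:
            pos = conserved_positions[rng.integers(len(conserved_positions))]
            seq = list(mutate(reference, 0.05, rng, conserved_positions))
            alternatives = [aa for aa in AA20 if aa != conserved[pos]]
            seq[pos - 1] = alternatives[rng.integers(len(alternatives))]
            pid = add_protein("".join(seq), "dCache_1 domain-containing protein")
            gtruth.decoys.append(DecoyTruth(protein_id=pid, mutated_position=pos))

        for _ in range(int(rng.integers(10, 20))):
            length = int(rng.integers(100, 400))
            add_protein(_random_sequence(length, rng), "hypothetical protein")

        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                lineage=lineage,
                completeness=completeness,
                contamination=contamination,
                source="synthetic",
            )
        )
        proteins.extend(gproteins)
        truth_genomes[genome_id] = gtruth

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genomes": n_genomes,
            "fractions": fractions,
            "decoy_rate": decoy_rate,
            "qc_fail_fraction": qc_fail_fraction,
            "lsrb_rate": lsrb_rate,
        },
        genomes=truth_genomes,
    )
    community = SyntheticCommunity(genomes=genomes, proteins=proteins, truth=truth)
    if out_dir is not None:
        write_community(community, out_dir)
    return community


def write_community(community: SyntheticCommunity, out_dir: str | Path) -> None:
    """Write per-genome FASTA + GFF3, the genome table, and truth.json."""
    out_dir = Path(out_dir)
    genome_dir = out_dir / "genomes"
    genome_dir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[ProteinRecord]] = {}
    for p in community.proteins:
        by_genome.setdefault(p.genome_id, []).append(p)
    for genome in community.genomes:
        gid = genome.genome_id
        with open(genome_dir / f"{gid}.faa", "w") as faa:
            for p in by_genome.get(gid, []):
                faa.write(f">{p.protein_id}\n{p.sequence}\n")
        with open(genome_dir / f"{gid}.gff3", "w") as gff:
            gff.write("##gff-version 3\n")
            start = 1
            for p in by_genome.get(gid, []):
                end = start + 3 * len(p.sequence) + 2
                gff.write(
                    f"{gid}_contig1\tqsweep_synthetic\tCDS\t{start}\t{end}\t.\t+\t0\t"
                    f"ID={p.protein_id};product={p.product_name}\n"
                )
                start = end + 1
    write_genome_table(community.genomes, out_dir / "genome_table.tsv")
    community.truth.to_json(out_dir / "truth.json")


def generate_counts(
    truth: SyntheticTruth,
    n_samples: int = 20,
    nb_mean: float = 50.0,
    nb_dispersion: float = 2.0,
    silent_fraction: float = 0.2,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count tables for the planted AI-2 genes.

    Counts for expressed genes are NB with mean ``nb_mean`` and size
    (dispersion) ``nb_dispersion`` (variance = m + m^2/k, so k -> inf recovers
    Poisson); a ``silent_fraction`` of genes is all-zero.  Library sizes are
    the per-sample column sums.  Updates ``truth.expression`` in place and
    returns (counts table, library-size table).
    """
    if not 0 <= silent_fraction < 1:
        raise ValueError("silent_fraction must lie in [0, 1)")
    if nb_mean <= 0 or nb_dispersion <= 0:
        raise ValueError("nb_mean and nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    protein_lengths = {}
    genes: list[tuple[str, str]] = []
    for g in sorted(truth.genomes):
        gt = truth.genomes[g]
        if not gt.qc_pass:
            continue
        for pid in gt.luxs_proteins + gt.lsrb_proteins + [c.protein_id for c in gt.cahr_proteins]:
            genes.append((pid, g))
    if not genes:
        raise ValueError("no planted AI-2 genes to generate counts for")

    sample_cols = [f"S{i + 1:02d}" for i in range(n_samples)]
    p_nb = nb_dispersion / (nb_dispersion + nb_mean)
    rows = []
    truth.expression.clear()
    for pid, gid in genes:
        silent = bool(rng.random() < silent_fraction)
        if silent:
            counts = np.zeros(n_samples, dtype=int)
        else:
            counts = rng.negative_binomial(nb_dispersion, p_nb, size=n_samples)
        truth.expression[pid] = bool(counts.sum() > 0)
        length = 3 * int(rng.integers(200, 400))  # bp, annotation-style gene length
        rows.append({"gene_id": pid, "genome_id": gid, "length": length, **dict(zip(sample_cols, counts.tolist()))})
    counts_df = pd.DataFrame(rows)
    libsizes = counts_df[sample_cols].sum(axis=0).clip(lower=1)
    lib_df = pd.DataFrame({"sample": sample_cols, "library_size": libsizes.to_numpy()})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        counts_df.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
        lib_df.to_csv(out_dir / "library_sizes.tsv", sep="\t", index=False)
    return counts_df, lib_df
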