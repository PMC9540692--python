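# qsweep

Quorum-sensing (QS) gene screening for microbial genome collections.

Dense microbial communities — the rumen, the gut, soil consortia — coordinate
group behaviour through secreted autoinducers. `qsweep` screens a collection
of annotated genomes for the genes behind that communication and asks, for
the universal interspecies signal autoinducer-2 (AI-2), *who talks and who
listens*:

1. **QC filter** — genomes are kept when CheckM-style completeness ≥ 80% and
   contamination ≤ 10% (both boundaries inclusive, both configurable).
2. **Family screen** — product names are matched against a keyword catalog
   covering all 15 known signal families (AHL, AIP, AI-2, AI-3, CAI-1,
   DSF/BDSF, indole, DKP, PQS/HHQ, IQS, PPY, DAR/CHD, CSP, DPO,
   3-OH-PAME/3-OH-MAME), and proteins are scanned with profile HMMs for the
   AI-2 components: the LuxS synthase (PF02664), the LsrB/LuxP periplasmic
   receptors (PF13407) and the dCache_1 sensor domain (PF02743).
3. **CahR classification** — every dCache_1 domain is globally aligned to a
   reference ligand-binding domain (PctA-LBD numbering) and called a
   CahR-type AI-2 receptor iff the five binding-pocket residues R126, W128,
   Y144, D146 and D173 are all conserved. The host protein's
   signal-transduction module is typed from its domain architecture:
   MCP (MCPsignal), HK (HisKA\*, HWE_HK, HATPase_c\*), GCD (GGDEF, EAL,
   HD-GYP), SP (SpoIIE, PP2C\*), STK (Pkinase), AC/GC (guanylate_cyc), or HP
   when no marker is present.
4. **Expression** — featureCounts-style count tables are converted to
   RPKM = count × 10⁹ / (library size × gene length in bp) and summarised per
   gene, genome and taxon.
5. **Prevalence & network** — every AI-2-positive genome is partitioned into
   producer (synthase only), sensor (receptor only) or both, and the
   species–signal–pathway graph is built with the produce (green), sense
   (blue) and produce-and-sense (purple) edge semantics, exportable as
   GraphML/SIF/CSV for Cytoscape.

A first-class synthetic-community generator (`qsweep.synthetic`) produces
proteomes with planted synthases, receptors and single-residue decoys, QC
tables, profile HMMs and negative-binomial count matrices — together with a
ground-truth manifest — so the whole pipeline is testable without any
downloads.

## Worked example

```python
import qsweep
from qsweep.synthetic import generate_community, build_profiles, synthetic_reference
from qsweep.cahr import CahRReference

community = generate_community(n_genomes=12, seed=7)
result = qsweep.analyze_community(
    community.genomes,
    community.proteins,
    build_profiles(),
    CahRReference(sequence=synthetic_reference()),
)
print(result.report["role_partition"])
```

prints

```
{'synthase_only': 3, 'receptor_only': 2, 'both': 2,
 'lsrb_only': 0, 'cahr_only': 2, 'lsrb_and_cahr': 0}
```

i.e. of the 11 genomes passing QC (one of 12 is dropped for low quality), 7
are AI-2-positive: 3 can only produce the signal, 2 can only sense it (both
via CahR-type receptors), and 2 do both. The full `result.report` adds the
component counts (5 LuxS, 1 LsrB, 0 LuxP, 4 CahR genomes here), prevalence
percentages, and the network breakdown (3 green, 2 purple and 11 blue edges
once pathway-class nodes are materialised). `result.cahr_calls` holds the
per-domain residue states behind every verdict.

The same run from a shell:

```bash
qsweep simulate --n-genomes 12 --seed 7 --out sim/
qsweep screen --community-dir sim/ --profiles sim/profiles.hmm --out-dir run/
```

which writes `run/report.json`, `run/cahr_calls.tsv`, `run/network.graphml`
and `run/network.sif`.

For real data, point `qsweep screen` at a directory of per-genome
`.faa`/`.gff3` files plus a `genome_table.tsv`, pass Pfam profile files via
`--profiles`, and supply the real PctA ligand-binding-domain sequence with
`--reference` (the packaged scaffold is synthetic and intended for testing).

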