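"""Genome table loading, the quality filter, and proteome parsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsweep.ingest import (
    GenomeRecord,
    load_genome_table,
    load_proteome,
    qc_filter,
    write_genome_table,
)


def _table(tmp_path, text, name="genomes.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadGenomeTable:
    def test_three_row_identity_load(self, tmp_path):
        path = _table(
            tmp_path,
            "genome_id\tphylum\tgenus\tcompleteness\tcontamination\n"
            "g1\tFirmicutes\tButyrivibrio\t95.5\t1.2\n"
            "g2\tBacteroidetes\tPrevotella\t80\t10\n"
            "g3\tSpirochaetes\tTreponema\t99.9\t0.1\n",
        )
        records = load_genome_table(path)
        assert [r.genome_id for r in records] == ["g1", "g2", "g3"]
        assert records[0].completeness == 95.5
        assert records[1].lineage["genus"] == "Prevotella"

    def test_empty_genus_becomes_unknown(self, tmp_path):
        path = _table(
            tmp_path,
            "genome_id\tgenus\tcompleteness\tcontamination\ng1\t\t90\t2\n",
        )
        (rec,) = load_genome_table(path)
        assert rec.lineage["genus"] == "unknown"
        assert rec.lineage["phylum"] == "unknown"  # absent column too

    def test_write_read_round_trip(self, tmp_path):
        genomes = [
            GenomeRecord("g1", {"phylum": "Firmicutes"}, 91.25, 3.5, source="jgi"),
            GenomeRecord("g2", {}, 80.0, 10.0),
        ]
        out = tmp_path / "rt.tsv"
        write_genome_table(genomes, out)
        back = load_genome_table(out)
        assert [(g.genome_id, g.lineage, g.completeness, g.contamination) for g in genomes] == [
            (g.genome_id, g.lineage, g.completeness, g.contamination) for g in back
        ]

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        path = _table(tmp_path, "genome_id\tcompleteness\ng1\t90\n")
        with pytest.raises(ValueError, match="contamination"):
            load_genome_table(path)

    def test_non_numeric_metric_is_fatal_with_row_id(self, tmp_path):
        path = _table(
            tmp_path,
            "genome_id\tcompleteness\tcontamination\ngX\thigh\t1\n",
        )
        with pytest.raises(ValueError, match="gX"):
            load_genome_table(path)


class TestQCFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (80.0, 10.0, True),  # boundaries are inclusive
            (79.9, 0.0, False),
            (100.0, 10.01, False),
            (95.0, 5.0, True),
        ],
    )
    def test_threshold_boundaries(self, completeness, contamination, kept):
        g = GenomeRecord("g", {}, completeness, contamination)
        kept_list, dropped_list = qc_filter([g])
        assert (g in kept_list) is kept
        assert (g in dropped_list) is not kept

    def test_enumerated_five_genome_example(self):
        metrics = [(95, 1), (80, 10), (79, 0), (100, 11), (85, 5)]
        genomes = [GenomeRecord(f"g{i}", {}, c, x) for i, (c, x) in enumerate(metrics, 1)]
        kept, dropped = qc_filter(genomes)
        assert [g.genome_id for g in kept] == ["g1", "g2", "g5"]
        assert [g.genome_id for g in dropped] == ["g3", "g4"]

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 50, allow_nan=False),
            ),
            max_size=30,
        )
    )
    @settings(deadline=None)
    def test_partition_and_idempotence(self, metrics):
        genomes = [GenomeRecord(f"g{i}", {}, c, x) for i, (c, x) in enumerate(metrics)]
        kept, dropped = qc_filter(genomes)
        assert len(kept) + len(dropped) == len(genomes)
        assert {g.genome_id for g in kept}.isdisjoint(g.genome_id for g in dropped)
        kept2, dropped2 = qc_filter(kept)
        assert kept2 == kept and dropped2 == []


class TestLoadProteome:
    def test_fasta_with_gff_products(self, tmp_path):
        faa = tmp_path / "g.faa"
        faa.write_text(">p1\nmkvl*\n>p2\nACDE\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tx\tCDS\t1\t15\t.\t+\t0\tID=p1;product=S-ribosylhomocysteine lyase\n"
            "c1\tx\tCDS\t20\t31\t.\t+\t0\tID=p2;product=hypothetical protein\n"
        )
        records = load_proteome(faa, gff, genome_id="g")
        assert records[0].sequence == "MKVL"  # upper-cased, stop stripped
        assert records[0].product_name == "S-ribosylhomocysteine lyase"
        assert records[1].genome_id == "g"

    def test_two_column_table_dialect(self, tmp_path):
        faa = tmp_path / "g.faa"
        faa.write_text(">p1\nMK\n")
        tab = tmp_path / "names.tsv"
        tab.write_text("p1\tLuxS\n")
        (rec,) = load_proteome(faa, tab, genome_id="g")
        assert rec.product_name == "LuxS"

    def test_unannotated_entry_warns_and_gets_empty_name(self, tmp_path, caplog):
        faa = tmp_path / "g.faa"
        faa.write_text(">p1\nMK\n>p2\nMV\n")
        tab = tmp_path / "names.tsv"
        tab.write_text("p1\tLuxS\n")
        with caplog.at_level("WARNING"):
            records = load_proteome(faa, tab, genome_id="g")
        assert records[1].product_name == ""
        assert any("p2" in m for m in caplog.messages)

    def test_empty_fasta_is_fatal(self, tmp_path):
        faa = tmp_path / "empty.faa"
        faa.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            load_proteome(faa, None, genome_id="g")

    def test_duplicate_id_is_fatal(self, tmp_path):
        faa = tmp_path / "dup.faa"
        faa.write_text(">p1\nMK\n>p1\nMV\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_proteome(faa, None, genome_id="g")

    def test_synthetic_manifest_ids_round_trip(self, tmp_path, community):
        from qsweep.synthetic import write_community

        write_community(community, tmp_path)
        gid = community.genomes[0].genome_id
        records = load_proteome(
            tmp_path / "genomes" / f"{gid}.faa",
            tmp_path / "genomes" / f"{gid}.gff3",
            genome_id=gid,
        )
        expected = [p.protein_id for p in community.proteins if p.genome_id == gid]
        assert [r.protein_id for r in records] == expected
        by_id = {p.protein_id: p for p in community.proteins}
        assert all(r.product_name == by_id[r.protein_id].product_name for r in records)
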