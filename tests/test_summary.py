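"""Prevalence arithmetic, the AI-2 role partition, rollups and the report."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsweep.ingest import GenomeRecord
from qsweep.summary import (
    RolePartition,
    partition_ai2_roles,
    prevalence,
    read_report,
    summary_report,
    taxon_rollup,
    write_report,
)


def _component_table(rows):
    cols = ("has_luxS", "has_lsrB", "has_luxP", "has_cahR")
    full = {g: {c: bool(r.get(c, False)) for c in cols} for g, r in rows.items()}
    df = pd.DataFrame.from_dict(full, orient="index", dtype=bool).reindex(columns=cols)
    df.index.name = "genome_id"
    return df


class TestPrevalence:
    @pytest.mark.parametrize(
        "n_hit,n_total,decimals,expected",
        [
            (767, 981, 2, 78.19),
            (0, 981, 2, 0.00),
            (680, 981, 2, 69.32),
            (1, 16, 1, 6.3),  # 6.25 rounds half-up, not to even
            (981, 981, 2, 100.00),
        ],
    )
    def test_rounding_half_up(self, n_hit, n_total, decimals, expected):
        assert prevalence(n_hit, n_total, decimals) == expected

    def test_zero_denominator_fatal(self):
        with pytest.raises(ValueError):
            prevalence(1, 0)

    @given(st.integers(1, 500), st.data())
    @settings(deadline=None)
    def test_monotone_in_numerator(self, n_total, data):
        a = data.draw(st.integers(0, n_total))
        b = data.draw(st.integers(a, n_total))
        assert prevalence(a, n_total) <= prevalence(b, n_total)


class TestPartition:
    def test_three_genome_example(self):
        table = _component_table(
            {
                "s": {"has_luxS": True},
                "r": {"has_cahR": True},
                "sr": {"has_luxS": True, "has_cahR": True},
            }
        )
        part = partition_ai2_roles(table)
        assert part.synthase_only == {"s"}
        assert part.receptor_only == {"r"}
        assert part.both == {"sr"}

    def test_receptor_only_breakdown(self):
        table = _component_table(
            {
                "a": {"has_lsrB": True},
                "b": {"has_cahR": True},
                "c": {"has_lsrB": True, "has_cahR": True},
                "d": {"has_luxP": True},  # known PBP receptor counts as LsrB side
            }
        )
        part = partition_ai2_roles(table)
        assert part.lsrb_only == {"a", "d"}
        assert part.cahr_only == {"b"}
        assert part.lsrb_and_cahr == {"c"}

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=3),
            st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
            max_size=20,
        )
    )
    @settings(deadline=None)
    def test_agrees_with_set_arithmetic_oracle(self, flags):
        table = _component_table(
            {
                g: {"has_luxS": s, "has_lsrB": l, "has_luxP": p, "has_cahR": c}
                for g, (s, l, p, c) in flags.items()
            }
        )
        part = partition_ai2_roles(table)
        synthase = {g for g, (s, l, p, c) in flags.items() if s}
        receptor = {g for g, (s, l, p, c) in flags.items() if l or p or c}
        assert part.synthase_only == synthase - receptor
        assert part.receptor_only == receptor - synthase
        assert part.both == synthase & receptor
        # partition sizes always sum to the AI-2-positive total
        assert len(part.positives) == len(synthase | receptor)
        assert (
            len(part.synthase_only) + len(part.receptor_only) + len(part.both)
            == len(part.positives)
        )


class TestTaxonRollup:
    def _genomes(self):
        return [
            GenomeRecord("g1", {"genus": "Prevotella"}, 95, 1),
            GenomeRecord("g2", {"genus": "Prevotella"}, 90, 2),
            GenomeRecord("g3", {}, 85, 3),
        ]

    def test_taxon_counted_once_per_component(self):
        table = _component_table(
            {
                "g1": {"has_luxS": True},
                "g2": {"has_luxS": True},
                "g3": {"has_cahR": True},
            }
        )
        out = taxon_rollup(table, self._genomes(), rank="genus")
        assert out.loc["Prevotella", "n_genomes"] == 2
        assert out.loc["Prevotella", "luxS"] == 2
        assert (out["luxS"] > 0).sum() == 1  # genera carrying luxS

    def test_unknown_genus_grouped_under_unknown(self):
        table = _component_table({"g3": {"has_cahR": True}})
        out = taxon_rollup(table, self._genomes(), rank="genus")
        assert out.loc["unknown", "cahR"] == 1


class TestSummaryReport:
    def test_report_round_trips_through_json(self, tmp_path, pipeline_result):
        out = tmp_path / "report.json"
        write_report(pipeline_result.report, out)
        assert read_report(out) == pipeline_result.report

    def test_report_matches_independent_tallies(self, community, pipeline_result):
        sizes = community.truth.expected_partition_sizes()
        report = pipeline_result.report
        assert report["role_partition"]["synthase_only"] == sizes["synthase_only"]
        assert report["role_partition"]["both"] == sizes["both"]
        expected_table = community.truth.expected_component_table()
        assert report["ai2_components"]["luxS_genomes"] == int(
            expected_table["has_luxS"].sum()
        )
        assert report["genomes"]["kept"] == len(community.truth.kept())

    def test_empty_community_reports_zero_percentages(self, caplog):
        table = _component_table({})
        part = RolePartition()
        with caplog.at_level("WARNING"):
            report = summary_report(
                genomes_kept=[],
                genomes_dropped=[],
                name_calls=[],
                component_table=table,
                partition=part,
            )
        assert report["qs_positive"] == {"n": 0, "pct": 0.0}
        assert any("empty community" in m for m in caplog.messages)
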