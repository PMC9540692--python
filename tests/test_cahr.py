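"""The five-conserved-residue screen, functional typing, and conservation profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsweep.cahr import (
    AA20,
    CLASS_PRECEDENCE,
    FUNCTIONAL_MODULE_MARKERS,
    CahRReference,
    classify_functional_module,
    conservation_profile,
    export_domain_alignment,
    map_reference_positions,
    screen_five_residues,
)
from qsweep.synthetic import mutate, synthetic_reference

CONSERVED = (126, 128, 144, 146, 173)


@pytest.fixture(scope="module")
def ref():
    return CahRReference(sequence=synthetic_reference())


class TestMapReferencePositions:
    def test_identity_maps_each_position_to_itself(self, ref):
        states = map_reference_positions(ref.sequence, ref)
        assert {p: s.candidate_index for p, s in states.items()} == {
            p: p for p in CONSERVED
        }
        assert [states[p].residue for p in CONSERVED] == ["R", "W", "Y", "D", "D"]

    def test_insertion_shifts_mapping_by_three(self, ref):
        candidate = ref.sequence[:50] + "GGG" + ref.sequence[50:]
        states = map_reference_positions(candidate, ref)
        assert {p: s.candidate_index for p, s in states.items()} == {
            p: p + 3 for p in CONSERVED
        }
        assert screen_five_residues(states, ref)

    def test_deleted_conserved_residue_is_unmapped(self, ref):
        candidate = ref.sequence[:172] + ref.sequence[173:]
        states = map_reference_positions(candidate, ref)
        assert not states[173].mapped
        assert not screen_five_residues(states, ref)

    def test_short_fragment_auto_fails(self, ref):
        states = map_reference_positions(ref.sequence[:29], ref)
        assert all(not s.mapped for s in states.values())

    def test_x_at_conserved_position_is_unmapped(self, ref):
        candidate = list(ref.sequence)
        candidate[125] = "X"
        states = map_reference_positions("".join(candidate), ref)
        assert not states[126].mapped

    def test_invalid_letters_are_fatal(self, ref):
        with pytest.raises(ValueError, match="non-amino-acid"):
            map_reference_positions("MK!" + "A" * 40, ref)


class TestScreenFiveResidues:
    def test_all_five_required_residues_pass(self, ref):
        states = map_reference_positions(ref.sequence, ref)
        assert screen_five_residues(states, ref)

    def test_single_mismatch_fails(self, ref):
        candidate = list(ref.sequence)
        candidate[172] = "A"  # D173 -> A
        states = map_reference_positions("".join(candidate), ref)
        assert states[173].residue == "A"
        assert not screen_five_residues(states, ref)

    def test_planted_positives_and_single_position_mutants(self, ref):
        """25 scaffold copies pass; 25 one-conserved-position mutants fail."""
        rng = np.random.default_rng(11)
        passed = failed = 0
        for i in range(25):
            positive = mutate(ref.sequence, 0.08, rng, CONSERVED)
            assert screen_five_residues(map_reference_positions(positive, ref), ref)
            passed += 1
            pos = CONSERVED[i % 5]
            mutant = list(positive)
            required = ref.sequence[pos - 1]
            mutant[pos - 1] = "A" if required != "A" else "G"
            assert not screen_five_residues(
                map_reference_positions("".join(mutant), ref), ref
            )
            failed += 1
        assert (passed, failed) == (25, 25)

    @given(st.data())
    @settings(deadline=None, max_examples=15)
    def test_invariant_to_non_conserved_mutations(self, ref, data):
        """Mutating non-conserved sites of a passing domain never flips the verdict."""
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        candidate = mutate(ref.sequence, 0.10, rng, CONSERVED)
        assert screen_five_residues(map_reference_positions(candidate, ref), ref)


class TestClassifyFunctionalModule:
    @pytest.mark.parametrize(
        "architecture,expected",
        [
            (["dCache_1", "MCPsignal"], "MCP"),
            (["dCache_1"], "HP"),
            (["dCache_1", "HisKA", "HATPase_c", "GGDEF"], "HK"),  # precedence
            (["dCache_1", "EAL"], "GCD"),
            (["dCache_1", "PP2C"], "SP"),
            (["dCache_1", "Pkinase"], "STK"),
            (["dCache_1", "guanylate_cyc"], "ACGC"),
            (["dCache_1", "MCPsignal", "HisKA"], "MCP"),
        ],
    )
    def test_marker_classes_and_precedence(self, architecture, expected):
        assert classify_functional_module(architecture) == expected

    @given(
        st.lists(
            st.sampled_from(
                sorted(set().union(*FUNCTIONAL_MODULE_MARKERS.values()))
                + ["dCache_1", "PAS", "unknown_domain"]
            ),
            max_size=6,
        )
    )
    def test_total_function(self, architecture):
        cls = classify_functional_module(["dCache_1"] + architecture)
        assert cls in CLASS_PRECEDENCE + ("HP",)


class TestConservationProfile:
    def test_identical_sequences_give_unit_columns(self, ref):
        prof = conservation_profile([ref.sequence] * 3, ref)
        assert prof.n_sequences == 3
        assert (prof.frequencies.max(axis=1) == 1.0).all()
        np.testing.assert_allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_required_residues_fully_conserved_over_passing_set(self, ref):
        rng = np.random.default_rng(5)
        domains = [mutate(ref.sequence, 0.1, rng, CONSERVED) for _ in range(8)]
        prof = conservation_profile(domains, ref)
        for pos, residue in ref.conserved_positions:
            assert prof.frequencies.loc[pos, residue] == 1.0

    def test_planted_composition_at_one_column(self, ref):
        # 10 domains, column 200 planted as 6x K and 4x E
        domains = []
        for i in range(10):
            seq = list(ref.sequence)
            seq[199] = "K" if i < 6 else "E"
            domains.append("".join(seq))
        prof = conservation_profile(domains, ref)
        assert prof.frequencies.loc[200, "K"] == pytest.approx(0.6)
        assert prof.frequencies.loc[200, "E"] == pytest.approx(0.4)

    def test_empty_input_is_fatal(self, ref):
        with pytest.raises(ValueError):
            conservation_profile([], ref)


class TestExportDomainAlignment:
    def _read_fasta(self, path):
        entries = {}
        current = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                current = line[1:]
                entries[current] = ""
            else:
                entries[current] += line
        return entries

    def test_identical_sequences_align_gap_free(self, ref, tmp_path):
        out = tmp_path / "aln.fasta"
        export_domain_alignment(
            {"a": ref.sequence, "b": ref.sequence}, ref, out
        )
        entries = self._read_fasta(out)
        assert set(entries) == {"PctA-LBD", "a", "b"}
        assert all("-" not in seq for seq in entries.values())

    def test_insertion_mutant_gaps_the_reference_row(self, ref, tmp_path):
        mutant = ref.sequence[:50] + "GGG" + ref.sequence[50:]
        out = tmp_path / "aln.fasta"
        export_domain_alignment({"ref2": ref.sequence, "ins": mutant}, ref, out)
        entries = self._read_fasta(out)
        assert entries["PctA-LBD"].count("-") == 3
        assert entries["ins"].count("-") == 0
        lengths = {len(s) for s in entries.values()}
        assert len(lengths) == 1  # rectangular alignment

    def test_round_trip_recovers_sequences(self, ref, tmp_path):
        rng = np.random.default_rng(9)
        domains = {
            f"d{i}": mutate(ref.sequence, 0.1, rng, CONSERVED) for i in range(3)
        }
        out = tmp_path / "aln.fasta"
        export_domain_alignment(domains, ref, out)
        entries = self._read_fasta(out)
        for name, seq in domains.items():
            assert entries[name].replace("-", "") == seq

    def test_single_sequence_is_rejected(self, ref, tmp_path):
        with pytest.raises(ValueError):
            export_domain_alignment({"a": ref.sequence}, ref, tmp_path / "x.fasta")
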