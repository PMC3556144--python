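"""Identity statistics, consensus, signature discovery/classification,
coding consequences, and protein utilities."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralogsift.alignment_signature import (
    UNCLASSIFIED,
    MultipleAlignment,
    SignatureScheme,
    align_pair,
    call_consensus,
    classify_by_signature,
    compare_proteins,
    detect_premature_stop,
    discover_signature,
    isoelectric_point,
    net_charge,
    pairwise_identity,
    translate_cdna,
    variant_prevalence,
)
from tests.conftest import read_with_signature


class TestPairwiseIdentity:
    def test_identical_rows(self):
        res = pairwise_identity(MultipleAlignment({"x": "ACGT", "y": "ACGT"}))
        assert res["per_pair"][("x", "y")] == 100.0
        assert res["identical_sites"] == 4
        assert res["identical_sites_pct"] == 100.0

    def test_three_row_toy_counts(self):
        # brute-force column count: columns 1 (A/A/A) and 3 (G/G/G) are
        # monomorphic; x vs y match at 3 of 4 columns
        res = pairwise_identity(
            MultipleAlignment({"x": "ACGT", "y": "ACGA", "z": "AGGT"})
        )
        assert res["identical_sites"] == 2
        assert res["identical_sites_pct"] == 50.0
        assert res["per_pair"][("x", "y")] == 75.0

    def test_gapped_columns_excluded_from_pair(self):
        res = pairwise_identity(MultipleAlignment({"x": "AC-T", "y": "ACGT"}))
        assert res["per_pair"][("x", "y")] == 100.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity(MultipleAlignment({"x": "ACGT"}))


class TestCallConsensus:
    def test_identical_replicates(self):
        assert call_consensus(["ACGT"] * 4) == "ACGT"

    def test_even_split_gives_ambiguity_code(self):
        # 2xC + 2xA at threshold 0.75 -> M (IUPAC A/C)
        assert call_consensus(["C", "C", "A", "A"]) == "M"

    def test_three_quarters_majority_called_outright(self):
        assert call_consensus(["A", "A", "A", "G"]) == "A"

    def test_permutation_invariance(self):
        reps = ["ACGT", "ACGA", "ACGT", "TCGT"]
        for perm in itertools.permutations(reps):
            assert call_consensus(list(perm)) == call_consensus(reps)

    def test_conflicting_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            call_consensus(["ACGT", "ACG"])


def _brute_force_signature(aln: MultipleAlignment, max_columns: int):
    """Oracle: first valid subset over ALL columns by (size, lexicographic)."""
    from paralogsift.alignment_signature import expand_iupac

    ids = list(aln.rows)
    table = {
        cid: [frozenset() if c == "-" else expand_iupac(c) for c in aln.rows[cid]]
        for cid in ids
    }
    for size in range(1, max_columns + 1):
        for combo in itertools.combinations(range(aln.length), size):
            ok = all(
                any(table[a][j].isdisjoint(table[b][j]) and (table[a][j] or table[b][j])
                    for j in combo)
                for a, b in itertools.combinations(ids, 2)
            )
            if ok:
                return [j + 1 for j in combo]
    return None


class TestDiscoverSignature:
    def test_three_copy_toy(self):
        aln = MultipleAlignment({"X": "ACGT", "Y": "ACGA", "Z": "AGGT"})
        assert discover_signature(aln).columns == [2, 4]

    def test_two_copies_single_difference(self):
        aln = MultipleAlignment({"a": "ACGT", "b": "AGGT"})
        assert discover_signature(aln).columns == [2]

    def test_indistinguishable_copies_raise(self):
        with pytest.raises(ValueError, match="no diagnostic"):
            discover_signature(MultipleAlignment({"a": "ACGT", "b": "ACGT"}))

    def test_matches_exhaustive_search_on_random_alignments(self):
        rng = random.Random(17)
        for _ in range(30):
            n_cols = rng.randint(4, 12)
            rows = {}
            for cid in "abc":
                rows[cid] = "".join(rng.choice("ACGT") for _ in range(n_cols))
            aln = MultipleAlignment(rows)
            oracle = _brute_force_signature(aln, 4)
            if oracle is None:
                with pytest.raises(ValueError):
                    discover_signature(aln, max_columns=4)
            else:
                assert discover_signature(aln, max_columns=4).columns == oracle

    def test_discovered_scheme_separates_every_pair(self, family):
        aln = MultipleAlignment(family.cdnas)
        scheme = discover_signature(aln)
        for a, b in itertools.combinations(scheme.alleles, 2):
            assert any(
                sa.isdisjoint(sb)
                for sa, sb in zip(scheme.alleles[a], scheme.alleles[b])
            )

    def test_polymorphic_signature_base_kept_as_allele_set(self):
        # an M (A/C) in one copy expands to {A, C} in its allele set
        aln = MultipleAlignment({"p": "MCGT", "q": "GCGT"})
        scheme = discover_signature(aln)
        assert scheme.alleles["p"][0] == frozenset("AC")


class TestClassifyBySignature:
    @pytest.mark.parametrize(
        "observed, expected",
        [("AAA", "SCGB1A1"), ("AGG", "SCGB1A1A"), ("CGA", "SCGB1A1P")],
    )
    def test_study_worked_examples(self, study_scheme, observed, expected):
        read = read_with_signature(observed)
        res = classify_by_signature(read, study_scheme)
        assert res.copy_id == expected
        assert res.mismatches == 0

    def test_no_copy_matches_is_unclassified(self, study_scheme):
        res = classify_by_signature(read_with_signature("GGG"), study_scheme)
        assert res.copy_id == UNCLASSIFIED

    def test_tie_is_unclassified_even_within_tolerance(self):
        scheme = SignatureScheme(
            columns=[1, 2],
            alleles={"a": (frozenset("A"), frozenset("C")),
                     "b": (frozenset("G"), frozenset("T"))},
        )
        # read 'AT' matches one column of each copy: tie at 1 mismatch
        res = classify_by_signature("AT", scheme, tolerance=1)
        assert res.copy_id == UNCLASSIFIED

    def test_offset_maps_cdna_to_read_coordinates(self, study_scheme):
        read = read_with_signature("AGG")[100:]  # read starts at cDNA pos 101
        res = classify_by_signature(read, study_scheme, offset=100)
        assert res.copy_id == "SCGB1A1A"

    def test_column_outside_read_raises(self, study_scheme):
        with pytest.raises(ValueError, match="outside read"):
            classify_by_signature("ACGT", study_scheme)

    def test_tolerance_allows_sequencing_error(self, study_scheme):
        read = read_with_signature("TGG")  # one error at the first column
        assert classify_by_signature(read, study_scheme).copy_id == UNCLASSIFIED
        res = classify_by_signature(read, study_scheme, tolerance=1)
        assert res.copy_id == "SCGB1A1A"
        assert res.mismatches == 1


class TestSignatureScheme:
    def test_non_discriminating_scheme_rejected(self):
        with pytest.raises(ValueError, match="discriminate"):
            SignatureScheme(
                columns=[1],
                alleles={"a": (frozenset("AC"),), "b": (frozenset("A"),)},
            )

    def test_json_round_trip(self, tmp_path, study_scheme):
        p = tmp_path / "scheme.json"
        study_scheme.to_json(p)
        back = SignatureScheme.from_json(p)
        assert back.columns == study_scheme.columns
        assert back.alleles == study_scheme.alleles


class TestCodingConsequences:
    def test_stop_gained_at_codon_boundary(self):
        # A->T at cDNA position 220 turns the AAG (Lys) codon into TAG (stop)
        ref = "ATG" + "GCT" * 72 + "AAG" + "GCT" * 3
        var = ref[:219] + "T" + ref[220:]
        (cons,) = detect_premature_stop(ref, var)
        assert cons.cdna_position == 220
        assert (cons.ref_codon, cons.alt_codon) == ("AAG", "TAG")
        assert cons.kind == "stop_gained"

    def test_tta_ctc_is_synonymous_leucine(self):
        ref = "ATG" + "GCT" * 76 + "TTA"
        var = ref[:-3] + "CTC"
        (cons,) = detect_premature_stop(ref, var)
        assert cons.kind == "synonymous"
        assert cons.ref_aa == cons.alt_aa == "L"

    def test_identical_sequences_no_consequences(self):
        seq = "ATGAAACCCGGG"
        assert detect_premature_stop(seq, seq) == []

    def test_missense_and_stop_lost(self):
        ref = "ATGTAG"
        var = "ATGCAG"
        (cons,) = detect_premature_stop(ref, var)
        assert cons.kind == "stop_lost"
        assert detect_premature_stop("ATGAAA", "ATGGAA")[0].kind == "missense"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_premature_stop("ATGAAA", "ATGAAATTT")

    def test_translation_helper(self):
        assert translate_cdna("ATGAAACTCGCC") == "MKLA"


class TestCompareProteins:
    def test_identical(self):
        assert compare_proteins("MKLA", "MKLA") == (0, [])

    def test_all_positions_differ(self):
        n, subs = compare_proteins("FAIGF", "LVVAY")
        assert n == 5
        assert subs == [(1, "F", "L"), (2, "A", "V"), (3, "I", "V"),
                        (4, "G", "A"), (5, "F", "Y")]

    def test_single_difference_position(self):
        n, subs = compare_proteins("MKLA", "MKVA")
        assert n == 1 and subs == [(3, "L", "V")]

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            compare_proteins("MK", "MKL")


def test_variant_prevalence_rounds_to_integer_percent():
    frac, pct = variant_prevalence(13, 24)
    assert pct == 54
    assert frac == pytest.approx(13 / 24)
    with pytest.raises(ValueError):
        variant_prevalence(5, 0)


class TestIsoelectricPoint:
    @staticmethod
    def _grid_pi(prot: str, pka_set: str = "emboss") -> float:
        grid = [i / 1000 for i in range(0, 14001)]
        return min(grid, key=lambda ph: abs(net_charge(prot, ph, pka_set)))

    def test_agrees_with_grid_oracle_on_random_peptides(self):
        rng = random.Random(3)
        for _ in range(100):
            pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 30)))
            assert abs(isoelectric_point(pep) - self._grid_pi(pep)) <= 0.01

    def test_no_ionizable_side_chains_matches_oracle(self):
        assert abs(isoelectric_point("GGG") - self._grid_pi("GGG")) <= 0.01

    def test_basic_peptide_above_acidic_peptide(self):
        assert isoelectric_point("K") > isoelectric_point("D")

    def test_adding_acidic_residue_never_raises_pi(self):
        rng = random.Random(9)
        for _ in range(20):
            pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(10))
            assert isoelectric_point(pep + "D") <= isoelectric_point(pep) + 1e-9

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            isoelectric_point("MKX")

    def test_alternative_pka_set_selectable(self):
        assert isoelectric_point("MKLA", pka_set="sillero") > 0
        with pytest.raises(ValueError):
            isoelectric_point("MKLA", pka_set="nope")


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet="ACGT", min_size=5, max_size=40),
       st.text(alphabet="ACGT", min_size=5, max_size=40))
def test_align_pair_rows_equal_length_and_degap_to_inputs(a, b):
    ra, rb = align_pair(a, b)
    assert len(ra) == len(rb)
    assert ra.replace("-", "") == a
    assert rb.replace("-", "") == b
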