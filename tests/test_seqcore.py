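"""Sequence model: translation, mutation application/classification, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydsel.seqcore import (
    AMINO_ACIDS,
    CLASS_ORDER,
    CODON_TABLE,
    Category,
    Charge,
    ChargeChangeClass,
    ChargeScheme,
    CodingSequence,
    PointMutation,
    ValidationError,
    VariantRecord,
    apply_mutations,
    classify_mutation,
    classify_variant,
    count_charge_changes,
    read_fasta,
    read_variant_table,
    single_mutation_code_table,
    write_fasta,
    write_variant_table,
)

# Independent oracle: the standard genetic code, all 64 codons, hard-coded.
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def cds_strategy(max_codons=40):
    return st.integers(2, max_codons).flatmap(
        lambda n: st.text(alphabet="ACGT", min_size=3 * n, max_size=3 * n)
    ).map(lambda nt: CodingSequence(id="rand", nt=nt))


class TestCodingSequence:
    def test_translation_agrees_with_codon_table_oracle_on_all_64_codons(self):
        assert len(STANDARD_CODE) == 64
        for codon, aa in STANDARD_CODE.items():
            assert CODON_TABLE[codon] == aa
            assert CodingSequence(id="c", nt=codon).translate() == aa

    @pytest.mark.parametrize(
        "nt", ["ATGAA", "AT", "", "ATGNAA", "atgaaa "]
    )
    def test_invalid_sequences_rejected(self, nt):
        with pytest.raises(ValidationError):
            CodingSequence(id="bad", nt=nt)

    def test_protein_strips_single_terminal_stop(self):
        assert CodingSequence(id="c", nt="ATGAAATAA").protein == "MK"
        assert CodingSequence(id="c", nt="ATGAAA").protein == "MK"


class TestFastaIO:
    def test_single_record_read(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">g1 a gene\nATGAAATAA\n")
        (rec,) = read_fasta(p)
        assert rec.id == "g1" and rec.nt == "ATGAAATAA"

    def test_ambiguity_codes_rejected_with_position(self, tmp_path):
        p = tmp_path / "n.fasta"
        p.write_text(">g1\nATGNAATAA\n")
        with pytest.raises(ValidationError, match="g1.*position 4"):
            read_fasta(p)

    @settings(max_examples=25, derandomize=True)
    @given(seqs=st.lists(cds_strategy(), min_size=1, max_size=4),
           wrap=st.sampled_from([10, 60, 80]))
    def test_round_trip_is_identical(self, seqs, wrap, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fasta")
        seqs = [
            CodingSequence(id=f"s{i}", nt=s.nt) for i, s in enumerate(seqs)
        ]
        p = tmp / "roundtrip.fasta"
        write_fasta(seqs, p, wrap=wrap)
        back = read_fasta(p)
        assert [(s.id, s.nt) for s in back] == [(s.id, s.nt) for s in seqs]


class TestApplyMutations:
    def test_empty_mutation_list_is_identity(self, toy_cds):
        assert apply_mutations(toy_cds, []).nt == toy_cds.nt

    def test_direct_substitution(self):
        seq = CodingSequence(id="s", nt="ATGAAA")
        out = apply_mutations(seq, [PointMutation(4, "A", "T")])
        assert out.nt == "ATGTAA"

    def test_ref_mismatch_names_position(self, toy_cds):
        with pytest.raises(ValidationError, match="position 1"):
            apply_mutations(toy_cds, [PointMutation(1, "C", "G")])

    def test_duplicate_positions_rejected(self, toy_cds):
        muts = [PointMutation(4, "A", "C"), PointMutation(4, "A", "G")]
        with pytest.raises(ValidationError, match="duplicate"):
            apply_mutations(toy_cds, muts)

    @settings(max_examples=50, derandomize=True)
    @given(data=st.data(), seq=cds_strategy())
    def test_hamming_distance_equals_mutation_count_and_involution(self, data, seq):
        k = data.draw(st.integers(0, min(8, len(seq.nt))))
        positions = data.draw(
            st.lists(
                st.integers(1, len(seq.nt)), min_size=k, max_size=k, unique=True
            )
        )
        muts = []
        for p in positions:
            ref = seq.nt[p - 1]
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
            muts.append(PointMutation(p, ref, alt))
        out = apply_mutations(seq, muts)
        hamming = sum(a != b for a, b in zip(seq.nt, out.nt))
        assert hamming == len(muts)
        back = apply_mutations(
            out, [PointMutation(m.position, m.alt_base, m.ref_base) for m in muts]
        )
        assert back.nt == seq.nt


class TestChargeScheme:
    def test_default_partitions_twenty_residues(self, scheme):
        assert scheme.positive == frozenset("KR")
        assert scheme.negative == frozenset("DE")
        assert "H" in scheme.neutral
        assert scheme.charge_of("*") is None

    def test_histidine_configurable(self):
        s = ChargeScheme.default(histidine_positive=True)
        assert s.charge_of("H") is Charge.POS

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValidationError):
            ChargeScheme(frozenset("KRH"), frozenset("DE"),
                         frozenset(set(AMINO_ACIDS) - set("KRDE")))

    def test_exactly_nine_classes(self):
        assert len(CLASS_ORDER) == len(set(CLASS_ORDER)) == 9


class TestClassifyMutation:
    # codon AAA (K) mutated four ways at a Lys codon starting at nt 1
    @pytest.mark.parametrize(
        "mut, category, alt_aa, charge",
        [
            (PointMutation(3, "A", "G"), Category.SILENT, "K", None),       # AAG
            (PointMutation(3, "A", "T"), Category.MISSENSE, "N", "POS->NEU"),  # AAT
            (PointMutation(2, "A", "G"), Category.MISSENSE, "R", "POS->POS"),  # AGA
            (PointMutation(1, "A", "T"), Category.NONSENSE, "*", None),     # TAA
        ],
    )
    def test_lysine_codon_fates(self, scheme, mut, category, alt_aa, charge):
        seq = CodingSequence(id="s", nt="AAACCCTAA")
        ch = classify_mutation(seq, mut, scheme)
        assert ch.category is category
        assert ch.alt_aa == alt_aa
        if charge is None:
            assert ch.charge_class is None
        else:
            assert ch.charge_class == ChargeChangeClass.from_label(charge)

    def test_stop_loss_is_missense_without_class(self, scheme):
        seq = CodingSequence(id="s", nt="ATGTAA")
        ch = classify_mutation(seq, PointMutation(5, "A", "T"), scheme)  # TAA->TTA (L)
        assert ch.ref_aa == "*" and ch.category is Category.MISSENSE
        assert ch.charge_class is None

    def test_code_table_matches_per_mutation_classification(self, toy_cds, scheme):
        table = single_mutation_code_table(toy_cds, scheme)
        for p in range(1, len(toy_cds) + 1):
            ref = toy_cds.nt[p - 1]
            for b in "ACGT":
                if b == ref:
                    assert table[p - 1, "ACGT".index(b)] == 255
                    continue
                ch = classify_mutation(toy_cds, PointMutation(p, ref, b), scheme)
                assert table[p - 1, "ACGT".index(b)] == ch.code


class TestCountChargeChanges:
    def test_empty_variant_list_all_zero(self, toy_cds, scheme):
        counts = count_charge_changes([], toy_cds, scheme)
        assert counts.total == 0 and all(v == 0 for v in counts.classes.values())

    def test_three_example_mutations_tally(self, scheme):
        seq = CodingSequence(id="s", nt="AAACCCAAATAA")
        var = VariantRecord(
            variant_id="v1",
            parent_id="s",
            mutations=(
                PointMutation(3, "A", "T"),  # AAA->AAT  K->N
                PointMutation(6, "C", "A"),  # CCC->CCA  silent (P)
                PointMutation(7, "A", "T"),  # AAA->TAA  nonsense
            ),
        )
        counts = count_charge_changes([var], seq, scheme)
        assert counts.classes[ChargeChangeClass.from_label("POS->NEU")] == 1
        assert counts.nonsense == 1 and counts.silent == 1
        assert counts.total == 3

    def test_wrong_parent_rejected(self, toy_cds, scheme):
        var = VariantRecord(variant_id="v", parent_id="other", mutations=())
        with pytest.raises(ValidationError, match="other"):
            count_charge_changes([var], toy_cds, scheme)

    @settings(max_examples=30, derandomize=True)
    @given(data=st.data(), seq=cds_strategy(max_codons=20))
    def test_conservation_class_counts_sum_to_total(self, data, seq):
        k = data.draw(st.integers(0, min(6, len(seq.nt))))
        positions = data.draw(
            st.lists(st.integers(1, len(seq.nt)), min_size=k, max_size=k, unique=True)
        )
        muts = tuple(
            PointMutation(
                p, seq.nt[p - 1],
                data.draw(st.sampled_from([b for b in "ACGT" if b != seq.nt[p - 1]])),
            )
            for p in positions
        )
        var = VariantRecord(variant_id="v", parent_id=seq.id, mutations=muts)
        counts = count_charge_changes([var], seq)
        assert counts.total == len(muts)

    def test_same_codon_double_mutation_uses_joint_translation(self, scheme):
        # AAA with A2G and A3G jointly -> AGG (Arg): both mutations POS->POS,
        # though A3G alone would be silent (AAG is still Lys)
        seq = CodingSequence(id="s", nt="AAATAA")
        muts = (PointMutation(2, "A", "G"), PointMutation(3, "A", "G"))
        changes = classify_variant(seq, muts, scheme)
        assert all(ch.alt_aa == "R" for ch in changes)
        assert all(
            ch.charge_class == ChargeChangeClass.from_label("POS->POS")
            for ch in changes
        )


class TestVariantTable:
    def test_round_trip(self, tmp_path, summary):
        p = tmp_path / "variants.tsv"
        write_variant_table(summary.variants, p)
        back = read_variant_table(p)
        assert back == summary.variants

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("variant_id\tparent_id\nv1\tp1\n")
        with pytest.raises(ValidationError, match="missing columns"):
            read_variant_table(p)
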