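import random

import pytest

from mirscreen import genome_io
from mirscreen.genome_io import (
    ExonRecord,
    IntronCandidate,
    attach_sequence,
    derive_introns,
    filter_by_length,
    read_exons_gff3,
    read_genome,
)
from mirscreen.synthetic_data import write_gff3


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestReadGenome:
    def test_case_and_u_normalisation(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("s", "acgu")])
        g = read_genome(p)
        assert g["s"].residues == "ACGT"
        assert g["s"].length == 4

    def test_empty_file_gives_empty_genome(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        assert read_genome(p) == {}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("s", "ACGT"), ("s", "TTTT")])
        with pytest.raises(ValueError, match="duplicate"):
            read_genome(p)

    def test_non_iupac_character_names_record(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("bad_rec", "ACXT")])
        with pytest.raises(ValueError, match="bad_rec"):
            read_genome(p)

    def test_ambiguity_codes_collapse_to_n(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("s", "ARYT")])
        assert read_genome(p)["s"].residues == "ANNT"


class TestDeriveIntrons:
    def test_single_exon_transcript_has_no_introns(self):
        assert derive_introns([ExonRecord("s", 1, 100, "+", "t1")]) == []

    def test_gap_arithmetic(self):
        exons = [
            ExonRecord("s", 1, 100, "+", "t1"),
            ExonRecord("s", 151, 200, "+", "t1"),
        ]
        (intron,) = derive_introns(exons)
        assert (intron.start, intron.end, intron.length) == (101, 150, 50)
        assert intron.donor_pos == 101 and intron.acceptor_pos == 150

    def test_minus_strand_donor_acceptor(self):
        exons = [
            ExonRecord("s", 1, 100, "-", "t1"),
            ExonRecord("s", 151, 200, "-", "t1"),
        ]
        (intron,) = derive_introns(exons)
        assert intron.donor_pos == 150 and intron.acceptor_pos == 101

    def test_isoform_duplicates_collapse(self):
        exons = [
            ExonRecord("s", 1, 100, "+", "t1"),
            ExonRecord("s", 151, 200, "+", "t1"),
            ExonRecord("s", 1, 100, "+", "t2"),
            ExonRecord("s", 151, 200, "+", "t2"),
        ]
        assert len(derive_introns(exons)) == 1

    def test_zero_gap_emits_no_intron(self):
        exons = [
            ExonRecord("s", 1, 100, "+", "t1"),
            ExonRecord("s", 101, 200, "+", "t1"),
        ]
        assert derive_introns(exons) == []

    def test_overlapping_exons_rejected(self):
        exons = [
            ExonRecord("s", 1, 100, "+", "t1"),
            ExonRecord("s", 90, 200, "+", "t1"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            derive_introns(exons)

    def test_order_invariance_and_span_conservation(self):
        rng = random.Random(0)
        for _ in range(20):
            pos, exons = 1, []
            for i in range(rng.randint(2, 6)):
                elen = rng.randint(10, 50)
                exons.append(ExonRecord("s", pos, pos + elen - 1, "+", "t"))
                pos += elen + rng.randint(1, 80)
            shuffled = exons[:]
            rng.shuffle(shuffled)
            introns = derive_introns(exons)
            assert introns == derive_introns(shuffled)
            span = exons[-1].end - exons[0].start + 1
            total = sum(e.end - e.start + 1 for e in exons) + sum(
                i.length for i in introns
            )
            assert total == span


class TestAttachSequence:
    GENOME = {"s": genome_io.GenomeSequence("s", "GTAAGTACCT")}

    def test_plus_strand_is_rna_slice(self):
        intron = IntronCandidate("s", 1, 6, "+")
        assert attach_sequence(intron, self.GENOME).sequence == "GUAAGU"

    def test_minus_strand_reverse_complement(self):
        intron = IntronCandidate("s", 7, 10, "-")
        assert attach_sequence(intron, self.GENOME).sequence == "AGGU"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            attach_sequence(IntronCandidate("s", 5, 11, "+"), self.GENOME)

    def test_idempotent(self):
        intron = IntronCandidate("s", 1, 6, "+")
        once = attach_sequence(intron, self.GENOME)
        assert attach_sequence(once, self.GENOME) == once


class TestFilterByLength:
    INTRONS = [IntronCandidate("s", 1, n, "+") for n in (49, 50, 120, 121)]

    def test_core_window_bounds_inclusive(self):
        kept = filter_by_length(self.INTRONS, 50, 120)
        assert sorted(i.length for i in kept) == [50, 120]

    def test_extension_window_disjoint(self):
        kept = filter_by_length(self.INTRONS, 121, 150)
        assert [i.length for i in kept] == [121]

    def test_empty_input(self):
        assert filter_by_length([], 50, 120) == []

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_length(self.INTRONS, 120, 50)


def test_gff3_roundtrip(tmp_path):
    exons = [
        ExonRecord("s1", 1, 100, "+", "tx1"),
        ExonRecord("s1", 161, 260, "+", "tx1"),
        ExonRecord("s2", 11, 60, "-", "tx2"),
        ExonRecord("s2", 101, 180, "-", "tx2"),
    ]
    p = tmp_path / "a.gff3"
    write_gff3(exons, p)
    assert set(read_exons_gff3(p)) == set(exons)


def test_bed_export_is_zero_based_half_open(tmp_path):
    p = tmp_path / "i.bed"
    genome_io.write_intron_bed([IntronCandidate("s", 101, 150, "-")], p)
    assert p.read_text() == "s\t100\t150\ts:101-150(-)\t0\t-\n"
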