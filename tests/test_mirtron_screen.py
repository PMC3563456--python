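import pytest

from mirscreen.genome_io import IntronCandidate
from mirscreen.hairpin import HairpinFeatures
from mirscreen.mirtron_screen import (
    MirtronCandidate,
    SpliceSignature,
    StructureScoreParams,
    count_splice_reads,
    rank_candidates,
    score_mirtron_structure,
    screen_introns,
)
from mirscreen.read_mapper import ReadAlignment


def features(**kw):
    base = dict(
        stem_len=0, loop_len=0, paired_fraction=0.0, overhang5=0, overhang3=0,
        n_bulges=0, gu_fraction=0.0,
    )
    base.update(kw)
    return HairpinFeatures(**base)


class TestStructureScore:
    def test_pairless_floor(self):
        f = features(overhang5=50, overhang3=50)
        assert score_mirtron_structure(f) < 0.05

    def test_ideal_hairpin_scores_high(self):
        f = features(
            stem_len=30, loop_len=6, paired_fraction=60 / 68, overhang3=2
        )
        assert score_mirtron_structure(f) > 0.9

    def test_monotone_in_stem_length(self):
        lo = features(stem_len=10, loop_len=8, paired_fraction=0.5)
        hi = features(stem_len=20, loop_len=8, paired_fraction=0.5)
        assert score_mirtron_structure(hi) > score_mirtron_structure(lo)

    def test_monotone_in_paired_fraction(self):
        lo = features(stem_len=15, loop_len=8, paired_fraction=0.4)
        hi = features(stem_len=15, loop_len=8, paired_fraction=0.8)
        assert score_mirtron_structure(hi) > score_mirtron_structure(lo)

    def test_bulges_penalised(self):
        clean = features(stem_len=20, loop_len=8, paired_fraction=0.8)
        bulged = features(stem_len=20, loop_len=8, paired_fraction=0.8, n_bulges=4)
        assert score_mirtron_structure(bulged) < score_mirtron_structure(clean)

    def test_bounded(self):
        for f in (features(), features(stem_len=100, paired_fraction=1.0, loop_len=8)):
            assert 0.0 <= score_mirtron_structure(f) <= 1.0


class TestSpliceCounting:
    INTRON = IntronCandidate("s", 101, 192, "+")  # donor 101, acceptor 192

    def aln(self, start, length=22, strand="+", count=1, seq=None):
        return ReadAlignment(seq or "A" * length, "s", start, strand, 0, count)

    def test_no_nearby_reads(self):
        sig = count_splice_reads(self.INTRON, [self.aln(500)])
        assert (sig.n5, sig.n3) == (0, 0)

    def test_read_at_donor(self):
        sig = count_splice_reads(self.INTRON, [self.aln(101)])
        assert (sig.n5, sig.n3) == (1, 0)

    def test_wrong_orientation_ignored(self):
        sig = count_splice_reads(self.INTRON, [self.aln(101, strand="-")])
        assert (sig.n5, sig.n3) == (0, 0)

    def test_buffer_is_three_nt(self):
        inside = count_splice_reads(self.INTRON, [self.aln(104)])
        outside = count_splice_reads(self.INTRON, [self.aln(105)])
        assert inside.n5 == 1 and outside.n5 == 0

    def test_three_prime_end_anchors_acceptor(self):
        # read 3' end at 192 = acceptor
        sig = count_splice_reads(self.INTRON, [self.aln(171, length=22)])
        assert (sig.n5, sig.n3) == (0, 1)

    def test_minus_strand_intron_uses_transcript_ends(self):
        intron = IntronCandidate("s", 101, 192, "-")  # donor 192, acceptor 101
        # '-' read with genomic end 192 -> transcript 5' end at donor
        sig = count_splice_reads(intron, [self.aln(171, length=22, strand="-")])
        assert (sig.n5, sig.n3) == (1, 0)

    def test_counts_sum_multiplicities_and_unique(self):
        reads = [
            self.aln(101, count=6),
            self.aln(100, count=2, seq="C" * 22),
        ]
        sig = count_splice_reads(self.INTRON, reads)
        assert sig.n5 == 8 and sig.distinct5 == 2 and sig.unique5 == 8

    def test_multimapper_excluded_from_unique(self):
        reads = [
            self.aln(101, count=3),
            ReadAlignment("A" * 22, "s", 400, "+", 1, 3),  # same seq elsewhere
        ]
        sig = count_splice_reads(self.INTRON, reads)
        assert sig.n5 == 3 and sig.unique5 == 0


class TestRankings:
    def cand(self, seq_id, start, score, total):
        intron = IntronCandidate(seq_id, start, start + 91, "+")
        return MirtronCandidate(
            intron, None, None, score, SpliceSignature(n5=total)
        )

    def test_structure_ranking(self):
        cands = [self.cand("s", 1, 0.9, 0), self.cand("s", 200, 0.5, 0)]
        rank_candidates(cands)
        assert [c.rank_structure for c in cands] == [1, 2]

    def test_combined_tie_broken_by_coordinate(self):
        a = self.cand("s", 1, 0.9, 0)
        b = self.cand("s", 200, 0.5, 10)
        rank_candidates([a, b])
        # both sum to 3; 'a' has the earlier coordinate
        assert a.rank_combined == 1 and b.rank_combined == 2

    def test_single_candidate_all_ranks_one(self):
        (c,) = rank_candidates([self.cand("s", 1, 0.5, 2)])
        assert (c.rank_structure, c.rank_reads, c.rank_combined) == (1, 1, 1)

    def test_rankings_are_permutations(self):
        cands = [
            self.cand("s", 100 * i + 1, score, total)
            for i, (score, total) in enumerate(
                [(0.9, 0), (0.9, 5), (0.2, 5), (0.2, 0), (0.5, 1)]
            )
        ]
        rank_candidates(cands)
        n = len(cands)
        for attr in ("rank_structure", "rank_reads", "rank_combined"):
            assert sorted(getattr(c, attr) for c in cands) == list(range(1, n + 1))


class TestScreenWindows:
    def _intron(self, length, start=1000):
        seq = ("GC" * 40 + "AAAAAA" + "GC" * 40)[:length]
        return IntronCandidate("s", start, start + length - 1, "+", sequence=seq.replace("T", "U"))

    def test_window_membership(self):
        introns = [self._intron(92), self._intron(130, start=3000)]
        core = screen_introns(introns, [])
        ext = screen_introns(introns, [], bounds=(121, 150))
        assert [c.intron.length for c in core] == [92]
        assert [c.intron.length for c in ext] == [130]

    def test_empty_extension_set(self):
        assert screen_introns([self._intron(92)], [], bounds=(121, 150)) == []

    def test_n_containing_introns_excluded(self):
        intron = IntronCandidate("s", 1, 92, "+", sequence="N" + "A" * 91)
        assert screen_introns([intron], []) == []

    def test_signature_totals_bounded_by_overlapping_counts(self, small_bundle):
        alignments = small_bundle["alignments"]
        from mirscreen import genome_io

        introns = [
            genome_io.attach_sequence(i, small_bundle["genome"])
            for i in genome_io.derive_introns(small_bundle["exons"])
        ]
        cands = screen_introns(introns, alignments)
        for c in cands[:50]:
            i = c.intron
            nearby = sum(
                a.read_count
                for a in alignments
                if a.seq_id == i.seq_id
                and a.start <= i.end + 3
                and a.end >= i.start - 3
            )
            assert c.splice.total <= 2 * nearby
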