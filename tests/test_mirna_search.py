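import random

import pytest

from mirscreen.hairpin import fold_hairpin
from mirscreen.mirna_search import (
    KnownMature,
    PredictedLocus,
    classify_locus,
    consensus_filter,
    discover_loci,
    match_mature,
    scan_identity,
    seed_of,
)
from mirscreen.read_mapper import ReadAlignment, revcomp

MIR100 = KnownMature("mir-100", "ACCCGUAGAUCCGAACUUGUG")
MIR2022 = KnownMature("mir-2022", "UUUGCUAGUUGCUUUUGUCCC")


class TestSeed:
    def test_mir100_seed(self):
        assert seed_of(MIR100.sequence) == "CCCGUA"

    def test_mir2022_seed(self):
        assert seed_of(MIR2022.sequence) == "UUGCUA"

    def test_dna_input_equivalent(self):
        assert seed_of("ACCCGTAGATCCGAACTTGTG") == "CCCGUA"

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            seed_of("ACGUAC")


def mutate(seq, positions, rng=None):
    rng = rng or random.Random(0)
    out = list(seq)
    for p in positions:  # 0-based
        out[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[out[p]]
    return "".join(out)


class TestMatchMature:
    QUERY = KnownMature("q", "UGAGGUAGUAGGUUGUAUAGUU")  # 22 nt

    def test_identical_matches(self):
        m = match_mature(self.QUERY.sequence, self.QUERY)
        assert m and m.mismatches_rest == 0

    def test_seed_mismatch_rejected(self):
        cand = mutate(self.QUERY.sequence, [3])  # inside seed (positions 2-7)
        assert match_mature(cand, self.QUERY) is None

    def test_three_outside_mismatches_accepted(self):
        cand = mutate(self.QUERY.sequence, [9, 14, 20])
        m = match_mature(cand, self.QUERY)
        assert m and m.mismatches_rest == 3

    def test_four_outside_mismatches_rejected(self):
        cand = mutate(self.QUERY.sequence, [9, 14, 18, 20])
        assert match_mature(cand, self.QUERY) is None

    def test_position_one_counts_as_non_seed(self):
        cand = mutate(self.QUERY.sequence, [0, 9, 14, 20])
        assert match_mature(cand, self.QUERY) is None  # 4 non-seed mismatches

    def test_three_prime_overhang_uncounted(self):
        cand = self.QUERY.sequence + "ACGU"
        m = match_mature(cand, self.QUERY)
        assert m and m.mismatches_rest == 0

    def test_symmetric_at_equal_length(self):
        rng = random.Random(4)
        for _ in range(50):
            positions = rng.sample(range(22), rng.randint(0, 5))
            cand = mutate(self.QUERY.sequence, positions, rng)
            fwd = match_mature(cand, self.QUERY)
            rev = match_mature(self.QUERY.sequence, KnownMature("c", cand))
            assert (fwd is None) == (rev is None)

    def test_star_arm_label(self):
        m = match_mature(self.QUERY.sequence, self.QUERY, arm="star")
        assert m.matched_arm == "star"


def brute_force_identity(genome, query_dna, min_run=11):
    """All maximal identity runs via per-offset longest-common-run scan."""
    hits = set()
    for sid, seq in genome.items():
        for strand in "+-":
            q = query_dna if strand == "+" else revcomp(query_dna)
            for off in range(-len(q) + 1, len(seq)):
                run, best, best_end = 0, 0, -1
                for qi in range(len(q)):
                    g = off + qi
                    if 0 <= g < len(seq) and seq[g] == q[qi]:
                        run += 1
                        if run > best:
                            best, best_end = run, qi
                    else:
                        if run >= min_run:
                            hits.add((sid, strand, off + qi - run + 1, run))
                        run = 0
                if run >= min_run:
                    hits.add((sid, strand, off + len(q) - run + 1, run))
    return hits


class TestScanIdentity:
    def test_verbatim_query_found(self):
        qdna = MIR100.sequence.replace("U", "T")
        genome = {"s": "TTGACTGAC" + qdna + "GACTGACTGA"}
        hits = scan_identity(genome, MIR100)
        top = hits[0]
        assert top.run_length == 21 and top.covers_seed and top.strand == "+"
        assert top.start == 10

    def test_partial_hit_outside_seed(self):
        qdna = MIR100.sequence.replace("U", "T")
        genome = {"s": "CCTTCCTTCC" + qdna[7:21] + "CCTTCCTTCC"}
        hits = scan_identity(genome, MIR100)
        assert any(h.run_length == 14 and not h.covers_seed for h in hits)

    def test_reverse_strand_hit(self):
        qdna = MIR2022.sequence.replace("U", "T")
        genome = {"s": "AACCTTAACC" + revcomp(qdna) + "AACCTTAACC"}
        hits = scan_identity(genome, MIR2022)
        assert any(h.run_length == 21 and h.strand == "-" and h.covers_seed for h in hits)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(21)
        qdna = MIR100.sequence.replace("U", "T")
        for trial in range(10):
            g = "".join(rng.choice("ACGT") for _ in range(800))
            if trial % 2 == 0:  # plant a partial copy
                p = rng.randint(0, 770)
                frag = qdna[3:18]
                g = g[:p] + frag + g[p + len(frag):]
            genome = {"s": g}
            got = {
                (h.seq_id, h.strand, h.start, h.run_length)
                for h in scan_identity(genome, MIR100)
            }
            assert got == brute_force_identity(genome, qdna)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            scan_identity({"s": "ACGTACGTACGT"}, KnownMature("q", "ACGUACGU"))


class TestConsensusFilter:
    def locus(self, start, methods=("m1",), seq_id="s", strand="+", length=60):
        return PredictedLocus(seq_id, start, start + length - 1, strand, frozenset(methods))

    def test_single_sample_locus_dropped(self):
        preds = {"s1": [self.locus(100)], "s2": [self.locus(5000)]}
        assert consensus_filter(preds) == []

    def test_shared_locus_retained_with_method_union(self):
        preds = {
            "s1": [self.locus(100, methods=("m1",))],
            "s2": [self.locus(120, methods=("m1", "m2"))],
        }
        (kept,) = consensus_filter(preds)
        assert kept.methods == frozenset({"m1", "m2"})

    def test_strand_mismatch_not_overlap(self):
        preds = {
            "s1": [self.locus(100, strand="+")],
            "s2": [self.locus(100, strand="-")],
        }
        assert consensus_filter(preds) == []

    def test_ranking_by_method_support(self):
        preds = {
            "s1": [self.locus(100, methods=("m1",)), self.locus(900, methods=("m1", "m2"))],
            "s2": [self.locus(100, methods=("m1",)), self.locus(900, methods=("m1", "m2"))],
        }
        kept = consensus_filter(preds)
        assert [k.start for k in kept] == [900, 100]

    def test_empty_input(self):
        assert consensus_filter({}) == []

    def test_single_sample_passthrough_warns(self, caplog):
        preds = {"s1": [self.locus(100)]}
        with caplog.at_level("WARNING"):
            kept = consensus_filter(preds)
        assert len(kept) == 1 and "1 sample" in caplog.text


class TestClassifyLocus:
    def test_zero_reads_is_atypical_no_expression(self):
        structure = fold_hairpin("GGGGGGAAAACCCCCC")
        sig = classify_locus(("s", 1, 16, "+"), [], structure)
        assert sig.classification == "atypical"
        assert sig.reasons == ("no expression",)

    def test_planted_canonical_loci_plausible(self, small_bundle):
        truth, genome = small_bundle["truth"], small_bundle["genome"]
        alns = small_bundle["alignments"]
        results = []
        for l in truth.of_kind("canonical"):
            seq = genome[l.seq_id].residues[l.start - 1 : l.end]
            if l.strand == "-":
                seq = revcomp(seq)
            sig = classify_locus(
                (l.seq_id, l.start, l.end, l.strand), alns, fold_hairpin(seq)
            )
            results.append(sig.classification)
        assert results.count("plausible") >= 0.9 * len(results)

    def test_scatter_decoys_atypical(self, small_bundle):
        truth, genome = small_bundle["truth"], small_bundle["genome"]
        alns = small_bundle["alignments"]
        results = []
        for l in truth.of_kind("scatter_decoy"):
            seq = genome[l.seq_id].residues[l.start - 1 : l.end]
            if l.strand == "-":
                seq = revcomp(seq)
            sig = classify_locus(
                (l.seq_id, l.start, l.end, l.strand), alns, fold_hairpin(seq)
            )
            results.append(sig.classification)
        assert results.count("atypical") >= 0.9 * len(results)


def test_discover_loci_merges_and_thresholds():
    alns = [
        ReadAlignment("A" * 22, "s", 100, "+", 0, 5),
        ReadAlignment("C" * 22, "s", 130, "+", 0, 4),
        ReadAlignment("G" * 22, "s", 5000, "+", 0, 1),  # below min_total
    ]
    loci = discover_loci(alns, min_total=3, merge_gap=30, flank=10)
    assert loci == [("s", 90, 161, "+")]
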