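"""Conserved canonical miRNA screening.

Three complementary screens:

* seed-match homology of candidate small-RNA sequences against known mature
  miRNAs (identical seed, nucleotides 2-7, and at most three mismatches over
  the remainder of the mature or mature-star arm);
* an exact identity-run scan of the genome for specific mature queries
  (e.g. miR-100, miR-2022), reporting the longest contiguous exact match at
  every gapless offset on both strands and whether it covers the seed site;
* a read-mapping-signature classifier that labels candidate hairpin loci
  ``plausible`` or ``atypical`` from how reads stack on the mature arm,
  star arm and loop.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .hairpin import HairpinStructure, main_stem_path
from .read_mapper import GenomeLike, ReadAlignment, _as_strings, revcomp

logger = logging.getLogger(__name__)

SEED_START = 2  # 1-based, inclusive
SEED_END = 7
MAX_ARM_MISMATCHES = 3
MIN_IDENTITY_RUN = 11


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class KnownMature:
    """A known mature miRNA; the seed is nucleotides 2-7 (1-based)."""

    name: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _rna(self.sequence))

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)


@dataclass(frozen=True)
class SeedMatch:
    query_name: str
    candidate_sequence: str
    seed_identical: bool
    mismatches_rest: int
    matched_arm: str  # 'mature' or 'star'


@dataclass(frozen=True)
class IdentityHit:
    seq_id: str
    start: int  # 1-based genomic start of the identity run
    strand: str
    run_length: int
    covers_seed: bool
    query_start: int = 0  # 1-based query position where the run begins


@dataclass(frozen=True)
class SignatureThresholds:
    min_mature_fraction: float = 0.5
    max_end_heterogeneity: int = 2
    max_loop_fraction: float = 0.1
    end_mode_mass: float = 0.8  # fraction of 5' ends the mode window must hold
    star_overhang_tolerance: int = 3
    min_star_reads: int = 3  # star stack size below which the duplex check is uninformative


@dataclass(frozen=True)
class LocusSignature:
    seq_id: str
    start: int
    end: int
    strand: str
    mature_stack_fraction: float
    star_stack_fraction: float
    loop_fraction: float
    end_heterogeneity: int
    classification: str  # 'plausible' or 'atypical'
    reasons: Tuple[str, ...]


@dataclass(frozen=True)
class PredictedLocus:
    """A candidate miRNA locus from one sample, tagged with the predicting
    method labels (for consensus filtering and method-support ranking)."""

    seq_id: str
    start: int
    end: int
    strand: str
    methods: frozenset

    def overlaps(self, other: "PredictedLocus") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


def seed_of(mature_sequence: str) -> str:
    """Return the 6-nt seed: positions 2-7, 1-based inclusive."""
    seq = _rna(mature_sequence)
    if len(seq) < SEED_END:
        raise ValueError(f"mature sequence shorter than {SEED_END} nt")
    return seq[SEED_START - 1 : SEED_END]


def load_known_matures(fasta_path: str | Path) -> List[KnownMature]:
    """Load a miRBase-style mature FASTA (RNA alphabet, U/T equivalent)."""
    return [
        KnownMature(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]


def match_mature(
    candidate: str,
    known: KnownMature,
    arm: str = "mature",
    max_mismatches_rest: int = MAX_ARM_MISMATCHES,
) -> Optional[SeedMatch]:
    """Seed-match homology test against one known mature (or star) arm.

    The candidate matches iff its seed (positions 2-7) is identical to the
    query's and the remaining compared positions carry at most three
    mismatches. Sequences are compared 5'-anchored over their common length;
    3'-overhanging bases are not counted (mature 3' ends are heterogeneous).
    """
    cand = _rna(candidate)
    ref = known.sequence
    n = min(len(cand), len(ref))
    if n < SEED_END:
        return None
    seed_identical = cand[SEED_START - 1 : SEED_END] == ref[SEED_START - 1 : SEED_END]
    rest = [
        (i, cand[i] != ref[i])
        for i in range(n)
        if not (SEED_START - 1 <= i <= SEED_END - 1)
    ]
    mismatches_rest = sum(1 for _, bad in rest if bad)
    if seed_identical and mismatches_rest <= max_mismatches_rest:
        return SeedMatch(known.name, cand, True, mismatches_rest, arm)
    return None


def screen_reads_against_matures(
    reads: Iterable, knowns: Sequence[KnownMature]
) -> List[SeedMatch]:
    """Match every collapsed read against every known mature sequence."""
    matches: List[SeedMatch] = []
    for r in reads:
        for known in knowns:
            m = match_mature(r.sequence, known)
            if m:
                matches.append(m)
    return matches


def _runs_for_query(
    sid: str, genome_seq: str, query_dna: str, strand: str, qlen: int, min_run: int
) -> List[IdentityHit]:
    """Maximal identity runs of query_dna against one forward genome string.

    For a '-' hit the run is found on the reverse-complemented query; query
    coordinates are reported in the original query's 5'->3' frame.
    """
    hits: Dict[Tuple[int, int], IdentityHit] = {}
    word = min(min_run, len(query_dna))
    n = len(genome_seq)
    for qi in range(0, len(query_dna) - word + 1):
        w = query_dna[qi : qi + word]
        p = genome_seq.find(w)
        while p != -1:
            # extend to the maximal run through this word occurrence
            gs, qs = p, qi
            while gs > 0 and qs > 0 and genome_seq[gs - 1] == query_dna[qs - 1]:
                gs -= 1
                qs -= 1
            ge, qe = p + word, qi + word  # exclusive
            while (
                ge < n and qe < len(query_dna) and genome_seq[ge] == query_dna[qe]
            ):
                ge += 1
                qe += 1
            run = ge - gs
            if run >= min_run:
                if strand == "+":
                    q_start0, q_end0 = qs, qe - 1  # 0-based inclusive
                else:
                    q_start0 = qlen - qe
                    q_end0 = qlen - qs - 1
                covers = q_start0 + 1 <= SEED_START and q_end0 + 1 >= SEED_END
                key = (gs, run)
                if key not in hits:
                    hits[key] = IdentityHit(
                        sid, gs + 1, strand, run, covers, q_start0 + 1
                    )
            p = genome_seq.find(w, p + 1)
    return list(hits.values())


def scan_identity(
    genome: GenomeLike, query: KnownMature, min_run: int = MIN_IDENTITY_RUN
) -> List[IdentityHit]:
    """Scan the genome for identity runs of a mature miRNA query.

    Reports, for both strands, every maximal contiguous exact match of
    length >= ``min_run`` (word-size floor 11 by default, below which short
    random matches are uninformative), annotated with whether the run covers
    the query's seed site (positions 2-7).
    """
    qdna = _rna(query.sequence).replace("U", "T")
    if len(qdna) < min_run:
        raise ValueError(f"query shorter than the minimum run length {min_run}")
    hits: List[IdentityHit] = []
    for sid, seq in sorted(_as_strings(genome).items()):
        hits.extend(_runs_for_query(sid, seq, qdna, "+", len(qdna), min_run))
        hits.extend(
            _runs_for_query(sid, seq, revcomp(qdna), "-", len(qdna), min_run)
        )
    hits.sort(key=lambda h: (-h.run_length, h.seq_id, h.start, h.strand))
    return hits


def consensus_filter(
    predictions_by_sample: Mapping[str, Sequence[PredictedLocus]],
    primary_method: Optional[str] = None,
) -> List[PredictedLocus]:
    """Keep loci present in every sample; rank by method support.

    A locus is retained iff every sample contains an overlapping same-strand
    prediction. The retained locus carries the union of method labels across
    all overlapping predictions; the list is ordered by descending method
    support, with loci supported by ``primary_method`` favoured on ties,
    then by coordinate. A single-sample input passes through with a warning.
    """
    samples = list(predictions_by_sample)
    if len(samples) < 2:
        logger.warning(
            "consensus_filter called with %d sample(s); passing through", len(samples)
        )
        loci = list(predictions_by_sample[samples[0]]) if samples else []
        return sorted(loci, key=lambda l: (l.seq_id, l.start, l.end, l.strand))

    anchor_sample, *others = samples
    retained: List[PredictedLocus] = []
    for locus in predictions_by_sample[anchor_sample]:
        methods = set(locus.methods)
        in_all = True
        for s in others:
            overlapping = [o for o in predictions_by_sample[s] if locus.overlaps(o)]
            if not overlapping:
                in_all = False
                break
            for o in overlapping:
                methods |= set(o.methods)
        if in_all:
            retained.append(
                PredictedLocus(
                    locus.seq_id, locus.start, locus.end, locus.strand,
                    frozenset(methods),
                )
            )
    retained.sort(
        key=lambda l: (
            -len(l.methods),
            0 if (primary_method and primary_method in l.methods) else 1,
            l.seq_id,
            l.start,
        )
    )
    return retained


def _mode_window(
    positions: Counter, mass: float
) -> Tuple[int, int]:
    """(mode, h): smallest h such that [mode-h, mode+h] holds >= mass of counts."""
    total = sum(positions.values())
    mode = min(p for p, c in positions.items() if c == max(positions.values()))
    h = 0
    while True:
        covered = sum(c for p, c in positions.items() if abs(p - mode) <= h)
        if covered >= mass * total:
            return mode, h
        h += 1


def classify_locus(
    locus: Tuple[str, int, int, str],
    alignments: Sequence[ReadAlignment],
    structure: HairpinStructure,
    thresholds: SignatureThresholds = SignatureThresholds(),
) -> LocusSignature:
    """Classify a candidate hairpin locus by its read-mapping signature.

    A locus is ``plausible`` when reads pile on one arm (the mature) with
    homogeneous 5' ends, the loop carries almost no reads, and any star
    reads sit where Dicer processing would leave them (duplex partner of the
    mature with a ~2-nt 3' overhang). Everything else — scattered reads,
    ragged 5' ends, loop-dominated coverage, no expression — is ``atypical``
    with the failing criteria listed.
    """
    seq_id, start, end, strand = locus
    length = end - start + 1

    def to_local5(a: ReadAlignment) -> int:
        """Read 5' end in 1-based transcript-orientation locus coordinates."""
        return (
            a.five_prime_pos - start + 1 if strand == "+" else end - a.five_prime_pos + 1
        )

    def to_local3(a: ReadAlignment) -> int:
        return (
            a.three_prime_pos - start + 1
            if strand == "+"
            else end - a.three_prime_pos + 1
        )

    reads = [
        a
        for a in alignments
        if a.seq_id == seq_id
        and a.strand == strand
        and a.start <= end
        and a.end >= start
    ]
    total = sum(a.read_count for a in reads)
    if total == 0:
        return LocusSignature(
            seq_id, start, end, strand, 0.0, 0.0, 0.0, 0, "atypical",
            ("no expression",),
        )

    pairs = structure.pairs
    if pairs:
        path = main_stem_path(pairs)
        outer, inner = path[0], path[-1]
        first_i = min(i for i, _ in pairs)
        last_j = max(j for _, j in pairs)
        arm5 = (first_i, inner[0])
        loop = (inner[0] + 1, inner[1] - 1)
        arm3 = (inner[1], last_j)
    else:
        arm5 = (1, length // 2)
        loop = (0, -1)
        arm3 = (length // 2 + 1, length)

    def arm_key_of(lo5: int, lo3: int) -> str:
        mid = (lo5 + lo3) // 2
        if arm5[0] <= mid <= arm5[1]:
            return "arm5"
        if arm3[0] <= mid <= arm3[1]:
            return "arm3"
        if loop[0] <= mid <= loop[1]:
            return "loop"
        return "out"

    region_counts = {"arm5": Counter(), "arm3": Counter(), "loop": 0, "out": 0}
    for a in reads:
        lo5 = to_local5(a)
        key = arm_key_of(lo5, to_local3(a))
        if key in ("arm5", "arm3"):
            region_counts[key][lo5] += a.read_count
        else:
            region_counts[key] += a.read_count

    c5 = sum(region_counts["arm5"].values())
    c3 = sum(region_counts["arm3"].values())
    mature_key = "arm5" if c5 >= c3 else "arm3"
    star_key = "arm3" if mature_key == "arm5" else "arm5"
    mature_frac = region_counts[mature_key].total() / total
    star_frac = region_counts[star_key].total() / total
    loop_frac = region_counts["loop"] / total

    reasons: List[str] = []
    if mature_frac < thresholds.min_mature_fraction:
        reasons.append(f"mature_stack_fraction {mature_frac:.2f} < {thresholds.min_mature_fraction}")
    if loop_frac > thresholds.max_loop_fraction:
        reasons.append(f"loop_fraction {loop_frac:.2f} > {thresholds.max_loop_fraction}")

    end_het = 0
    mature_positions = region_counts[mature_key]
    if mature_positions:
        mode5, end_het = _mode_window(mature_positions, thresholds.end_mode_mass)
        if end_het > thresholds.max_end_heterogeneity:
            reasons.append(
                f"end_heterogeneity {end_het} > {thresholds.max_end_heterogeneity}"
            )
        # Dicer-consistent duplex: star 3' end pairs ~2 nt inside the mature 5' end
        star_positions = region_counts[star_key]
        if (
            pairs
            and star_positions
            and sum(star_positions.values()) >= thresholds.min_star_reads
        ):
            partner = {i: j for i, j in pairs}
            partner.update({j: i for i, j in pairs})
            anchor = next(
                (partner[p] for p in range(mode5, mode5 + 4) if p in partner), None
            )
            if anchor is not None:
                # star arm 3' ends: most read mass must sit where Dicer
                # processing leaves the duplex partner (2-nt 3' overhang)
                star3 = Counter()
                for a in reads:
                    if arm_key_of(to_local5(a), to_local3(a)) == star_key:
                        star3[to_local3(a)] += a.read_count
                if star3:
                    expected = anchor + 2
                    within = sum(
                        c
                        for p, c in star3.items()
                        if abs(p - expected) <= thresholds.star_overhang_tolerance
                    )
                    if within < 0.5 * sum(star3.values()):
                        reasons.append(
                            f"star 3' ends not Dicer-consistent (expected ~{expected})"
                        )
    else:
        reasons.append("no mature-arm reads")

    classification = "plausible" if not reasons else "atypical"
    return LocusSignature(
        seq_id, start, end, strand,
        round(mature_frac, 4), round(star_frac, 4), round(loop_frac, 4),
        end_het, classification, tuple(reasons),
    )


def discover_loci(
    alignments: Sequence[ReadAlignment],
    min_total: int = 3,
    merge_gap: int = 30,
    flank: int = 15,
    genome_lengths: Optional[Mapping[str, int]] = None,
) -> List[Tuple[str, int, int, str]]:
    """Cluster read alignments into candidate expressed loci.

    Same-strand alignments separated by at most ``merge_gap`` nt are merged;
    clusters with summed counts >= ``min_total`` are reported, extended by
    ``flank`` nt on both sides (clipped to the sequence when lengths are
    given). This is the locus proposal step feeding the signature classifier.
    """
    by_group: Dict[Tuple[str, str], List[ReadAlignment]] = {}
    for a in alignments:
        by_group.setdefault((a.seq_id, a.strand), []).append(a)
    loci: List[Tuple[str, int, int, str]] = []
    for (sid, strand), alns in sorted(by_group.items()):
        alns.sort(key=lambda a: a.start)
        cur_start, cur_end, cur_count = None, None, 0
        def flush():
            if cur_start is not None and cur_count >= min_total:
                lo = max(1, cur_start - flank)
                hi = cur_end + flank
                if genome_lengths and sid in genome_lengths:
                    hi = min(hi, genome_lengths[sid])
                loci.append((sid, lo, hi, strand))
        for a in alns:
            if cur_end is None or a.start > cur_end + merge_gap:
                flush()
                cur_start, cur_end, cur_count = a.start, a.end, a.read_count
            else:
                cur_end = max(cur_end, a.end)
                cur_count += a.read_count
        flush()
    loci.sort()
    return loci


def write_seed_matches_tsv(matches: Sequence[SeedMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_name\tcandidate_sequence\tseed_identical\tmismatches_rest\tmatched_arm\n")
        for m in matches:
            fh.write(
                f"{m.query_name}\t{m.candidate_sequence}\t{int(m.seed_identical)}"
                f"\t{m.mismatches_rest}\t{m.matched_arm}\n"
            )


def write_identity_hits_tsv(hits: Sequence[IdentityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tstrand\trun_length\tcovers_seed\tquery_start\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.strand}\t{h.run_length}"
                f"\t{int(h.covers_seed)}\t{h.query_start}\n"
            )


def write_signatures_tsv(sigs: Sequence[LocusSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tstart\tend\tstrand\tmature_stack_fraction\tstar_stack_fraction"
            "\tloop_fraction\tend_heterogeneity\tclassification\treasons\n"
        )
        for s in sigs:
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.mature_stack_fraction}"
                f"\t{s.star_stack_fraction}\t{s.loop_fraction}\t{s.end_heterogeneity}"
                f"\t{s.classification}\t{';'.join(s.reasons)}\n"
            )
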