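# Methods

This note documents the models, parameter choices and known limits of
`mirscreen`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Intron derivation and coordinates

Coordinates are 1-based inclusive throughout the library (BED exports
convert to 0-based half-open). Introns are the gaps between coordinate-sorted
adjacent exons of each transcript; introns identical in
(sequence, start, end, strand) across isoforms are collapsed once, because
the screen counts introns, not transcript–intron incidences. Annotation
sets that distinguish isoform-specific intron usage will therefore report
slightly lower intron counts than a per-incidence accounting. The donor is
the intron base adjacent to the upstream exon in transcript orientation
(genomic `start` on `+`, `end` on `-`); the acceptor is the opposite
terminus. Length-window bounds are inclusive on both ends, so the core
window [50, 120] and the extension window [121, 150] are disjoint.
IUPAC ambiguity codes other than N are normalised to N on input; introns
containing N are carried through extraction but excluded from folding,
since their base pairing is undefined.

## Read preparation

Raw reads are the insert followed by the 3′ sequencing adapter
(default `ATCTCGTATGCCGTCTTCTGCTTGT`). Trimming removes the leftmost
position where the read suffix matches an adapter prefix (or a full
internal adapter copy) with ≥5 nt overlap and mismatch fraction ≤0.1 —
standard small-RNA trimmer behaviour. The quality/length filter keeps
18–26 nt reads (the mature-miRNA length spectrum) with mean Phred ≥20 and
no N; FASTQ input must be Phred+33 and other encodings are rejected with an
explicit error rather than silently mis-decoded. An optional blocklist
FASTA removes contaminant-derived reads (e.g. an over-represented rRNA
fragment) by sub-string match with ≤1 mismatch; contaminants differ between
libraries, so no fixed list is built in. Identical sequences are collapsed
to one record carrying their multiplicity; collapse order (descending
count, then lexicographic) is deterministic.

## Read mapping

Reads map to both genome strands with up to 2 substitutions and no indels;
at 18–26 nt, substitution-only Hamming alignment matches the behaviour of
short-read seed-and-extend mappers while keeping an exact exhaustive oracle
feasible. The mapper seeds with `max_mismatches + 1` non-overlapping k-mers
(pigeonhole: at least one seed must be exact in any qualifying alignment);
k defaults to 6 so the guarantee covers the shortest accepted read
(18 = 3·6) at the default mismatch budget. Reads below the pigeonhole
length fall back to the exhaustive scan, so completeness holds
unconditionally; the test suite verifies exact agreement with
`brute_force_map` over hundreds of random read/genome pairs. All hits are
reported and each alignment carries the full collapsed count — multi-mapped
reads are not fractionally weighted, and splice signatures report raw,
unique-only and distinct-sequence tallies side by side so either convention
can be read off.

## Hairpin folding and the structure score

Folding is a maximum-weight nested-pairing dynamic program (Nussinov
recurrence) over pair weights GC=3, AU=2, GU=1 with a minimum hairpin loop
of 3 nt. A pair type weighted 0 is treated as unpairable. Weighted
base-pair maximisation is not a thermodynamic model: it ignores stacking
context and loop entropies, and will over-pair long random sequences. It
is, however, exactly checkable (the suite enumerates all nested structures
for sequences ≤14 nt and confirms the DP optimum under several weight
schemes) and fully deterministic: traceback pairs the leftmost base
whenever pairing attains the optimum, taking the smallest admissible
partner, so identical inputs give bit-identical structures. An adapter
point (`fold_hairpin(..., folder=...)`) accepts an external dot-bracket
predictor for cross-checks; no part of the package requires one.

One symmetry subtlety: the optimum is invariant under sequence *reversal*
(each pair maps onto itself), but reverse *complement* preserves only
Watson–Crick pairs — a G·U wobble maps to A/C, which cannot pair — so
revcomp invariance holds only when GU is disabled. The tests assert exactly
these two forms.

Features are read off the main stem path (descending from the outermost
pair into the branch with the most pairs, leftmost on ties, down to the
terminal loop): stem length in pairs, terminal-loop size, paired fraction,
5′/3′ overhangs, bulge count (interruptions of the path), GU fraction.
The mirtron structure score is a logistic over these features:

    z = -5 + 0.2·stem_len + 3·paired_fraction - 0.5·loop_dev
        - 0.8·n_bulges - 0.3·excess_overhang

where `loop_dev` is the distance of the terminal loop from the [4, 20] nt
window and `excess_overhang` counts overhang nt beyond the 2-nt allowance
characteristic of Dicer substrates. The score is monotone in stem length
and paired fraction with everything else fixed; a pairless intron scores
below 0.01 and a clean 30-bp stem with a 6-nt loop scores above 0.97. The
weights are fixed in `StructureScoreParams` and were chosen (and are only
validated) on synthetic data; they are a transparent stand-in for trained
structure classifiers and make no calibrated probability claim on real
genomes.

## Splice-site read signatures and rankings

A read supports an intron's 5′ site iff its transcript-orientation 5′ end
lies within ±3 nt of the donor and its strand equals the intron strand
(mirtron small RNAs derive from the spliced sense intron); the read's 3′
end anchors the acceptor analogously. The read terminus nearest the
relevant splice site is the anchor because mirtron pre-miRNA ends coincide
with the splice sites. A read can satisfy both conditions and then counts
once per site. Candidates receive three rankings: descending structure
score, descending splice-anchored total, and ascending sum of those two
ranks (the "intersection" ranking — sum-of-ranks is symmetric and total,
where a literal set intersection is not). All ties break on (sequence id,
start) so every ranking is a permutation.

## Canonical miRNA screens

*Seed matching.* Candidates are compared 5′-anchored over the common
length; the match requires an identical 6-nt seed (positions 2–7, U/T
equivalent) and ≤3 mismatches over the remaining compared positions.
3′-overhanging bases are not counted, reflecting the heterogeneity of
mature 3′ ends.

*Identity runs.* The genome scan reports every maximal contiguous exact
match ≥11 nt between a mature query and either genome strand, annotated
with whether the run covers the query's seed site. Exact identity-run
length is the quantity of interest for short conserved queries (word floor
11 keeps random hits rare: a given 11-mer occurs by chance ~once per 2 Mb
per strand); the implementation is verified against a per-offset
longest-common-run oracle.

*Locus signature classification.* Discovered (or supplied) loci are folded
and their orientation-correct reads assigned to the 5′ arm, 3′ arm or loop
by read midpoint. A locus is `plausible` iff the dominant (mature) arm
holds ≥50% of read mass, mature 5′ ends are homogeneous (the smallest
window around the modal 5′ end holding 80% of the mass spans ≤2 nt), the
loop holds ≤10% of reads, and — when the star arm carries at least 3
reads — the majority of star 3′ ends lie within ±3 nt of the mature 5′
end's duplex partner plus the 2-nt 3′ overhang that Dicer processing
leaves. Below 3 star reads the duplex test is uninformative (a single
degradation fragment would otherwise define the "star end") and is
skipped. Loci with no reads are `atypical` with reason "no expression".
All thresholds live in `SignatureThresholds`. These criteria follow
community miRNA-annotation practice; they are a documented stand-in for
the published predictors' internal scoring and are deliberately simple
enough to audit.

*Consensus.* With two or more samples, a locus is retained iff every
sample contains an overlapping same-strand prediction ("present in both
samples"); retained loci are ranked by the number of supporting method
labels, a designated primary method breaking ties. One-sample input passes
through with a logged warning.

## Synthetic data: what it emulates, and what it does not

The generator lays out genes (4 exons of 100–220 nt by default) on a few
scaffolds with random strands. Decoy introns are uniform random sequence,
80% drawn uniformly from 50–150 nt and 20% from 151–400 nt, so both screen
windows are populated along with longer out-of-window introns. Planted
mirtrons (70–110 nt) are built as a GC-rich stem (60% GC), a 6–10 nt loop,
the reverse-complement stem and a 2-nt 3′ overhang, so the spliced intron
folds into a long clean hairpin whose arms abut the splice sites.
Canonical-style loci (30-bp stem, 8-nt loop, 5-nt flanks) sit in
intergenic spacers, with the mature arm at the start of the 5′ stem arm
and the star arm as its duplex partner plus the 2-nt overhang. Scatter
decoys reuse the hairpin construction but emit uniformly placed reads.

Each expressed locus draws its level once (uniform 0.6–1.4 × the
configured mean of 20 reads); each sample then draws Poisson counts at
that level: mature reads with 5′ ends within ±1 nt of the arm start, star
reads at one fifth the mature rate anchored at the star 3′ end, and rare
(2%) loop fragments. Background is 2,000 reads per sample: random genomic
fragments of 18–30 nt plus 15% drawn from a 120-nt rRNA-like transcript
that is deliberately absent from the assembly (exercising the blocklist
path), and 2% low-quality reads (exercising the quality filter). Every raw
read is insert + adapter truncated to 36 nt with Phred+33 qualities. Two
samples share one truth ledger with independent sampling noise; a
configurable fraction of loci is expressed in only one sample to exercise
the consensus filter. Everything is a deterministic function of the config
seed.

The generator's GC-rich perfect stems are a simulation convenience, not a
biological claim: they guarantee that a weighted-pairing folder separates
planted hairpins from random introns. Passing recovery tests therefore
demonstrates that the pipeline's plumbing, coordinates, orientation logic
and rankings are correct — not that the structure score would discriminate
real mirtrons from real introns, which have subtler folds and would need a
thermodynamic model and trained calibration. The simulator also omits
sequencing-error models beyond none at all, quality degradation along the
read, isoform complexity and cross-mapping repeat structure.

## Problem sizes and numerical choices

The acceptance-level checks run at the standard study scale used
throughout: 20 planted mirtrons among 2,000 decoy introns (a ~0.9 Mb
genome) for recovery and decoy control, 10 canonical + 10 scatter loci for
classification, and several independent seeds of each; oracle-agreement
checks use 200 random instances apiece (folding sequences of 8–14 nt,
genomes of 0.5–3 kb for mapping). A full screen of one simulated
experiment takes a few seconds on one CPU with the numba-compiled folding
kernel; the brute-force oracles are pure Python and deliberately naive.

Degenerate inputs are defined rather than accidental: empty FASTA gives an
empty genome; a zero-length exon gap emits no intron; unmapped reads give
empty alignment lists; a pairless structure reports zero stem with the
sequence length split at the midpoint as overhangs; a candidate list of
one gets rank 1 in all three rankings.

## Known limitations

- Weighted base-pair maximisation over-estimates pairing in random
  sequence; absolute structure scores are comparable only within a run.
- No indel alignment: reads crossing indel polymorphisms are lost.
- Multi-mapping reads carry full counts at every placement; unique-only
  tallies are provided but no rescue/fractional model is attempted.
- The locus classifier assumes a single dominant stem; tandem or
  multi-branched precursors are classified by their heaviest branch only.
- The consensus filter matches loci by interval overlap, not by read-set
  identity; adjacent distinct loci closer than a read length can merge.
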