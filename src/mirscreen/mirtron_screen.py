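"""Mirtron candidate screening: structure scoring, splice-site read evidence,
and the three candidate rankings.

Candidate introns (by default 50-120 nt, with a separate 121-150 nt extension
window) are folded, scored for hairpin quality, and paired with counts of
small-RNA reads anchored at the splice sites in the correct orientation
(read strand equal to the intron's transcript strand, read terminus within
+/- 3 nt of the splice boundary). Candidates are ranked by structure score,
by splice-anchored read total, and by the sum of those two ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .genome_io import IntronCandidate
from .hairpin import (
    HairpinFeatures,
    HairpinStructure,
    extract_features,
    fold_hairpin,
)
from .read_mapper import ReadAlignment

CORE_LENGTH_BOUNDS = (50, 120)
EXTENDED_LENGTH_BOUNDS = (121, 150)
SPLICE_BUFFER = 3


@dataclass(frozen=True)
class StructureScoreParams:
    """Weights of the logistic hairpin-quality score.

    The score rises with stem length and paired fraction, is flat for
    terminal loops inside [loop_min, loop_max], and is penalised per bulge
    and per overhang nt beyond the 2-nt allowance characteristic of
    Dicer substrates.
    """

    bias: float = -5.0
    w_stem: float = 0.2
    w_paired: float = 3.0
    w_loop_dev: float = 0.5
    w_bulge: float = 0.8
    w_overhang: float = 0.3
    loop_min: int = 4
    loop_max: int = 20
    overhang_allowance: int = 2


@dataclass(frozen=True)
class SpliceSignature:
    """Orientation-correct read counts anchored at the two splice sites.

    ``n5``/``n3`` sum collapsed multiplicities; ``unique5``/``unique3``
    restrict to uniquely-mapping reads; ``distinct5``/``distinct3`` count
    distinct read sequences (collapsed records) regardless of multiplicity.
    """

    n5: int = 0
    n3: int = 0
    unique5: int = 0
    unique3: int = 0
    distinct5: int = 0
    distinct3: int = 0

    @property
    def total(self) -> int:
        return self.n5 + self.n3


@dataclass
class MirtronCandidate:
    intron: IntronCandidate
    structure: HairpinStructure
    features: HairpinFeatures
    structure_score: float
    splice: SpliceSignature
    rank_structure: int = 0
    rank_reads: int = 0
    rank_combined: int = 0


def score_mirtron_structure(
    features: HairpinFeatures, params: StructureScoreParams = StructureScoreParams()
) -> float:
    """Logistic hairpin-quality score in [0, 1]; monotone in stem length and
    paired fraction with all other features fixed."""
    if features.loop_len < params.loop_min:
        loop_dev = params.loop_min - features.loop_len
    elif features.loop_len > params.loop_max:
        loop_dev = features.loop_len - params.loop_max
    else:
        loop_dev = 0
    excess_overhang = max(0, features.overhang5 - params.overhang_allowance) + max(
        0, features.overhang3 - params.overhang_allowance
    )
    z = (
        params.bias
        + params.w_stem * features.stem_len
        + params.w_paired * features.paired_fraction
        - params.w_loop_dev * loop_dev
        - params.w_bulge * features.n_bulges
        - params.w_overhang * excess_overhang
    )
    return 1.0 / (1.0 + math.exp(-z))


class SpliceEndIndex:
    """Constant-time lookup of read 5'/3' termini by genomic position.

    Built once from the full alignment list; a read is 'unique' when its
    sequence has exactly one alignment genome-wide.
    """

    def __init__(self, alignments: Sequence[ReadAlignment]):
        n_hits: Dict[str, int] = {}
        for a in alignments:
            n_hits[a.read_seq] = n_hits.get(a.read_seq, 0) + 1
        self.five: Dict[Tuple[str, str, int], List[int]] = {}
        self.three: Dict[Tuple[str, str, int], List[int]] = {}
        for a in alignments:
            unique = n_hits[a.read_seq] == 1
            k5 = (a.seq_id, a.strand, a.five_prime_pos)
            k3 = (a.seq_id, a.strand, a.three_prime_pos)
            for key, store in ((k5, self.five), (k3, self.three)):
                rec = store.setdefault(key, [0, 0, 0])
                rec[0] += a.read_count
                rec[1] += a.read_count if unique else 0
                rec[2] += 1


def count_splice_reads(
    intron: IntronCandidate,
    alignments: Sequence[ReadAlignment] | SpliceEndIndex,
    buffer: int = SPLICE_BUFFER,
) -> SpliceSignature:
    """Count reads anchored at the intron's splice sites.

    A read supports the 5' site iff its transcript-orientation 5' end lies
    within ``buffer`` nt of the donor position and its strand matches the
    intron strand; analogously the read's 3' end for the acceptor. A read
    satisfying both conditions counts once at each site.
    """
    index = (
        alignments
        if isinstance(alignments, SpliceEndIndex)
        else SpliceEndIndex(alignments)
    )
    tallies = {"five": [0, 0, 0], "three": [0, 0, 0]}
    for site, anchor, store in (
        ("five", intron.donor_pos, index.five),
        ("three", intron.acceptor_pos, index.three),
    ):
        for d in range(-buffer, buffer + 1):
            rec = store.get((intron.seq_id, intron.strand, anchor + d))
            if rec:
                for i in range(3):
                    tallies[site][i] += rec[i]
    f, t = tallies["five"], tallies["three"]
    return SpliceSignature(f[0], t[0], f[1], t[1], f[2], t[2])


def rank_candidates(candidates: List[MirtronCandidate]) -> List[MirtronCandidate]:
    """Assign the three rankings in place and return candidates sorted by
    the combined rank.

    rank_structure: descending structure score; rank_reads: descending
    splice-anchored total; rank_combined: ascending sum of the two ranks.
    All ties break on (seq_id, start) so each ranking is a permutation.
    """
    def coord(c: MirtronCandidate):
        return (c.intron.seq_id, c.intron.start)

    by_structure = sorted(candidates, key=lambda c: (-c.structure_score, coord(c)))
    for r, c in enumerate(by_structure, start=1):
        c.rank_structure = r
    by_reads = sorted(candidates, key=lambda c: (-c.splice.total, coord(c)))
    for r, c in enumerate(by_reads, start=1):
        c.rank_reads = r
    by_combined = sorted(
        candidates, key=lambda c: (c.rank_structure + c.rank_reads, coord(c))
    )
    for r, c in enumerate(by_combined, start=1):
        c.rank_combined = r
    return by_combined


def screen_introns(
    introns: Iterable[IntronCandidate],
    alignments: Sequence[ReadAlignment] | SpliceEndIndex,
    bounds: Tuple[int, int] = CORE_LENGTH_BOUNDS,
    buffer: int = SPLICE_BUFFER,
    score_params: StructureScoreParams = StructureScoreParams(),
    min_loop: int = 3,
) -> List[MirtronCandidate]:
    """Fold, score, count and rank every intron in the length window.

    Introns containing N are excluded (undefined base pairing). Returns
    candidates sorted by the combined ranking.
    """
    lo, hi = bounds
    index = (
        alignments
        if isinstance(alignments, SpliceEndIndex)
        else SpliceEndIndex(alignments)
    )
    candidates: List[MirtronCandidate] = []
    for intron in introns:
        if not (lo <= intron.length <= hi):
            continue
        if intron.sequence is None:
            raise ValueError(f"intron {intron.name} has no attached sequence")
        if "N" in intron.sequence:
            continue
        structure = fold_hairpin(intron.sequence, min_loop=min_loop)
        features = extract_features(structure)
        candidates.append(
            MirtronCandidate(
                intron=intron,
                structure=structure,
                features=features,
                structure_score=score_mirtron_structure(features, score_params),
                splice=count_splice_reads(intron, index, buffer),
            )
        )
    return rank_candidates(candidates)


def extended_length_screen(
    introns: Iterable[IntronCandidate],
    alignments: Sequence[ReadAlignment] | SpliceEndIndex,
    bounds: Tuple[int, int] = EXTENDED_LENGTH_BOUNDS,
    **kwargs,
) -> List[MirtronCandidate]:
    """Run the same screen on the longer-intron extension window."""
    return screen_introns(introns, alignments, bounds=bounds, **kwargs)


def candidates_to_frame(candidates: Sequence[MirtronCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "seq_id": c.intron.seq_id,
                "start": c.intron.start,
                "end": c.intron.end,
                "strand": c.intron.strand,
                "length": c.intron.length,
                "structure_score": round(c.structure_score, 6),
                "dotbracket": c.structure.dotbracket,
                "n5": c.splice.n5,
                "n3": c.splice.n3,
                "total": c.splice.total,
                "unique5": c.splice.unique5,
                "unique3": c.splice.unique3,
                "distinct5": c.splice.distinct5,
                "distinct3": c.splice.distinct3,
                "rank_structure": c.rank_structure,
                "rank_reads": c.rank_reads,
                "rank_combined": c.rank_combined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "start", "end", "strand", "length", "structure_score",
            "dotbracket", "n5", "n3", "total", "unique5", "unique3",
            "distinct5", "distinct3", "rank_structure", "rank_reads",
            "rank_combined",
        ],
    )


def write_screen_tsv(candidates: Sequence[MirtronCandidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def write_topk_bed(
    candidates: Sequence[MirtronCandidate], path: str | Path, k: int = 5
) -> None:
    """BED6 of the top-k candidates of the combined ranking."""
    top = sorted(candidates, key=lambda c: c.rank_combined)[:k]
    with open(path, "w") as fh:
        for c in top:
            i = c.intron
            fh.write(f"{i.seq_id}\t{i.start - 1}\t{i.end}\t{i.name}\t{c.splice.total}\t{i.strand}\n")
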