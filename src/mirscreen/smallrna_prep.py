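"""Raw small-RNA read preparation: 3' adapter trimming, filtering, collapsing.

The default adapter is the Illumina small-RNA 3' adapter used in 36-cycle
single-read runs (``ATCTCGTATGCCGTCTTCTGCTTGT``); raw reads carry the insert
followed by as much of the adapter as fits the read length.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from Bio import SeqIO

DEFAULT_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTGT"

# Sanger/Illumina-1.8 FASTQ tops out around Q41; anything far above that is
# a sign of a Phred+64 file decoded with the wrong offset.
_MAX_SANE_PHRED = 45


@dataclass(frozen=True)
class SmallRead:
    """A (possibly collapsed) small-RNA read; count is multiplicity >= 1."""

    read_id: str
    sequence: str
    qualities: Optional[tuple] = None  # per-base Phred scores, or None
    count: int = 1

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length != sequence length")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class TrimParams:
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 5
    max_mismatch_fraction: float = 0.1
    min_len: int = 18
    max_len: int = 26
    min_mean_quality: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap <= len(self.adapter)):
            raise ValueError("min_overlap must be in (0, adapter length]")


def read_fastq(path: str | Path) -> List[SmallRead]:
    """Read a Phred+33 FASTQ file; other encodings are rejected."""
    reads: List[SmallRead] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        if quals and max(quals) > _MAX_SANE_PHRED:
            raise ValueError(
                f"read {rec.id!r} has Phred score {max(quals)} > {_MAX_SANE_PHRED}: "
                "input does not look like Phred+33; re-encode before processing"
            )
        reads.append(SmallRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapter(read: SmallRead, params: TrimParams) -> SmallRead:
    """Remove the leftmost 3' adapter occurrence from a read.

    Scans left to right for a position where the remainder of the read matches
    a prefix of the adapter (or a full internal adapter copy) with mismatch
    fraction <= ``max_mismatch_fraction`` and overlap >= ``min_overlap``.
    Reads without an adapter-compatible suffix pass through unchanged.
    """
    seq = read.sequence
    if not seq:
        raise ValueError("empty read")
    adapter = params.adapter.upper()
    for p in range(0, len(seq) - params.min_overlap + 1):
        olap = min(len(seq) - p, len(adapter))
        mm = _mismatches(seq[p : p + olap], adapter[:olap])
        if mm <= params.max_mismatch_fraction * olap:
            quals = read.qualities[:p] if read.qualities is not None else None
            return replace(read, sequence=seq[:p], qualities=quals)
    return read


def quality_length_filter(
    reads: Iterable[SmallRead], params: TrimParams
) -> List[SmallRead]:
    """Keep reads in the length window with mean Phred >= threshold and no N."""
    kept: List[SmallRead] = []
    for r in reads:
        n = len(r.sequence)
        if not (params.min_len <= n <= params.max_len):
            continue
        if "N" in r.sequence:
            continue
        if r.qualities:
            if sum(r.qualities) / len(r.qualities) < params.min_mean_quality:
                continue
        kept.append(r)
    return kept


def remove_contaminants(
    reads: Iterable[SmallRead],
    blocklist: Sequence[str],
    max_mismatches: int = 1,
) -> List[SmallRead]:
    """Drop reads matching any blocklist sequence (e.g. a known rRNA fragment).

    A read is dropped if it occurs as a substring of a blocklist sequence with
    at most ``max_mismatches`` substitutions. The blocklist is an optional
    input: contaminant transcripts differ between libraries.
    """
    targets = [b.upper().replace("U", "T") for b in blocklist]
    kept = []
    for r in reads:
        seq = r.sequence
        hit = False
        for t in targets:
            for p in range(0, len(t) - len(seq) + 1):
                if _mismatches(seq, t[p : p + len(seq)]) <= max_mismatches:
                    hit = True
                    break
            if hit:
                break
        if not hit:
            kept.append(r)
    return kept


def read_blocklist_fasta(path: str | Path) -> List[str]:
    return [str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path), "fasta")]


def collapse_reads(reads: Iterable[SmallRead]) -> List[SmallRead]:
    """Collapse identical sequences to one record with its multiplicity.

    Output order is deterministic: descending count, then lexicographic
    sequence. Qualities are dropped (they are per-copy, not per-sequence).
    """
    counts: Counter = Counter()
    for r in reads:
        counts[r.sequence] += r.count
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRead(f"seq{i}_x{c}", seq, None, c)
        for i, (seq, c) in enumerate(ordered, start=1)
    ]


def write_collapsed_fasta(reads: Iterable[SmallRead], path: str | Path) -> None:
    """Write collapsed reads with the multiplicity embedded as ``id_xN``."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_collapsed_tsv(reads: Iterable[SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for r in reads:
            fh.write(f"{r.sequence}\t{r.count}\n")


def read_collapsed_tsv(path: str | Path) -> List[SmallRead]:
    reads: List[SmallRead] = []
    with open(path) as fh:
        header = fh.readline()
        for i, line in enumerate(fh, start=1):
            seq, count = line.rstrip("\n").split("\t")
            reads.append(SmallRead(f"seq{i}_x{count}", seq, None, int(count)))
    return reads


def prepare_reads(
    raw_reads: Iterable[SmallRead],
    params: TrimParams,
    blocklist: Sequence[str] = (),
) -> Dict[str, object]:
    """Run trim -> quality/length filter -> contaminant removal -> collapse.

    Returns a dict with the collapsed reads and per-stage counts for the
    run summary.
    """
    raw = list(raw_reads)
    trimmed = [trim_adapter(r, params) for r in raw]
    filtered = quality_length_filter(trimmed, params)
    if blocklist:
        clean = remove_contaminants(filtered, blocklist)
    else:
        clean = list(filtered)
    collapsed = collapse_reads(clean)
    return {
        "collapsed": collapsed,
        "n_raw": len(raw),
        "n_trimmed": len(trimmed),
        "n_filtered": len(filtered),
        "n_clean": len(clean),
        "n_distinct": len(collapsed),
    }
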