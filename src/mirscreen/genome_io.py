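"""Genome and annotation input: FASTA scaffolds, GFF3 exons, intron derivation.

Coordinates are 1-based inclusive throughout the library, matching the
convention in which candidate loci are reported (e.g. ``scaffold:40399-40490``).
BED exports convert to 0-based half-open on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

import gffutils

# IUPAC nucleotide codes accepted on input; ambiguity codes other than N are
# normalised to N (they cannot base-pair deterministically downstream).
_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIG = set("RYSWKMBDHV")


@dataclass(frozen=True)
class GenomeSequence:
    """A single genome scaffold with normalised residues (A/C/G/T/N)."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonRecord:
    """One exon feature, grouped into transcripts via ``transcript_id``."""

    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"exon start > end ({self.start} > {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class IntronCandidate:
    """A strand-aware spliced intron; the unit of the mirtron screen.

    ``donor_pos`` / ``acceptor_pos`` are the genomic coordinates of the intron
    bases adjacent to the upstream and downstream exon in *transcript*
    orientation: on '+' the donor is ``start``, on '-' it is ``end``.
    ``sequence``, when attached, is the spliced-out RNA 5'->3'.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    sequence: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def name(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}({self.strand})"


def _normalise_residues(seq_id: str, raw: str) -> str:
    s = raw.upper().replace("U", "T")
    bad = set(s) - _IUPAC - {"T"}
    if bad:
        raise ValueError(
            f"non-IUPAC character(s) {sorted(bad)} in record {seq_id!r}"
        )
    if set(s) & _AMBIG:
        s = "".join("N" if c in _AMBIG else c for c in s)
    return s


def read_genome(fasta_path: str | Path) -> Dict[str, GenomeSequence]:
    """Read a genome FASTA into a dict keyed by sequence id.

    Residues are uppercased, U converted to T, and IUPAC ambiguity codes
    collapsed to N. Duplicate ids and non-IUPAC characters are hard errors.
    """
    genome: Dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {fasta_path}")
        genome[rec.id] = GenomeSequence(rec.id, _normalise_residues(rec.id, str(rec.seq)))
    return genome


def read_exons_gff3(gff3_path: str | Path) -> List[ExonRecord]:
    """Parse exon features from a GFF3 file, grouping by the Parent attribute."""
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    exons: List[ExonRecord] = []
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent")
        if not parents:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks a Parent attribute"
            )
        for parent in parents:
            exons.append(
                ExonRecord(feat.seqid, feat.start, feat.end, feat.strand, parent)
            )
    return exons


def derive_introns(exons: Sequence[ExonRecord]) -> List[IntronCandidate]:
    """Derive introns from exons: one per adjacent exon pair per transcript.

    Exons are sorted by coordinate within each transcript; the intron is the
    gap between consecutive exons. Introns shared between isoforms are
    collapsed on (seq_id, start, end, strand). Overlapping exons within one
    transcript are a hard error; a zero-length gap simply emits no intron.
    """
    by_tx: Dict[str, List[ExonRecord]] = {}
    for ex in exons:
        by_tx.setdefault(ex.transcript_id, []).append(ex)

    seen = set()
    introns: List[IntronCandidate] = []
    for tx_id, tx_exons in by_tx.items():
        ordered = sorted(tx_exons, key=lambda e: (e.start, e.end))
        for a, b in zip(ordered, ordered[1:]):
            if a.seq_id != b.seq_id or a.strand != b.strand:
                raise ValueError(f"transcript {tx_id!r} spans sequences or strands")
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping exons in transcript {tx_id!r}: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )
            if b.start == a.end + 1:
                continue  # zero-length gap: no intron
            key = (a.seq_id, a.end + 1, b.start - 1, a.strand)
            if key in seen:
                continue
            seen.add(key)
            introns.append(IntronCandidate(a.seq_id, a.end + 1, b.start - 1, a.strand))
    introns.sort(key=lambda i: (i.seq_id, i.start, i.end, i.strand))
    return introns


def attach_sequence(
    intron: IntronCandidate, genome: Dict[str, GenomeSequence]
) -> IntronCandidate:
    """Attach the intron's RNA sequence (5'->3' in transcript orientation)."""
    if intron.seq_id not in genome:
        raise KeyError(f"unknown sequence {intron.seq_id!r}")
    scaffold = genome[intron.seq_id]
    if intron.start < 1 or intron.end > scaffold.length:
        raise ValueError(
            f"intron {intron.name} outside sequence bounds (1-{scaffold.length})"
        )
    dna = scaffold.residues[intron.start - 1 : intron.end]
    if intron.strand == "-":
        dna = str(Seq(dna).reverse_complement())
    return replace(intron, sequence=dna.replace("T", "U"))


def filter_by_length(
    introns: Iterable[IntronCandidate], min_len: int, max_len: int
) -> List[IntronCandidate]:
    """Keep introns with min_len <= length <= max_len (both bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [i for i in introns if min_len <= i.length <= max_len]


def write_intron_bed(
    introns: Iterable[IntronCandidate], path: str | Path
) -> None:
    """Write intron candidates as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for i in introns:
            fh.write(
                f"{i.seq_id}\t{i.start - 1}\t{i.end}\t{i.name}\t0\t{i.strand}\n"
            )
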