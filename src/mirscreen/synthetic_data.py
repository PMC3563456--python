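"""Synthetic genomes, annotations and small-RNA libraries with planted truth.

The generator emulates the structure of a two-sample 36-cycle small-RNA
sequencing experiment over a multi-gene genome:

* genes with exon/intron structure; most introns are random ("decoy")
  sequence drawn from a length spectrum spanning the 50-150 nt screening
  windows and beyond;
* a minority of introns are planted mirtrons: a GC-rich stem, a short
  terminal loop, the reverse-complement stem, and a 2-nt 3' overhang, so the
  spliced intron folds directly into a pre-miRNA-like hairpin whose arms
  abut the splice sites;
* intergenic canonical miRNA-like hairpin loci whose mature/star arms emit
  read stacks with Dicer-like geometry (duplex partner, 2-nt 3' overhang);
* scatter-decoy hairpin loci whose reads are spread uniformly (the
  "atypical signature" control);
* background noise: random genomic fragments (degradation-like) and
  fragments of an rRNA-like contaminant transcript that is absent from the
  genome assembly;
* every raw read is the insert followed by the 3' adapter, truncated to
  exactly 36 nt, with Phred+33 qualities.

All outputs are deterministic functions of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import ExonRecord, GenomeSequence
from .read_mapper import revcomp
from .smallrna_prep import DEFAULT_ADAPTER, SmallRead

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment."""

    n_planted_mirtrons: int = 20
    n_decoy_introns: int = 2000
    n_planted_canonical: int = 8
    n_scatter_decoys: int = 8
    exons_per_gene: int = 4
    exon_length_range: Tuple[int, int] = (100, 220)
    decoy_intron_range: Tuple[int, int] = (50, 150)
    long_intron_fraction: float = 0.2  # decoys beyond the screen windows
    long_intron_range: Tuple[int, int] = (151, 400)
    mirtron_length_range: Tuple[int, int] = (70, 110)
    mirtron_loop_range: Tuple[int, int] = (6, 10)
    stem_gc: float = 0.6
    reads_per_expressed_locus: float = 20.0
    star_rate: float = 0.2  # star reads per mature read
    loop_rate: float = 0.02
    background_read_count: int = 2000
    rrna_contaminant_fraction: float = 0.15
    low_quality_fraction: float = 0.02
    sample_specific_fraction: float = 0.0
    read_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    seed: int = 1


@dataclass(frozen=True)
class PlantedLocus:
    """One entry of the truth ledger (genomic 1-based inclusive intervals)."""

    kind: str  # 'mirtron' | 'canonical' | 'scatter_decoy' | 'decoy_intron'
    locus_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    mature_start: int = 0
    mature_end: int = 0
    star_start: int = 0
    star_end: int = 0
    expression: float = 0.0
    samples: Tuple[str, ...] = ()

    @property
    def mature_five_prime(self) -> int:
        return self.mature_start if self.strand == "+" else self.mature_end

    @property
    def star_three_prime(self) -> int:
        return self.star_end if self.strand == "+" else self.star_start


@dataclass
class SimTruth:
    config: SimConfig
    loci: List[PlantedLocus]
    rrna_sequence: str

    def of_kind(self, kind: str) -> List[PlantedLocus]:
        return [l for l in self.loci if l.kind == kind]


def _rand_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mirtron_intron(rng: np.random.Generator, length: int, cfg: SimConfig) -> Tuple[str, int]:
    """Hairpin-forming intron sequence: stem + loop + revcomp(stem) + 2-nt
    3' overhang. Returns (sequence, stem length)."""
    loop = int(rng.integers(cfg.mirtron_loop_range[0], cfg.mirtron_loop_range[1] + 1))
    if (length - loop - 2) % 2 == 1:
        loop += 1
    stem = (length - loop - 2) // 2
    arm = _rand_dna(rng, stem, gc=cfg.stem_gc)
    loop_seq = _rand_dna(rng, loop, gc=0.3)
    overhang = _rand_dna(rng, 2)
    return arm + loop_seq + revcomp(arm) + overhang, stem


def _hairpin_locus_seq(rng: np.random.Generator, cfg: SimConfig) -> Dict[str, object]:
    """Canonical-style hairpin with flanks; local coordinates are 1-based.

    Mature arm = first 22 nt of the 5' stem arm; star arm = its duplex
    partner extended by the 2-nt 3' overhang.
    """
    flank5, flank3 = 5, 5
    stem, loop = 30, 8
    arm = _rand_dna(rng, stem, gc=cfg.stem_gc)
    seq = (
        _rand_dna(rng, flank5)
        + arm
        + _rand_dna(rng, loop, gc=0.3)
        + revcomp(arm)
        + _rand_dna(rng, 2)
        + _rand_dna(rng, flank3)
    )
    # stem position t (1..stem) on the 5' arm sits at flank5+t and pairs with
    # flank5 + stem + loop + (stem - t + 1)
    def partner(t: int) -> int:
        return flank5 + stem + loop + (stem - t + 1)

    mature = (flank5 + 1, flank5 + 22)  # stem t = 1..22
    star = (partner(22), partner(1) + 2)  # duplex partner + 2-nt 3' overhang
    return {"seq": seq, "mature": mature, "star": star}


def generate_genome(
    config: SimConfig,
) -> Tuple[Dict[str, GenomeSequence], List[ExonRecord], SimTruth]:
    """Build the genome, exon annotation and truth ledger.

    Genes are laid out sequentially on a handful of scaffolds with random
    strands; planted mirtrons replace randomly chosen introns; canonical and
    scatter-decoy hairpin loci are placed in intergenic space.
    """
    rng = np.random.default_rng(config.seed)
    n_introns = config.n_planted_mirtrons + config.n_decoy_introns
    introns_per_gene = max(1, config.exons_per_gene - 1)
    n_genes = -(-n_introns // introns_per_gene)  # ceil
    if config.exons_per_gene < 2 and config.n_planted_mirtrons + config.n_decoy_introns > 0:
        raise ValueError("need at least 2 exons per gene to carry introns")

    # which intron slots carry planted mirtrons
    mirtron_slots = set(
        rng.choice(n_introns, size=config.n_planted_mirtrons, replace=False).tolist()
    )

    n_scaffolds = max(1, n_genes // 40)
    genes_per_scaffold = -(-n_genes // n_scaffolds)

    scaffolds: Dict[str, str] = {}
    exons: List[ExonRecord] = []
    loci: List[PlantedLocus] = []
    intron_slot = 0
    gene_idx = 0

    intergenic_sites: List[Tuple[str, int]] = []  # (seq_id, offset in parts)

    for s in range(n_scaffolds):
        sid = f"scf{s + 1:03d}"
        parts: List[str] = [_rand_dna(rng, int(rng.integers(150, 400)))]
        pos = len(parts[0])
        for _ in range(genes_per_scaffold):
            if gene_idx >= n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            tx_id = f"tx{gene_idx + 1:05d}"
            gene_exon_intervals: List[Tuple[int, int]] = []
            gene_parts: List[str] = []
            gpos = pos
            intron_meta: List[Optional[Tuple[int, int, int]]] = []  # (start,end,stem)
            for e in range(config.exons_per_gene):
                elen = int(
                    rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1)
                )
                gene_parts.append(_rand_dna(rng, elen))
                gene_exon_intervals.append((gpos + 1, gpos + elen))
                gpos += elen
                if e < config.exons_per_gene - 1 and intron_slot < n_introns:
                    if intron_slot in mirtron_slots:
                        ilen = int(
                            rng.integers(
                                config.mirtron_length_range[0],
                                config.mirtron_length_range[1] + 1,
                            )
                        )
                        iseq, stem = _mirtron_intron(rng, ilen, config)
                        if strand == "-":
                            iseq = revcomp(iseq)
                        gene_parts.append(iseq)
                        intron_meta.append((gpos + 1, gpos + len(iseq), stem))
                    else:
                        if rng.random() < config.long_intron_fraction:
                            lo, hi = config.long_intron_range
                        else:
                            lo, hi = config.decoy_intron_range
                        ilen = int(rng.integers(lo, hi + 1))
                        gene_parts.append(_rand_dna(rng, ilen))
                        intron_meta.append(None)
                        loci.append(
                            PlantedLocus(
                                "decoy_intron",
                                f"decoy{intron_slot + 1:05d}",
                                sid,
                                gpos + 1,
                                gpos + ilen,
                                strand,
                            )
                        )
                    gpos += ilen if intron_meta[-1] is None else (
                        intron_meta[-1][1] - intron_meta[-1][0] + 1
                    )
                    intron_slot += 1
            for mi, meta in enumerate(intron_meta):
                if meta is None:
                    continue
                istart, iend, stem = meta
                # mature arm abuts the donor, star arm ends at the acceptor
                arm_len = min(22, stem)
                if strand == "+":
                    mature = (istart, istart + arm_len - 1)
                    star = (iend - arm_len - 1, iend)
                else:
                    mature = (iend - arm_len + 1, iend)
                    star = (istart, istart + arm_len + 1)
                loci.append(
                    PlantedLocus(
                        "mirtron",
                        f"mirtron{len([l for l in loci if l.kind == 'mirtron']) + 1:03d}",
                        sid,
                        istart,
                        iend,
                        strand,
                        mature[0],
                        mature[1],
                        star[0],
                        star[1],
                    )
                )
            for a, b in gene_exon_intervals:
                exons.append(ExonRecord(sid, a, b, strand, tx_id))
            parts.append("".join(gene_parts))
            spacer = _rand_dna(rng, int(rng.integers(200, 450)))
            intergenic_sites.append((sid, gpos + len(spacer) // 2))
            parts.append(spacer)
            pos = gpos + len(spacer)
            gene_idx += 1
        scaffolds[sid] = "".join(parts)

    # place canonical and scatter-decoy hairpin loci in intergenic spacers
    n_hairpins = config.n_planted_canonical + config.n_scatter_decoys
    if n_hairpins > len(intergenic_sites):
        raise ValueError("not enough intergenic space for the requested hairpin loci")
    site_idx = rng.choice(len(intergenic_sites), size=n_hairpins, replace=False)
    muts: Dict[str, List[Tuple[int, str, PlantedLocus]]] = {}
    for h, si in enumerate(sorted(site_idx.tolist())):
        sid, centre = intergenic_sites[si]
        hp = _hairpin_locus_seq(rng, config)
        seq = hp["seq"]
        strand = "+" if rng.random() < 0.5 else "-"
        gseq = seq if strand == "+" else revcomp(seq)
        start = centre - len(seq) // 2
        end = start + len(seq) - 1

        def g(local: int) -> int:
            return start + local - 1 if strand == "+" else end - local + 1

        m_lo, m_hi = hp["mature"]
        s_lo, s_hi = hp["star"]
        kind = "canonical" if h < config.n_planted_canonical else "scatter_decoy"
        locus = PlantedLocus(
            kind,
            f"{kind}{h + 1:03d}",
            sid,
            start,
            end,
            strand,
            min(g(m_lo), g(m_hi)),
            max(g(m_lo), g(m_hi)),
            min(g(s_lo), g(s_hi)),
            max(g(s_lo), g(s_hi)),
        )
        muts.setdefault(sid, []).append((start, gseq, locus))

    for sid, entries in muts.items():
        s = list(scaffolds[sid])
        for start, gseq, locus in entries:
            s[start - 1 : start - 1 + len(gseq)] = list(gseq)
            loci.append(locus)
        scaffolds[sid] = "".join(s)

    # per-locus expression levels (shared by both samples)
    mean = config.reads_per_expressed_locus
    out_loci: List[PlantedLocus] = []
    for l in loci:
        if l.kind in ("mirtron", "canonical", "scatter_decoy"):
            expr = float(mean * rng.uniform(0.6, 1.4))
            out_loci.append(replace(l, expression=expr))
        else:
            out_loci.append(l)

    # sample assignment: a configurable fraction expressed in only one sample
    assigned: List[PlantedLocus] = []
    for l in out_loci:
        if l.kind in ("mirtron", "canonical", "scatter_decoy"):
            if rng.random() < config.sample_specific_fraction:
                samples = ("sample1",) if rng.random() < 0.5 else ("sample2",)
            else:
                samples = ("sample1", "sample2")
            assigned.append(replace(l, samples=samples))
        else:
            assigned.append(l)

    rrna = _rand_dna(rng, 120, gc=0.55)
    genome = {sid: GenomeSequence(sid, s) for sid, s in scaffolds.items()}
    return genome, exons, SimTruth(config, assigned, rrna)


def _emit_read(
    rng: np.random.Generator,
    genome: Dict[str, GenomeSequence],
    sid: str,
    five_prime: int,
    strand: str,
    length: int,
) -> Optional[str]:
    """Transcript-orientation insert sequence for a read with the given
    genomic 5' end, or None when it would run off the scaffold."""
    s = genome[sid].residues
    if strand == "+":
        start, end = five_prime, five_prime + length - 1
    else:
        start, end = five_prime - length + 1, five_prime
    if start < 1 or end > len(s):
        return None
    frag = s[start - 1 : end]
    return frag if strand == "+" else revcomp(frag)


def simulate_reads(
    truth: SimTruth,
    genome: Dict[str, GenomeSequence],
    sample_id: str,
    seed: Optional[int] = None,
) -> List[SmallRead]:
    """Simulate one raw FASTQ-ready read set for ``sample_id``.

    Expressed loci emit mature-arm reads (5' ends within +/-1 nt of the arm
    start, counts Poisson at the locus expression), star reads at
    ``star_rate`` of the mature rate anchored at the star arm 3' end, and
    rare loop reads. Background reads come from random genome positions and
    from the rRNA-like contaminant. Every raw read is insert + adapter
    truncated to the configured read length.
    """
    cfg = truth.config
    if seed is None:
        sample_index = {"sample1": 1, "sample2": 2}.get(sample_id, 3)
        seed = (cfg.seed * 1000003 + sample_index) % (2**31)
    rng = np.random.default_rng(seed)
    inserts: List[str] = []

    for locus in truth.loci:
        if locus.kind == "decoy_intron":
            continue
        if locus.samples and sample_id not in locus.samples:
            continue
        expr = locus.expression
        if locus.kind == "scatter_decoy":
            n = rng.poisson(expr)
            for _ in range(n):
                length = int(rng.integers(20, 25))
                local = int(rng.integers(0, locus.end - locus.start - length + 1))
                fp = (
                    locus.start + local
                    if locus.strand == "+"
                    else locus.end - local
                )
                ins = _emit_read(rng, genome, locus.seq_id, fp, locus.strand, length)
                if ins:
                    inserts.append(ins)
            continue
        # mature stack: tight 5' ends at the mature arm start
        n_mature = rng.poisson(expr)
        sign = 1 if locus.strand == "+" else -1
        for _ in range(n_mature):
            jitter = int(rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1]))
            fp = locus.mature_five_prime + sign * jitter
            length = int(rng.integers(20, 25))
            ins = _emit_read(rng, genome, locus.seq_id, fp, locus.strand, length)
            if ins:
                inserts.append(ins)
        # star stack: 3' ends at the star arm 3' end (acceptor for mirtrons)
        n_star = rng.poisson(expr * cfg.star_rate)
        for _ in range(n_star):
            jitter = int(rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1]))
            tp = locus.star_three_prime + sign * jitter
            length = int(rng.integers(20, 25))
            fp = tp - sign * (length - 1)
            ins = _emit_read(rng, genome, locus.seq_id, fp, locus.strand, length)
            if ins:
                inserts.append(ins)
        # rare loop fragments
        n_loop = rng.poisson(expr * cfg.loop_rate)
        mid = (locus.start + locus.end) // 2
        for _ in range(n_loop):
            ins = _emit_read(
                rng, genome, locus.seq_id, mid, locus.strand, int(rng.integers(18, 23))
            )
            if ins:
                inserts.append(ins)

    sids = sorted(genome)
    lengths = np.array([genome[s].length for s in sids], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(cfg.background_read_count):
        if rng.random() < cfg.rrna_contaminant_fraction:
            length = int(rng.integers(18, 31))
            p = int(rng.integers(0, len(truth.rrna_sequence) - length + 1))
            inserts.append(truth.rrna_sequence[p : p + length])
        else:
            sid = sids[int(rng.choice(len(sids), p=probs))]
            length = int(rng.integers(18, 31))
            strand = "+" if rng.random() < 0.5 else "-"
            s = genome[sid].residues
            start = int(rng.integers(1, len(s) - length + 1))
            frag = s[start - 1 : start + length - 1]
            inserts.append(frag if strand == "+" else revcomp(frag))

    reads: List[SmallRead] = []
    for i, ins in enumerate(inserts):
        raw = (ins + cfg.adapter * 3)[: cfg.read_length]
        if rng.random() < cfg.low_quality_fraction:
            quals = tuple(int(q) for q in rng.integers(5, 16, size=len(raw)))
        else:
            quals = tuple(int(q) for q in rng.integers(34, 41, size=len(raw)))
        reads.append(SmallRead(f"{sample_id}_r{i + 1:06d}", raw, quals))
    return reads


def generate_two_samples(
    config: SimConfig,
) -> Tuple[Dict[str, GenomeSequence], List[ExonRecord], SimTruth, Dict[str, List[SmallRead]]]:
    """Genome + annotation + truth + two read sets with independent noise."""
    genome, exons, truth = generate_genome(config)
    samples = {
        sample_id: simulate_reads(truth, genome, sample_id)
        for sample_id in ("sample1", "sample2")
    }
    return genome, exons, truth, samples


# ---------------------------------------------------------------------------
# plain-text writers (all deterministic given the config seed)

def write_genome_fasta(genome: Dict[str, GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(genome):
            fh.write(f">{sid}\n")
            res = genome[sid].residues
            for i in range(0, len(res), 70):
                fh.write(res[i : i + 70] + "\n")


def write_gff3(exons: Sequence[ExonRecord], path: str | Path) -> None:
    by_tx: Dict[str, List[ExonRecord]] = {}
    for ex in exons:
        by_tx.setdefault(ex.transcript_id, []).append(ex)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(by_tx):
            exs = sorted(by_tx[tx], key=lambda e: e.start)
            lo, hi = exs[0].start, exs[-1].end
            sid, strand = exs[0].seq_id, exs[0].strand
            fh.write(f"{sid}\tsim\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\tID={tx}\n")
            for i, e in enumerate(exs, start=1):
                fh.write(
                    f"{sid}\tsim\texon\t{e.start}\t{e.end}\t.\t{strand}\t.\t"
                    f"ID={tx}.exon{i};Parent={tx}\n"
                )


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "kind\tlocus_id\tseq_id\tstart\tend\tstrand\tmature_start\tmature_end"
            "\tstar_start\tstar_end\texpression\tsamples\n"
        )
        for l in truth.loci:
            fh.write(
                f"{l.kind}\t{l.locus_id}\t{l.seq_id}\t{l.start}\t{l.end}\t{l.strand}"
                f"\t{l.mature_start}\t{l.mature_end}\t{l.star_start}\t{l.star_end}"
                f"\t{l.expression:.3f}\t{','.join(l.samples)}\n"
            )


def write_fastq(reads: Sequence[SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in (r.qualities or ()))
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
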