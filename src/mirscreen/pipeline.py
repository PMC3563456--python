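"""End-to-end orchestration: trim -> filter -> collapse -> map -> screens ->
classification -> summary report.

Every stage is also runnable on its own saved intermediates through the CLI;
this module holds the shared plumbing and the deterministic report writer.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import genome_io, mirna_search, mirtron_screen, read_mapper, smallrna_prep
from .genome_io import GenomeSequence, IntronCandidate
from .hairpin import fold_hairpin
from .mirna_search import (
    KnownMature,
    LocusSignature,
    PredictedLocus,
    SignatureThresholds,
)
from .read_mapper import ReadAlignment
from .smallrna_prep import SmallRead, TrimParams

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; every field is echoed into the report header."""

    genome_fasta: str = ""
    gff3: str = ""
    fastq_paths: Dict[str, str] = field(default_factory=dict)  # sample_id -> path
    known_matures_fasta: Optional[str] = None
    blocklist_fasta: Optional[str] = None
    out_dir: str = "mirscreen_out"

    core_bounds: Tuple[int, int] = mirtron_screen.CORE_LENGTH_BOUNDS
    extended_bounds: Tuple[int, int] = mirtron_screen.EXTENDED_LENGTH_BOUNDS
    splice_buffer: int = 3
    max_mismatches: int = 2
    index_k: int = 6
    trim: TrimParams = field(default_factory=TrimParams)
    signature: SignatureThresholds = field(default_factory=SignatureThresholds)
    score: mirtron_screen.StructureScoreParams = field(
        default_factory=mirtron_screen.StructureScoreParams
    )
    min_locus_reads: int = 3
    seed: int = 1

    def header_lines(self) -> List[str]:
        lines = ["# mirscreen run configuration"]
        for key in (
            "genome_fasta", "gff3", "known_matures_fasta", "blocklist_fasta",
            "core_bounds", "extended_bounds", "splice_buffer", "max_mismatches",
            "index_k", "min_locus_reads", "seed",
        ):
            lines.append(f"#   {key} = {getattr(self, key)}")
        for sample, path in sorted(self.fastq_paths.items()):
            lines.append(f"#   fastq[{sample}] = {path}")
        t = self.trim
        lines.append(
            f"#   trim = adapter:{t.adapter} min_overlap:{t.min_overlap} "
            f"max_mismatch_fraction:{t.max_mismatch_fraction} len:[{t.min_len},{t.max_len}] "
            f"min_mean_quality:{t.min_mean_quality}"
        )
        s = self.signature
        lines.append(
            f"#   signature = mature>={s.min_mature_fraction} end_het<={s.max_end_heterogeneity} "
            f"loop<={s.max_loop_fraction}"
        )
        return lines


@dataclass
class SampleResult:
    sample_id: str
    counts: Dict[str, int]
    collapsed: List[SmallRead]
    alignments: List[ReadAlignment]
    mapped_fraction: float
    loci: List[Tuple[str, int, int, str]]


@dataclass
class PipelineResult:
    config: RunConfig
    samples: Dict[str, SampleResult]
    core_candidates: List[mirtron_screen.MirtronCandidate]
    extended_candidates: List[mirtron_screen.MirtronCandidate]
    seed_matches: List[mirna_search.SeedMatch]
    identity_hits: List[mirna_search.IdentityHit]
    signatures: List[LocusSignature]
    consensus: List[PredictedLocus]


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full screen and write all artifacts under ``out_dir``.

    Stage errors abort with the stage name; artifacts written before the
    failure are retained and MANIFEST notes the incompleteness.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    stage = "genome_io"
    try:
        t0 = _stage(stage)
        genome = genome_io.read_genome(config.genome_fasta)
        exons = genome_io.read_exons_gff3(config.gff3)
        introns = [
            genome_io.attach_sequence(i, genome)
            for i in genome_io.derive_introns(exons)
        ]
        blocklist: List[str] = []
        if config.blocklist_fasta:
            blocklist = smallrna_prep.read_blocklist_fasta(config.blocklist_fasta)
        knowns: List[KnownMature] = []
        if config.known_matures_fasta:
            knowns = mirna_search.load_known_matures(config.known_matures_fasta)

        stage = "smallrna_prep"
        _stage(stage)
        index = read_mapper.build_index(genome, config.index_k)
        samples: Dict[str, SampleResult] = {}
        pooled_alignments: List[ReadAlignment] = []
        genome_lengths = {sid: g.length for sid, g in genome.items()}
        for sample_id in sorted(config.fastq_paths):
            raw = smallrna_prep.read_fastq(config.fastq_paths[sample_id])
            prep = smallrna_prep.prepare_reads(raw, config.trim, blocklist)
            collapsed: List[SmallRead] = prep["collapsed"]  # type: ignore[assignment]
            smallrna_prep.write_collapsed_fasta(collapsed, out / f"{sample_id}.collapsed.fa")
            smallrna_prep.write_collapsed_tsv(collapsed, out / f"{sample_id}.collapsed.tsv")
            written += [out / f"{sample_id}.collapsed.fa", out / f"{sample_id}.collapsed.tsv"]

            stage = "read_mapper"
            alignments = read_mapper.map_collapsed_reads(
                collapsed, index, config.max_mismatches
            )
            read_mapper.write_alignments_tsv(alignments, out / f"{sample_id}.alignments.tsv")
            written.append(out / f"{sample_id}.alignments.tsv")
            mapped_seqs = {a.read_seq for a in alignments}
            n_clean_total = sum(r.count for r in collapsed)
            mapped_total = sum(r.count for r in collapsed if r.sequence in mapped_seqs)
            mapped_fraction = mapped_total / n_clean_total if n_clean_total else 0.0
            loci = mirna_search.discover_loci(
                alignments,
                min_total=config.min_locus_reads,
                genome_lengths=genome_lengths,
            )
            counts = {
                "n_raw": prep["n_raw"],
                "n_filtered": prep["n_filtered"],
                "n_clean": prep["n_clean"],
                "n_distinct": prep["n_distinct"],
            }
            samples[sample_id] = SampleResult(
                sample_id, counts, collapsed, alignments, mapped_fraction, loci
            )
            pooled_alignments.extend(alignments)

        stage = "mirtron_screen"
        _stage(stage)
        end_index = mirtron_screen.SpliceEndIndex(pooled_alignments)
        core = mirtron_screen.screen_introns(
            introns, end_index, bounds=config.core_bounds,
            buffer=config.splice_buffer, score_params=config.score,
        )
        extended = mirtron_screen.extended_length_screen(
            introns, end_index, bounds=config.extended_bounds,
            buffer=config.splice_buffer, score_params=config.score,
        )
        mirtron_screen.write_screen_tsv(core, out / "mirtrons.core.tsv")
        mirtron_screen.write_screen_tsv(extended, out / "mirtrons.extended.tsv")
        mirtron_screen.write_topk_bed(core, out / "mirtrons.top5.bed", k=5)
        written += [out / "mirtrons.core.tsv", out / "mirtrons.extended.tsv",
                    out / "mirtrons.top5.bed"]

        stage = "mirna_search"
        _stage(stage)
        seed_matches: List[mirna_search.SeedMatch] = []
        identity_hits: List[mirna_search.IdentityHit] = []
        if knowns:
            all_collapsed = [r for s in samples.values() for r in s.collapsed]
            seed_matches = mirna_search.screen_reads_against_matures(
                all_collapsed, knowns
            )
            for known in knowns:
                if len(known.sequence) >= mirna_search.MIN_IDENTITY_RUN:
                    identity_hits.extend(mirna_search.scan_identity(genome, known))
            mirna_search.write_seed_matches_tsv(seed_matches, out / "seed_matches.tsv")
            mirna_search.write_identity_hits_tsv(identity_hits, out / "identity_hits.tsv")
            written += [out / "seed_matches.tsv", out / "identity_hits.tsv"]

        stage = "classify"
        _stage(stage)
        signatures: List[LocusSignature] = []
        predictions_by_sample: Dict[str, List[PredictedLocus]] = {}
        for sample_id, sres in samples.items():
            preds: List[PredictedLocus] = []
            for (sid, lo, hi, strand) in sres.loci:
                length = hi - lo + 1
                if length < 40 or length > 200:
                    continue
                seq = genome[sid].residues[lo - 1 : hi]
                if strand == "-":
                    seq = read_mapper.revcomp(seq)
                if "N" in seq:
                    continue
                structure = fold_hairpin(seq)
                sig = mirna_search.classify_locus(
                    (sid, lo, hi, strand), sres.alignments, structure, config.signature
                )
                signatures.append(sig)
                methods = {"signature"}
                if any(
                    mirna_search.match_mature(a.read_seq, kn)
                    for kn in knowns
                    for a in sres.alignments
                    if a.seq_id == sid and a.strand == strand
                    and a.start <= hi and a.end >= lo
                ):
                    methods.add("homology")
                preds.append(PredictedLocus(sid, lo, hi, strand, frozenset(methods)))
            predictions_by_sample[sample_id] = preds
        consensus: List[PredictedLocus] = []
        if len(predictions_by_sample) >= 2:
            consensus = mirna_search.consensus_filter(
                predictions_by_sample, primary_method="signature"
            )
        mirna_search.write_signatures_tsv(signatures, out / "locus_signatures.tsv")
        written.append(out / "locus_signatures.tsv")

        result = PipelineResult(
            config, samples, core, extended, seed_matches, identity_hits,
            signatures, consensus,
        )
        stage = "report"
        _stage(stage)
        summary = write_summary(result, out / "summary.txt")
        written.append(out / "summary.txt")
        _write_manifest(written, out / "MANIFEST.tsv", complete=True)
        return result
    except Exception as exc:
        _write_manifest(written, out / "MANIFEST.tsv", complete=False, failed_stage=stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(
    files: Sequence[Path], path: Path, complete: bool, failed_stage: str = ""
) -> None:
    with open(path, "w") as fh:
        status = "complete" if complete else f"INCOMPLETE (failed at {failed_stage})"
        fh.write(f"# status: {status}\n")
        fh.write("file\tsha256\n")
        for f in sorted(set(files)):
            if f.exists():
                fh.write(f"{f.name}\t{_sha256(f)}\n")


def write_summary(result: PipelineResult, path: str | Path) -> str:
    """Deterministic plain-text run summary; returns the text written."""
    lines: List[str] = list(result.config.header_lines())
    lines.append("")
    lines.append("== per-sample read accounting ==")
    for sample_id in sorted(result.samples):
        s = result.samples[sample_id]
        c = s.counts
        lines.append(
            f"{sample_id}: raw={c['n_raw']} after_filter={c['n_filtered']} "
            f"after_blocklist={c['n_clean']} distinct={c['n_distinct']} "
            f"mapped_fraction={s.mapped_fraction:.4f}"
        )
    lines.append("")
    lines.append("== mirtron screen ==")
    for label, cands, bounds in (
        ("core", result.core_candidates, result.config.core_bounds),
        ("extended", result.extended_candidates, result.config.extended_bounds),
    ):
        lines.append(f"{label} window {bounds[0]}-{bounds[1]} nt: {len(cands)} candidates")
        for ranking, keyfun in (
            ("structure", lambda c: c.rank_structure),
            ("reads", lambda c: c.rank_reads),
            ("combined", lambda c: c.rank_combined),
        ):
            top = sorted(cands, key=keyfun)[:5]
            for c in top:
                i = c.intron
                lines.append(
                    f"  top-{ranking} #{keyfun(c)}: {i.seq_id}:{i.start}-{i.end}({i.strand}) "
                    f"len={i.length} score={c.structure_score:.4f} "
                    f"n5={c.splice.n5} n3={c.splice.n3}"
                )
    lines.append("")
    lines.append("== canonical miRNA screen ==")
    lines.append(f"seed matches vs known matures: {len(result.seed_matches)}")
    lines.append(f"identity-run hits (>= {mirna_search.MIN_IDENTITY_RUN} nt): {len(result.identity_hits)}")
    for h in result.identity_hits[:5]:
        lines.append(
            f"  {h.seq_id}:{h.start}({h.strand}) run={h.run_length} covers_seed={h.covers_seed}"
        )
    n_pl = sum(1 for s in result.signatures if s.classification == "plausible")
    n_at = len(result.signatures) - n_pl
    lines.append(f"locus signatures: {len(result.signatures)} (plausible={n_pl} atypical={n_at})")
    lines.append(f"consensus-retained loci (all samples): {len(result.consensus)}")
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return text
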