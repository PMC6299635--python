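"""End-to-end orchestration: classify -> call breakpoints -> annotate ->
assemble, streaming the alignment file once.

The single pass keeps only what later stages need — clip pileups, the
read-depth profile, one-end-unmapped mates with their anchors, and
fully-unmapped pairs — so memory scales with the insertion signal rather
than the total read count. Outputs are deterministic for a given config
and inputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import annotate as ann_mod
from . import assemble as asm_mod
from .breakpoints import (Breakpoint, ClipAccumulator, DepthTracker,
                          call_breakpoints, write_breakpoint_tsv)
from .classify import (ANCHORED, ClassifiedPair, PairClass, classify_pair,
                       pair_reads, rescue_distant_pair, write_class_summary)
from .config import PipelineConfig
from .sam_io import parse_alignments, read_fasta, write_fasta, write_gff

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    breakpoints: List[Breakpoint]
    annotations: List[ann_mod.MGEAnnotation]
    contigs: List[asm_mod.Contig]
    inserts: Dict[int, asm_mod.InsertSequence]
    class_counts: Dict[str, int]
    mean_read_length: float
    output_dir: Optional[Path] = None


def _stream_classify(config: PipelineConfig):
    """One pass over the SAM: depth, clips, anchored mates, unmapped pairs."""
    depth = DepthTracker()
    clips = ClipAccumulator(config.min_clip_length)
    support = ann_mod.SupportStore()
    uu_reads: List[Tuple[str, str]] = []
    counts = {pc.value: 0 for pc in PairClass}
    counts["rescued"] = 0
    len_sum = 0
    len_n = 0
    for r1, r2 in pair_reads(parse_alignments(config.sam_path)):
        if len_n < ann_mod.MEAN_READ_LENGTH_SAMPLE:
            len_sum += len(r1.sequence) + len(r2.sequence)
            len_n += 2
        for r in (r1, r2):
            if not r.is_unmapped and r.position is not None:
                if not r.is_duplicate:
                    depth.add_read(r)
                clips.add_read(r)
        pair = rescue_distant_pair(
            classify_pair(r1, r2, config.min_clip_length), config.max_insert)
        counts[pair.pair_class.value] += 1
        if pair.rescued:
            counts["rescued"] += 1
        if pair.pair_class in ANCHORED:
            support.add_pair(pair)
        elif pair.pair_class is PairClass.C6_UU:
            uu_reads.append((r1.query_name + "/1", r1.sequence))
            uu_reads.append((r2.query_name + "/2", r2.sequence))
    mean_rl = len_sum / len_n if len_n else 100.0
    return depth, clips, support, uu_reads, counts, mean_rl


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.time()
    config.validate_inputs()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = read_fasta(config.reference_path)
    library = ann_mod.load_library(read_fasta(config.library_path))

    depth, clips, support, uu_reads, counts, mean_rl = _stream_classify(config)
    logger.info("classified pairs: %s (%.1fs)", counts, time.time() - t0)

    breakpoints = call_breakpoints(clips, depth, reference, config)
    logger.info("breakpoints after filtering: %d", len(breakpoints))

    searcher = ann_mod.HomologySearcher(
        library, match=config.homology_match, mismatch=config.homology_mismatch,
        gap_open=config.homology_gap_open, gap_extend=config.homology_gap_extend)
    annotations = ann_mod.annotate_breakpoints(
        breakpoints, support, library, mean_rl,
        min_identity=config.min_identity,
        min_length_fraction=config.min_length_fraction,
        window=config.support_window, searcher=searcher)

    contigs: List[asm_mod.Contig] = []
    inserts: Dict[int, asm_mod.InsertSequence] = {}
    if config.assemble:
        contigs, inserts = _assembly_phase(config, breakpoints, annotations,
                                           support, uu_reads, library,
                                           mean_rl, searcher)

    _write_outputs(config, outdir, breakpoints, annotations, contigs,
                   inserts, counts)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return PipelineResult(breakpoints, annotations, contigs, inserts,
                          counts, mean_rl, outdir)


def _assembly_phase(config, breakpoints, annotations, support, uu_reads,
                    library, mean_rl, searcher):
    # per-breakpoint one-end-unmapped mates (these also vote for contigs)
    umates: Dict[int, List[Tuple[str, str]]] = {}
    seen = set()
    assembly_reads: List[Tuple[str, str]] = list(uu_reads)
    seen.update(name for name, _ in uu_reads)
    for i, bp in enumerate(breakpoints):
        reads = [(r.query_name, r.sequence)
                 for r in support.near(bp, config.support_window)]
        umates[i] = reads
        for name, seq in reads:
            if name not in seen:
                seen.add(name)
                assembly_reads.append((name, seq))
        for clip in bp.all_clips():
            name = clip.query_name + "/clip"
            if name not in seen:
                seen.add(name)
                assembly_reads.append((name, clip.read_sequence))
    if not assembly_reads:
        return [], {}
    usable = [r for r in assembly_reads if len(r[1]) >= config.kmer_size]
    if not usable:
        logger.warning("no assembly reads reach k=%d; skipping assembly",
                       config.kmer_size)
        return [], {}
    contigs = asm_mod.assemble_contigs(usable, k=config.kmer_size,
                                       min_contig_length=config.min_contig_length)
    logger.info("assembled %d contigs >= %d bp from %d reads",
                len(contigs), config.min_contig_length, len(usable))
    selected = asm_mod.assign_and_select(
        contigs, breakpoints, umates,
        max_alignments_per_read=config.max_alignments_per_read,
        min_read_support=config.min_read_support)
    inserts: Dict[int, asm_mod.InsertSequence] = {}
    for i, contig in sorted(selected.items()):
        bp = breakpoints[i]
        ins = asm_mod.trim_boundaries(
            contig,
            [c.sequence for c in bp.up_clips],
            [c.sequence for c in bp.down_clips],
            breakpoint=bp,
            match=config.trim_match, mismatch=config.trim_mismatch,
            gap_open=config.trim_gap_open, gap_extend=config.trim_gap_extend,
            accept_fraction=config.accept_fraction)
        if ins is None:
            continue
        ins = asm_mod.annotate_contig(ins, library, config.min_identity,
                                      config.min_length_fraction, mean_rl,
                                      searcher)
        inserts[i] = ins
        ann = annotations[i]
        # the contig is derived from more sequence than single reads: it wins
        ann.assembled = True
        ann.insert_id = f"insert_{i + 1}"
        if ins.is_novel:
            if ann.voted_name == "unassigned":
                ann.voted_name = "novel"
                ann.voted_family = "novel"
        else:
            ann.voted_name = ins.mge_name
            ann.voted_family = ins.mge_family
    return contigs, inserts


def _write_outputs(config, outdir: Path, breakpoints, annotations, contigs,
                   inserts, counts):
    write_breakpoint_tsv(breakpoints, outdir / "breakpoints.tsv")
    write_gff(annotations, outdir / "insertions.gff3")
    write_class_summary(counts, outdir / "pair_classes.tsv")
    if config.assemble:
        write_fasta([(c.contig_id, c.sequence) for c in contigs],
                    outdir / "contigs.fa")
        write_fasta([(f"insert_{i + 1}|{ins.contig_id}|{ins.strand}",
                      ins.trimmed_sequence)
                     for i, ins in sorted(inserts.items())],
                    outdir / "inserts.fa")
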