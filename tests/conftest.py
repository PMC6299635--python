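import numpy as np
import pytest

from mgescout.sam_io import AlignedRead, parse_cigar


def make_read(name="r1", flag=0, ref="chr1", pos=100, mapq=60, cigar="100M",
              seq=None, qual=None, mate_ref=None, mate_pos=None, tlen=0):
    """Hand-built alignment record for unit tests."""
    cig = parse_cigar(cigar)
    if seq is None:
        qlen = sum(n for op, n in cig if op in (0, 1, 4, 7, 8)) or 100
        seq = "A" * qlen
    if qual is None:
        qual = "?" * len(seq)
    unmapped = bool(flag & 0x4)
    return AlignedRead(
        query_name=name, flag=flag,
        reference_name=None if unmapped else ref,
        position=None if unmapped else pos,
        mapping_quality=mapq, cigar=[] if unmapped else cig,
        sequence=seq, qualities=qual,
        mate_reference=mate_ref, mate_position=mate_pos,
        template_length=tlen)


def sam_text(records, refs=(("chr1", 100_000),)):
    """Minimal SAM document from mandatory-column tuples or AlignedRead."""
    from mgescout.sam_io import serialize_alignment
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in refs]
    for rec in records:
        lines.append(serialize_alignment(rec) if isinstance(rec, AlignedRead) else rec)
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small end-to-end simulation bundle shared by pipeline-level tests:
    400 kb reference, 18 insertions (6 known / 6 diverged-sister / 6 novel),
    30x coverage."""
    from mgescout.config import PipelineConfig
    from mgescout.pipeline import run_pipeline
    from mgescout.sam_io import write_fasta
    from mgescout.simulate import (build_simulated_genome,
                                   emit_truth_alignments,
                                   simulate_paired_reads,
                                   simulation_set2_config)

    outdir = tmp_path_factory.mktemp("bundle")
    cfg = simulation_set2_config(n_per_group=6, reference_length=400_000,
                                 coverage=30, seed=3)
    genome = build_simulated_genome(cfg)
    readset = simulate_paired_reads(genome)
    sam = outdir / "truth.sam"
    emit_truth_alignments(readset, genome, sam)
    ref_fa = outdir / "ref.fa"
    lib_fa = outdir / "lib.fa"
    write_fasta(genome.reference_fasta(), ref_fa)
    write_fasta(genome.library_fasta(), lib_fa)
    pconf = PipelineConfig(sam_path=str(sam), reference_path=str(ref_fa),
                           library_path=str(lib_fa),
                           output_dir=str(outdir / "out"))
    result = run_pipeline(pconf)
    return {"config": cfg, "genome": genome, "readset": readset,
            "sam": sam, "ref_fa": ref_fa, "lib_fa": lib_fa,
            "pipeline_config": pconf, "result": result, "outdir": outdir}
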