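"""De novo assembly, contig assignment, boundary trimming, novelty calls."""

import pytest

from mgescout.align import revcomp
from mgescout.annotate import MGELibraryEntry
from mgescout.assemble import (Contig, ContigAligner, annotate_contig,
                               assemble_contigs, assign_and_select,
                               collect_assembly_reads, trim_boundaries)
from mgescout.breakpoints import Breakpoint, ClipRecord, DOWN, UP
from mgescout.classify import classify_pair
from mgescout.simulate import mutate

from conftest import make_read, random_seq


def tile_reads(seq, read_length=100, step=10):
    return [(f"t{i}", seq[i:i + read_length])
            for i in range(0, len(seq) - read_length + 1, step)]


class TestAssembleContigs:
    def test_tiling_reads_reassemble_element(self, rng):
        element = random_seq(rng, 600)
        contigs = assemble_contigs(tile_reads(element), k=51)
        assert len(contigs) == 1
        assert element in contigs[0].sequence or \
            element in revcomp(contigs[0].sequence)

    def test_short_insert_filtered(self, rng):
        element = random_seq(rng, 300)
        assert assemble_contigs(tile_reads(element), k=51,
                                min_contig_length=500) == []

    def test_empty_input(self):
        assert assemble_contigs([]) == []

    def test_reads_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            assemble_contigs([("a", "ACGT")], k=51)

    def test_deterministic_under_read_shuffling(self, rng):
        element = random_seq(rng, 700)
        reads = tile_reads(element, step=7)
        ref = [c.sequence for c in assemble_contigs(reads, k=51)]
        for _ in range(3):
            shuffled = [reads[i] for i in rng.permutation(len(reads))]
            assert [c.sequence for c in assemble_contigs(shuffled, k=51)] == ref

    def test_recurrent_error_bubble_is_popped(self, rng):
        # two reads share a sequencing error; the walk must keep the
        # high-coverage path instead of fragmenting at the bubble
        element = random_seq(rng, 800)
        reads = tile_reads(element, step=5)
        bad = list(element[300:400])
        bad[50] = "A" if bad[50] != "A" else "C"
        reads += [("e1", "".join(bad)), ("e2", "".join(bad))]
        contigs = assemble_contigs(reads, k=51)
        assert len(contigs) == 1
        assert element in contigs[0].sequence or \
            element in revcomp(contigs[0].sequence)


class TestCollectAssemblyReads:
    def _bp(self, pos):
        return Breakpoint("chr1", pos, pos, 1, 0, "", "", False, 0.5,
                          up_coordinate=pos,
                          up_clips=[ClipRecord(UP, "ACGTACG", "?" * 7,
                                               "C" * 100, "clipr")])

    def test_uu_pair_contributes_both_mates(self):
        r1 = make_read(name="uu", flag=0x1 | 0x40 | 0x4 | 0x8, seq="A" * 60)
        r2 = make_read(name="uu", flag=0x1 | 0x80 | 0x4 | 0x8, seq="G" * 60)
        out = collect_assembly_reads([classify_pair(r1, r2)], [self._bp(1000)], 500)
        seqs = [s for _, s in out]
        assert "A" * 60 in seqs and "G" * 60 in seqs

    def test_far_anchored_pair_excluded(self):
        r1 = make_read(name="far", flag=0x1 | 0x40, pos=50_000, cigar="100M")
        r2 = make_read(name="far", flag=0x1 | 0x80 | 0x4, seq="T" * 100)
        out = collect_assembly_reads([classify_pair(r1, r2)], [self._bp(1000)], 500)
        assert all(not s.startswith("T" * 50) for _, s in out)

    def test_clip_support_read_included_whole(self):
        out = collect_assembly_reads([], [self._bp(1000)], 500)
        assert ("clipr/clip/0", "C" * 100) in out

    def test_deduplicated_by_name_and_mate(self):
        r1 = make_read(name="uu", flag=0x1 | 0x40 | 0x4 | 0x8, seq="A" * 60)
        r2 = make_read(name="uu", flag=0x1 | 0x80 | 0x4 | 0x8, seq="G" * 60)
        pair = classify_pair(r1, r2)
        out = collect_assembly_reads([pair, pair], [], 500)
        assert len(out) == 2


class TestAssignAndSelect:
    def test_majority_contig_selected(self, rng):
        a = random_seq(rng, 600)
        b = random_seq(rng, 600)
        contigs = [Contig("c1", a), Contig("c2", b)]
        reads = {0: [(f"r{i}", a[i * 40:i * 40 + 100]) for i in range(9)]
                 + [("rb", b[100:200])]}
        selected = assign_and_select(contigs, [None], reads, min_read_support=2)
        assert selected[0].contig_id == "c1"

    def test_weakly_supported_contig_ineligible(self, rng):
        a = random_seq(rng, 600)
        contigs = [Contig("c1", a)]
        reads = {0: [("only", a[100:200])]}
        assert assign_and_select(contigs, [None], reads, min_read_support=2) == {}

    def test_read_counts_toward_at_most_five_contigs(self, rng):
        shared = random_seq(rng, 600)
        contigs = [Contig(f"c{i}", shared + random_seq(rng, 30))
                   for i in range(6)]
        aligner = ContigAligner(contigs)
        hits = aligner.alignments(shared[200:300], max_hits=5)
        assert len(hits) == 5


class TestTrimBoundaries:
    def test_exact_clip_accepted_at_threshold(self, rng):
        clip = "ACGTACGTAC"  # score 10 >= 0.75 * 10
        contig = Contig("c", random_seq(rng, 300) + clip + random_seq(rng, 300))
        ins = trim_boundaries(contig, [clip], [])
        assert ins is not None
        assert ins.trimmed_sequence.startswith(clip)
        assert ins.left_trim_score == 10

    def test_diverged_clip_rejected_below_threshold(self):
        # optimal score 8 < 0.75 * 20 = 15 (three spread mismatches)
        clip = "ACGTACGTACGTACGTACGT"
        sub = list(clip)
        for i in (4, 10, 16):
            sub[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[i]]
        contig = Contig("c", "G" * 100 + "".join(sub) + "G" * 100)
        assert trim_boundaries(contig, [clip], []) is None

    def test_reverse_complement_orientation_reported_once(self, rng):
        insert = random_seq(rng, 500)
        up, down = insert[:60], insert[-60:]
        contig = Contig("c", random_seq(rng, 100) + revcomp(insert)
                        + random_seq(rng, 100))
        ins = trim_boundaries(contig, [up], [down])
        assert ins is not None and ins.strand == "-"
        assert ins.trimmed_sequence == insert

    def test_two_sided_trim_spans_insert_exactly(self, rng):
        insert = random_seq(rng, 700)
        contig = Contig("c", random_seq(rng, 80) + insert + random_seq(rng, 80))
        ins = trim_boundaries(contig, [insert[:90]], [insert[-90:]])
        assert ins.trimmed_sequence == insert and ins.strand == "+"

    def test_no_clips_yields_nothing(self, rng):
        assert trim_boundaries(Contig("c", random_seq(rng, 600)), [], []) is None


class TestAnnotateContig:
    def _insert(self, seq):
        from mgescout.assemble import InsertSequence
        return InsertSequence(None, "c", seq, "+", 0, 0)

    def test_slightly_diverged_copy_identified(self, rng):
        lib = [MGELibraryEntry("L1PA4", "LINE", random_seq(rng, 900))]
        import numpy as np
        diverged = mutate(lib[0].sequence, 0.08, np.random.default_rng(1))
        ins = annotate_contig(self._insert(diverged), lib)
        assert not ins.is_novel and ins.mge_name == "L1PA4"

    def test_random_sequence_is_novel(self, rng):
        lib = [MGELibraryEntry("L1PA4", "LINE", random_seq(rng, 900))]
        ins = annotate_contig(self._insert(random_seq(rng, 800)), lib)
        assert ins.is_novel

    def test_heavily_diverged_copy_is_novel(self, rng):
        # ~15% substitution: expected identity ~0.85 < 0.90
        lib = [MGELibraryEntry("L1PA4", "LINE", random_seq(rng, 900))]
        import numpy as np
        diverged = mutate(lib[0].sequence, 0.20, np.random.default_rng(2))
        ins = annotate_contig(self._insert(diverged), lib)
        assert ins.is_novel
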