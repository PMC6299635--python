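"""Breakpoint filters: candidate formation, profile, zygosity, vicinity
merging, repeat/indel rejection — with a brute-force candidate oracle."""

from collections import defaultdict

import numpy as np
import pytest

from mgescout.breakpoints import (DOWN, UP, Breakpoint, BreakpointCandidate,
                                  ClipAccumulator, ClipRecord, DepthTracker,
                                  build_candidates, call_breakpoints,
                                  collect_candidates, merge_vicinity,
                                  profile_filter, repeat_indel_filter,
                                  zygosity_filter)
from mgescout.config import PipelineConfig
from mgescout.sam_io import clip_segments

from conftest import make_read, random_seq


def reads_with_clip_pileup(coord, side, n_clipped, n_plain, clip_seq="GATTACAGG",
                           qual_char="?", start_name=0):
    """n_clipped reads sharing one clip edge plus n_plain spanning reads."""
    reads = []
    cl = len(clip_seq)
    for i in range(n_clipped):
        if side == UP:   # right clip: alignment ends at coord
            pos = coord - 99
            read = make_read(name=f"c{start_name + i}", pos=pos,
                             cigar=f"100M{cl}S", seq="A" * 100 + clip_seq,
                             qual=qual_char * (100 + cl))
        else:            # left clip: alignment starts at coord
            read = make_read(name=f"c{start_name + i}", pos=coord,
                             cigar=f"{cl}S100M", seq=clip_seq + "A" * 100,
                             qual=qual_char * (100 + cl))
        reads.append(read)
    for i in range(n_plain):
        # long spanning reads so each contributes ~1x across the +/-100 window
        reads.append(make_read(name=f"p{start_name + i}",
                               pos=coord - 150 + (i * 7) % 100, cigar="200M",
                               seq="A" * 200, qual="?" * 200))
    return sorted(reads, key=lambda r: r.position)


def brute_force_candidates(reads, min_clip_length=5):
    """Independent oracle: enumerate every (coordinate, side) clip group."""
    groups = defaultdict(int)
    for read in reads:
        for clip in clip_segments(read):
            if clip.clip_length > min_clip_length:
                side = UP if clip.side == "right" else DOWN
                groups[(clip.clip_coordinate, side)] += 1
    return dict(groups)


class TestCollectCandidates:
    def test_supported_pileup_becomes_candidate(self):
        reads = reads_with_clip_pileup(1050, UP, n_clipped=12, n_plain=18)
        (cand,) = collect_candidates(iter(reads))
        assert cand.coordinate == 1050 and cand.side == UP
        assert cand.upstream_support == 12

    def test_low_support_rejected(self):
        # 2 clipped reads at ~30x: 2 <= 0.10 * 30
        reads = reads_with_clip_pileup(1050, UP, n_clipped=2, n_plain=28)
        assert collect_candidates(iter(reads)) == []

    def test_low_quality_clips_rejected(self):
        reads = reads_with_clip_pileup(1050, UP, n_clipped=12, n_plain=18,
                                       qual_char="#")  # phred 2
        assert collect_candidates(iter(reads)) == []

    def test_unsorted_input_raises(self):
        reads = reads_with_clip_pileup(1050, UP, 12, 18)
        with pytest.raises(ValueError, match="sorted"):
            collect_candidates(iter(reads[::-1]))

    def test_matches_brute_force_oracle_on_mixed_fixture(self, rng):
        reads = []
        reads += reads_with_clip_pileup(2000, UP, 15, 10, start_name=0)
        reads += reads_with_clip_pileup(2006, DOWN, 12, 8, clip_seq="CCATGCATT",
                                        start_name=100)
        reads += reads_with_clip_pileup(5000, UP, 9, 6, clip_seq="TTGACCAAT",
                                        start_name=200)
        reads.sort(key=lambda r: r.position)
        assert len(reads) == 60
        oracle = brute_force_candidates(reads)
        cands = collect_candidates(iter(reads), min_support_fraction=0.0,
                                   min_clip_quality=0)
        ours = {(c.coordinate, c.side): c.support for c in cands}
        assert ours == oracle


class TestProfileFilter:
    def _cand(self, seqs, side=UP):
        clips = [ClipRecord(side, s, "?" * len(s), s, f"r{i}")
                 for i, s in enumerate(seqs)]
        return BreakpointCandidate("chr1", 100, side, clips, 30.0, 30, 63.0)

    def test_identical_clips_pass(self):
        assert profile_filter(self._cand(["ACGTACGTACGTACGTACGT"] * 10))

    def test_random_clips_rejected_almost_always(self, rng):
        accepted = 0
        trials = 500
        for _ in range(trials):
            seqs = [random_seq(rng, 20) for _ in range(10)]
            if profile_filter(self._cand(seqs)):
                accepted += 1
        assert accepted / trials < 0.01  # expected agreement ~0.25

    def test_polya_exemption_with_mismatches(self, rng):
        # noisy poly-A tails: ~10% disagreement would fail the profile,
        # but the A-dominance exemption accepts and flags them
        seqs = []
        for i in range(10):
            s = list("A" * 20)
            s[(i * 3) % 20] = "G"
            seqs.append("".join(s))
        cand = self._cand(seqs)
        assert profile_filter(cand)
        assert cand.polya

    def test_single_clip_passes_vacuously(self):
        assert profile_filter(self._cand(["ACGTACGTAC"]))

    def test_left_clips_profiled_from_the_junction(self):
        # left clips share their junction-proximal suffix, not their prefix
        seqs = [("G" * i) + "ACGTACGTACGTACG" for i in range(2, 8)]
        assert profile_filter(self._cand(seqs, side=DOWN))


class TestZygosityFilter:
    def _cand(self, support, coverage):
        clips = [ClipRecord(UP, "ACGTAC", "??????", "", f"r{i}")
                 for i in range(support)]
        return BreakpointCandidate("chr1", 100, UP, clips, float(coverage),
                                   coverage, 63.0)

    def test_het_mode_accepts_half_ratio(self):
        assert zygosity_filter(self._cand(15, 30), call_heterozygous=True)

    def test_hom_mode_rejects_half_ratio(self):
        assert not zygosity_filter(self._cand(15, 30), call_heterozygous=False)

    def test_full_ratio_passes_both_modes(self):
        assert zygosity_filter(self._cand(30, 30), call_heterozygous=True)
        assert zygosity_filter(self._cand(30, 30), call_heterozygous=False)

    def test_zero_coverage_rejected(self):
        assert not zygosity_filter(self._cand(3, 0))


def _simple_cand(coord, side, support=10, ref="chr1"):
    clips = [ClipRecord(side, "ACGTACGTA", "?" * 9, "", f"{side}{coord}_{i}")
             for i in range(support)]
    return BreakpointCandidate(ref, coord, side, clips, 30.0, 30, 63.0)


class TestMergeVicinity:
    def test_opposite_sides_within_vicinity_merge_to_tsd_interval(self):
        bps = merge_vicinity([_simple_cand(1050, UP), _simple_cand(1057, DOWN)])
        (bp,) = bps
        assert (bp.interval_start, bp.interval_end) == (1050, 1057)
        assert bp.upstream_support == bp.downstream_support == 10

    def test_same_side_pileups_do_not_merge(self):
        bps = merge_vicinity([_simple_cand(1050, UP), _simple_cand(1055, UP)])
        assert len(bps) == 2

    def test_distant_pileups_stay_separate(self):
        bps = merge_vicinity([_simple_cand(1050, UP), _simple_cand(1090, DOWN)])
        assert len(bps) == 2
        assert all(bp.interval_start == bp.interval_end for bp in bps)

    def test_greedy_nearest_pairing_uses_each_candidate_once(self):
        cands = [_simple_cand(100, UP), _simple_cand(103, DOWN),
                 _simple_cand(110, UP)]
        bps = merge_vicinity(cands)
        widths = sorted(bp.width for bp in bps)
        assert len(bps) == 2 and widths == [0, 3]

    def test_interval_width_always_below_vicinity(self, rng):
        cands = []
        for i in range(40):
            coord = int(rng.integers(1000, 2000))
            side = UP if rng.random() < 0.5 else DOWN
            cands.append(_simple_cand(coord, side))
        for bp in merge_vicinity(cands, max_vicinity=25):
            assert bp.width < 25


class TestRepeatIndelFilter:
    def _bp(self, reference, coord, up_consensus="", down_consensus=""):
        return Breakpoint("chr1", coord, coord, 10 if up_consensus else 0,
                          10 if down_consensus else 0, up_consensus,
                          down_consensus, False, 0.5,
                          up_coordinate=coord if up_consensus else None,
                          down_coordinate=coord if down_consensus else None)

    def test_clip_replaying_reference_rejected(self, rng):
        flank = random_seq(rng, 200)
        ref = flank + "ACACACACACAC" + random_seq(rng, 200)
        bp = self._bp(ref, 200, up_consensus="ACACACACACAC")
        assert not repeat_indel_filter(bp, ref)

    def test_foreign_clip_kept(self, rng):
        ref = random_seq(rng, 400)
        bp = self._bp(ref, 200, up_consensus="GATTACAGATTACAG")
        assert repeat_indel_filter(bp, ref)

    def test_depth_cliff_rejected(self, rng):
        ref = random_seq(rng, 400)
        depth = DepthTracker()
        for i in range(30):   # left flank ~30x, right flank ~5x
            depth.add("chr1", 100 + i, 199)
        for i in range(5):
            depth.add("chr1", 201, 300)
        bp = self._bp(ref, 200, up_consensus="GATTACAGATTACAG")
        assert not repeat_indel_filter(bp, ref, depth=depth, depth_imbalance=3.0)

    def test_balanced_depth_kept(self, rng):
        ref = random_seq(rng, 400)
        depth = DepthTracker()
        for i in range(30):
            depth.add("chr1", 100, 300)
        bp = self._bp(ref, 200, up_consensus="GATTACAGATTACAG")
        assert repeat_indel_filter(bp, ref, depth=depth)

    def test_out_of_bounds_breakpoint_raises(self, rng):
        ref = random_seq(rng, 100)
        with pytest.raises(ValueError):
            repeat_indel_filter(self._bp(ref, 500, "ACGTACGTA"), ref)


class TestFilterMonotonicity:
    def test_disabling_any_filter_never_reduces_calls(self, small_bundle):
        """Every emitted breakpoint passed all five stages; switching one
        off can only widen the output."""
        from mgescout.pipeline import _stream_classify
        from mgescout.sam_io import read_fasta

        base = small_bundle["pipeline_config"]
        depth, clips, support, uu, counts, mrl = _stream_classify(base)
        reference = read_fasta(base.reference_path)
        n_base = len(call_breakpoints(clips, depth, reference, base))
        for toggle in ["enable_support_filter", "enable_quality_filter",
                       "enable_profile_filter", "enable_zygosity_filter",
                       "enable_repeat_filter"]:
            import dataclasses
            cfg = dataclasses.replace(base, **{toggle: False})
            n = len(call_breakpoints(clips, depth, reference, cfg))
            assert n >= n_base, toggle


class TestZygosityPooling:
    def test_opposite_side_clips_pool_to_homozygous_ratio(self):
        from mgescout.breakpoints import _opposite_support_in_vicinity
        up = _simple_cand(1050, UP, support=14)
        down = _simple_cand(1055, DOWN, support=13)
        far = _simple_cand(3000, DOWN, support=9)
        extra = _opposite_support_in_vicinity([up, down, far])
        assert extra == [13, 14, 0]
        up.coverage_at_coord = 30
        assert zygosity_filter(up, call_heterozygous=False, extra_clipped=13)
        assert not zygosity_filter(up, call_heterozygous=False)
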