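"""Breakpoint prediction from soft-clip pileups.

Five consecutive filters turn raw clip pileups into insertion breakpoints:

1. candidate formation — clip length > 5 bp, support > 10% of the local
   coverage, mean clipped-base quality above the threshold (default 59 on
   the ASCII phred+33 encoding, i.e. phred > 26);
2. profile similarity — the clipped tails flush to the breakpoint must
   agree column-wise (> 95% over >= 10 profiled columns), with a poly-A/T
   exemption because a homopolymer tail is genuine retrotransposition
   signal even when slightly noisy;
3. zygosity — the fraction of covering reads that are clipped must reach
   10% (heterozygous calling) or 90% (homozygous-only calling);
4. vicinity merging — an upstream (right-clip) and a downstream
   (left-clip) pileup within 25 bp merge into one breakpoint whose
   interval width estimates the target-site duplication;
5. repeat/indel rejection — clips that replay the reference across the
   junction, or sit on a strong read-depth cliff, are discarded as tandem
   repeat / short indel / deletion-edge artefacts.
"""

from __future__ import annotations

import logging
from array import array
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import edlib
import numpy as np

from .sam_io import AlignedRead, clip_segments

logger = logging.getLogger(__name__)

UP = "up"      # right-clipped reads: support toward the 5' side
DOWN = "down"  # left-clipped reads: support toward the 3' side

_SIDE_OF_CLIP = {"right": UP, "left": DOWN}


@dataclass(slots=True)
class ClipRecord:
    side: str                 # UP | DOWN
    sequence: str             # the clipped substring
    qualities: str            # phred+33 ASCII of the clipped bases
    read_sequence: str        # the full read (assembly wants whole reads)
    query_name: str


@dataclass(slots=True)
class BreakpointCandidate:
    reference_name: str
    coordinate: int                  # 1-based breakpoint edge
    side: str                        # UP | DOWN
    clips: List[ClipRecord]
    local_coverage: float            # mean depth over +/- window
    coverage_at_coord: int           # exact depth at the coordinate
    mean_clip_quality: float         # mean ASCII value of clipped bases
    polya: bool = False
    zygosity_ratio: float = 0.0

    @property
    def support(self) -> int:
        return len(self.clips)

    @property
    def upstream_support(self) -> int:
        return self.support if self.side == UP else 0

    @property
    def downstream_support(self) -> int:
        return self.support if self.side == DOWN else 0


@dataclass(slots=True)
class Breakpoint:
    reference_name: str
    interval_start: int              # 1-based inclusive
    interval_end: int
    upstream_support: int
    downstream_support: int
    clipped_consensus_up: str
    clipped_consensus_down: str
    polyA_flag: bool
    zygosity_ratio: float
    up_coordinate: Optional[int] = None    # edge of the right-clip pileup
    down_coordinate: Optional[int] = None  # edge of the left-clip pileup
    up_clips: List[ClipRecord] = field(default_factory=list)
    down_clips: List[ClipRecord] = field(default_factory=list)

    @property
    def support(self) -> int:
        return self.upstream_support + self.downstream_support

    @property
    def width(self) -> int:
        return self.interval_end - self.interval_start

    def midpoint(self) -> float:
        return (self.interval_start + self.interval_end) / 2

    def all_clips(self) -> List[ClipRecord]:
        return self.up_clips + self.down_clips

    def longest_clip(self, side: str) -> str:
        clips = self.up_clips if side == UP else self.down_clips
        return max((c.sequence for c in clips), key=len, default="")


# ---------------------------------------------------------------------------
# Accumulation (streaming-friendly)

class DepthTracker:
    """Read-depth accumulator: per-reference diff array -> cumulative depth."""

    def __init__(self):
        self._starts: Dict[str, array] = defaultdict(lambda: array("l"))
        self._ends: Dict[str, array] = defaultdict(lambda: array("l"))
        self._depth: Optional[Dict[str, np.ndarray]] = None

    def add(self, reference: str, start: int, end: int) -> None:
        """Record coverage of the 1-based inclusive interval [start, end]."""
        self._starts[reference].append(start)
        self._ends[reference].append(end)
        self._depth = None

    def add_read(self, read: AlignedRead) -> None:
        if not read.is_unmapped and read.position is not None and read.cigar:
            self.add(read.reference_name, read.position, read.reference_end())

    def _finalize(self) -> Dict[str, np.ndarray]:
        if self._depth is None:
            depth = {}
            for ref in self._starts:
                starts = np.frombuffer(self._starts[ref], dtype=np.int64)
                ends = np.frombuffer(self._ends[ref], dtype=np.int64)
                size = int(ends.max()) + 2 if len(ends) else 2
                diff = np.zeros(size, dtype=np.int32)
                np.add.at(diff, starts, 1)
                np.add.at(diff, ends + 1, -1)
                depth[ref] = np.cumsum(diff)
            self._depth = depth
        return self._depth

    def at(self, reference: str, coordinate: int) -> int:
        depth = self._finalize().get(reference)
        if depth is None or not (1 <= coordinate < len(depth)):
            return 0
        return int(depth[coordinate])

    def window_mean(self, reference: str, coordinate: int, half_window: int = 100) -> float:
        depth = self._finalize().get(reference)
        if depth is None:
            return 0.0
        lo = max(1, coordinate - half_window)
        hi = min(len(depth) - 1, coordinate + half_window)
        if hi < lo:
            return 0.0
        return float(depth[lo:hi + 1].mean())


class ClipAccumulator:
    """Groups clipped tails by (reference, breakpoint edge, support side)."""

    def __init__(self, min_clip_length: int = 5):
        self.min_clip_length = min_clip_length
        self.groups: Dict[Tuple[str, int, str], List[ClipRecord]] = defaultdict(list)

    def add_read(self, read: AlignedRead) -> None:
        if read.is_duplicate:  # PCR duplicates inflate clip support
            return
        for clip in clip_segments(read):
            if clip.clip_length <= self.min_clip_length:
                continue
            side = _SIDE_OF_CLIP[clip.side]
            self.groups[(read.reference_name, clip.clip_coordinate, side)].append(
                ClipRecord(side, clip.clipped_sequence, clip.clipped_qualities,
                           read.sequence, read.query_name))


# ---------------------------------------------------------------------------
# Filter 1: candidate formation

def _mean_ascii(quals: Iterable[str]) -> float:
    total = 0
    n = 0
    for q in quals:
        b = q.encode("ascii")
        total += sum(b)
        n += len(b)
    return total / n if n else 0.0


def build_candidates(clips: ClipAccumulator, depth: DepthTracker,
                     min_support_fraction: float = 0.10,
                     clip_quality_threshold: float = 59.0,
                     clip_quality_mode: str = "ascii",
                     coverage_window: int = 100,
                     enable_support_filter: bool = True,
                     enable_quality_filter: bool = True,
                     ) -> List[BreakpointCandidate]:
    out: List[BreakpointCandidate] = []
    for (ref, coord, side), records in sorted(clips.groups.items()):
        cov = depth.window_mean(ref, coord, coverage_window)
        mean_q = _mean_ascii(r.qualities for r in records)
        if enable_support_filter and not len(records) > min_support_fraction * cov:
            logger.debug("drop candidate %s:%d/%s: support %d <= %.1f",
                         ref, coord, side, len(records), min_support_fraction * cov)
            continue
        q_value = mean_q if clip_quality_mode == "ascii" else mean_q - 33.0
        if enable_quality_filter and not q_value > clip_quality_threshold:
            logger.debug("drop candidate %s:%d/%s: clip quality %.1f <= %.1f",
                         ref, coord, side, q_value, clip_quality_threshold)
            continue
        out.append(BreakpointCandidate(
            reference_name=ref, coordinate=coord, side=side, clips=records,
            local_coverage=cov, coverage_at_coord=depth.at(ref, coord),
            mean_clip_quality=mean_q))
    return out


def collect_candidates(reads: Iterable[AlignedRead], min_clip_length: int = 5,
                       min_support_fraction: float = 0.10,
                       min_clip_quality: float = 59.0,
                       clip_quality_mode: str = "ascii",
                       coverage_window: int = 100) -> List[BreakpointCandidate]:
    """One-shot candidate collection from a coordinate-sorted read stream."""
    clips = ClipAccumulator(min_clip_length)
    depth = DepthTracker()
    last: Dict[str, int] = {}
    for read in reads:
        if not read.is_unmapped and read.position is not None:
            if read.position < last.get(read.reference_name, 0):
                raise ValueError("input reads are not coordinate-sorted")
            last[read.reference_name] = read.position
            depth.add_read(read)
            clips.add_read(read)
    return build_candidates(clips, depth, min_support_fraction,
                            min_clip_quality, clip_quality_mode, coverage_window)


# ---------------------------------------------------------------------------
# Filter 2: clip-profile similarity

def _anchored_columns(seqs: List[str], side: str, n_columns: int):
    """Bases per profile column, flush to the breakpoint.

    Right clips (UP support) read away from the junction left-to-right;
    left clips (DOWN support) end at the junction, so their columns are
    indexed from the tail.
    """
    for col in range(n_columns):
        if side == UP:
            yield [s[col] for s in seqs if len(s) > col]
        else:
            yield [s[-1 - col] for s in seqs if len(s) > col]


def _polya_dominated(seqs: List[str], fraction: float) -> bool:
    bases = "".join(seqs)
    if not bases:
        return False
    counts = Counter(bases.upper())
    n = len(bases)
    return counts.get("A", 0) / n > fraction or counts.get("T", 0) / n > fraction


def profile_similarity(seqs: List[str], side: str, n_columns: int = 10) -> float:
    """Mean per-column majority agreement over the first columns with >=2 bases."""
    agreements = []
    for column in _anchored_columns(seqs, side, n_columns):
        if len(column) < 2:
            continue
        counts = Counter(c.upper() for c in column)
        agreements.append(counts.most_common(1)[0][1] / len(column))
    return float(np.mean(agreements)) if agreements else 1.0


def profile_filter(candidate: BreakpointCandidate, min_profile_length: int = 10,
                   min_similarity: float = 0.95,
                   polya_fraction: float = 0.8) -> bool:
    seqs = [c.sequence for c in candidate.clips]
    if _polya_dominated(seqs, polya_fraction):
        candidate.polya = True
        return True
    if len(seqs) < 2:
        return True  # a single clipped sequence passes vacuously
    return profile_similarity(seqs, candidate.side, min_profile_length) > min_similarity


# ---------------------------------------------------------------------------
# Filter 3: zygosity

def zygosity_filter(candidate: BreakpointCandidate, het_min_ratio: float = 0.10,
                    hom_min_ratio: float = 0.90,
                    call_heterozygous: bool = True,
                    extra_clipped: int = 0) -> bool:
    """``extra_clipped`` counts insertion-supporting reads from the opposite
    clip pileup of the same locus whose alignments also cover this
    coordinate (both junction pileups carry the insertion haplotype, so a
    homozygous insertion reaches ~0.9 only when they are pooled)."""
    cov = candidate.coverage_at_coord
    if cov <= 0:
        return False
    ratio = min(1.0, (candidate.support + extra_clipped) / cov)
    candidate.zygosity_ratio = ratio
    threshold = het_min_ratio if call_heterozygous else hom_min_ratio
    return ratio >= threshold


def _opposite_support_in_vicinity(candidates: List[BreakpointCandidate],
                                  max_vicinity: int = 25) -> List[int]:
    """Clip support from opposite-side pileups within the vicinity of each
    candidate (those reads span the candidate's coordinate)."""
    out = []
    for c in candidates:
        out.append(sum(o.support for o in candidates
                       if o.reference_name == c.reference_name
                       and o.side != c.side
                       and abs(o.coordinate - c.coordinate) < max_vicinity))
    return out


# ---------------------------------------------------------------------------
# Filter 4: vicinity merging

def _consensus(seqs: List[str], side: str) -> str:
    if not seqs:
        return ""
    longest = max(len(s) for s in seqs)
    cols = []
    for column in _anchored_columns(seqs, side, longest):
        if not column:
            break
        cols.append(Counter(c.upper() for c in column).most_common(1)[0][0])
    return "".join(cols) if side == UP else "".join(reversed(cols))


def _collapse_same_side(cands: List[BreakpointCandidate],
                        slop: int = 2) -> List[BreakpointCandidate]:
    """Near-duplicate pileups on the same side collapse to the strongest."""
    by_key: Dict[Tuple[str, str], List[BreakpointCandidate]] = defaultdict(list)
    for c in cands:
        by_key[(c.reference_name, c.side)].append(c)
    kept: List[BreakpointCandidate] = []
    for group in by_key.values():
        group.sort(key=lambda c: c.coordinate)
        cluster: List[BreakpointCandidate] = []
        for c in group:
            if cluster and c.coordinate - cluster[-1].coordinate > slop:
                kept.append(max(cluster, key=lambda x: (x.support, -x.coordinate)))
                cluster = []
            cluster.append(c)
        if cluster:
            kept.append(max(cluster, key=lambda x: (x.support, -x.coordinate)))
    kept.sort(key=lambda c: (c.reference_name, c.coordinate))
    return kept


def _make_breakpoint(up: Optional[BreakpointCandidate],
                     down: Optional[BreakpointCandidate]) -> Breakpoint:
    coords = [c.coordinate for c in (up, down) if c is not None]
    ref = (up or down).reference_name
    up_clips = up.clips if up else []
    down_clips = down.clips if down else []
    return Breakpoint(
        reference_name=ref,
        interval_start=min(coords), interval_end=max(coords),
        upstream_support=len(up_clips), downstream_support=len(down_clips),
        clipped_consensus_up=_consensus([c.sequence for c in up_clips], UP),
        clipped_consensus_down=_consensus([c.sequence for c in down_clips], DOWN),
        polyA_flag=any(c.polya for c in (up, down) if c is not None),
        zygosity_ratio=max((c.zygosity_ratio for c in (up, down) if c is not None),
                           default=0.0),
        up_coordinate=up.coordinate if up else None,
        down_coordinate=down.coordinate if down else None,
        up_clips=up_clips, down_clips=down_clips)


def merge_vicinity(candidates: List[BreakpointCandidate],
                   max_vicinity: int = 25) -> List[Breakpoint]:
    """Greedy nearest-pair merging of opposite-side pileups within the vicinity.

    The merged interval spans both clip edges; its width estimates the
    target-site duplication. Every candidate is used at most once and
    unmerged candidates become single-coordinate breakpoints.
    """
    cands = _collapse_same_side(candidates)
    ups = [c for c in cands if c.side == UP]
    downs = [c for c in cands if c.side == DOWN]
    pairs = []
    for i, u in enumerate(ups):
        for j, d in enumerate(downs):
            if u.reference_name != d.reference_name:
                continue
            dist = abs(u.coordinate - d.coordinate)
            if dist < max_vicinity:
                pairs.append((dist, i, j))
    pairs.sort()
    used_u, used_d = set(), set()
    breakpoints: List[Breakpoint] = []
    for dist, i, j in pairs:
        if i in used_u or j in used_d:
            continue
        used_u.add(i)
        used_d.add(j)
        breakpoints.append(_make_breakpoint(ups[i], downs[j]))
    for i, u in enumerate(ups):
        if i not in used_u:
            breakpoints.append(_make_breakpoint(u, None))
    for j, d in enumerate(downs):
        if j not in used_d:
            breakpoints.append(_make_breakpoint(None, d))
    breakpoints.sort(key=lambda b: (b.reference_name, b.interval_start))
    return breakpoints


# ---------------------------------------------------------------------------
# Filter 5: repeat / indel / deletion-edge rejection

def _matches_far_side(consensus: str, window: str, max_divergence: float = 0.05) -> bool:
    """Does the clip replay the reference beyond the junction (within a small
    edit distance, which also catches matches shifted by a short indel)?"""
    if len(consensus) < 5 or len(window) < len(consensus):
        return False
    k = max(0, int(max_divergence * len(consensus)))
    res = edlib.align(consensus.upper(), window.upper(), mode="HW", task="distance", k=k)
    return res["editDistance"] != -1


def repeat_indel_filter(breakpoint: Breakpoint, reference: str, flank: int = 50,
                        depth: Optional[DepthTracker] = None,
                        depth_imbalance: float = 3.0) -> bool:
    """True = keep. Rejects tandem-repeat / short-indel / deletion-edge artefacts."""
    L = len(reference)
    if not (1 <= breakpoint.interval_start <= L and 1 <= breakpoint.interval_end <= L):
        raise ValueError(
            f"breakpoint {breakpoint.interval_start}-{breakpoint.interval_end} "
            f"outside reference of length {L}")
    # (a) clipped consensus identical to the reference on the far side
    up = breakpoint.clipped_consensus_up
    if up and breakpoint.up_coordinate is not None:
        start = breakpoint.up_coordinate  # 0-based index of base after the edge
        window = reference[start:start + len(up) + flank]
        if _matches_far_side(up, window):
            logger.debug("reject %s:%d: upstream clip replays reference",
                         breakpoint.reference_name, breakpoint.interval_start)
            return False
    down = breakpoint.clipped_consensus_down
    if down and breakpoint.down_coordinate is not None:
        end = breakpoint.down_coordinate - 1  # 0-based index of the edge base
        window = reference[max(0, end - len(down) - flank):end]
        if _matches_far_side(down, window):
            logger.debug("reject %s:%d: downstream clip replays reference",
                         breakpoint.reference_name, breakpoint.interval_start)
            return False
    # (b) strong read-depth cliff across the junction (long-deletion edge)
    if depth is not None:
        ref = breakpoint.reference_name
        left = np.mean([depth.at(ref, p) for p in
                        range(max(1, breakpoint.interval_start - flank),
                              breakpoint.interval_start)] or [0.0])
        right = np.mean([depth.at(ref, p) for p in
                         range(breakpoint.interval_end + 1,
                               min(L, breakpoint.interval_end + flank) + 1)] or [0.0])
        hi, lo = max(left, right), min(left, right)
        if hi >= 5 and (lo == 0 or hi / lo > depth_imbalance):
            logger.debug("reject %s:%d: depth imbalance %.1f vs %.1f",
                         breakpoint.reference_name, breakpoint.interval_start, left, right)
            return False
    return True


# ---------------------------------------------------------------------------
# Orchestration

def call_breakpoints(clips: ClipAccumulator, depth: DepthTracker,
                     reference: Dict[str, str], config) -> List[Breakpoint]:
    """Run all five filter stages with a :class:`~mgescout.config.PipelineConfig`."""
    candidates = build_candidates(
        clips, depth,
        min_support_fraction=config.min_support_fraction,
        clip_quality_threshold=config.clip_quality_threshold,
        clip_quality_mode=config.clip_quality_mode,
        coverage_window=config.coverage_window,
        enable_support_filter=config.enable_support_filter,
        enable_quality_filter=config.enable_quality_filter)
    if config.enable_profile_filter:
        candidates = [c for c in candidates if profile_filter(
            c, config.min_profile_length, config.min_profile_similarity,
            config.polya_fraction)]
    else:
        for c in candidates:
            profile_filter(c, config.min_profile_length, 0.0, config.polya_fraction)
    extra = _opposite_support_in_vicinity(candidates, config.max_vicinity)
    if config.enable_zygosity_filter:
        candidates = [c for c, x in zip(candidates, extra) if zygosity_filter(
            c, config.het_min_ratio, config.hom_min_ratio,
            config.call_heterozygous, extra_clipped=x)]
    else:
        for c, x in zip(candidates, extra):
            zygosity_filter(c, 0.0, 0.0, True, extra_clipped=x)
    breakpoints = merge_vicinity(candidates, config.max_vicinity)
    if config.enable_repeat_filter:
        breakpoints = [b for b in breakpoints
                       if b.reference_name in reference
                       and repeat_indel_filter(b, reference[b.reference_name],
                                               config.repeat_flank, depth,
                                               config.depth_imbalance)]
    return breakpoints


def write_breakpoint_tsv(breakpoints: List[Breakpoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tup_support\tdown_support\t"
                 "mean_clip_quality\tzygosity_ratio\n")
        for b in breakpoints:
            quals = _mean_ascii(c.qualities for c in b.all_clips())
            fh.write(f"{b.reference_name}\t{b.interval_start}\t{b.interval_end}\t"
                     f"{b.upstream_support}\t{b.downstream_support}\t"
                     f"{quals:.2f}\t{b.zygosity_ratio:.3f}\n")
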