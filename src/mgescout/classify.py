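"""Read-status and pair-class assignment, with distant-pair anchor rescue.

Each read is Mapped, Soft-clipped (a soft clip strictly longer than the
minimum, default 5 bp) or Unmapped; each template falls into one of six
orientation-symmetric pair classes (M-U, S-U, M-S, S-S, M-M, U-U). Pairs
of the mapped classes whose mates sit further apart than the expected
insert (default > 500 bp), or on different references, are rescued: the
lower-quality mate is relabelled unmapped so its sequence can vote for the
inserted element like any one-end-unmapped mate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .sam_io import (FLAG_MATE_UNMAPPED, FLAG_UNMAPPED, AlignedRead,
                     clip_segments)


class ReadStatus(enum.Enum):
    MAPPED = "M"
    SOFT_CLIPPED = "S"
    UNMAPPED = "U"


class PairClass(enum.Enum):
    C1_MU = "M-U"
    C2_SU = "S-U"
    C3_MS = "M-S"
    C4_SS = "S-S"
    C5_MM = "M-M"
    C6_UU = "U-U"


_CLASS_BY_STATUSES = {
    frozenset({ReadStatus.MAPPED, ReadStatus.UNMAPPED}): PairClass.C1_MU,
    frozenset({ReadStatus.SOFT_CLIPPED, ReadStatus.UNMAPPED}): PairClass.C2_SU,
    frozenset({ReadStatus.MAPPED, ReadStatus.SOFT_CLIPPED}): PairClass.C3_MS,
    frozenset({ReadStatus.SOFT_CLIPPED}): PairClass.C4_SS,
    frozenset({ReadStatus.MAPPED}): PairClass.C5_MM,
    frozenset({ReadStatus.UNMAPPED}): PairClass.C6_UU,
}

RESCUABLE = (PairClass.C3_MS, PairClass.C4_SS, PairClass.C5_MM)
ANCHORED = (PairClass.C1_MU, PairClass.C2_SU)


@dataclass(slots=True)
class ClassifiedPair:
    read1: AlignedRead
    read2: AlignedRead
    status1: ReadStatus
    status2: ReadStatus
    pair_class: PairClass
    anchor: Optional[int] = None     # 1 or 2: the trusted mapped/clipped end
    rescued: bool = False

    @property
    def anchor_read(self) -> Optional[AlignedRead]:
        return None if self.anchor is None else (self.read1 if self.anchor == 1 else self.read2)

    @property
    def unmapped_read(self) -> Optional[AlignedRead]:
        if self.anchor is None:
            return None
        return self.read2 if self.anchor == 1 else self.read1


def classify_read(read: AlignedRead, min_clip_length: int = 5) -> ReadStatus:
    """M / S / U status; clips of at most ``min_clip_length`` count as mapped."""
    if read.is_unmapped:
        return ReadStatus.UNMAPPED
    for clip in clip_segments(read):
        if clip.clip_length > min_clip_length:
            return ReadStatus.SOFT_CLIPPED
    return ReadStatus.MAPPED


def classify_pair(read1: AlignedRead, read2: AlignedRead,
                  min_clip_length: int = 5) -> ClassifiedPair:
    if read1.query_name != read2.query_name:
        raise ValueError(
            f"mates have different names: {read1.query_name!r} vs {read2.query_name!r}")
    s1 = classify_read(read1, min_clip_length)
    s2 = classify_read(read2, min_clip_length)
    pc = _CLASS_BY_STATUSES[frozenset({s1, s2})]
    anchor = None
    if pc in ANCHORED:
        anchor = 1 if s1 is not ReadStatus.UNMAPPED else 2
    return ClassifiedPair(read1, read2, s1, s2, pc, anchor)


def _rescue_anchor(pair: ClassifiedPair) -> int:
    """Higher mapq wins; ties by longer aligned length, then by read1."""
    r1, r2 = pair.read1, pair.read2
    if r1.mapping_quality != r2.mapping_quality:
        return 1 if r1.mapping_quality > r2.mapping_quality else 2
    a1, a2 = r1.aligned_length(), r2.aligned_length()
    if a1 != a2:
        return 1 if a1 > a2 else 2
    return 1


def rescue_distant_pair(pair: ClassifiedPair, max_insert: int = 500) -> ClassifiedPair:
    """Convert a distant M-S/S-S/M-M pair into an anchored one-end-unmapped pair.

    Distance is the span between the outermost mapped reference coordinates
    of the two mates; inter-chromosomal pairs always rescue. The
    lower-quality mate keeps its record but is treated as unmapped
    downstream.
    """
    if pair.pair_class not in RESCUABLE:
        return pair
    r1, r2 = pair.read1, pair.read2
    if r1.position is None or r2.position is None:
        return pair
    if r1.reference_name == r2.reference_name:
        span = (max(r1.reference_end(), r2.reference_end())
                - min(r1.position, r2.position))
        if span <= max_insert:
            return pair
    anchor = _rescue_anchor(pair)
    s1, s2 = pair.status1, pair.status2
    if anchor == 1:
        s2 = ReadStatus.UNMAPPED
    else:
        s1 = ReadStatus.UNMAPPED
    pc = _CLASS_BY_STATUSES[frozenset({s1, s2})]
    return replace(pair, status1=s1, status2=s2, pair_class=pc,
                   anchor=anchor, rescued=True)


def pair_reads(reads: Iterable[AlignedRead]) -> Iterator[Tuple[AlignedRead, AlignedRead]]:
    """Group primary records into (mate1, mate2) templates by query name.

    Works on any ordering; memory is bounded by the number of templates
    whose mates have not both been seen yet (small for coordinate-sorted
    input where unmapped mates are placed at their anchor).
    """
    pending: Dict[str, AlignedRead] = {}
    for read in reads:
        other = pending.pop(read.query_name, None)
        if other is None:
            pending[read.query_name] = read
        else:
            if other.is_first_in_pair or not read.is_first_in_pair:
                yield other, read
            else:
                yield read, other
    # unpaired leftovers are silently dropped (orphan mates)


def classify_pairs(reads: Iterable[AlignedRead], min_clip_length: int = 5,
                   max_insert: int = 500) -> Iterator[ClassifiedPair]:
    for r1, r2 in pair_reads(reads):
        yield rescue_distant_pair(classify_pair(r1, r2, min_clip_length), max_insert)


def class_summary(pairs: Iterable[ClassifiedPair]) -> Dict[str, int]:
    counts: Dict[str, int] = {pc.value: 0 for pc in PairClass}
    counts["rescued"] = 0
    for p in pairs:
        counts[p.pair_class.value] += 1
        if p.rescued:
            counts["rescued"] += 1
    return counts


def write_class_summary(counts: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_class\tcount\n")
        for key, val in counts.items():
            fh.write(f"{key}\t{val}\n")
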