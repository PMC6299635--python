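"""Assembly of inserted sequences and breakpoint-precise boundary trimming.

Unmapped read pairs, one-end-unmapped mates near breakpoints and the
supporting soft-clipped reads are assembled with a k-mer (default k=51)
de Bruijn walk. Contigs are assigned to breakpoints by re-aligning each
breakpoint's one-end-unmapped reads (at most five placements per read,
majority vote), boundaries are trimmed by local DP against the longest
clipped sequence of each side (match 1, substitution -3, gap open -5,
gap extension -2; a side is accepted only when its optimal score reaches
75% of that clip's length), and the trimmed insert is called novel when
the library search finds no passing hit.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib

from .align import revcomp, sw_align
from .annotate import HomologySearcher, MGELibraryEntry, homology_search
from .breakpoints import DOWN, UP, Breakpoint
from .classify import ClassifiedPair, PairClass

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class Contig:
    contig_id: str
    sequence: str
    read_support: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class InsertSequence:
    breakpoint: Breakpoint
    contig_id: str
    trimmed_sequence: str
    strand: str                      # "+" | "-" relative to the contig
    left_trim_score: int
    right_trim_score: int
    is_novel: bool = False
    mge_name: Optional[str] = None
    mge_family: Optional[str] = None


# ---------------------------------------------------------------------------
# Read collection

def collect_assembly_reads(pairs: Iterable[ClassifiedPair],
                           breakpoints: Sequence[Breakpoint],
                           window: int = 500) -> List[Tuple[str, str]]:
    """(name, sequence) of every read feeding the assembler: both mates of
    fully-unmapped pairs, unmapped mates anchored within the window of any
    breakpoint, and the whole sequence of supporting soft-clipped reads."""
    by_ref: Dict[str, List[Breakpoint]] = defaultdict(list)
    for bp in breakpoints:
        by_ref[bp.reference_name].append(bp)

    def near_any(ref: Optional[str], pos: Optional[int]) -> bool:
        if ref is None or pos is None:
            return False
        return any(bp.interval_start - window <= pos <= bp.interval_end + window
                   for bp in by_ref.get(ref, ()))

    seen: Set[Tuple[str, int]] = set()
    out: List[Tuple[str, str]] = []

    def add(name: str, mate_index: int, seq: str) -> None:
        key = (name, mate_index)
        if seq and key not in seen:
            seen.add(key)
            out.append((f"{name}/{mate_index}", seq))

    for pair in pairs:
        if pair.pair_class is PairClass.C6_UU:
            add(pair.read1.query_name, 1, pair.read1.sequence)
            add(pair.read2.query_name, 2, pair.read2.sequence)
        elif pair.anchor is not None:
            anchor = pair.anchor_read
            if near_any(anchor.reference_name, anchor.position):
                mate = pair.unmapped_read
                add(mate.query_name, 2 if pair.anchor == 1 else 1, mate.sequence)
    for bp in breakpoints:
        for idx, clip in enumerate(bp.all_clips()):
            # whole read, not just the clip; clip records carry no mate index
            add(clip.query_name + "/clip", idx, clip.read_sequence)
    return out


# ---------------------------------------------------------------------------
# de Bruijn assembly

def _count_kmers(reads: Iterable[str], k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for seq in reads:
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            if "N" in s:
                s = max(s.split("N"), key=len)  # longest clean stretch
            n = len(s) - k
            for i in range(n + 1):
                kmer = s[i:i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _lookahead_mass(kmer: str, counts: Dict[str, int], steps: int) -> int:
    """Total k-mer count along a short greedy probe walk from ``kmer``.

    Bubble arms spawned by recurrent sequencing errors carry counts near
    the error multiplicity and usually dead-end within one k-mer length;
    the true path keeps genomic coverage. Comparing this mass over a short
    horizon separates the two far more reliably than the counts of the two
    branch k-mers alone.
    """
    total = counts.get(kmer, 0)
    for _ in range(steps):
        suffix = kmer[1:]
        succ = [(counts[nxt], nxt) for base in "ACGT"
                if (nxt := suffix + base) in counts]
        if not succ:
            break
        cnt, kmer = max(succ)
        total += cnt
    return total


def _extend(start: str, counts: Dict[str, int], visited: Set[str],
            dominance: float, lookahead: int = 25) -> str:
    """Greedy rightward walk following the dominant successor.

    A branch is taken outright when its k-mer count is ``dominance`` times
    any alternative. Otherwise the two strongest arms are probed a short
    distance ahead and the one carrying clearly more k-mer mass wins; if
    neither dominates (a genuine repeat junction) the walk stops. This
    pops the short error bubbles that would fragment every contig under a
    strict unitig stop, while refusing truly ambiguous junctions.
    """
    contig = [start]
    kmer = start
    while True:
        suffix = kmer[1:]
        succ = [(counts[nxt], base) for base in "ACGT"
                if (nxt := suffix + base) in counts]
        if not succ:
            break
        succ.sort(reverse=True)
        best_count, base = succ[0]
        if len(succ) > 1 and best_count < dominance * succ[1][0]:
            m0 = _lookahead_mass(suffix + succ[0][1], counts, lookahead)
            m1 = _lookahead_mass(suffix + succ[1][1], counts, lookahead)
            if m1 >= 2 * m0:
                base = succ[1][1]
            elif not m0 >= 2 * m1:
                break
        kmer = suffix + base
        if kmer in visited:
            break
        visited.add(kmer)
        contig.append(base)
    return "".join(contig)


def assemble_contigs(reads: Sequence[Tuple[str, str]] | Sequence[str],
                     k: int = 51, min_contig_length: int = 500,
                     min_kmer_count: int = 2,
                     dominance: float = 4.0) -> List[Contig]:
    """Assemble unmapped/clipped reads into insertion contigs.

    K-mers observed once are dropped as sequencing errors. Output is
    deterministic for any read ordering: seeds are processed by
    (count, k-mer) rank and contigs reported by (length desc, sequence).
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    if not seqs:
        return []
    if all(len(s) < k for s in seqs):
        raise ValueError(f"all reads are shorter than k={k}; use a smaller k")
    counts = _count_kmers(seqs, k)
    # k-mers observed once are untrusted: never seeds, and a walk crosses
    # one only when the branch rules still favour it (this bridges genuine
    # coverage dips without letting error k-mers nucleate contigs)
    seeds = sorted((m for m, c in counts.items() if c >= min_kmer_count),
                   key=lambda m: (-counts[m], m))
    visited: Set[str] = set()
    contigs: List[str] = []
    for seed in seeds:
        if seed in visited or revcomp(seed) in visited:
            continue
        visited.add(seed)
        right = _extend(seed, counts, visited, dominance)
        left = _extend(revcomp(seed), counts, visited, dominance)
        contig = revcomp(left) + right[k:]
        for i in range(len(contig) - k + 1):  # block the reverse strand too
            visited.add(revcomp(contig[i:i + k]))
        if len(contig) >= min_contig_length:
            contigs.append(contig)
    contigs.sort(key=lambda s: (-len(s), s))
    return [Contig(f"contig_{i + 1}", seq) for i, seq in enumerate(contigs)]


# ---------------------------------------------------------------------------
# Contig-to-breakpoint assignment

class ContigAligner:
    """Exact-seed + edit-distance verification of reads against contigs."""

    def __init__(self, contigs: Sequence[Contig], seed_k: int = 21,
                 max_divergence: float = 0.10):
        self.contigs = list(contigs)
        self.seed_k = seed_k
        self.max_divergence = max_divergence
        self.index: Dict[str, Set[int]] = defaultdict(set)
        for idx, contig in enumerate(self.contigs):
            seq = contig.sequence.upper()
            for i in range(len(seq) - seed_k + 1):
                self.index[seq[i:i + seed_k]].add(idx)

    def alignments(self, read: str, max_hits: int = 5) -> List[Tuple[int, int]]:
        """[(contig idx, edit distance)] for the best <= max_hits placements."""
        read = read.upper()
        candidates: Set[int] = set()
        for seq in (read, revcomp(read)):
            for i in range(0, len(seq) - self.seed_k + 1, self.seed_k):
                candidates |= self.index.get(seq[i:i + self.seed_k], set())
        k = int(self.max_divergence * len(read))
        hits = []
        for idx in candidates:
            target = self.contigs[idx].sequence
            best = -1
            for seq in (read, revcomp(read)):
                res = edlib.align(seq, target, mode="HW", task="distance", k=k)
                ed = res["editDistance"]
                if ed != -1 and (best == -1 or ed < best):
                    best = ed
            if best != -1:
                hits.append((best, idx))
        hits.sort()
        return [(idx, ed) for ed, idx in hits[:max_hits]]


def assign_and_select(contigs: Sequence[Contig],
                      breakpoints: Sequence[Breakpoint],
                      support_reads: Dict[int, List[Tuple[str, str]]],
                      max_alignments_per_read: int = 5,
                      min_read_support: int = 2) -> Dict[int, Contig]:
    """Pick each breakpoint's contig by majority vote of its unmapped reads.

    ``support_reads`` maps breakpoint index -> [(name, sequence)] of its
    one-end-unmapped mates. A read may count toward at most
    ``max_alignments_per_read`` contigs; contigs supported by fewer than
    ``min_read_support`` reads overall are removed before voting.
    """
    if not contigs:
        return {}
    aligner = ContigAligner(contigs)
    total_support: Dict[int, Set[str]] = defaultdict(set)
    votes_by_bp: Dict[int, Dict[int, int]] = {}
    for bp_idx, reads in support_reads.items():
        votes: Dict[int, int] = defaultdict(int)
        for name, seq in reads:
            for contig_idx, _ in aligner.alignments(seq, max_alignments_per_read):
                votes[contig_idx] += 1
                total_support[contig_idx].add(name)
        votes_by_bp[bp_idx] = dict(votes)
    for idx, contig in enumerate(contigs):
        contig.read_support = len(total_support.get(idx, ()))
    eligible = {idx for idx, contig in enumerate(contigs)
                if contig.read_support >= min_read_support}
    selected: Dict[int, Contig] = {}
    for bp_idx, votes in votes_by_bp.items():
        votes = {idx: n for idx, n in votes.items() if idx in eligible}
        if not votes:
            continue
        winner = sorted(votes, key=lambda i: (-votes[i], -contigs[i].length, i))[0]
        selected[bp_idx] = contigs[winner]
    return selected


# ---------------------------------------------------------------------------
# Boundary trimming

def trim_boundaries(contig: Contig, clipped_up: Sequence[str],
                    clipped_down: Sequence[str],
                    breakpoint: Optional[Breakpoint] = None,
                    match: int = 1, mismatch: int = -3,
                    gap_open: int = -5, gap_extend: int = -2,
                    accept_fraction: float = 0.75) -> Optional[InsertSequence]:
    """Trim the contig to the inserted fragment using the clip anchors.

    The longest clipped sequence of each supported side is locally aligned
    against the contig in both orientations; the orientation with the
    higher combined optimal score is reported, and each side must score at
    least ``accept_fraction`` times its clip length or the insert is not
    reported. The trimmed sequence runs from the upstream clip's alignment
    start to the downstream clip's alignment end (one-ended support trims
    that end only).
    """
    up = max(clipped_up, key=len, default="")
    down = max(clipped_down, key=len, default="")
    if not up and not down:
        return None
    best = None
    for strand, seq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
        up_aln = sw_align(up, seq, match, mismatch, gap_open, gap_extend) if up else None
        down_aln = sw_align(down, seq, match, mismatch, gap_open, gap_extend) if down else None
        total = (up_aln.score if up_aln else 0) + (down_aln.score if down_aln else 0)
        if best is None or total > best[0]:
            best = (total, strand, seq, up_aln, down_aln)
    _, strand, seq, up_aln, down_aln = best
    if up and up_aln.score < accept_fraction * len(up):
        logger.debug("trim rejected (%s): upstream score %d < %.1f",
                     contig.contig_id, up_aln.score, accept_fraction * len(up))
        return None
    if down and down_aln.score < accept_fraction * len(down):
        logger.debug("trim rejected (%s): downstream score %d < %.1f",
                     contig.contig_id, down_aln.score, accept_fraction * len(down))
        return None
    # project the clips' unaligned tips onto the contig so a terminal
    # sequencing error in a clip cannot shave bases off the boundary
    if up_aln:
        start = max(0, up_aln.s_start - up_aln.q_start)
    else:
        start = 0
    if down_aln:
        end = min(len(seq), down_aln.s_end + (len(down) - down_aln.q_end))
    else:
        end = len(seq)
    if end <= start:
        return None
    return InsertSequence(
        breakpoint=breakpoint, contig_id=contig.contig_id,
        trimmed_sequence=seq[start:end], strand=strand,
        left_trim_score=up_aln.score if up_aln else 0,
        right_trim_score=down_aln.score if down_aln else 0)


def annotate_contig(insert: InsertSequence, library: Sequence[MGELibraryEntry],
                    min_identity: float = 0.90,
                    min_length_fraction: float = 0.70,
                    mean_read_length: float = 100.0,
                    searcher: Optional[HomologySearcher] = None) -> InsertSequence:
    """Novelty call: novel iff no library hit passes the homology filters."""
    hits = homology_search([("contig", insert.trimmed_sequence)], library,
                           min_identity, min_length_fraction,
                           mean_read_length, searcher)
    if hits:
        insert.is_novel = False
        insert.mge_name = hits[0].subject_name
        insert.mge_family = hits[0].subject_family
    else:
        insert.is_novel = True
    return insert
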