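"""Annotation of breakpoints with the most likely known mobile element.

One-end-unmapped mates anchored near a breakpoint, together with the
supporting clipped tails, are searched against an MGE consensus library
(Repbase-style ``name#family`` headers). Hits need > 90% identity over
> 70% of the mean read length; each read contributes its single
best-scoring hit and the element with most votes is reported.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import LocalAlignment, SeedIndex, revcomp
from .breakpoints import Breakpoint
from .classify import ANCHORED, ClassifiedPair

MEAN_READ_LENGTH_SAMPLE = 10_000  # records used to estimate the read length


@dataclass(slots=True)
class MGELibraryEntry:
    name: str
    family: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"library entry {self.name} has an empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"library entry {self.name}: non-nucleotide {bad}")


@dataclass(slots=True)
class HomologyHit:
    query_name: str
    subject_name: str
    subject_family: str
    identity: float
    alignment_length: int
    score: int
    strand: str                      # "+" | "-"


@dataclass(slots=True)
class MGEAnnotation:
    breakpoint: Breakpoint
    voted_name: str                  # element name, "novel" or "unassigned"
    voted_family: str
    vote_counts: Dict[str, int]
    supporting_read_count: int
    assembled: bool = False
    insert_id: Optional[str] = None


def parse_library_entry(name: str, sequence: str) -> MGELibraryEntry:
    """Repbase convention ``name#family``, or ``name`` alone (family unknown)."""
    if "#" in name:
        base, family = name.split("#", 1)
    else:
        base, family = name, "unknown"
    return MGELibraryEntry(base, family, sequence)


def load_library(fasta_records: Dict[str, str]) -> List[MGELibraryEntry]:
    return [parse_library_entry(n, s) for n, s in fasta_records.items()]


class HomologySearcher:
    """Seeded double-stranded local-alignment search over the MGE library.

    Scoring mirrors the megablast-style defaults (match +1, mismatch -2,
    gap open -5, gap extend -2); identity is matches over alignment
    columns. The backend contract (filter on identity and hit length) is
    the same one an external BLAST shell-out would satisfy.
    """

    def __init__(self, library: Sequence[MGELibraryEntry], seed_k: int = 11,
                 match: int = 1, mismatch: int = -2,
                 gap_open: int = -5, gap_extend: int = -2):
        if not library:
            raise ValueError("MGE library is empty")
        self.library = list(library)
        self.scoring = (match, mismatch, gap_open, gap_extend)
        self.index = SeedIndex([(e.name, e.sequence) for e in self.library], k=seed_k)

    def best_hit(self, query_name: str, query: str) -> Optional[HomologyHit]:
        best: Optional[HomologyHit] = None
        for strand, seq in (("+", query), ("-", revcomp(query))):
            for idx, aln in self.index.search(seq, *self.scoring):
                entry = self.library[idx]
                hit = HomologyHit(query_name, entry.name, entry.family,
                                  aln.identity, aln.columns, aln.score, strand)
                if best is None or (hit.score, hit.identity) > (best.score, best.identity):
                    best = hit
        return best


def homology_search(queries: Iterable[Tuple[str, str]] | Iterable[str],
                    library: Sequence[MGELibraryEntry],
                    min_identity: float = 0.90,
                    min_length_fraction: float = 0.70,
                    mean_read_length: float = 100.0,
                    searcher: Optional[HomologySearcher] = None) -> List[HomologyHit]:
    """Per-query best hits passing the identity and hit-length filters.

    ``queries`` may be plain sequences or ``(name, sequence)`` pairs.
    """
    searcher = searcher or HomologySearcher(library)
    min_len = min_length_fraction * mean_read_length
    hits: List[HomologyHit] = []
    for i, q in enumerate(queries):
        name, seq = q if isinstance(q, tuple) else (f"q{i}", q)
        hit = searcher.best_hit(name, seq)
        if hit is None:
            continue
        if hit.identity > min_identity and hit.alignment_length > min_len:
            hits.append(hit)
    return hits


def majority_vote(hits: Sequence[HomologyHit], breakpoint: Breakpoint) -> MGEAnnotation:
    """One vote per supporting read; ties break on total score, then name."""
    votes: Dict[str, int] = {}
    scores: Dict[str, int] = {}
    family: Dict[str, str] = {}
    for hit in hits:
        votes[hit.subject_name] = votes.get(hit.subject_name, 0) + 1
        scores[hit.subject_name] = scores.get(hit.subject_name, 0) + hit.score
        family[hit.subject_name] = hit.subject_family
    if not votes:
        return MGEAnnotation(breakpoint, "unassigned", "unknown", {},
                             breakpoint.support)
    winner = sorted(votes, key=lambda n: (-votes[n], -scores[n], n))[0]
    return MGEAnnotation(breakpoint, winner, family[winner], votes,
                         breakpoint.support)


# ---------------------------------------------------------------------------
# Support-read gathering

@dataclass(slots=True)
class SupportRead:
    query_name: str
    sequence: str                    # oriented consistently with the anchor strand
    anchor_position: int
    anchor_reverse: bool
    anchor_reference: str


class SupportStore:
    """One-end-unmapped mates indexed by their anchor position.

    Forward anchors point rightward (the insertion is downstream of the
    anchor), reverse anchors leftward; ``near`` returns the mates whose
    anchor sits within the window on the pointing side of the breakpoint.
    Mate sequences are stored reverse-complemented relative to the anchor
    strand so every support read reads into the insertion consistently.
    """

    def __init__(self):
        self._fwd: List[Tuple[str, int, SupportRead]] = []
        self._rev: List[Tuple[str, int, SupportRead]] = []
        self._sorted = False

    def add_pair(self, pair: ClassifiedPair) -> None:
        if pair.pair_class not in ANCHORED:
            return
        anchor = pair.anchor_read
        mate = pair.unmapped_read
        if anchor is None or anchor.position is None or not mate.sequence:
            return
        seq = revcomp(mate.sequence) if not anchor.is_reverse else mate.sequence
        rec = SupportRead(mate.query_name, seq, anchor.position,
                          anchor.is_reverse, anchor.reference_name)
        if anchor.is_reverse:
            self._rev.append((anchor.reference_name, anchor.position, rec))
        else:
            self._fwd.append((anchor.reference_name, anchor.position, rec))
        self._sorted = False

    def _ensure_sorted(self):
        if not self._sorted:
            self._fwd.sort(key=lambda t: (t[0], t[1]))
            self._rev.sort(key=lambda t: (t[0], t[1]))
            self._sorted = True

    @staticmethod
    def _range(items, ref, lo, hi):
        keys = [(r, p) for r, p, _ in items]
        i = bisect.bisect_left(keys, (ref, lo))
        j = bisect.bisect_right(keys, (ref, hi))
        return [items[k][2] for k in range(i, j)]

    def near(self, breakpoint: Breakpoint, window: int) -> List[SupportRead]:
        self._ensure_sorted()
        ref = breakpoint.reference_name
        out = self._range(self._fwd, ref,
                          breakpoint.interval_start - window, breakpoint.interval_end)
        out += self._range(self._rev, ref,
                           breakpoint.interval_start, breakpoint.interval_end + window)
        return out


def gather_support_reads(breakpoint: Breakpoint,
                         pairs: Iterable[ClassifiedPair] | SupportStore,
                         window: int = 500) -> List[Tuple[str, str]]:
    """(name, sequence) of every read that can vote for this breakpoint:
    unmapped mates of anchored pairs within the window, plus the clipped
    substrings of the supporting soft-clipped reads."""
    if isinstance(pairs, SupportStore):
        store = pairs
    else:
        store = SupportStore()
        for p in pairs:
            store.add_pair(p)
    out = [(r.query_name, r.sequence) for r in store.near(breakpoint, window)]
    out += [(c.query_name + "/clip", c.sequence) for c in breakpoint.all_clips()]
    return out


def annotate_breakpoints(breakpoints: Sequence[Breakpoint],
                         support: SupportStore,
                         library: Sequence[MGELibraryEntry],
                         mean_read_length: float,
                         min_identity: float = 0.90,
                         min_length_fraction: float = 0.70,
                         window: int = 500,
                         searcher: Optional[HomologySearcher] = None
                         ) -> List[MGEAnnotation]:
    searcher = searcher or HomologySearcher(library)
    annotations = []
    for bp in breakpoints:
        queries = gather_support_reads(bp, support, window)
        hits = homology_search(queries, library, min_identity,
                               min_length_fraction, mean_read_length, searcher)
        annotations.append(majority_vote(hits, bp))
    return annotations
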