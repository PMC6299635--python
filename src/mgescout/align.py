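"""Local alignment primitives shared by annotation, assembly and evaluation.

The scorer is a standard affine-gap Smith-Waterman with full traceback
(gap of length L costs open + (L-1)*extend, i.e. the open charge sits on
the first gap base). A k-mer seeded, windowed variant keeps whole-library
homology searches fast: exact seed diagonals select a subject window and
the full DP runs only inside it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass(slots=True)
class LocalAlignment:
    """0-based half-open coordinates on query and subject."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap_open, gap_extend):
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10 ** 8, dtype=np.int32)  # gap in subject (up)
    F = np.full((n + 1, m + 1), -10 ** 8, dtype=np.int32)  # gap in query (left)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 fromE, 3 fromF
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 opened, 1 extended
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] + gap_open
            e_ext = E[i - 1, j] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i, j - 1] + gap_open
            f_ext = F[i, j - 1] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            sub = match if qi == s[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


@njit(cache=True)
def _sw_trace(q, s, bi, bj, ptrH, ptrE, ptrF):
    i, j = bi, bj
    matches = 0
    columns = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in subject: consume query base
            ext = ptrE[i, j]
            columns += 1
            i -= 1
            if ext == 0:
                state = 0
        else:  # gap in query: consume subject base
            ext = ptrF[i, j]
            columns += 1
            j -= 1
            if ext == 0:
                state = 0
    return i, j, matches, columns


def sw_align(query, subject, match: int = 1, mismatch: int = -3,
             gap_open: int = -5, gap_extend: int = -2) -> LocalAlignment:
    """Optimal local alignment of two sequences (str or uint8 arrays)."""
    q = seq_to_u8(query) if isinstance(query, str) else query
    s = seq_to_u8(subject) if isinstance(subject, str) else subject
    if len(q) == 0 or len(s) == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    best, bi, bj, ptrH, ptrE, ptrF = _sw_fill(
        q, s, match, mismatch, gap_open, gap_extend)
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    i0, j0, matches, columns = _sw_trace(q, s, bi, bj, ptrH, ptrE, ptrF)
    return LocalAlignment(int(best), i0, bi, j0, bj, int(matches), int(columns))


# ---------------------------------------------------------------------------
# Seeded search

class SeedIndex:
    """Exact k-mer index over a set of subject sequences (forward strand)."""

    def __init__(self, subjects: Sequence[Tuple[str, str]], k: int = 11,
                 max_seed_frequency: int = 32):
        self.k = k
        self.names = [name for name, _ in subjects]
        self.seqs = [seq.upper() for _, seq in subjects]
        self.arrs = [seq_to_u8(s) for s in self.seqs]
        index: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
        for idx, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                index[seq[pos:pos + k]].append((idx, pos))
        # mask ubiquitous seeds (homopolymer tails, simple repeats): they
        # seed everywhere and carry no positional information
        self.index = {kmer: hits for kmer, hits in index.items()
                      if len(hits) <= max_seed_frequency}

    def seed_diagonals(self, query: str) -> Dict[int, Dict[int, int]]:
        """subject idx -> {diagonal: seed count}; diagonal = s_pos - q_pos."""
        k = self.k
        hits: Dict[int, Dict[int, int]] = {}
        for qpos in range(len(query) - k + 1):
            for idx, spos in self.index.get(query[qpos:qpos + k], ()):
                d = hits.setdefault(idx, {})
                diag = spos - qpos
                d[diag] = d.get(diag, 0) + 1
        return hits

    def search(self, query: str, match: int = 1, mismatch: int = -2,
               gap_open: int = -5, gap_extend: int = -2,
               pad: int = 25, max_windows: int = 3, top_subjects: int = 4
               ) -> List[Tuple[int, LocalAlignment]]:
        """Best windowed local alignment per seeded subject.

        Seed diagonals within ``pad`` of each other are pooled into one
        subject window, ranked by seed count; at most ``max_windows``
        windows per subject are extended with the full DP, and only the
        ``top_subjects`` subjects with most seeds are extended at all (a
        homologous subject dominates the seed tally long before the DP).
        Long queries extend their single best window only.
        """
        query = query.upper()
        q = seq_to_u8(query)
        if len(q) > 300:
            max_windows = 1
        results: List[Tuple[int, LocalAlignment]] = []
        seeded = self.seed_diagonals(query)
        ranked = sorted(seeded.items(),
                        key=lambda kv: (-sum(kv[1].values()), kv[0]))[:top_subjects]
        for idx, diags in ranked:
            s = self.arrs[idx]
            # cluster diagonals
            items = sorted(diags.items())
            clusters: List[List[int]] = []  # [diag_lo, diag_hi, count]
            for diag, cnt in items:
                if clusters and diag - clusters[-1][1] <= pad:
                    clusters[-1][1] = diag
                    clusters[-1][2] += cnt
                else:
                    clusters.append([diag, diag, cnt])
            clusters.sort(key=lambda c: -c[2])
            best: Optional[LocalAlignment] = None
            for diag_lo, diag_hi, _ in clusters[:max_windows]:
                w0 = max(0, diag_lo - pad)
                w1 = min(len(s), diag_hi + len(q) + pad)
                aln = sw_align(q, s[w0:w1], match, mismatch, gap_open, gap_extend)
                aln = LocalAlignment(aln.score, aln.q_start, aln.q_end,
                                     aln.s_start + w0, aln.s_end + w0,
                                     aln.matches, aln.columns)
                if best is None or aln.score > best.score:
                    best = aln
            if best is not None and best.score > 0:
                results.append((idx, best))
        return results


def warm_up() -> None:
    """Trigger numba compilation once (useful before timing runs)."""
    sw_align("ACGTACGT", "ACGTACGT")
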