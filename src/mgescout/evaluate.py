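"""Scoring of predictions against simulator ground truth.

Breakpoints match greedily one-to-one when the gap between the predicted
interval and the true insertion coordinate is at most 20 bp (the interval
itself may cover the coordinate). Element-type calls are scored with one
reported type per breakpoint — reporting more than one type is a false
positive — at family level by default, and a novel insertion counts as
recovered only when its assembled sequence matches the true fragment
within two bases at each end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import revcomp, sw_align
from .annotate import MGEAnnotation
from .assemble import InsertSequence
from .breakpoints import Breakpoint
from .simulate import TruthRecord

Interval = Tuple[str, int, int]


@dataclass
class ScoreReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    per_category: Dict[str, Tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict)
    matches: List[Tuple[int, int, int]] = field(default_factory=list)

    @property
    def recall(self) -> Optional[float]:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else None

    @property
    def precision(self) -> Optional[float]:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else None

    def category_recalls(self) -> Dict[str, Optional[float]]:
        return {k: rec for k, (rec, _) in self.per_category.items()}

    def mean_category_recall(self) -> Optional[float]:
        vals = [r for r, _ in self.per_category.values() if r is not None]
        return sum(vals) / len(vals) if vals else None


def _interval_of(pred) -> Interval:
    if isinstance(pred, Breakpoint):
        return (pred.reference_name, pred.interval_start, pred.interval_end)
    ref, start, end = pred[:3]
    return (ref, int(start), int(end))


def _distance(interval: Interval, truth: TruthRecord) -> Optional[int]:
    ref, start, end = interval
    if ref != truth.reference_name:
        return None
    c = truth.insertion_coordinate
    if start <= c <= end:
        return 0
    return min(abs(start - c), abs(end - c))


def match_breakpoints(predicted: Sequence, truth: Sequence[TruthRecord],
                      tolerance: int = 20) -> List[Tuple[int, int, int]]:
    """Greedy nearest-first one-to-one matching: [(pred_idx, truth_idx, dist)]."""
    pairs = []
    intervals = [_interval_of(p) for p in predicted]
    for pi, interval in enumerate(intervals):
        for ti, tr in enumerate(truth):
            d = _distance(interval, tr)
            if d is not None and d <= tolerance:
                pairs.append((d, pi, ti))
    pairs.sort()
    used_p, used_t = set(), set()
    matches = []
    for d, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti, d))
    return matches


def score_breakpoints(predicted: Sequence, truth: Sequence[TruthRecord],
                      tolerance: int = 20) -> ScoreReport:
    matches = match_breakpoints(predicted, truth, tolerance)
    matched_t = {ti for _, ti, _ in matches}
    tp = len(matches)
    report = ScoreReport(tp, len(predicted) - tp, len(truth) - tp, matches=matches)
    by_cat: Dict[str, List[int]] = {}
    for ti, tr in enumerate(truth):
        by_cat.setdefault(tr.category or "all", []).append(ti)
    for cat, indices in sorted(by_cat.items()):
        hits = sum(1 for ti in indices if ti in matched_t)
        report.per_category[cat] = (hits / len(indices) if indices else None, None)
    return report


# ---------------------------------------------------------------------------
# MGE-type scoring

TYPED = ("unassigned",)  # annotations with these names carry no type call


def _reported_types(ann: MGEAnnotation) -> int:
    """Number of distinct element types the annotation reports (must be 1)."""
    return 0 if ann.voted_name in TYPED else 1


def contig_completeness(reported: str, truth_insert: str,
                        max_end_difference: int = 2,
                        min_interior_identity: float = 0.99) -> bool:
    """Does the assembled sequence reproduce the true fragment end to end
    (either strand), with at most ``max_end_difference`` bases missing or
    extra at each end and a near-perfect interior?"""
    if not reported or not truth_insert:
        return False
    for seq in (reported, revcomp(reported)):
        aln = sw_align(seq, truth_insert, match=1, mismatch=-3,
                       gap_open=-5, gap_extend=-2)
        if aln.columns == 0:
            continue
        left = max(aln.q_start, aln.s_start)
        right = max(len(seq) - aln.q_end, len(truth_insert) - aln.s_end)
        if (left <= max_end_difference and right <= max_end_difference
                and aln.identity >= min_interior_identity):
            return True
    return False


def score_mge_types(annotations: Sequence[MGEAnnotation],
                    truth: Sequence[TruthRecord],
                    inserts: Optional[Dict[int, InsertSequence]] = None,
                    tolerance: int = 20,
                    family_level: bool = True,
                    max_end_difference: int = 2) -> ScoreReport:
    """Score the reported element types against truth.

    ``inserts`` maps annotation index -> assembled insert, needed to judge
    novel-truth records ("accurate insertion sequence"). A truth record
    whose breakpoint is found but typed wrongly yields both a false
    positive and a false negative; a typed prediction with no matching
    truth is a false positive; truths without any matched annotation are
    false negatives.
    """
    inserts = inserts or {}
    matches = match_breakpoints([a.breakpoint for a in annotations], truth, tolerance)
    matched_t = {ti: pi for pi, ti, _ in matches}
    tp = fp = fn = 0
    correct_t: set = set()
    for ti, tr in enumerate(truth):
        pi = matched_t.get(ti)
        if pi is None:
            fn += 1
            continue
        ann = annotations[pi]
        n_types = _reported_types(ann)
        if n_types != 1:
            fn += 1
            continue
        if tr.element_name == "novel":
            ins = inserts.get(pi)
            ok = (ann.voted_name == "novel" and ins is not None
                  and contig_completeness(ins.trimmed_sequence,
                                          tr.inserted_sequence,
                                          max_end_difference))
        elif family_level:
            ok = (ann.voted_name not in ("novel",)
                  and ann.voted_family == tr.element_family)
        else:
            ok = ann.voted_name == tr.element_name
        if ok:
            tp += 1
            correct_t.add(ti)
        else:
            fn += 1
            fp += 1
    matched_p = set(matched_t.values())
    for pi, ann in enumerate(annotations):
        if pi not in matched_p and _reported_types(ann) >= 1:
            fp += 1  # a typed prediction with no true insertion behind it
    report = ScoreReport(tp, fp, fn)
    by_cat: Dict[str, List[int]] = {}
    for ti, tr in enumerate(truth):
        by_cat.setdefault(tr.category or "all", []).append(ti)
    for cat, indices in sorted(by_cat.items()):
        hits = sum(1 for ti in indices if ti in correct_t)
        report.per_category[cat] = (hits / len(indices) if indices else None, None)
    return report


def novel_insert_recall(annotations: Sequence[MGEAnnotation],
                        truth: Sequence[TruthRecord],
                        inserts: Dict[int, InsertSequence],
                        tolerance: int = 20,
                        max_end_difference: int = 2) -> Optional[float]:
    """Fraction of novel truth records whose breakpoint is found and whose
    assembled, trimmed insert passes the completeness check."""
    novel = [(ti, tr) for ti, tr in enumerate(truth) if tr.element_name == "novel"]
    if not novel:
        return None
    matches = match_breakpoints([a.breakpoint for a in annotations], truth, tolerance)
    matched_t = {ti: pi for pi, ti, _ in matches}
    hits = 0
    for ti, tr in novel:
        pi = matched_t.get(ti)
        if pi is None or pi not in inserts:
            continue
        if contig_completeness(inserts[pi].trimmed_sequence, tr.inserted_sequence,
                               max_end_difference):
            hits += 1
    return hits / len(novel)
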