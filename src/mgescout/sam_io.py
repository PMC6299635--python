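"""SAM / FASTA / GFF3 input-output and the uniform alignment record.

SAM text is the contract for alignments (BAM works too, through pysam);
FASTA carries the reference, the MGE library and assembled contigs; GFF3 is
the primary annotated output. Coordinates are 1-based inclusive everywhere
user-facing, matching SAM and GFF conventions.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Dict, Iterable, Iterator, List, Optional, Tuple

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

# SAM FLAG bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

# CIGAR op codes (BAM encoding, as used by pysam)
OP_M, OP_I, OP_D, OP_N, OP_S, OP_H, OP_P, OP_EQ, OP_X = range(9)
_QUERY_OPS = {OP_M, OP_I, OP_S, OP_EQ, OP_X}
_REF_OPS = {OP_M, OP_D, OP_N, OP_EQ, OP_X}
CIGAR_CHARS = "MIDNSHP=X"
_CIGAR_CODE = {c: i for i, c in enumerate(CIGAR_CHARS)}


class SamParseError(ValueError):
    pass


@dataclass(slots=True)
class AlignedRead:
    """One primary SAM record with decoded flags and CIGAR."""

    query_name: str
    flag: int
    reference_name: Optional[str]
    position: Optional[int]          # 1-based leftmost mapped coordinate
    mapping_quality: int
    cigar: List[Tuple[int, int]]     # [(op_code, length), ...]; empty if unmapped
    sequence: str
    qualities: str                   # phred+33 ASCII, "" when absent ("*")
    mate_reference: Optional[str]
    mate_position: Optional[int]
    template_length: int

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_first_in_pair(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    def reference_length(self) -> int:
        """Reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    def reference_end(self) -> Optional[int]:
        """1-based inclusive coordinate of the last mapped base."""
        if self.is_unmapped or self.position is None:
            return None
        return self.position + self.reference_length() - 1

    def aligned_length(self) -> int:
        """Query bases inside M/=/X ops (used for rescue tie-breaks)."""
        return sum(n for op, n in self.cigar if op in (OP_M, OP_EQ, OP_X))


@dataclass(slots=True)
class ClipInfo:
    """A soft-clipped tail of a read, anchored at a breakpoint edge.

    ``clip_coordinate`` is the 1-based reference position of the first
    mapped base for a left clip, and of the last mapped base for a right
    clip: the reference edge the clipped sequence hangs off.
    """

    side: str                        # "left" | "right"
    clip_length: int
    clipped_sequence: str
    clipped_qualities: str           # phred+33 ASCII ("" if unavailable)
    clip_coordinate: int

    def __post_init__(self):
        if self.clip_length != len(self.clipped_sequence):
            raise ValueError("clip_length must equal len(clipped_sequence)")


def parse_cigar(text: str) -> List[Tuple[int, int]]:
    if text == "*":
        return []
    out: List[Tuple[int, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in _CIGAR_CODE:
                raise SamParseError(f"unknown CIGAR op code in {text!r}")
            out.append((_CIGAR_CODE[ch], int(num)))
            num = ""
    if num:
        raise SamParseError(f"truncated CIGAR {text!r}")
    return out


def cigar_to_text(cigar: List[Tuple[int, int]]) -> str:
    if not cigar:
        return "*"
    return "".join(f"{n}{CIGAR_CHARS[op]}" for op, n in cigar)


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    unmapped = rec.is_unmapped
    cigar = [] if unmapped else list(rec.cigartuples or [])
    qual = rec.qual  # phred+33 string or None
    return AlignedRead(
        query_name=rec.query_name or "",
        flag=rec.flag,
        reference_name=None if rec.reference_id < 0 else rec.reference_name,
        position=None if unmapped or rec.reference_start < 0 else rec.reference_start + 1,
        mapping_quality=rec.mapping_quality,
        cigar=cigar,
        sequence=rec.query_sequence or "",
        qualities=qual or "",
        mate_reference=None if rec.next_reference_id < 0 else rec.next_reference_name,
        mate_position=None if rec.next_reference_start < 0 else rec.next_reference_start + 1,
        template_length=rec.template_length,
    )


def parse_alignments(source: str | Path | IO[str],
                     keep_secondary: bool = False) -> Iterator[AlignedRead]:
    """Yield one :class:`AlignedRead` per primary record of a SAM/BAM file.

    Secondary (0x100) and supplementary (0x800) records are skipped unless
    ``keep_secondary``. Malformed mandatory fields raise
    :class:`SamParseError` naming the record index; unknown optional fields
    are ignored (pysam tolerates them).
    """
    tmp_name = None
    if hasattr(source, "read"):  # file-like: pysam wants a path
        fh = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        fh.write(source.read())
        fh.close()
        path = tmp_name = fh.name
    else:
        path = os.fspath(source)
    try:
        try:
            af = pysam.AlignmentFile(path, check_sq=False)
        except ValueError as exc:
            raise SamParseError(f"cannot open SAM: {exc}") from exc
        with af:
            it = af.fetch(until_eof=True)
            i = 0
            while True:
                try:
                    rec = next(it)
                except StopIteration:
                    break
                except (ValueError, OSError) as exc:
                    raise SamParseError(f"malformed SAM record #{i + 1}: {exc}") from exc
                i += 1
                if not keep_secondary and (rec.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)):
                    continue
                yield _from_pysam(rec)
    finally:
        if tmp_name:
            os.unlink(tmp_name)


def clip_segments(read: AlignedRead) -> List[ClipInfo]:
    """Extract the 0-2 soft-clipped tails of a mapped read.

    Hard clips carry no sequence and yield nothing; they are skipped when
    locating the terminal soft clip.
    """
    if read.is_unmapped or not read.cigar or read.position is None:
        return []
    out: List[ClipInfo] = []
    cig = read.cigar
    # leading soft clip (possibly behind a hard clip)
    i = 0
    if i < len(cig) and cig[i][0] == OP_H:
        i += 1
    if i < len(cig) and cig[i][0] == OP_S:
        n = cig[i][1]
        out.append(ClipInfo("left", n, read.sequence[:n],
                            read.qualities[:n] if read.qualities else "",
                            read.position))
    # trailing soft clip
    j = len(cig) - 1
    if j >= 0 and cig[j][0] == OP_H:
        j -= 1
    if j > 0 and cig[j][0] == OP_S:
        n = cig[j][1]
        end = read.position + read.reference_length() - 1
        seq = read.sequence[len(read.sequence) - n:]
        qual = read.qualities[len(read.qualities) - n:] if read.qualities else ""
        out.append(ClipInfo("right", n, seq, qual, end))
    return out


def serialize_alignment(read: AlignedRead) -> str:
    """One SAM line (mandatory columns only)."""
    rnext = read.mate_reference or "*"
    if rnext != "*" and read.reference_name and rnext == read.reference_name:
        rnext = "="
    return "\t".join([
        read.query_name,
        str(read.flag),
        read.reference_name or "*",
        str(read.position or 0),
        str(read.mapping_quality),
        cigar_to_text(read.cigar),
        rnext,
        str(read.mate_position or 0),
        str(read.template_length),
        read.sequence or "*",
        read.qualities or "*",
    ])


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Dict[str, str]:
    """Name (up to first whitespace) -> sequence; duplicate names are an error."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else title
            if name in out:
                raise ValueError(f"duplicate FASTA name: {name}")
            out[name] = seq
    return out


def write_fasta(records: Dict[str, str] | Iterable[Tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _gff_escape(value: str) -> str:
    return (value.replace("%", "%25").replace(";", "%3B")
            .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09"))


def write_gff(annotations, path: str | Path, source: str = "mgescout") -> None:
    """Write one ``mobile_element_insertion`` feature per annotated breakpoint.

    Start/end are the 1-based inclusive breakpoint interval (its width is
    the TSD estimate), the score column is the supporting-read count, and
    attributes carry the voted element, the vote tally, support counts, the
    novelty flag and, when present, the assembled-insert identifier.
    """
    lines = ["##gff-version 3"]
    for i, ann in enumerate(annotations):
        bp = ann.breakpoint
        attrs = [
            f"ID=mgeins{i + 1}",
            f"Name={_gff_escape(ann.voted_name)}",
            f"mge_family={_gff_escape(ann.voted_family or 'NA')}",
            "vote_counts=" + _gff_escape(
                "|".join(f"{k}:{v}" for k, v in sorted(ann.vote_counts.items())) or "NA"),
            f"support_up={bp.upstream_support}",
            f"support_down={bp.downstream_support}",
            f"zygosity_ratio={bp.zygosity_ratio:.3f}",
            f"novel={'true' if ann.voted_name == 'novel' else 'false'}",
            f"assembled={'true' if ann.assembled else 'false'}",
        ]
        if getattr(ann, "insert_id", None):
            attrs.append(f"insert_id={_gff_escape(ann.insert_id)}")
        lines.append("\t".join([
            bp.reference_name, source, "mobile_element_insertion",
            str(bp.interval_start), str(bp.interval_end),
            str(ann.supporting_read_count), ".", ".", ";".join(attrs),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff_intervals(path: str | Path) -> List[Tuple[str, int, int, Dict[str, str]]]:
    """Minimal GFF3 reader for scoring: (seqid, start, end, attributes)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GFF line does not have 9 columns: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        out.append((cols[0], int(cols[3]), int(cols[4]), attrs))
    return out
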