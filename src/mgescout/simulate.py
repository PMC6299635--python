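"""Synthetic evaluation data: genomes with planted insertions, paired reads
and truth-aware alignments.

The generator reproduces the study conditions the detector is meant for:
a random reference (with optional N-masked blocks that insertions avoid),
an MGE consensus library over four families (LINE/SINE/LTR/DNA, with
poly-A tails on the retrotransposon families), a donor genome carrying
fragments >= 500 bp inserted at random positions with 2-9 bp target-site
duplications, 100 bp read pairs at 30x or 90x with insert size 400 +/- 20
and ~0.8% substitution error, and a coordinate-sorted SAM in which every
read is placed exactly where a local aligner would put it: full matches in
untouched sequence, soft clips across junctions, unmapped (placed at the
mate) inside inserts.

Two study designs are packaged as factories: a divergence ladder
(families at 0/10/20/30/40/50% SNV plus random-sequence controls) and a
known/diverged/novel mixture (exact library copies, ~15%-diverged sister
elements that are themselves in the library, and novel random fragments).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import MGELibraryEntry

REFERENCE_NAME = "chr1"
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")
Q_GOOD = 30 + 33   # constant base quality
Q_BAD = 10 + 33    # quality assigned to errored bases
MIN_MAPPED = 20    # a junction read needs this many reference bases to map

# family -> (min_len, max_len, has_polyA_tail)
FAMILY_SPECS = {
    "LINE": (1200, 2000, True),
    "SINE": (520, 800, True),
    "LTR": (800, 1500, False),
    "DNA": (600, 1200, False),
}
FAMILIES = tuple(FAMILY_SPECS)
NOVEL_LENGTH_RANGE = (520, 1500)
POLYA_RANGE = (12, 24)


@dataclass(slots=True)
class InsertionSpec:
    """One planned insertion: which element, how diverged, which category."""
    family: str
    divergence: float = 0.0
    novel: bool = False
    sister: bool = False      # diverged copy is itself a library entry
    category: str = ""


@dataclass(slots=True)
class TruthRecord:
    reference_name: str
    insertion_coordinate: int        # 1-based position before which the fragment sits
    inserted_sequence: str
    element_name: str                # library entry name or "novel"
    element_family: str
    tsd_length: int
    snv_fraction: float
    category: str = ""


@dataclass
class SimConfig:
    reference_length: int = 1_000_000
    n_insertions: int = 24
    divergence_levels: Sequence[float] = (0.0,)
    novel_fraction: float = 0.0
    sister_library: bool = False     # diverged elements live in the library
    tsd_range: Tuple[int, int] = (2, 9)
    read_length: int = 100
    coverage: float = 30.0
    insert_mean: float = 400.0
    insert_sd: float = 20.0
    error_rate: float = 0.008
    seed: int = 1
    n_masked_blocks: int = 3
    masked_block_length: int = 2000
    diploid: bool = False            # mix donor and reference reads 50/50
    plan: Optional[List[InsertionSpec]] = None

    def __post_init__(self):
        for name, rate in (("novel_fraction", self.novel_fraction),
                           ("error_rate", self.error_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= d <= 1.0 for d in self.divergence_levels):
            raise ValueError("divergence levels must be in [0, 1]")

    def build_plan(self) -> List[InsertionSpec]:
        if self.plan is not None:
            return list(self.plan)
        plan: List[InsertionSpec] = []
        n_novel = int(round(self.novel_fraction * self.n_insertions))
        n_known = self.n_insertions - n_novel
        cats = [(fam, div) for div in self.divergence_levels for fam in FAMILIES]
        for i in range(n_known):
            fam, div = cats[i % len(cats)]
            plan.append(InsertionSpec(fam, div, sister=self.sister_library,
                                      category=f"{fam}:snv{int(div * 100)}"))
        for i in range(n_novel):
            fam = FAMILIES[i % len(FAMILIES)]
            plan.append(InsertionSpec(fam, 0.0, novel=True, category="novel"))
        return plan


def simulation_set1_config(n_per_category: int = 8,
                           reference_length: int = 5_000_000,
                           coverage: float = 30.0, seed: int = 1) -> SimConfig:
    """Divergence-ladder design: every family without SNV, LINE/SINE/LTR at
    10-50% SNV, and random-sequence controls of family-typical length."""
    plan: List[InsertionSpec] = []
    for fam in FAMILIES:
        plan += [InsertionSpec(fam, 0.0, category=f"{fam}:snv0")
                 for _ in range(n_per_category)]
    for div in (0.10, 0.20, 0.30, 0.40, 0.50):
        for fam in ("LINE", "SINE", "LTR"):
            plan += [InsertionSpec(fam, div, category=f"{fam}:snv{int(div * 100)}")
                     for _ in range(n_per_category)]
    for fam in FAMILIES:
        plan += [InsertionSpec(fam, 0.0, novel=True, category=f"random:{fam}")
                 for _ in range(n_per_category)]
    return SimConfig(reference_length=reference_length, n_insertions=len(plan),
                     tsd_range=(0, 0), coverage=coverage, seed=seed, plan=plan)


def simulation_set2_config(n_per_group: int = 80,
                           reference_length: int = 5_000_000,
                           coverage: float = 30.0, seed: int = 1,
                           sister_divergence: float = 0.15) -> SimConfig:
    """Known/diverged/novel design: exact library copies, diverged sister
    elements (present in the library, like a cross-species consensus set),
    and novel random fragments; all with 2-9 bp TSDs."""
    plan: List[InsertionSpec] = []
    for i in range(n_per_group):
        plan.append(InsertionSpec(FAMILIES[i % 4], 0.0, category="human"))
    for i in range(n_per_group):
        plan.append(InsertionSpec(FAMILIES[i % 4], sister_divergence,
                                  sister=True, category="primate"))
    for i in range(n_per_group):
        plan.append(InsertionSpec(FAMILIES[i % 4], 0.0, novel=True,
                                  category="novel"))
    return SimConfig(reference_length=reference_length, n_insertions=len(plan),
                     tsd_range=(2, 9), coverage=coverage, seed=seed, plan=plan)


# ---------------------------------------------------------------------------
# Genome construction

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, length)]


def mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute at iid positions with a uniformly drawn base (so roughly
    three quarters of the draws actually change the base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < fraction
    arr[mask] = BASES[rng.integers(0, 4, int(mask.sum()))]
    return arr.tobytes().decode()


@dataclass
class SimulatedGenome:
    config: SimConfig
    reference: np.ndarray            # uint8 ASCII
    donor: np.ndarray                # uint8 ASCII
    library: List[MGELibraryEntry]
    truth: List[TruthRecord]
    # alternating segment model of the donor (reference segment / insert)
    seg_starts: np.ndarray           # donor start of each segment
    seg_is_insert: np.ndarray        # bool per segment
    seg_ref_starts: np.ndarray       # 0-based reference start (-1 for inserts)

    @property
    def reference_str(self) -> str:
        return self.reference.tobytes().decode()

    @property
    def donor_str(self) -> str:
        return self.donor.tobytes().decode()

    def reference_fasta(self) -> Dict[str, str]:
        return {REFERENCE_NAME: self.reference_str}

    def library_fasta(self) -> Dict[str, str]:
        return {f"{e.name}#{e.family}": e.sequence for e in self.library}


def _make_library_entry(rng, fam: str, name: str) -> MGELibraryEntry:
    lo, hi, polya = FAMILY_SPECS[fam]
    seq = _random_seq(rng, int(rng.integers(lo, hi + 1))).tobytes().decode()
    if polya:
        seq += "A" * int(rng.integers(*POLYA_RANGE))
    return MGELibraryEntry(name, fam, seq)


def _insertion_positions(rng, config: SimConfig, reference: np.ndarray) -> np.ndarray:
    """Random, sorted, well-separated 0-based positions avoiding N blocks."""
    n = config.n_insertions
    margin = 3000
    usable = config.reference_length - 2 * margin
    spacing = usable / max(n, 1)
    if spacing < 2500:
        raise ValueError("insertions denser than the genome allows")
    guard = 1200  # keep junction neighbourhoods independent
    positions = []
    is_n = reference == _N
    for i in range(n):
        lo = int(margin + i * spacing)
        hi = int(margin + (i + 1) * spacing - guard)
        for _ in range(200):
            pos = int(rng.integers(lo, hi))
            if not is_n[max(0, pos - guard):pos + guard].any():
                positions.append(pos)
                break
        else:
            raise ValueError("could not place an insertion outside N-masked blocks")
    return np.array(sorted(positions), dtype=np.int64)


def build_simulated_genome(config: SimConfig) -> SimulatedGenome:
    rng = np.random.default_rng(config.seed)
    reference = _random_seq(rng, config.reference_length)
    # N-masked blocks the insertion placer must avoid
    for _ in range(config.n_masked_blocks):
        start = int(rng.integers(10_000, config.reference_length
                                 - config.masked_block_length - 10_000))
        reference[start:start + config.masked_block_length] = _N

    plan = config.build_plan()
    library: List[MGELibraryEntry] = []
    counters: Dict[str, int] = {}
    inserts: List[Tuple[str, str, str, float]] = []  # (seq, name, family, divergence)
    for spec in plan:
        if spec.novel:
            length = int(rng.integers(*NOVEL_LENGTH_RANGE))
            seq = _random_seq(rng, length).tobytes().decode()
            inserts.append((seq, "novel", spec.family, 0.0))
            continue
        counters[spec.family] = counters.get(spec.family, 0) + 1
        base_name = f"{spec.family}-{counters[spec.family]}"
        entry = _make_library_entry(rng, spec.family, base_name)
        library.append(entry)
        if spec.divergence == 0.0:
            inserts.append((entry.sequence, entry.name, entry.family, 0.0))
        elif spec.sister:
            # the diverged element is itself a (cross-species) library entry,
            # inserted exactly
            sister = MGELibraryEntry(base_name + "_sister", spec.family,
                                     mutate(entry.sequence, spec.divergence, rng))
            library.append(sister)
            inserts.append((sister.sequence, sister.name, sister.family,
                            spec.divergence))
        else:
            # divergence applied at insertion; the library keeps the base entry
            inserts.append((mutate(entry.sequence, spec.divergence, rng),
                            entry.name, entry.family, spec.divergence))

    positions = _insertion_positions(rng, config, reference)
    tsd_lo, tsd_hi = config.tsd_range
    tsds = rng.integers(tsd_lo, tsd_hi + 1, size=len(plan))

    truth: List[TruthRecord] = []
    parts: List[np.ndarray] = []
    seg_starts, seg_is_insert, seg_ref_starts = [0], [False], [0]
    prev_ref = 0          # 0-based reference position where the current segment starts
    donor_len = 0
    # scatter the plan (built in category blocks) across the sorted positions
    perm = rng.permutation(len(plan))
    for rank, pos in enumerate(positions):
        idx = int(perm[rank])
        seq, name, family, div = inserts[idx]
        spec = plan[idx]
        c0 = int(pos)                        # 0-based: insert before this base
        t = int(tsds[idx])
        parts.append(reference[prev_ref:c0])
        donor_len += c0 - prev_ref
        ins_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        seg_starts.append(donor_len)
        seg_is_insert.append(True)
        seg_ref_starts.append(-1)
        parts.append(ins_arr)
        donor_len += len(ins_arr)
        # reference resumes t bases early: the duplicated target site
        prev_ref = c0 - t
        seg_starts.append(donor_len)
        seg_is_insert.append(False)
        seg_ref_starts.append(prev_ref)
        truth.append(TruthRecord(REFERENCE_NAME, c0 + 1, seq, name, family,
                                 t, div, spec.category))
    parts.append(reference[prev_ref:])
    donor = np.concatenate(parts) if parts else reference.copy()
    return SimulatedGenome(config, reference, donor, library, truth,
                           np.array(seg_starts, dtype=np.int64),
                           np.array(seg_is_insert, dtype=bool),
                           np.array(seg_ref_starts, dtype=np.int64))


# ---------------------------------------------------------------------------
# Read simulation

@dataclass
class ReadSet:
    """Paired reads in donor-forward orientation plus their true coordinates.

    ``seq1``/``seq2`` rows are donor-forward; mate 2 was sequenced from the
    reverse strand, so its FASTQ record is the reverse complement.
    """
    config: SimConfig
    frag_start: np.ndarray           # 0-based donor coordinate
    frag_len: np.ndarray
    seq1: np.ndarray                 # uint8 [n, read_length]
    seq2: np.ndarray
    qual1: np.ndarray
    qual2: np.ndarray
    from_reference: np.ndarray       # bool: read pair drawn from the reference haplotype

    @property
    def n_pairs(self) -> int:
        return len(self.frag_start)


_COMP_LUT = np.arange(256, dtype=np.uint8)
for a, b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_LUT[a] = b


def _apply_errors(rng, seqs: np.ndarray, quals: np.ndarray, rate: float) -> None:
    n_chunk = 250_000
    for lo in range(0, len(seqs), n_chunk):
        block = seqs[lo:lo + n_chunk]
        mask = rng.random(block.shape, dtype=np.float32) < rate
        mask &= block != _N
        # shift by 1-3 positions in the base alphabet: always a different base
        idx = np.searchsorted(BASES, block[mask])
        block[mask] = BASES[(idx + rng.integers(1, 4, idx.size)) % 4]
        quals[lo:lo + n_chunk][mask] = Q_BAD


def simulate_paired_reads(genome: SimulatedGenome,
                          config: Optional[SimConfig] = None) -> ReadSet:
    config = config or genome.config
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    donor = genome.donor
    sources = [donor]
    if config.diploid:
        sources = [donor, genome.reference]
    frag_starts, frag_lens, seqs1, seqs2, origin = [], [], [], [], []
    for src_idx, src in enumerate(sources):
        length = len(src)
        if length <= config.insert_mean + 4 * config.insert_sd:
            raise ValueError("genome too short for the configured insert size")
        n_pairs = int(round(config.coverage * length / (2 * rl) / len(sources)))
        fl = np.clip(np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                        n_pairs)).astype(np.int64),
                     rl, int(config.insert_mean + 5 * config.insert_sd))
        fs = (rng.random(n_pairs) * (length - fl + 1)).astype(np.int64)
        offs = np.arange(rl)
        seqs1.append(src[fs[:, None] + offs])
        seqs2.append(src[(fs + fl - rl)[:, None] + offs])
        frag_starts.append(fs)
        frag_lens.append(fl)
        origin.append(np.full(n_pairs, src_idx == 1))
    seq1 = np.concatenate(seqs1)
    seq2 = np.concatenate(seqs2)
    qual1 = np.full(seq1.shape, Q_GOOD, dtype=np.uint8)
    qual2 = np.full(seq2.shape, Q_GOOD, dtype=np.uint8)
    _apply_errors(rng, seq1, qual1, config.error_rate)
    _apply_errors(rng, seq2, qual2, config.error_rate)
    return ReadSet(config, np.concatenate(frag_starts), np.concatenate(frag_lens),
                   seq1, seq2, qual1, qual2, np.concatenate(origin))


def write_fastq(readset: ReadSet, path1, path2) -> None:
    rl = readset.config.read_length
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(readset.n_pairs):
            s1 = readset.seq1[i].tobytes().decode()
            q1 = readset.qual1[i].tobytes().decode()
            s2 = _COMP_LUT[readset.seq2[i]][::-1].tobytes().decode()
            q2 = readset.qual2[i][::-1].tobytes().decode()
            f1.write(f"@sim{i}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@sim{i}/2\n{s2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# Truth-aware alignment emission

CASE_FULL, CASE_RIGHT_CLIP, CASE_LEFT_CLIP, CASE_UNMAPPED = 0, 1, 2, 3


def _map_intervals(genome: SimulatedGenome, starts: np.ndarray, rl: int,
                   from_reference: np.ndarray):
    """Vectorised donor->reference placement of read intervals [a, a+rl)."""
    seg_starts = genome.seg_starts
    bounds = np.append(seg_starts, len(genome.donor))
    seg = np.searchsorted(bounds, starts, side="right") - 1
    seg_end = bounds[seg + 1]
    is_ins = genome.seg_is_insert[seg]
    ends = starts + rl
    crosses = ends > seg_end

    case = np.empty(len(starts), dtype=np.int8)
    pos0 = np.zeros(len(starts), dtype=np.int64)     # 0-based ref of first mapped base
    mapped = np.full(len(starts), rl, dtype=np.int64)

    ref_off = genome.seg_ref_starts[seg] + (starts - seg_starts[seg])
    # fully inside a reference segment
    full = ~is_ins & ~crosses
    case[full] = CASE_FULL
    pos0[full] = ref_off[full]
    # reference -> insert: right clip
    rc = ~is_ins & crosses
    case[rc] = CASE_RIGHT_CLIP
    pos0[rc] = ref_off[rc]
    mapped[rc] = (seg_end - starts)[rc]
    # wholly inside an insert
    inside = is_ins & ~crosses
    case[inside] = CASE_UNMAPPED
    # insert -> reference: left clip; alignment starts at the next segment
    lc = is_ins & crosses
    case[lc] = CASE_LEFT_CLIP
    # an insert segment is never last, so seg+1 is always a reference segment
    next_ref = genome.seg_ref_starts[np.minimum(seg + 1, len(seg_starts) - 1)]
    pos0[lc] = next_ref[lc]
    mapped[lc] = (ends - seg_end)[lc]
    # junction reads with too little reference sequence cannot be placed
    short = (case != CASE_UNMAPPED) & (mapped < MIN_MAPPED) & (mapped < rl)
    case[short] = CASE_UNMAPPED
    # reads drawn from the reference haplotype (diploid mode) map trivially
    if from_reference.any():
        ref_reads = from_reference
        case[ref_reads] = CASE_FULL
        pos0[ref_reads] = starts[ref_reads]
        mapped[ref_reads] = rl
    return case, pos0, mapped


def emit_truth_alignments(readset: ReadSet, genome: SimulatedGenome, path) -> None:
    """Write a valid coordinate-sorted SAM reflecting the true read placement."""
    config = readset.config
    rl = config.read_length
    n = readset.n_pairs
    a1 = readset.frag_start
    a2 = readset.frag_start + readset.frag_len - rl
    case1, pos1, map1 = _map_intervals(genome, a1, rl, readset.from_reference)
    case2, pos2, map2 = _map_intervals(genome, a2, rl, readset.from_reference)

    unm1 = case1 == CASE_UNMAPPED
    unm2 = case2 == CASE_UNMAPPED
    both_unmapped = unm1 & unm2

    flag1 = np.full(n, 0x1 | 0x40, dtype=np.int32)
    flag2 = np.full(n, 0x1 | 0x80, dtype=np.int32)
    flag2[~unm2] |= 0x10          # mate 2 sequenced from the reverse strand
    flag1[~unm2] |= 0x20
    flag1[unm1] |= 0x4
    flag2[unm1] |= 0x8
    flag2[unm2] |= 0x4
    flag1[unm2] |= 0x8

    # proper-pair bit and TLEN for doubly mapped templates
    both = ~unm1 & ~unm2
    left = np.minimum(pos1, pos2)
    right = np.maximum(pos1 + map1, pos2 + map2)
    tlen = np.where(both, right - left, 0)
    proper = both & (tlen <= config.insert_mean + 10 * config.insert_sd)
    flag1[proper] |= 0x2
    flag2[proper] |= 0x2
    tlen1 = np.where(both, np.where(pos1 <= pos2, tlen, -tlen), 0)
    tlen2 = np.where(both, -tlen1, 0)

    # SAM placement column: unmapped reads sit at their mapped mate
    sam_pos1 = np.where(unm1, np.where(unm2, -1, pos2), pos1)
    sam_pos2 = np.where(unm2, np.where(unm1, -1, pos1), pos2)

    order = np.lexsort((np.tile(np.arange(n), 2),
                        np.concatenate((sam_pos1, sam_pos2)),
                        np.concatenate((sam_pos1, sam_pos2)) < 0))
    which = np.concatenate((np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)))

    ref_len = len(genome.reference)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{REFERENCE_NAME}\tLN:{ref_len}\n")
        write = fh.write
        for k in order:
            i = int(k % n)
            if which[k] == 0:
                case, pos, mp, sp, msp, fl, tl = (case1[i], pos1[i], map1[i],
                                                  sam_pos1[i], sam_pos2[i],
                                                  flag1[i], tlen1[i])
                seq_arr, qual_arr = readset.seq1[i], readset.qual1[i]
                name = f"sim{i}"
            else:
                case, pos, mp, sp, msp, fl, tl = (case2[i], pos2[i], map2[i],
                                                  sam_pos2[i], sam_pos1[i],
                                                  flag2[i], tlen2[i])
                seq_arr, qual_arr = readset.seq2[i], readset.qual2[i]
                name = f"sim{i}"
            if case == CASE_FULL:
                cigar = f"{rl}M"
            elif case == CASE_RIGHT_CLIP:
                cigar = f"{mp}M{rl - mp}S"
            elif case == CASE_LEFT_CLIP:
                cigar = f"{rl - mp}S{mp}M"
            else:
                cigar = "*"
            if case == CASE_UNMAPPED and which[k] == 1:
                # unmapped reads are stored as sequenced (reverse strand for mate 2)
                seq = _COMP_LUT[seq_arr][::-1].tobytes().decode()
                qual = qual_arr[::-1].tobytes().decode()
            else:
                seq = seq_arr.tobytes().decode()
                qual = qual_arr.tobytes().decode()
            unmapped_pair = sp < 0
            write("\t".join((
                name,
                str(fl),
                "*" if unmapped_pair else REFERENCE_NAME,
                "0" if unmapped_pair else str(sp + 1),
                "0" if case == CASE_UNMAPPED else "60",
                cigar,
                "*" if unmapped_pair else "=",
                "0" if unmapped_pair else str((msp if msp >= 0 else sp) + 1),
                str(tl),
                seq,
                qual)) + "\n")


# ---------------------------------------------------------------------------
# Truth table I/O

TRUTH_COLUMNS = ["reference_name", "insertion_coordinate", "element_name",
                 "element_family", "tsd_length", "snv_fraction", "category",
                 "inserted_sequence"]


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(TRUTH_COLUMNS)
        for t in truth:
            writer.writerow([t.reference_name, t.insertion_coordinate,
                             t.element_name, t.element_family, t.tsd_length,
                             f"{t.snv_fraction:g}", t.category, t.inserted_sequence])


def read_truth(path) -> List[TruthRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(TruthRecord(
                row["reference_name"], int(row["insertion_coordinate"]),
                row["inserted_sequence"], row["element_name"],
                row["element_family"], int(row["tsd_length"]),
                float(row["snv_fraction"]), row.get("category", "")))
    return out


def simulate_bundle(config: SimConfig, outdir) -> Dict[str, Path]:
    """Generate and write the full evaluation bundle to a directory."""
    from .sam_io import write_fasta
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_simulated_genome(config)
    readset = simulate_paired_reads(genome)
    paths = {key: outdir / name for key, name in [
        ("reference", "reference.fa"), ("donor", "donor.fa"),
        ("library", "library.fa"), ("truth", "truth.tsv"),
        ("reads_1", "reads_1.fq"), ("reads_2", "reads_2.fq"),
        ("sam", "truth.sam")]}
    write_fasta(genome.reference_fasta(), paths["reference"])
    write_fasta({REFERENCE_NAME + "_donor": genome.donor_str}, paths["donor"])
    write_fasta(genome.library_fasta(), paths["library"])
    write_truth(genome.truth, paths["truth"])
    write_fastq(readset, paths["reads_1"], paths["reads_2"])
    emit_truth_alignments(readset, genome, paths["sam"])
    return paths
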