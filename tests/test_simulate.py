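"""Simulator correctness: genome construction, reads, truth alignments."""

import numpy as np
import pytest

from mgescout.align import revcomp
from mgescout.sam_io import parse_alignments, OP_M, OP_S
from mgescout.simulate import (REFERENCE_NAME, SimConfig,
                               build_simulated_genome, emit_truth_alignments,
                               mutate, read_truth, simulate_paired_reads,
                               simulation_set1_config, simulation_set2_config,
                               write_truth)


def small_config(**kw):
    base = dict(reference_length=120_000, n_insertions=4, coverage=20,
                seed=9, n_masked_blocks=1, masked_block_length=1500,
                divergence_levels=(0.0,))
    base.update(kw)
    return SimConfig(**base)


class TestGenomeConstruction:
    def test_no_insertions_leaves_reference_untouched(self):
        g = build_simulated_genome(small_config(n_insertions=0))
        assert np.array_equal(g.donor, g.reference)
        assert g.truth == []

    def test_tsd_duplicates_reference_bases_around_insert(self):
        g = build_simulated_genome(small_config(tsd_range=(7, 7)))
        donor = g.donor_str
        ref = g.reference_str
        for tr in g.truth:
            c0 = tr.insertion_coordinate - 1
            tsd = ref[c0 - 7:c0]
            i = donor.find(tr.inserted_sequence)
            assert i >= 0
            assert donor[i - 7:i] == tsd           # left copy
            assert donor[i + len(tr.inserted_sequence):
                         i + len(tr.inserted_sequence) + 7] == tsd  # right copy

    def test_snv_divergence_matches_binomial_expectation(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        diffs = [sum(a != b for a, b in zip(seq, mutate(seq, 0.10, np.random.default_rng(s))))
                 for s in range(30)]
        # expected Hamming distance: 1000 * 0.10 * 3/4 = 75
        assert 55 <= np.mean(diffs) <= 95

    def test_insertions_avoid_masked_blocks(self):
        g = build_simulated_genome(small_config(n_masked_blocks=2))
        is_n = g.reference == ord("N")
        for tr in g.truth:
            c0 = tr.insertion_coordinate - 1
            assert not is_n[c0 - 500:c0 + 500].any()
        assert set(tr.inserted_sequence) <= set("ACGT")

    def test_insert_lengths_at_least_500(self):
        g = build_simulated_genome(small_config(novel_fraction=0.5))
        assert all(len(t.inserted_sequence) >= 500 for t in g.truth)

    def test_overdense_insertions_rejected(self):
        with pytest.raises(ValueError, match="denser"):
            build_simulated_genome(small_config(reference_length=30_000,
                                                n_insertions=50))

    def test_set_factories_build_expected_categories(self):
        s1 = simulation_set1_config(n_per_category=2)
        cats1 = {spec.category for spec in s1.build_plan()}
        assert "LINE:snv10" in cats1 and "random:DNA" in cats1
        assert len(cats1) == 23
        s2 = simulation_set2_config(n_per_group=4)
        cats2 = [spec.category for spec in s2.build_plan()]
        assert cats2.count("human") == cats2.count("primate") == \
            cats2.count("novel") == 4

    def test_sister_entries_join_library(self):
        g = build_simulated_genome(
            simulation_set2_config(n_per_group=4, reference_length=200_000))
        names = {e.name for e in g.library}
        sisters = {n for n in names if n.endswith("_sister")}
        assert len(sisters) == 4
        inserted_sisters = {t.element_name for t in g.truth
                            if t.element_name.endswith("_sister")}
        assert inserted_sisters <= names


class TestReadSimulation:
    def test_read_count_follows_coverage_formula(self):
        g = build_simulated_genome(small_config())
        rs = simulate_paired_reads(g)
        expected = round(20 * len(g.donor) / (2 * 100))
        assert rs.n_pairs == expected

    def test_error_free_reads_are_donor_substrings(self):
        g = build_simulated_genome(small_config(error_rate=0.0))
        rs = simulate_paired_reads(g)
        donor = g.donor_str
        for i in range(0, rs.n_pairs, 500):
            assert rs.seq1[i].tobytes().decode() in donor
            assert rs.seq2[i].tobytes().decode() in donor

    def test_seed_determinism_is_byte_exact(self, tmp_path):
        outs = []
        for _ in range(2):
            g = build_simulated_genome(small_config())
            rs = simulate_paired_reads(g)
            p = tmp_path / "x.sam"
            emit_truth_alignments(rs, g, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_errored_bases_get_low_quality(self):
        g = build_simulated_genome(small_config(error_rate=0.05))
        rs = simulate_paired_reads(g)
        donor = g.donor
        i = 0
        s = rs.frag_start[i]
        orig = donor[s:s + 100]
        mism = rs.seq1[i] != orig
        assert (rs.qual1[i][mism] == 10 + 33).all()
        assert (rs.qual1[i][~mism] == 30 + 33).all()


def independent_mapping(genome, a, read_length):
    """Prefix-sum oracle: map a donor interval to the reference by walking
    the truth records directly."""
    donor_pos = 0
    ref_pos = 0
    segments = []  # (donor_start, donor_end, ref_start or None)
    for tr in sorted(genome.truth, key=lambda t: t.insertion_coordinate):
        c0 = tr.insertion_coordinate - 1
        seg_len = c0 - ref_pos
        segments.append((donor_pos, donor_pos + seg_len, ref_pos))
        donor_pos += seg_len
        segments.append((donor_pos, donor_pos + len(tr.inserted_sequence), None))
        donor_pos += len(tr.inserted_sequence)
        ref_pos = c0 - tr.tsd_length
    segments.append((donor_pos, len(genome.donor), ref_pos))
    b = a + read_length
    for d0, d1, r0 in segments:
        if d0 <= a < d1:
            if r0 is None:
                if b <= d1:
                    return ("unmapped",)
                mapped = b - d1
                return ("left", mapped)
            if b <= d1:
                return ("full", r0 + (a - d0))
            return ("right", r0 + (a - d0), d1 - a)
    raise AssertionError("interval not located")


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    g = build_simulated_genome(SimConfig(
        reference_length=150_000, n_insertions=5, coverage=15, seed=21,
        tsd_range=(2, 9), error_rate=0.005))
    rs = simulate_paired_reads(g)
    p = tmp_path_factory.mktemp("sam") / "truth.sam"
    emit_truth_alignments(rs, g, p)
    reads = list(parse_alignments(p))
    return g, rs, reads


class TestTruthAlignments:
    def test_straddling_reads_are_soft_clipped_at_junctions(self, bundle):
        g, rs, reads = bundle
        junctions = {t.insertion_coordinate - 1 for t in g.truth}  # up edges
        right_clip_coords = set()
        for r in reads:
            if r.cigar and r.cigar[-1][0] == OP_S and r.cigar[0][0] == OP_M:
                right_clip_coords.add(r.position + r.cigar[0][1] - 1)
        assert junctions <= right_clip_coords

    def test_mapping_cases_match_prefix_sum_oracle(self, bundle):
        g, rs, reads = bundle
        by_name = {}
        for r in reads:
            by_name.setdefault(r.query_name, []).append(r)
        rl = 100
        for i in range(0, rs.n_pairs, 97):
            mate1 = [r for r in by_name[f"sim{i}"] if r.is_first_in_pair][0]
            oracle = independent_mapping(g, int(rs.frag_start[i]), rl)
            if oracle[0] == "unmapped":
                assert mate1.is_unmapped
            elif oracle[0] == "full":
                assert mate1.cigar == [(OP_M, rl)]
                assert mate1.position == oracle[1] + 1
            elif oracle[0] == "right":
                assert not mate1.is_unmapped
                if mate1.cigar != [(OP_M, rl)]:
                    assert mate1.position == oracle[1] + 1
                    assert mate1.cigar[0] == (OP_M, oracle[2])

    def test_mapped_reads_match_reference_except_errors(self, bundle):
        g, rs, reads = bundle
        ref = g.reference_str
        checked = 0
        for r in reads[:4000]:
            if r.is_unmapped or len(r.cigar) != 1:
                continue
            span = ref[r.position - 1:r.position - 1 + 100]
            mism = sum(a != b for a, b in zip(r.sequence, span))
            low_q = sum(q != "?" for q in r.qualities)
            assert mism <= low_q  # every mismatch is a flagged error base
            checked += 1
        assert checked > 100

    def test_sam_is_coordinate_sorted(self, bundle):
        _, _, reads = bundle
        positions = [r.position for r in reads if r.position is not None]
        assert positions == sorted(positions)

    def test_unmapped_mate_placed_at_anchor(self, bundle):
        g, rs, reads = bundle
        by_name = {}
        for r in reads:
            by_name.setdefault(r.query_name, []).append(r)
        found = 0
        for name, pair in by_name.items():
            if len(pair) != 2:
                continue
            a, b = pair
            if a.is_unmapped != b.is_unmapped:
                unm = a if a.is_unmapped else b
                anc = b if a.is_unmapped else a
                assert unm.mate_position == anc.position
                found += 1
        assert found > 0


class TestDiploidMode:
    def test_half_of_reads_come_from_reference(self):
        g = build_simulated_genome(small_config(diploid=True))
        rs = simulate_paired_reads(g)
        frac = rs.from_reference.mean()
        assert 0.45 < frac < 0.55


class TestTruthTable:
    def test_round_trip(self, tmp_path):
        g = build_simulated_genome(small_config(novel_fraction=0.5))
        p = tmp_path / "truth.tsv"
        write_truth(g.truth, p)
        back = read_truth(p)
        assert back == g.truth
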