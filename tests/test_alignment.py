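"""Feature extraction from alignments: MD parsing, coordinate mapping,
context statistics and observation building."""

import math

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from plasmavar.alignment import (
    AlignedReadRecord,
    ContextError,
    MDParseError,
    ReadFilter,
    build_observations,
    extract_read_features,
    iter_alignments,
    map_query_to_reference,
    parse_md_mismatches,
    read_cycle,
    window_stats,
)


def rec(seq="ACGTACGTACGTACGT", md=None, cigar=None, flags=99, pos=1000,
        isize=180, chrom="chr1", **kw):
    cigar = cigar or f"{len(seq)}M"
    md = md if md is not None else str(len(seq))
    return AlignedReadRecord(query_name="r1", flags=flags, chrom=chrom,
                             pos=pos, cigar=cigar, md=md, isize=isize,
                             seq=seq, **kw)


class TestMDParsing:
    def test_all_match(self):
        assert parse_md_mismatches(rec(seq="ACGTA", md="5")) == []

    def test_single_substitution(self):
        r = rec(seq="ACGTACGTACGTACGT", md="10A5")
        assert parse_md_mismatches(r) == [(10, "A", r.seq[10])]

    def test_leading_and_trailing_zero_runs(self):
        r = rec(seq="GCGTA", md="0C3T0")
        assert parse_md_mismatches(r) == [(0, "C", "G"), (4, "T", "A")]

    def test_deletion_consumes_reference_only(self):
        # 5M2D5M: MD deletion run between the match blocks, no query entry
        r = rec(seq="ACGTAACGTA", cigar="5M2D5M", md="5^TT5")
        assert parse_md_mismatches(r) == []

    def test_mismatch_after_insertion_offsets_are_query_based(self):
        # 4M2I4M: insertion shifts query offsets but not MD accounting
        r = rec(seq="ACGTTTACGT", cigar="4M2I4M", md="4C3")
        assert parse_md_mismatches(r) == [(6, "C", "A")]

    def test_malformed_md_raises(self):
        with pytest.raises(MDParseError, match="malformed"):
            parse_md_mismatches(rec(seq="ACGTA", md="2+3"))

    def test_md_cigar_inconsistency_raises(self):
        with pytest.raises(MDParseError):
            parse_md_mismatches(rec(seq="ACGTA", md="10"))
        with pytest.raises(MDParseError):
            parse_md_mismatches(rec(seq="ACGTA", md="1A1A1A1A1A1A"))


class TestQueryToReference:
    def test_pure_match(self):
        assert map_query_to_reference("100M", 1000, 10) == 1010

    def test_soft_clip_returns_none(self):
        assert map_query_to_reference("5S95M", 1000, 4) is None
        assert map_query_to_reference("5S95M", 1000, 5) == 1000

    def test_deletion_shifts_reference(self):
        assert map_query_to_reference("10M2D10M", 1000, 10) == 1012

    def test_insertion_has_no_reference_coordinate(self):
        assert map_query_to_reference("5M3I5M", 1000, 6) is None
        assert map_query_to_reference("5M3I5M", 1000, 8) == 1005

    def test_offset_out_of_range(self):
        with pytest.raises(IndexError):
            map_query_to_reference("10M", 1000, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_agrees_with_pysam_aligned_pairs(self, seed):
        """Random CIGARs: our walk must match pysam's aligned-pairs table."""
        rng = np.random.default_rng(seed)
        ops = []
        # clip / match / indel mix; always at least one M block
        if rng.random() < 0.3:
            ops.append((int(rng.integers(1, 6)), "S"))
        ops.append((int(rng.integers(1, 30)), "M"))
        for _ in range(int(rng.integers(0, 3))):
            ops.append((int(rng.integers(1, 5)),
                        str(rng.choice(["I", "D", "N"]))))
            ops.append((int(rng.integers(1, 30)), "M"))
        if rng.random() < 0.3:
            ops.append((int(rng.integers(1, 6)), "S"))
        cigar = "".join(f"{n}{op}" for n, op in ops)
        qlen = sum(n for n, op in ops if op in "MIS")
        header = pysam.AlignmentHeader.from_dict(
            {"SQ": [{"SN": "c", "LN": 100000}]})
        a = pysam.AlignedSegment(header)
        a.query_name = "q"
        a.reference_id = 0
        a.reference_start = 499
        a.cigarstring = cigar
        a.query_sequence = "A" * qlen
        expected = {q: (r + 1 if r is not None else None)
                    for q, r in a.get_aligned_pairs() if q is not None}
        for q in range(qlen):
            assert map_query_to_reference(cigar, 500, q) == expected[q]


class TestWindowStats:
    def test_homopolymer(self):
        ref = {"c": "GGGGGGGGGGG"}
        ctx = window_stats(ref, "c", 6)
        assert ctx.gc_content == 1.0
        assert ctx.entropy_1mer == 0.0
        assert ctx.trinucleotide == "GGG"

    def test_periodic_window(self):
        ref = {"c": "ACGTACGTACG"}
        ctx = window_stats(ref, "c", 6)
        assert ctx.gc_content == pytest.approx(6 / 11)
        # counts A3 C3 G3 T2
        expected = -(3 * (3 / 11) * math.log2(3 / 11)
                     + (2 / 11) * math.log2(2 / 11))
        assert ctx.entropy_1mer == pytest.approx(expected, abs=1e-9)
        assert ctx.entropy_1mer == pytest.approx(1.9808, abs=5e-4)
        assert ctx.trinucleotide == "ACG"
        assert ctx.trinucleotide == ctx.window[4:7]

    def test_edge_and_ambiguous_windows_rejected(self):
        ref = {"c": "ACGTACGTACGTACG"}
        with pytest.raises(ContextError):
            window_stats(ref, "c", 3)
        with pytest.raises(ContextError):
            window_stats({"c": "ACGTANGTACG"}, "c", 6)

    def test_entropy_2mer_counts_overlapping_pairs(self):
        ctx = window_stats({"c": "AAAAAAAAAAA"}, "c", 6)
        assert ctx.entropy_2mer == 0.0


class TestReadFeatures:
    def test_flag_decoding(self):
        f = extract_read_features(rec(flags=99))
        assert f["strand"] == "forward" and f["first_in_pair"] is True
        f = extract_read_features(rec(flags=147))
        assert f["strand"] == "reverse" and f["first_in_pair"] is False

    def test_fragment_size_is_absolute_isize(self):
        assert extract_read_features(rec(isize=-180))["fragment_size"] == 180

    def test_indel_counts_from_cigar(self):
        r = rec(seq="ACGTACGTAC", cigar="4M1I3M2D2M", md="7^TT2")
        f = extract_read_features(r)
        assert f["n_insertions"] == 1 and f["n_deletions"] == 1

    def test_read_cycle_reverse_counts_from_right(self):
        fwd = rec(flags=99, seq="ACGTACGT", md="8", cigar="8M")
        rev = rec(flags=147, seq="ACGTACGT", md="8", cigar="8M")
        assert read_cycle(fwd, 0) == 1
        assert read_cycle(rev, 0) == 8
        assert read_cycle(rev, 7) == 1


class TestBuildObservations:
    REF = {"chr1": "A" * 2020}

    def test_mismatch_harvest(self):
        r = rec(seq="AAAAAAAAAACAAAAA", md="10A5", pos=1000)
        obs = build_observations(r, self.REF)
        assert len(obs) == 1
        o = obs[0]
        assert o.ref_allele == "A" and o.obs_allele == "C"
        assert o.genomic_pos == 1010
        assert o.n_other_errors == 0
        assert o.read_position == 11  # forward strand: query offset + 1

    def test_excluded_site_dropped(self):
        r = rec(seq="AAAAAAAAAACAAAAA", md="10A5", pos=1000)
        obs = build_observations(r, self.REF, exclusions={("chr1", 1010)})
        assert obs == []

    def test_reference_matching_read_yields_nothing(self):
        r = rec(seq="A" * 16, md="16", pos=1000)
        assert build_observations(r, self.REF) == []

    def test_n_observation_dropped(self):
        r = rec(seq="AAAAAAAAAANAAAAA", md="10A5", pos=1000)
        assert build_observations(r, self.REF) == []

    def test_target_sites_include_matches(self):
        r = rec(seq="A" * 16, md="16", pos=1000)
        sites = {("chr1", 1005): ("A", "T")}
        obs = build_observations(r, self.REF, target_sites=sites)
        assert len(obs) == 1
        assert obs[0].obs_allele == obs[0].ref_allele == "A"
        assert obs[0].genomic_pos == 1005

    def test_n_other_errors_excludes_own_position(self):
        r = rec(seq="CAAAAAAAAAAAAAAG", md="0A14A0", pos=1000)
        obs = build_observations(r, self.REF)
        assert len(obs) == 2
        assert all(o.n_other_errors == 1 for o in obs)

    def test_unpaired_zero_isize_excluded(self):
        r = rec(seq="AAAAAAAAAACAAAAA", md="10A5", pos=1000, isize=0)
        assert build_observations(r, self.REF) == []

    def test_trimmed_cycles_excluded(self):
        r = rec(seq="CAAAAAAAAAAAAAAA", md="0A15", pos=1000)
        rf = ReadFilter(trim_start=2)
        assert build_observations(r, self.REF, read_filter=rf) == []


class TestRoundTrip:
    def test_harvest_equals_injected_truth(self, sim_reference, sim_fixture):
        """Every simulated substitution (away from contig edges) is
        recovered with identical (read, chrom, pos, ref, obs)."""
        chrom = next(iter(sim_reference))
        n = len(sim_reference[chrom])
        harvested = set()
        for r in iter_alignments(str(sim_fixture["sam"])):
            for o in build_observations(r, sim_reference):
                harvested.add((o.query_name, o.chrom, o.genomic_pos,
                               o.ref_allele, o.obs_allele))
        truth = {tuple(t) for t in sim_fixture["truth"][
            ["query_name", "chrom", "pos", "ref", "obs"]].itertuples(index=False)}
        truth = {t for t in truth if 6 <= t[2] <= n - 5}
        assert harvested == truth

    def test_context_recomputation_is_bit_exact(self, sim_reference, sim_fixture):
        for r in iter_alignments(str(sim_fixture["sam"])):
            for o in build_observations(r, sim_reference):
                again = window_stats(sim_reference, o.chrom, o.genomic_pos)
                assert again == o.context

    def test_md_parse_agrees_with_per_base_reconstruction(
            self, sim_reference, sim_fixture):
        """Mismatch sets from MD parsing equal direct seq-vs-reference
        comparison for every simulated read."""
        chrom = next(iter(sim_reference))
        ref = sim_reference[chrom]
        for r in iter_alignments(str(sim_fixture["sam"])):
            direct = {(q, ref[r.pos - 1 + q], r.seq[q])
                      for q in range(len(r.seq))
                      if r.seq[q] != ref[r.pos - 1 + q]}
            assert set(parse_md_mismatches(r)) == direct
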