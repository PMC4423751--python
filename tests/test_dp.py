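import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedwave.dp import (
    AlignmentResult,
    ScoringScheme,
    align_candidate,
    align_window,
    fill_antidiagonal,
    pack_cell,
    rescore_cigar,
    traceback,
    unpack_cell,
)
from seedwave.seeding import CandidateRegion
from seedwave import Reference

from oracles import gotoh_best, gotoh_dense, random_genome


def _random_scheme(rng) -> ScoringScheme:
    e = int(rng.integers(1, 4))
    return ScoringScheme(
        match=int(rng.integers(1, 6)),
        mismatch=int(rng.integers(1, 7)),
        gap_open=int(rng.integers(e, 8)),
        gap_extend=e,
    )


# ---- packed cells -----------------------------------------------------------


@settings(derandomize=True, max_examples=200)
@given(st.integers(-(1 << 20), (1 << 20) - 1),
       st.integers(-(1 << 20), (1 << 20) - 1),
       st.integers(-(1 << 20), (1 << 20) - 1))
def test_pack_unpack_roundtrip(m, i, d):
    assert unpack_cell(pack_cell(m, i, d)) == (m, i, d)


def test_pack_saturation_is_explicit():
    with pytest.raises(OverflowError):
        pack_cell(1 << 20, 0, 0)
    with pytest.raises(OverflowError):
        pack_cell(0, 0, -(1 << 20) - 1)


# ---- fill -------------------------------------------------------------------


def test_identity_alignment_scores_full_match():
    table = fill_antidiagonal("ACGT", "ACGT", ScoringScheme(match=1))
    assert table.best_score() == 4
    res = traceback(table)
    assert res.cigar_string == "4M" and res.ref_start == 0


def test_mismatch_vs_gap_tradeoff_matches_oracle():
    # frozen from the row-major Gotoh oracle: local model clips the
    # trailing T (3 matches) rather than paying the mismatch or a gap
    sc = ScoringScheme(1, 2, 3, 1)
    assert gotoh_best("ACGT", "ACGAT", 1, 2, 3, 1) == 3
    res = align_window("ACGT", "ACGAT", sc)
    assert res.score == 3 and res.cigar_string == "3M1S"


def test_window_shorter_than_read_rejected():
    with pytest.raises(ValueError):
        fill_antidiagonal("ACGTACGT", "ACG")


def test_diagonal_mapping_is_bijection():
    table = fill_antidiagonal("ACGTA", "ACGTACG")
    m, n = table.m, table.n
    offsets = {table.diag_offset(i, j) for i in range(m + 1) for j in range(n + 1)}
    assert offsets == set(range((m + 1) * (n + 1)))


def test_lane_width_invariance(rng):
    for _ in range(10):
        read = random_genome(rng, int(rng.integers(5, 80)))
        win = random_genome(rng, len(read) + int(rng.integers(0, 60)))
        sc = _random_scheme(rng)
        tables = [fill_antidiagonal(read, win, sc, lw) for lw in (1, 4, 16)]
        assert np.array_equal(tables[0].flat, tables[1].flat)
        assert np.array_equal(tables[1].flat, tables[2].flat)


def test_dense_tables_equal_row_major_recurrence(rng):
    for _ in range(25):
        read = random_genome(rng, int(rng.integers(3, 50)))
        win = random_genome(rng, len(read) + int(rng.integers(0, 40)))
        sc = _random_scheme(rng)
        M, I, D = fill_antidiagonal(read, win, sc).to_dense()
        Mo, Io, Do = gotoh_dense(read, win, sc.match, sc.mismatch,
                                 sc.gap_open, sc.gap_extend)
        assert np.array_equal(M, Mo)
        assert np.array_equal(I, Io)
        assert np.array_equal(D, Do)


# ---- traceback --------------------------------------------------------------


def test_soft_clip_of_unmatched_prefix():
    res = align_window("TTACGT", "ACGTAAAA", ScoringScheme(1, 2, 3, 1))
    assert res.cigar_string == "2S4M"
    assert res.score == 4 and res.ref_start == 0


def test_deletion_cigar_rescores_to_reported_score():
    sc = ScoringScheme(1, 2, 3, 1)
    read, win = "AACGTGTCATGC", "AACGTGATCATGC"  # extra A in the window
    res = align_window(read, win, sc)
    assert res.cigar_string == "6M1D6M"
    assert res.score == 12 - sc.gap_first == rescore_cigar(res, read, win, sc)
    assert res.score == gotoh_best(read, win, 1, 2, 3, 1)
    assert res.n_indel == 1 and res.n_mismatch == 0


def test_unalignable_read_reports_unmapped():
    res = align_window("AAAA", "CCCCCCCC", ScoringScheme(1, 2, 3, 1))
    assert not res.mapped and res.cigar_string == "*"


def test_cigar_consistency_on_random_instances(rng):
    for _ in range(50):
        read = random_genome(rng, int(rng.integers(4, 60)))
        win = random_genome(rng, len(read) + int(rng.integers(0, 50)))
        sc = _random_scheme(rng)
        res = align_window(read, win, sc)
        if not res.mapped:
            continue
        assert sum(ln for op, ln in res.cigar if op in "MIS") == len(read)
        assert rescore_cigar(res, read, win, sc) == res.score
        assert res.ref_end <= len(win)


# ---- candidate verification -------------------------------------------------


def _region(contig, start, end, strand, read_len):
    return CandidateRegion(contig, start, end, strand, [0], max(start, 0), read_len)


def test_align_candidate_recovers_true_locus(rng):
    genome = random_genome(rng, 4000)
    ref = Reference([("c1", genome)])
    read = genome[1200:1350]
    res = align_candidate(read, _region("c1", 1184, 1366, "+", 150), ref)
    assert res.accepted and res.ref_start == 1200 and res.cigar_string == "150M"
    # unrelated locus: score below the acceptance threshold
    bad = align_candidate(read, _region("c1", 2984, 3166, "+", 150), ref)
    assert not (bad.mapped and bad.accepted)


def test_align_candidate_clamps_window_at_contig_start(rng):
    genome = random_genome(rng, 1000)
    ref = Reference([("c1", genome)])
    read = genome[0:100]
    res = align_candidate(read, _region("c1", -16, 116, "+", 100), ref)
    assert res.accepted and res.ref_start == 0


def test_align_candidate_reverse_strand(rng):
    from seedwave.reference import revcomp

    genome = random_genome(rng, 2000)
    ref = Reference([("c1", genome)])
    read = revcomp(genome[700:850])
    res = align_candidate(read, _region("c1", 684, 866, "-", 150), ref)
    assert res.accepted and res.ref_start == 700 and res.strand == "-"
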