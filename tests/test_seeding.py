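import numpy as np
import pytest

from seedwave import FMIndex, Reference
from seedwave.fm_index import OVERFLOW
from seedwave.pipeline import ReadRecord
from seedwave.seeding import (
    DEFAULT_ROUNDS,
    RoundConfig,
    multi_round_candidates,
    run_round,
    search_seed,
    tile_seeds,
)

from oracles import bmnbm_oracle, random_genome


def _index(text: str) -> FMIndex:
    return FMIndex.build(Reference([("c1", text)]), occ_rate=16, sa_rate=4)


def _flatten(hits) -> dict[int, int]:
    out = {}
    for h in hits:
        if h.overflowed:
            continue
        for p in h.positions:
            tot = h.n_bm + h.n_nbm
            if p not in out or out[p] > tot:
                out[p] = tot
    return out


# ---- tiling -----------------------------------------------------------------


@pytest.mark.parametrize(
    "read_len,cfg,expect",
    [
        (150, RoundConfig(140, 0, 1000), [0, 10]),
        (100, RoundConfig(140, 0, 1000), []),  # round skipped
        (8, RoundConfig(4, 0, 1000), [0, 4]),
        (150, RoundConfig(80, 0, 1000), [0, 70]),
        (150, RoundConfig(46, 0, 100), [0, 46, 92, 104]),
        (10, RoundConfig(6, 2, 50), [0, 4]),  # overlap shortens the step
    ],
)
def test_tiling_rule(read_len, cfg, expect):
    assert [off for off, _ in tile_seeds(read_len, cfg)] == expect


def test_tile_lengths_and_config_validation():
    assert all(ln == 46 for _, ln in tile_seeds(150, RoundConfig(46, 0, 100)))
    with pytest.raises(ValueError):
        RoundConfig(0, 0, 10)
    with pytest.raises(ValueError):
        RoundConfig(10, 10, 10)
    with pytest.raises(ValueError):
        RoundConfig(10, 0, 0)


def test_low_quality_base_moved_to_seed_boundary():
    quals = [30] * 20
    quals[9] = 5  # suspect base inside the first tile
    tiles = tile_seeds(20, RoundConfig(10, 0, 100), quals, quality_floor=13)
    for off, ln in tiles:
        assert not (off <= 9 < off + ln)
    # unshiftable: every placement covers a suspect base -> seed kept as-is
    quals = [5] * 20
    assert tile_seeds(20, RoundConfig(10, 0, 100), quals, 13) == [(0, 10), (10, 10)]


# ---- BM/NBM search ----------------------------------------------------------


def test_branching_mismatch_forks_search():
    idx = _index("ATGAAG")
    got = _flatten(search_seed(idx, "ACG", max_bm=1, max_nbm=0))
    assert got == {0: 1, 3: 1}  # the step before G admits T and A: branching


def test_non_branching_mismatch_is_forced():
    idx = _index("ACGTGA")
    hits = search_seed(idx, "ACTTGA", max_bm=0, max_nbm=1)
    assert _flatten(hits) == {0: 1}
    assert hits[0].n_nbm == 1 and hits[0].n_bm == 0


def test_exact_search_no_budget():
    idx = _index("ACGTACGT")
    hits = search_seed(idx, "ACGT", 0, 0)
    assert _flatten(hits) == {0: 0, 4: 0}


def test_seed_with_n_returns_nothing(small_index):
    assert search_seed(small_index, "GANTA") == []


def test_overflow_reported_per_limit():
    idx = _index("AC" * 40)
    hits = search_seed(idx, "ACAC", 0, 0, candidate_limit=5)
    assert len(hits) == 1 and hits[0].positions is OVERFLOW


def test_monotone_budget_sensitivity(rng):
    for _ in range(30):
        genome = random_genome(rng, int(rng.integers(100, 2000)))
        idx = _index(genome)
        ln = int(rng.integers(8, 30))
        start = int(rng.integers(0, len(genome) - ln))
        seed = list(genome[start : start + ln])
        for _ in range(int(rng.integers(0, 3))):  # plant mismatches
            i = int(rng.integers(0, ln))
            seed[i] = "ACGT"[int(rng.integers(0, 4))]
        seed = "".join(seed)
        h00 = set(_flatten(search_seed(idx, seed, 0, 0)))
        h10 = set(_flatten(search_seed(idx, seed, 1, 0)))
        h12 = set(_flatten(search_seed(idx, seed, 1, 2)))
        assert h00 <= h10 <= h12


def test_index_search_equals_text_oracle(rng):
    for _ in range(60):
        genome = random_genome(rng, int(rng.integers(50, 3000)))
        idx = _index(genome)
        ln = int(rng.integers(5, 41))
        start = int(rng.integers(0, max(1, len(genome) - ln)))
        seed = list(genome[start : start + ln])
        for _ in range(int(rng.integers(0, 4))):
            seed[int(rng.integers(0, len(seed)))] = "ACGT"[int(rng.integers(0, 4))]
        seed = "".join(seed)
        for bm, nbm in [(0, 0), (1, 0), (1, 2)]:
            got = _flatten(search_seed(idx, seed, bm, nbm))
            assert got == bmnbm_oracle(genome, seed, bm, nbm)


def test_reported_positions_verify_textually(rng):
    genome = random_genome(rng, 3000)
    idx = _index(genome)
    for _ in range(20):
        ln = int(rng.integers(10, 35))
        start = int(rng.integers(0, len(genome) - ln))
        seed = list(genome[start : start + ln])
        seed[int(rng.integers(0, ln))] = "ACGT"[int(rng.integers(0, 4))]
        seed = "".join(seed)
        for h in search_seed(idx, seed, 1, 2):
            assert not h.overflowed
            for p in h.positions:
                ref = genome[p : p + ln]
                mm = sum(a != b for a, b in zip(seed, ref))
                assert mm == h.n_bm + h.n_nbm


# ---- rounds -----------------------------------------------------------------


def _read(seq: str) -> ReadRecord:
    return ReadRecord("r", seq, [30] * len(seq))


def test_unique_read_yields_single_forward_region(rng):
    genome = random_genome(rng, 20_000)
    idx = _index(genome)
    read = _read(genome[5000:5150])
    regions = run_round(idx, read, DEFAULT_ROUNDS[0])
    fwd = [r for r in regions if r.strand == "+"]
    assert len(fwd) == 1
    assert fwd[0].diag == 5000
    assert fwd[0].window_start <= 5000 < 5150 <= fwd[0].window_end


def test_short_read_skips_long_round(rng):
    genome = random_genome(rng, 5000)
    idx = _index(genome)
    assert run_round(idx, _read(genome[100:200]), DEFAULT_ROUNDS[0]) == []


def test_tandem_repeat_overflows_candidate_limit():
    unit = "ACGTTGCAGT"
    genome = unit * 50
    idx = _index(genome)
    read = _read(genome[:40])
    assert run_round(idx, read, RoundConfig(20, 0, 10)) == []


def test_default_round_schedule_values():
    assert [(c.seed_length, c.seed_overlap, c.candidate_limit) for c in DEFAULT_ROUNDS] \
        == [(140, 0, 1000), (80, 0, 1000), (46, 0, 100)]


def test_multi_round_stops_at_first_productive_round(rng):
    genome = random_genome(rng, 30_000)
    idx = _index(genome)
    clean = _read(genome[9000:9150])
    cands, used = multi_round_candidates(idx, clean)
    assert used == 0 and cands
    # a mid-read deletion splits every round-0 and round-1 seed
    broken = genome[9000:9075] + genome[9078:9153]
    cands, used = multi_round_candidates(idx, _read(broken))
    assert used is not None and used >= 1
    with pytest.raises(ValueError):
        multi_round_candidates(idx, clean, rounds=())
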