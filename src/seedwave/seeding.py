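"""Seed generation and mismatch-tolerant FM-index seed search.

Seeds are searched backward through the index allowing one *branching*
mismatch (BM) plus up to two *non-branching* mismatches (NBM).  At an
extension step where the read character dies: if exactly one other base
continues the pattern the correction is forced (an NBM, no fork); if two
or more bases continue, each mismatching continuation forks the search
and costs a BM.  When the read character itself continues alongside at
least one alternative, the matching branch is free and each alternative
costs a BM.  This finds more seed placements than a 1-mismatch search at
nearly the cost of an exact one, because forced corrections do not
branch the search tree.

Rounds run from long seeds (few, specific candidates) to short seeds
(sensitive, more candidates); most reads resolve in the first round and
only complicated reads descend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fm_index import FMIndex, OVERFLOW, Overflow, SAInterval
from .reference import revcomp

DEFAULT_MAX_BM = 1
DEFAULT_MAX_NBM = 2
DEFAULT_QUALITY_FLOOR = 13
DEFAULT_MERGE_TOL = 8
DEFAULT_INDEL_MARGIN = 16


@dataclass(frozen=True)
class RoundConfig:
    """Per-round seed length, overlap between consecutive seeds, and the
    maximum occurrence count before a seed is dropped as repetitive."""

    seed_length: int
    seed_overlap: int
    candidate_limit: int

    def __post_init__(self) -> None:
        if self.seed_length <= 0:
            raise ValueError("seed_length must be positive")
        if not 0 <= self.seed_overlap < self.seed_length:
            raise ValueError("seed_overlap must be in [0, seed_length)")
        if self.candidate_limit <= 0:
            raise ValueError("candidate_limit must be positive")


#: Default multi-round schedule: 140/0/1,000 then 80/0/1,000 then 46/0/100.
DEFAULT_ROUNDS: tuple[RoundConfig, ...] = (
    RoundConfig(140, 0, 1000),
    RoundConfig(80, 0, 1000),
    RoundConfig(46, 0, 100),
)


@dataclass
class SeedHit:
    """Placements of one seed with its mismatch budget usage."""

    read_offset: int
    length: int
    strand: str
    positions: list[int] | Overflow
    n_bm: int
    n_nbm: int

    @property
    def overflowed(self) -> bool:
        return self.positions is OVERFLOW


@dataclass
class CandidateRegion:
    """Genomic window nominated by seeds, to be verified by DP."""

    contig: str
    window_start: int
    window_end: int
    strand: str
    supporting_seed_offsets: list[int]
    diag: int  # projected global read start
    read_len: int

    @property
    def support(self) -> int:
        return len(self.supporting_seed_offsets)


# ---- seed tiling ------------------------------------------------------------


def tile_seeds(
    read_length: int,
    config: RoundConfig,
    qualities=None,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
) -> list[tuple[int, int]]:
    """Seed (offset, length) tiles for one round.

    Tiles advance from the 5' end by ``seed_length - seed_overlap``; a
    final seed is anchored flush at the 3' end when the last tile would
    overrun.  A round whose seed is longer than the read is skipped.

    When qualities are supplied, a seed spanning a base below
    ``quality_floor`` is shifted so the suspect base sits at a seed
    boundary when an in-bounds shift clears the span; otherwise the seed
    is kept as tiled.  This keeps likely errors and variants out of seed
    matching (which tolerates mismatches but no indels).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    L = config.seed_length
    if L > read_length:
        return []
    step = L - config.seed_overlap
    offsets = list(range(0, read_length - L + 1, step))
    if offsets[-1] != read_length - L:
        offsets.append(read_length - L)
    if qualities is not None:
        low = [i for i, q in enumerate(qualities) if q < quality_floor]
        if low:
            offsets = [_shift_clear(off, L, read_length, low) for off in offsets]
            seen: set[int] = set()
            offsets = [o for o in offsets if not (o in seen or seen.add(o))]
    return [(off, L) for off in offsets]


def _shift_clear(off: int, L: int, read_length: int, low: list[int]) -> int:
    in_span = [q for q in low if off <= q < off + L]
    if not in_span:
        return off
    cands = []
    for q in in_span:
        cands.append(q + 1)  # seed begins just after the suspect base
        cands.append(q - L)  # seed ends just before it
    cands = sorted(
        {c for c in cands if 0 <= c <= read_length - L},
        key=lambda c: (abs(c - off), c),
    )
    for c in cands:
        if not any(c <= q < c + L for q in low):
            return c
    return off


# ---- index search with BM/NBM budget ---------------------------------------


def search_seed(
    index: FMIndex,
    seed: str,
    max_bm: int = DEFAULT_MAX_BM,
    max_nbm: int = DEFAULT_MAX_NBM,
    candidate_limit: int | None = None,
    read_offset: int = 0,
    strand: str = "+",
) -> list[SeedHit]:
    """Depth-first backward search of one seed under the BM/NBM budget.

    Returns one hit per surviving correction path; positions are
    deduplicated and an interval wider than ``candidate_limit`` is
    reported as overflow rather than enumerated.
    """
    if max_bm < 0 or max_nbm < 0:
        raise ValueError("mismatch budgets must be non-negative")
    if not seed or "N" in seed:
        return []
    L = len(seed)
    terminals: list[tuple[SAInterval, int, int]] = []
    stack: list[tuple[SAInterval, int, int, int]] = [
        (index.full_interval(), L - 1, 0, 0)
    ]
    while stack:
        interval, pos, bm, nbm = stack.pop()
        if pos < 0:
            terminals.append((interval, bm, nbm))
            continue
        c = seed[pos]
        if bm < max_bm:
            ext = {b: iv for b, iv in index.extend_all(interval).items() if iv.width > 0}
        else:
            iv = index.backward_extend(interval, c)
            if iv.width > 0:
                ext = {c: iv}
            else:
                ext = {
                    b: iv
                    for b, iv in index.extend_all(interval).items()
                    if iv.width > 0
                }
        match_iv = ext.get(c)
        if match_iv is not None:
            stack.append((match_iv, pos - 1, bm, nbm))
            if len(ext) >= 2 and bm < max_bm:
                for b in sorted(ext):
                    if b != c:
                        stack.append((ext[b], pos - 1, bm + 1, nbm))
        elif len(ext) == 1 and nbm < max_nbm:
            (only_iv,) = ext.values()
            stack.append((only_iv, pos - 1, bm, nbm + 1))
        elif len(ext) >= 2 and bm < max_bm:
            for b in sorted(ext):
                stack.append((ext[b], pos - 1, bm + 1, nbm))
        # zero continuations, or budget exhausted: dead end
    hits: list[SeedHit] = []
    seen: set[int] = set()
    for interval, bm, nbm in sorted(
        terminals, key=lambda t: (t[1] + t[2], t[1], t[0].low)
    ):
        located = index.locate(interval, candidate_limit)
        if located is OVERFLOW:
            hits.append(SeedHit(read_offset, L, strand, OVERFLOW, bm, nbm))
            continue
        fresh = [p for p in located if p not in seen]
        if fresh:
            seen.update(fresh)
            hits.append(SeedHit(read_offset, L, strand, fresh, bm, nbm))
    return hits


# ---- rounds -----------------------------------------------------------------


def run_round(
    index: FMIndex,
    read,
    config: RoundConfig,
    budgets: tuple[int, int] = (DEFAULT_MAX_BM, DEFAULT_MAX_NBM),
    quality_floor: int | None = DEFAULT_QUALITY_FLOOR,
    merge_tol: int = DEFAULT_MERGE_TOL,
    indel_margin: int = DEFAULT_INDEL_MARGIN,
) -> list[CandidateRegion]:
    """Tile, search, and merge seeds of one round on both strands.

    ``read`` needs ``sequence`` and (optionally) ``qualities`` attributes
    or may be a plain string.  Positions landing on the same diagonal
    (projected read start within ``merge_tol``) merge into one candidate
    region per strand, with a window of the read span plus
    ``indel_margin`` on both sides.
    """
    seq = read if isinstance(read, str) else read.sequence
    quals = None if isinstance(read, str) else getattr(read, "qualities", None)
    max_bm, max_nbm = budgets
    rl = len(seq)
    regions: list[CandidateRegion] = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        q = quals if strand == "+" else (quals[::-1] if quals is not None else None)
        tiles = tile_seeds(rl, config, q if quality_floor is not None else None,
                           quality_floor or 0)
        diag_support: list[tuple[int, int]] = []
        for off, L in tiles:
            seed = s[off : off + L]
            if "N" in seed:
                continue
            for hit in search_seed(
                index, seed, max_bm, max_nbm, config.candidate_limit, off, strand
            ):
                if hit.overflowed:
                    continue
                for pos in hit.positions:
                    diag_support.append((pos - off, off))
        if not diag_support:
            continue
        diag_support.sort()
        group: list[tuple[int, int]] = []
        for item in diag_support:
            if group and item[0] - group[-1][0] > merge_tol:
                regions.append(_make_region(index, group, strand, rl, indel_margin))
                group = []
            group.append(item)
        if group:
            regions.append(_make_region(index, group, strand, rl, indel_margin))
    return regions


def _make_region(
    index: FMIndex, group: list[tuple[int, int]], strand: str, read_len: int,
    indel_margin: int,
) -> CandidateRegion:
    diags = [d for d, _ in group]
    offsets = sorted({o for _, o in group})
    rep = min(diags)
    total = index.reference.total_length
    contig, _ = index.reference.contig_of(min(max(rep, 0), total - 1))
    return CandidateRegion(
        contig=contig,
        window_start=rep - indel_margin,
        window_end=max(diags) + read_len + indel_margin,
        strand=strand,
        supporting_seed_offsets=offsets,
        diag=rep,
        read_len=read_len,
    )


def multi_round_candidates(
    index: FMIndex,
    read,
    rounds=DEFAULT_ROUNDS,
    stop_rule=None,
    budgets: tuple[int, int] = (DEFAULT_MAX_BM, DEFAULT_MAX_NBM),
    **round_kw,
) -> tuple[list[CandidateRegion], int | None]:
    """Run rounds in order; stop at the first one ``stop_rule`` accepts.

    ``stop_rule(candidates, round_index)`` returns truthy to stop (e.g.
    downstream DP produced an accepted alignment).  With no rule, the
    first round yielding any candidate wins.  Exhausting all rounds
    returns ``([], None)`` — unmapped.
    """
    if not rounds:
        raise ValueError("at least one round is required")
    for ri, cfg in enumerate(rounds):
        cands = run_round(index, read, cfg, budgets, **round_kw)
        if not cands:
            continue
        if stop_rule is None or stop_rule(cands, ri):
            return cands, ri
    return [], None
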