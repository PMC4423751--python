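"""Affine-gap alignment engine with anti-diagonal (wavefront) fill.

The scoring model is local over the read: unaligned read prefix/suffix
is soft-clipped free of charge and reference flanks are free, which is
the classic Smith-Waterman/Gotoh local model with three score tables
M (last column aligned), I (gap in reference, read base consumed) and
D (gap in read, reference base consumed).  The first base of a gap
costs ``gap_open + gap_extend``; each further base ``gap_extend``.

Cells are stored in anti-diagonal order as a single flat array; the
three scores of a cell are packed into one 64-bit word so a whole
wavefront chunk is carried in contiguous memory.  Cells on a diagonal
``i + j = const`` depend only on the two previous diagonals, so the
kernel fills each diagonal in lane-sized chunks (default 16 lanes);
results are invariant to the lane width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .reference import encode, revcomp

# ---- packed cell layout -----------------------------------------------------

_FIELD_BITS = 21
_BIAS = 1 << 20  # stored = value + bias, 21 bits per field
_MASK = (1 << _FIELD_BITS) - 1
NEG = -(1 << 19)  # "minus infinity" floor for gap states

MAX_READ_LEN = 1024


def pack_cell(m: int, i: int, d: int) -> int:
    """Pack (M, I, D) scores into one 64-bit cell word.

    Raises ``OverflowError`` when a score falls outside the representable
    field range — saturation is explicit, never silent wraparound.
    """
    word = 0
    for k, v in enumerate((m, i, d)):
        if not -_BIAS <= v < _BIAS:
            raise OverflowError(
                f"score {v} saturates the {_FIELD_BITS}-bit packed-cell field"
            )
        word |= (v + _BIAS) << (_FIELD_BITS * k)
    return word


def unpack_cell(word: int) -> tuple[int, int, int]:
    """Inverse of :func:`pack_cell`."""
    return tuple(
        ((word >> (_FIELD_BITS * k)) & _MASK) - _BIAS for k in range(3)
    )


# ---- scoring ----------------------------------------------------------------


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; penalties are stored as positive magnitudes."""

    match: int = 1
    mismatch: int = 2
    gap_open: int = 3
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("penalties must be positive")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")

    @property
    def gap_first(self) -> int:
        """Cost of the first base of a gap (open + extend)."""
        return self.gap_open + self.gap_extend

    def min_accept_score(self, read_len: int, frac: float = 0.3) -> int:
        return int(np.ceil(self.match * read_len * frac))


# ---- wavefront kernel -------------------------------------------------------


@njit(cache=True)
def _fill_kernel(read, win, match, mismatch, gap_first, gap_ext, lane_width, flat, diag_start):
    m = read.shape[0]
    n = win.shape[0]
    bias = _BIAS
    mask = _MASK
    neg = NEG
    boundary = (0 + bias) | ((neg + bias) << 21) | ((neg + bias) << 42)
    # boundary row i=0 and column j=0: M=0 (free start), gaps undefined
    for j in range(n + 1):
        d = j
        i0 = d - n if d > n else 0
        flat[diag_start[d] + (0 - i0)] = boundary
    for i in range(1, m + 1):
        d = i
        flat[diag_start[d] + i] = boundary
    for d in range(2, m + n + 1):
        i_lo = 1 if d - n < 1 else d - n
        i_hi = m if d - 1 > m else d - 1
        i0 = d - n if d > n else 0
        base_d = diag_start[d]
        i0p = (d - 1) - n if (d - 1) > n else 0
        base_p = diag_start[d - 1]
        i0pp = (d - 2) - n if (d - 2) > n else 0
        base_pp = diag_start[d - 2]
        for chunk in range(i_lo, i_hi + 1, lane_width):
            chunk_end = chunk + lane_width - 1
            if chunk_end > i_hi:
                chunk_end = i_hi
            for i in range(chunk, chunk_end + 1):
                j = d - i
                w_diag = flat[base_pp + (i - 1 - i0pp)]  # (i-1, j-1)
                w_up = flat[base_p + (i - 1 - i0p)]  # (i-1, j)
                w_left = flat[base_p + (i - i0p)]  # (i, j-1)
                dm = (w_diag & mask) - bias
                di = ((w_diag >> 21) & mask) - bias
                dd = ((w_diag >> 42) & mask) - bias
                um = (w_up & mask) - bias
                ui = ((w_up >> 21) & mask) - bias
                lm = (w_left & mask) - bias
                ld = ((w_left >> 42) & mask) - bias
                rc = read[i - 1]
                wc = win[j - 1]
                if rc == wc and rc != 5:  # N (code 5) never matches
                    s = match
                else:
                    s = -mismatch
                best_prev = dm
                if di > best_prev:
                    best_prev = di
                if dd > best_prev:
                    best_prev = dd
                mval = best_prev + s
                if mval < 0:
                    mval = 0
                ival = um - gap_first
                alt = ui - gap_ext
                if alt > ival:
                    ival = alt
                if ival < neg:
                    ival = neg
                dval = lm - gap_first
                alt = ld - gap_ext
                if alt > dval:
                    dval = alt
                if dval < neg:
                    dval = neg
                flat[base_d + (i - i0)] = (
                    (mval + bias) | ((ival + bias) << 21) | ((dval + bias) << 42)
                )


# ---- table ------------------------------------------------------------------


@dataclass
class DPTable:
    """Filled DP table in anti-diagonal order.

    ``flat[diag_offset(i, j)]`` is the packed cell for read prefix i,
    window prefix j.  The mapping is a bijection onto the cell count.
    """

    read: str
    window: str
    scoring: ScoringScheme
    lane_width: int
    flat: np.ndarray = field(repr=False)
    diag_start: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.read)

    @property
    def n(self) -> int:
        return len(self.window)

    def diag_offset(self, i: int, j: int) -> int:
        d = i + j
        i0 = max(0, d - self.n)
        return int(self.diag_start[d]) + (i - i0)

    def to_dense(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unpack into row-major (m+1, n+1) M, I, D score matrices."""
        m, n = self.m, self.n
        ii, jj = np.meshgrid(np.arange(m + 1), np.arange(n + 1), indexing="ij")
        d = ii + jj
        off = self.diag_start[d] + (ii - np.maximum(0, d - n))
        words = self.flat[off]
        M = (words & _MASK) - _BIAS
        I = ((words >> _FIELD_BITS) & _MASK) - _BIAS
        D = ((words >> (2 * _FIELD_BITS)) & _MASK) - _BIAS
        return M, I, D

    def best_score(self) -> int:
        M, _, _ = self.to_dense()
        return int(M.max())


def _diag_starts(m: int, n: int) -> np.ndarray:
    d = np.arange(m + n + 1)
    lengths = np.minimum(d, m) - np.maximum(0, d - n) + 1
    starts = np.zeros(m + n + 1, dtype=np.int64)
    starts[1:] = np.cumsum(lengths)[:-1]
    return starts


def fill_antidiagonal(
    read: str,
    window: str,
    scoring: ScoringScheme | None = None,
    lane_width: int = 16,
) -> DPTable:
    """Fill the three affine tables wavefront-by-wavefront.

    The resulting M/I/D values are identical to the row-major Gotoh
    recurrence and invariant to ``lane_width``.
    """
    scoring = scoring or ScoringScheme()
    if len(read) == 0:
        raise ValueError("empty read")
    if len(read) > MAX_READ_LEN:
        raise ValueError(f"read longer than configured maximum {MAX_READ_LEN}")
    if len(window) < len(read):
        raise ValueError("window shorter than read")
    if lane_width <= 0:
        raise ValueError("lane_width must be positive")
    m, n = len(read), len(window)
    starts = _diag_starts(m, n)
    flat = np.zeros((m + 1) * (n + 1), dtype=np.int64)
    _fill_kernel(
        encode(read),
        encode(window),
        np.int64(scoring.match),
        np.int64(scoring.mismatch),
        np.int64(scoring.gap_first),
        np.int64(scoring.gap_extend),
        np.int64(lane_width),
        flat,
        starts,
    )
    return DPTable(read, window, scoring, lane_width, flat, starts)


# ---- results & traceback ----------------------------------------------------


@dataclass
class AlignmentResult:
    """One read's alignment against a window or reference.

    ``ref_start`` is 0-based; window-local from :func:`traceback`, global
    after :func:`align_candidate`.  ``cigar`` runs over M/I/D/S ops in
    read orientation on the aligned strand.
    """

    mapped: bool
    ref_start: int = 0
    strand: str = "+"
    score: int = 0
    cigar: list[tuple[str, int]] = field(default_factory=list)
    n_mismatch: int = 0
    n_indel: int = 0
    contig: str | None = None
    mapq: int = 0
    accepted: bool = False
    read_len: int = 0

    @property
    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{ln}{op}" for op, ln in self.cigar)

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span

    @property
    def edit_distance(self) -> int:
        return self.n_mismatch + sum(ln for op, ln in self.cigar if op in "ID")


def _runs(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def traceback(table: DPTable) -> AlignmentResult:
    """Trace the best local path to an M/I/D/S CIGAR.

    Ties prefer M over D over I at every step; among equal-scoring end
    cells the smallest reference coordinate (then read coordinate) wins.
    """
    M, I, D = table.to_dense()
    read, win, sc = table.read, table.window, table.scoring
    best = int(M.max())
    if best <= 0:
        return AlignmentResult(mapped=False, read_len=len(read))
    ends = np.argwhere(M == best)
    order = np.lexsort((ends[:, 0], ends[:, 1]))  # min j, then min i
    i, j = (int(v) for v in ends[order[0]])
    end_i = i
    ops: list[str] = []
    n_mismatch = 0
    state = "M"
    while True:
        if state == "M":
            rc, wc = read[i - 1], win[j - 1]
            if rc != wc or rc == "N" or wc == "N":
                n_mismatch += 1
            ops.append("M")
            pm, pi, pd = int(M[i - 1, j - 1]), int(I[i - 1, j - 1]), int(D[i - 1, j - 1])
            i, j = i - 1, j - 1
            prev = max(pm, pd, pi)
            if prev <= 0:
                break
            state = "M" if pm == prev else ("D" if pd == prev else "I")
        elif state == "D":
            ops.append("D")
            state = "M" if int(D[i, j]) == int(M[i, j - 1]) - sc.gap_first else "D"
            j -= 1
        else:
            ops.append("I")
            state = "M" if int(I[i, j]) == int(M[i - 1, j]) - sc.gap_first else "I"
            i -= 1
    start_i, start_j = i, j
    ops.reverse()
    cigar = _runs(ops)
    if start_i > 0:
        cigar.insert(0, ("S", start_i))
    if end_i < len(read):
        cigar.append(("S", len(read) - end_i))
    n_indel = sum(1 for op, _ in cigar if op in "ID")
    return AlignmentResult(
        mapped=True,
        ref_start=start_j,
        score=best,
        cigar=cigar,
        n_mismatch=n_mismatch,
        n_indel=n_indel,
        read_len=len(read),
    )


def rescore_cigar(
    result: AlignmentResult, read: str, window: str, scoring: ScoringScheme
) -> int:
    """Recompute the alignment score from the CIGAR (consistency check)."""
    score = 0
    ri = 0
    wj = result.ref_start
    for op, ln in result.cigar:
        if op == "S":
            ri += ln
        elif op == "M":
            for _ in range(ln):
                rc, wc = read[ri], window[wj]
                eq = rc == wc and rc != "N"
                score += scoring.match if eq else -scoring.mismatch
                ri += 1
                wj += 1
        elif op == "I":
            score -= scoring.gap_first + scoring.gap_extend * (ln - 1)
            ri += ln
        elif op == "D":
            score -= scoring.gap_first + scoring.gap_extend * (ln - 1)
            wj += ln
    return score


def align_window(
    read: str,
    window: str,
    scoring: ScoringScheme | None = None,
    lane_width: int = 16,
) -> AlignmentResult:
    """Fill + traceback in one call (window-local coordinates)."""
    table = fill_antidiagonal(read, window, scoring, lane_width)
    return traceback(table)


def align_candidate(
    read: str,
    region,
    reference,
    scoring: ScoringScheme | None = None,
    min_score_frac: float = 0.3,
    lane_width: int = 16,
) -> AlignmentResult:
    """Verify a candidate region by DP on the proper strand.

    Window-local coordinates are converted to global; an alignment is
    ``accepted`` when its score reaches ``match * read_len * min_score_frac``.
    """
    scoring = scoring or ScoringScheme()
    lo, hi = reference.contig_bounds(region.contig)
    win_start = max(lo, region.window_start)
    win_end = min(hi, region.window_end)
    if win_end - win_start < len(read):
        # widen within the contig so DP stays feasible near contig edges
        win_start = max(lo, min(win_start, hi - len(read)))
        win_end = min(hi, max(win_end, win_start + len(read)))
    if win_end - win_start < len(read):
        return AlignmentResult(mapped=False, read_len=len(read))
    window = reference.fetch(win_start, win_end)
    query = revcomp(read) if region.strand == "-" else read
    res = align_window(query, window, scoring, lane_width)
    if not res.mapped:
        return res
    res.ref_start += win_start
    res.strand = region.strand
    res.contig = region.contig
    res.accepted = res.score >= scoring.min_accept_score(len(read), min_score_frac)
    return res
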