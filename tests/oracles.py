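"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own data paths: suffix sorting by
direct comparison, substring search by text scan, seed search by a
recursive text-space procedure, and affine alignment by a row-major
Gotoh recurrence (numpy row scans).
"""

from __future__ import annotations

import numpy as np

NEG = -(1 << 19)


# ---- suffix array / substring search ---------------------------------------

_ORDER = {"$": 0, "A": 1, "C": 2, "G": 3, "T": 4, "N": 5}


def naive_suffix_array(text: str) -> list[int]:
    """Sort suffixes of text+'$' by direct comparison in the package's
    character order."""
    t = text + "$"
    keyed = [([_ORDER[c] for c in t[i:]], i) for i in range(len(t))]
    keyed.sort()
    return [i for _, i in keyed]


def naive_occurrences(text: str, pattern: str) -> list[int]:
    if not pattern:
        return list(range(len(text) + 1))
    out = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


# ---- BM/NBM seed search over raw text ---------------------------------------


def bmnbm_oracle(text: str, seed: str, max_bm: int, max_nbm: int) -> dict[int, int]:
    """Recursive backward search over the text applying the per-step
    BM/NBM classification; returns {position: total_mismatches}."""
    terminals: list[tuple[str, int, int]] = []

    def rec(suffix: str, pos: int, bm: int, nbm: int) -> None:
        if pos < 0:
            terminals.append((suffix, bm, nbm))
            return
        c = seed[pos]
        ext = {b for b in "ACGT" if (b + suffix) in text}
        if c in ext:
            rec(c + suffix, pos - 1, bm, nbm)
            if len(ext) >= 2 and bm < max_bm:
                for b in sorted(ext - {c}):
                    rec(b + suffix, pos - 1, bm + 1, nbm)
        elif len(ext) == 1 and nbm < max_nbm:
            (b,) = ext
            rec(b + suffix, pos - 1, bm, nbm + 1)
        elif len(ext) >= 2 and bm < max_bm:
            for b in sorted(ext):
                rec(b + suffix, pos - 1, bm + 1, nbm)

    rec("", len(seed) - 1, 0, 0)
    out: dict[int, int] = {}
    for pattern, bm, nbm in terminals:
        for i in naive_occurrences(text, pattern):
            tot = bm + nbm
            if i not in out or out[i] > tot:
                out[i] = tot
    return out


# ---- row-major Gotoh --------------------------------------------------------


def gotoh_dense(read: str, window: str, match: int, mismatch: int,
                gap_open: int, gap_extend: int):
    """Row-major three-matrix local (free-clip) affine DP.

    M has a zero floor (free read clips / reference flanks); the first
    gap base costs gap_open + gap_extend.  Returns (M, I, D) int64
    matrices of shape (m+1, n+1).
    """
    m, n = len(read), len(window)
    oe = gap_open + gap_extend
    e = gap_extend
    win = np.frombuffer(window.encode(), dtype=np.uint8)
    M = np.zeros((m + 1, n + 1), dtype=np.int64)
    I = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    D = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    ks = np.arange(n, dtype=np.int64)
    for i in range(1, m + 1):
        rc = read[i - 1]
        eq = (win == ord(rc)) & (rc != "N") & (win != ord("N"))
        s = np.where(eq, match, -mismatch)
        prev = np.maximum(np.maximum(M[i - 1, :-1], I[i - 1, :-1]), D[i - 1, :-1])
        M[i, 1:] = np.maximum(0, prev + s)
        I[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] - oe, I[i - 1, 1:] - e), NEG
        )
        run = np.maximum.accumulate(M[i, :-1] + e * ks)
        D[i, 1:] = np.maximum(run - oe - e * ks, NEG)
    return M, I, D


def gotoh_best(read: str, window: str, match: int, mismatch: int,
               gap_open: int, gap_extend: int) -> int:
    M, _, _ = gotoh_dense(read, window, match, mismatch, gap_open, gap_extend)
    return int(M.max())


# ---- random instance helpers ------------------------------------------------


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
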