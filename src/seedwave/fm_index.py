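"""FM-index over the concatenated reference.

The index is a Burrows-Wheeler transform of ``text + $`` together with
the cumulative-count (C) array, occurrence counts checkpointed every
``occ_rate`` positions, and suffix-array values sampled every
``sa_rate`` rows.  Backward search refines an :class:`SAInterval`
(a half-open range of suffix-array rows) one character at a time;
``locate`` resolves rows to text positions by walking the LF mapping to
the nearest sampled row.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .reference import BASE_CODE, Reference, encode

_MAGIC = b"SWFM"
_VERSION = 2
_ALPHA = 6  # $ A C G T N


class Overflow:
    """Marker returned by ``locate`` when an interval exceeds its limit."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "OVERFLOW"


OVERFLOW = Overflow()


@dataclass(frozen=True)
class SAInterval:
    """Half-open range [low, high) of suffix-array rows sharing a prefix."""

    low: int
    high: int

    @property
    def width(self) -> int:
        return self.high - self.low

    @property
    def empty(self) -> bool:
        return self.high <= self.low


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of a coded text by prefix doubling (O(n log n))."""
    n = len(codes)
    rank = codes.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        # recompute ranks: identical (rank, key2) pairs share the new rank
        r1, r2 = rank[sa], key2[sa]
        diff = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        tmp[sa[0]] = 0
        tmp[sa[1:]] = np.cumsum(diff)
        rank, tmp = tmp, rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa


class FMIndex:
    """Searchable FM-index of a :class:`Reference`.

    Attributes
    ----------
    bwt : np.ndarray of uint8 codes, length total_length + 1
    count : cumulative counts; ``count[c]`` = number of text characters
        with code < c (the C array)
    occ_checkpoints : (n_ckpt, 6) int64, occurrence counts of each code
        strictly before row ``k * occ_rate``
    sa_samples : suffix-array values at rows ``r`` with ``r % sa_rate == 0``
    """

    def __init__(
        self,
        reference: Reference,
        bwt: np.ndarray,
        count: np.ndarray,
        occ_checkpoints: np.ndarray,
        sa_samples: np.ndarray,
        occ_rate: int,
        sa_rate: int,
    ):
        self.reference = reference
        self.bwt = bwt
        self.count = count
        self.occ_checkpoints = occ_checkpoints
        self.sa_samples = sa_samples
        self.occ_rate = occ_rate
        self.sa_rate = sa_rate
        self.n_rows = len(bwt)

    # ---- queries ------------------------------------------------------------

    def full_interval(self) -> SAInterval:
        return SAInterval(0, self.n_rows)

    def occ(self, code: int, row: int) -> int:
        """Occurrences of ``code`` in bwt[0:row]."""
        block = row // self.occ_rate
        base = int(self.occ_checkpoints[block, code])
        start = block * self.occ_rate
        if row > start:
            base += int(np.count_nonzero(self.bwt[start:row] == code))
        return base

    def _occ_all(self, row: int) -> np.ndarray:
        """Occurrence counts of every code in bwt[0:row] (one bincount)."""
        block = row // self.occ_rate
        out = self.occ_checkpoints[block].copy()
        start = block * self.occ_rate
        if row > start:
            out += np.bincount(self.bwt[start:row], minlength=_ALPHA)
        return out

    def backward_extend(self, interval: SAInterval, base: str) -> SAInterval:
        """Prepend ``base`` to the pattern represented by ``interval``."""
        code = BASE_CODE.get(base)
        if code is None or base == "N":
            raise ValueError(f"cannot extend with base {base!r}")
        c0 = int(self.count[code])
        return SAInterval(
            c0 + self.occ(code, interval.low), c0 + self.occ(code, interval.high)
        )

    def extend_all(self, interval: SAInterval) -> dict[str, SAInterval]:
        """Backward extension of an interval with each of A, C, G, T at once."""
        lo = self._occ_all(interval.low)
        hi = self._occ_all(interval.high)
        out = {}
        for base in "ACGT":
            c = BASE_CODE[base]
            c0 = int(self.count[c])
            out[base] = SAInterval(c0 + int(lo[c]), c0 + int(hi[c]))
        return out

    def row_to_position(self, row: int) -> int:
        """Text position of the suffix at a suffix-array row (LF walk)."""
        steps = 0
        while row % self.sa_rate != 0:
            code = int(self.bwt[row])
            if code == 0:  # row holds suffix 0; bwt is the sentinel
                return steps
            row = int(self.count[code]) + self.occ(code, row)
            steps += 1
        return int(self.sa_samples[row // self.sa_rate]) + steps

    def locate(self, interval: SAInterval, limit: int | None = None):
        """Text positions of an interval, or :data:`OVERFLOW` above ``limit``."""
        if interval.empty:
            return []
        if limit is not None and interval.width > limit:
            return OVERFLOW
        return sorted(self.row_to_position(r) for r in range(interval.low, interval.high))

    # ---- construction -------------------------------------------------------

    @classmethod
    def build(
        cls, reference: Reference, occ_rate: int = 64, sa_rate: int = 8
    ) -> "FMIndex":
        if occ_rate <= 0 or sa_rate <= 0:
            raise ValueError("occ_rate and sa_rate must be positive")
        codes = np.concatenate(
            [encode(reference.text), np.zeros(1, dtype=np.uint8)]
        )
        sa = suffix_array(codes)
        prev = sa - 1
        prev[prev < 0] = len(codes) - 1
        bwt = codes[prev]
        totals = np.bincount(codes, minlength=_ALPHA).astype(np.int64)
        count = np.concatenate([[0], np.cumsum(totals)[:-1]])
        n_ckpt = len(bwt) // occ_rate + 1
        occ_ck = np.zeros((n_ckpt, _ALPHA), dtype=np.int64)
        onehot = np.zeros((len(bwt), _ALPHA), dtype=np.int64)
        onehot[np.arange(len(bwt)), bwt] = 1
        cum = np.cumsum(onehot, axis=0)
        for k in range(1, n_ckpt):
            occ_ck[k] = cum[k * occ_rate - 1]
        sa_samples = sa[::sa_rate].astype(np.int64)
        return cls(reference, bwt, count, occ_ck, sa_samples, occ_rate, sa_rate)

    # ---- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the index to a binary file (magic, version, rates, contigs)."""
        meta = {
            "occ_rate": self.occ_rate,
            "sa_rate": self.sa_rate,
            "contigs": [[n, len(s)] for n, s in self.reference.contigs],
        }
        meta_b = json.dumps(meta).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<II", _VERSION, len(meta_b)))
            fh.write(meta_b)
            np.save(fh, self.bwt)
            np.save(fh, self.count)
            np.save(fh, self.occ_checkpoints)
            np.save(fh, self.sa_samples)
            seq_b = self.reference.text.encode("ascii")
            fh.write(struct.pack("<Q", len(seq_b)))
            fh.write(seq_b)

    @classmethod
    def load(cls, path: str | Path) -> "FMIndex":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a seedwave index (bad magic)")
            head = fh.read(8)
            if len(head) < 8:
                raise ValueError(f"{path}: truncated index header")
            version, meta_len = struct.unpack("<II", head)
            if version != _VERSION:
                raise ValueError(f"{path}: unsupported index version {version}")
            try:
                meta = json.loads(fh.read(meta_len).decode())
                bwt = np.load(fh)
                count = np.load(fh)
                occ_ck = np.load(fh)
                sa_samples = np.load(fh)
                (seq_len,) = struct.unpack("<Q", fh.read(8))
                seq = fh.read(seq_len).decode("ascii")
                if len(seq) != seq_len:
                    raise ValueError("short read")
            except Exception as exc:
                raise ValueError(f"{path}: truncated or corrupt index: {exc}") from exc
        contigs = []
        pos = 0
        for name, ln in meta["contigs"]:
            contigs.append((name, seq[pos : pos + ln]))
            pos += ln
        ref = Reference(contigs)
        return cls(
            ref, bwt, count, occ_ck, sa_samples, meta["occ_rate"], meta["sa_rate"]
        )
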