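"""Reference genome container and FASTA I/O.

A :class:`Reference` holds an ordered set of contigs and maps between
global (concatenated) coordinates and per-contig local coordinates.
Global coordinates are 0-based half-open throughout the package; only
SAM emission converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

# Alphabet codes used everywhere in the package.  The sentinel sorts first;
# N is a distinct code that no query base ever equals, so runs of N are
# invisible to seed matching but still score as mismatches in DP.
SENTINEL = 0
BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}
CODE_BASE = "$ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a base string to uint8 codes (no sentinel appended)."""
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.zeros(128, dtype=np.uint8)
    for b, c in BASE_CODE.items():
        table[ord(b)] = c
    return table[out]


@dataclass
class Reference:
    """Ordered contigs concatenated into one global coordinate space.

    Parameters
    ----------
    contigs
        Ordered ``(name, sequence)`` pairs; sequences over A/C/G/T/N,
        uppercase.
    """

    contigs: list[tuple[str, str]]
    offsets: dict[str, int] = field(init=False)
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.contigs or all(len(s) == 0 for _, s in self.contigs):
            raise ValueError("reference is empty")
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names are not unique")
        self.offsets = {}
        pos = 0
        for name, seq in self.contigs:
            bad = set(seq) - VALID_BASES
            if bad:
                idx = next(i for i, ch in enumerate(seq) if ch in bad)
                raise ValueError(
                    f"non-ACGTN character {seq[idx]!r} in contig {name!r} at position {idx}"
                )
            self.offsets[name] = pos
            pos += len(seq)
        self.total_length = pos

    # ---- coordinate mapping -------------------------------------------------

    def contig_of(self, gpos: int) -> tuple[str, int]:
        """Map a global position to ``(contig_name, local_pos)``."""
        if not 0 <= gpos < self.total_length:
            raise IndexError(f"global position {gpos} out of range")
        for name, seq in self.contigs:
            off = self.offsets[name]
            if off <= gpos < off + len(seq):
                return name, gpos - off
        raise IndexError(gpos)  # pragma: no cover

    def contig_bounds(self, name: str) -> tuple[int, int]:
        """Global half-open interval covered by a contig."""
        off = self.offsets[name]
        return off, off + self.contig_length(name)

    def contig_length(self, name: str) -> int:
        for n, s in self.contigs:
            if n == name:
                return len(s)
        raise KeyError(name)

    @property
    def text(self) -> str:
        """The concatenated sequence (no sentinel); cached after first use."""
        if not hasattr(self, "_text"):
            self._text = "".join(s for _, s in self.contigs)
        return self._text

    def fetch(self, start: int, end: int) -> str:
        """Slice of the concatenated sequence, clamped to [0, total_length)."""
        start = max(0, start)
        end = min(self.total_length, end)
        return self.text[start:end]

    # ---- I/O ----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Reference":
        contigs = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not contigs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
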