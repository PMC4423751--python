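"""Candidate pairing, pair selection and mate rescue.

Candidate regions from the two ends of a fragment are paired *before*
any DP runs: only cross pairs on one contig, in FR orientation (forward
mate leftmost, reverse mate rightmost) and with an implied template
length inside the insert band are verified.  This avoids spending DP on
placements that could never form a proper pair.  A mate whose own seeds
failed can still be rescued by DP against the window its anchored
partner implies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dp import AlignmentResult, ScoringScheme, align_window
from .reference import revcomp
from .seeding import CandidateRegion


@dataclass(frozen=True)
class InsertModel:
    """Insert-size model; the acceptance band is mean +/- n_sd * sd."""

    mean: int = 500
    sd: int = 25
    n_sd: int = 4
    orientation: str = "FR"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("insert mean must be positive")
        if self.sd < 0:
            raise ValueError("insert sd must be non-negative")

    @property
    def band(self) -> tuple[int, int]:
        lo = max(0, self.mean - self.n_sd * self.sd)
        return lo, self.mean + self.n_sd * self.sd

    def in_band(self, tlen: int) -> bool:
        lo, hi = self.band
        return lo <= abs(tlen) <= hi


@dataclass
class CandidatePair:
    """Two candidate regions whose joint placement looks like a fragment."""

    region_1: CandidateRegion
    region_2: CandidateRegion
    implied_tlen: int
    orientation_ok: bool

    @property
    def support(self) -> int:
        return self.region_1.support + self.region_2.support


def _implied_tlen(fwd: CandidateRegion, rev: CandidateRegion) -> int:
    """Template length from the forward read's start to the reverse read's end."""
    return (rev.diag + rev.read_len) - fwd.diag


def pair_candidates(
    cands_1: list[CandidateRegion],
    cands_2: list[CandidateRegion],
    model: InsertModel,
    read_lengths: tuple[int, int] | None = None,
) -> list[CandidatePair]:
    """All viable cross pairs: one contig, FR orientation, tlen in band.

    Sorted by combined seed support (descending) then coordinate, so the
    best-supported pairing is verified first.
    """
    pairs: list[CandidatePair] = []
    for r1 in cands_1:
        for r2 in cands_2:
            if r1.contig != r2.contig or r1.strand == r2.strand:
                continue
            fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
            if fwd.diag > rev.diag:  # forward mate must be leftmost in FR
                continue
            tlen = _implied_tlen(fwd, rev)
            if not model.in_band(tlen):
                continue
            pairs.append(CandidatePair(r1, r2, tlen, True))
    pairs.sort(key=lambda p: (-p.support, min(p.region_1.diag, p.region_2.diag)))
    return pairs


def mate_rescue(
    anchored: AlignmentResult,
    mate_read: str,
    reference,
    model: InsertModel,
    scoring: ScoringScheme | None = None,
    min_score_frac: float = 0.3,
    margin: int = 16,
) -> AlignmentResult:
    """Windowed DP of an unplaced mate against its partner's implied locus.

    Under FR orientation a forward anchor implies a reverse mate
    downstream (and vice versa); the window spans the insert band plus a
    margin, clamped to the contig.
    """
    scoring = scoring or ScoringScheme()
    lo_t, hi_t = model.band
    lm = len(mate_read)
    clo, chi = reference.contig_bounds(anchored.contig)
    if anchored.strand == "+":
        win_start = anchored.ref_start + lo_t - lm - margin
        win_end = anchored.ref_start + hi_t + margin
        query = revcomp(mate_read)
        strand = "-"
    else:
        frag_end = anchored.ref_end
        win_start = frag_end - hi_t - margin
        win_end = frag_end - lo_t + lm + margin
        query = mate_read
        strand = "+"
    win_start = max(clo, win_start)
    win_end = min(chi, win_end)
    if win_end - win_start < lm:
        win_start = max(clo, min(win_start, chi - lm))
        win_end = min(chi, max(win_end, win_start + lm))
    if win_end - win_start < lm:
        return AlignmentResult(mapped=False, read_len=lm)
    window = reference.fetch(win_start, win_end)
    res = align_window(query, window, scoring)
    if not res.mapped:
        return res
    res.ref_start += win_start
    res.strand = strand
    res.contig = anchored.contig
    res.accepted = res.score >= scoring.min_accept_score(lm, min_score_frac)
    if not res.accepted:
        return AlignmentResult(mapped=False, read_len=lm)
    return res


def template_length(a1: AlignmentResult, a2: AlignmentResult) -> int:
    """Signed-magnitude template length of two mapped mates (absolute value)."""
    left = min(a1.ref_start, a2.ref_start)
    right = max(a1.ref_end, a2.ref_end)
    return right - left


def is_proper(a1: AlignmentResult, a2: AlignmentResult, model: InsertModel) -> bool:
    """Proper pair: both accepted, one contig, FR layout, tlen in band."""
    if not (a1.mapped and a2.mapped and a1.accepted and a2.accepted):
        return False
    if a1.contig != a2.contig or a1.strand == a2.strand:
        return False
    fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
    if fwd.ref_start > rev.ref_start:
        return False
    return model.in_band(template_length(a1, a2))


def select_final(
    pairs_scored: list[tuple[AlignmentResult, AlignmentResult]],
    model: InsertModel,
) -> tuple[AlignmentResult, AlignmentResult, bool] | None:
    """Pick the pair maximizing summed score; deterministic tie-breaks.

    Ties go to the leftmost coordinate, then to the pair whose first end
    is on the forward strand.  Returns ``(end1, end2, proper)`` or None.
    """
    best = None
    best_key = None
    for a1, a2 in pairs_scored:
        if not (a1.mapped and a2.mapped):
            continue
        key = (
            -(a1.score + a2.score),
            min(a1.ref_start, a2.ref_start),
            0 if a1.strand == "+" else 1,
        )
        if best_key is None or key < best_key:
            best_key = key
            best = (a1, a2)
    if best is None:
        return None
    a1, a2 = best
    return a1, a2, is_proper(a1, a2, model)
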