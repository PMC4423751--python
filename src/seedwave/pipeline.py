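"""Batch-oriented end-to-end driver: FASTQ in, aligned SAM out.

Reads stream through in bounded batches; every read is an independent
work item, so a batch may be split across any number of workers with an
order-preserving merge — results are identical for 1 or many workers.
"""

from __future__ import annotations

import itertools
import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__ as _pkg_version
from .dp import AlignmentResult, ScoringScheme, align_candidate
from .fm_index import FMIndex
from .pairing import (
    InsertModel,
    is_proper,
    mate_rescue,
    pair_candidates,
    select_final,
    template_length,
)
from .reference import revcomp
from .seeding import (
    DEFAULT_MAX_BM,
    DEFAULT_MAX_NBM,
    DEFAULT_QUALITY_FLOOR,
    DEFAULT_ROUNDS,
    run_round,
)

DEFAULT_BATCH_SIZE = 1_000_000


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]
    mate_of: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class Batch:
    """Ordered read pairs (mate2 None for single-end) plus batch ordinal."""

    pairs: list[tuple[ReadRecord, ReadRecord | None]]
    ordinal: int

    def __len__(self) -> int:
        return len(self.pairs)


# ---- input ------------------------------------------------------------------


def _parse_reads(path: str | Path):
    """Yield ReadRecords from FASTQ (or FASTA with synthetic max qualities)."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fasta" if first == ">" else "fastq"
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq).upper()
        if fmt == "fasta":
            quals = [40] * len(seq)
        else:
            quals = rec.letter_annotations["phred_quality"]
        yield ReadRecord(rec.id, seq, list(quals))


def read_batches(
    fastq_1: str | Path,
    fastq_2: str | Path | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
):
    """Stream batches of <= batch_size read pairs (or single reads)."""
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    it1 = _parse_reads(fastq_1)
    it2 = _parse_reads(fastq_2) if fastq_2 is not None else None
    ordinal = 0
    pairs: list[tuple[ReadRecord, ReadRecord | None]] = []
    for i in itertools.count():
        r1 = next(it1, None)
        r2 = next(it2, None) if it2 is not None else None
        if r1 is None and (it2 is None or r2 is None):
            break
        if it2 is not None and (r1 is None) != (r2 is None):
            raise ValueError(
                f"mate files differ in record count: pair index {i} has only one mate"
            )
        if r1 is not None and r2 is not None:
            r1.mate_of, r2.mate_of = r2.id, r1.id
        pairs.append((r1, r2))
        if len(pairs) == batch_size:
            yield Batch(pairs, ordinal)
            ordinal += 1
            pairs = []
    if pairs:
        yield Batch(pairs, ordinal)


# ---- SAM records ------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 1-based; 0 when unmapped
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[str] = field(default_factory=list)

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ] + self.tags
        return "\t".join(fields)


def _qual_string(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_sam(records, header_info: dict, path: str | Path | None) -> None:
    """Emit a SAM file: @HD/@SQ/@PG header then the records, input order."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in header_info["contigs"]:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    cl = header_info.get("command_line", "seedwave")
    lines.append(f"@PG\tID:seedwave\tPN:seedwave\tVN:{_pkg_version}\tCL:{cl}")
    out = sys.stdout if path in (None, "-") else open(path, "w")
    try:
        for ln in lines:
            out.write(ln + "\n")
        for rec in records:
            out.write(rec.to_line() + "\n")
    except OSError as exc:
        raise OSError(f"failed writing SAM to {path}: {exc}") from exc
    finally:
        if out is not sys.stdout:
            out.close()


# ---- aligner ----------------------------------------------------------------


def _mapq(best: int, second: int | None) -> int:
    if best <= 0:
        return 0
    if second is None or second <= 0:
        return 60
    if second >= best:
        return 0
    return max(0, min(60, round(60 * (best - second) / best)))


@dataclass
class Aligner:
    """End-to-end per-read/per-pair alignment policy.

    Rounds descend from long to short seeds; a pair stops at the first
    round that yields a proper pair, and only after the last round do we
    fall back to best single-end placements plus mate rescue.
    """

    index: FMIndex
    rounds: tuple = DEFAULT_ROUNDS
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    insert_model: InsertModel = field(default_factory=InsertModel)
    budgets: tuple[int, int] = (DEFAULT_MAX_BM, DEFAULT_MAX_NBM)
    quality_floor: int | None = DEFAULT_QUALITY_FLOOR
    max_pairs: int = 10
    max_single: int = 10
    min_score_frac: float = 0.3
    lane_width: int = 16

    # -- internals ------------------------------------------------------------

    def _dp(self, read: ReadRecord, region) -> AlignmentResult:
        return align_candidate(
            read.sequence,
            region,
            self.index.reference,
            self.scoring,
            self.min_score_frac,
            self.lane_width,
        )

    def _best_single(self, read: ReadRecord, cands) -> tuple[AlignmentResult | None, list[int]]:
        """Best accepted single-end alignment among top candidates + all scores."""
        ranked = sorted(cands, key=lambda r: (-r.support, r.diag, r.strand))
        scores: list[int] = []
        best = None
        for region in ranked[: self.max_single]:
            res = self._dp(read, region)
            if res.mapped:
                scores.append(res.score)
            if res.mapped and res.accepted:
                if best is None or res.score > best.score:
                    best = res
        return best, sorted(scores, reverse=True)

    @staticmethod
    def _mapq_from(scores: list[int], best: int) -> int:
        second = next((s for s in scores if s < best), None)
        ambiguous = sum(1 for s in scores if s == best) > 1
        if ambiguous:
            return 0
        return _mapq(best, second)

    # -- public ---------------------------------------------------------------

    def align_pair(self, r1: ReadRecord, r2: ReadRecord):
        """Align a read pair; returns (res1, res2, proper, round_used)."""
        best1 = best2 = None
        scores1: list[int] = []
        scores2: list[int] = []
        round1 = round2 = None
        for ri, rcfg in enumerate(self.rounds):
            c1 = run_round(self.index, r1, rcfg, self.budgets,
                           quality_floor=self.quality_floor)
            c2 = run_round(self.index, r2, rcfg, self.budgets,
                           quality_floor=self.quality_floor)
            pairs = pair_candidates(c1, c2, self.insert_model,
                                    (len(r1.sequence), len(r2.sequence)))
            scored = []
            pair_scores1: list[int] = []
            pair_scores2: list[int] = []
            for p in pairs[: self.max_pairs]:
                a1 = self._dp(r1, p.region_1)
                a2 = self._dp(r2, p.region_2)
                if a1.mapped:
                    pair_scores1.append(a1.score)
                if a2.mapped:
                    pair_scores2.append(a2.score)
                if a1.accepted and a2.accepted:
                    scored.append((a1, a2))
            sel = select_final(scored, self.insert_model)
            if sel is not None and sel[2]:
                a1, a2, _ = sel
                a1.mapq = self._mapq_from(sorted(pair_scores1, reverse=True), a1.score)
                a2.mapq = self._mapq_from(sorted(pair_scores2, reverse=True), a2.score)
                return a1, a2, True, ri
            # remember best single-end placements in case all rounds fail
            if best1 is None and c1:
                best1, scores1 = self._best_single(r1, c1)
                round1 = ri if best1 is not None else None
            if best2 is None and c2:
                best2, scores2 = self._best_single(r2, c2)
                round2 = ri if best2 is not None else None
        # no proper pair from seeding: rescue around the better anchor
        anchor, mate, anchor_is_1 = None, None, True
        if best1 is not None and (best2 is None or best1.score >= best2.score):
            anchor, mate, anchor_is_1 = best1, r2, True
        elif best2 is not None:
            anchor, mate, anchor_is_1 = best2, r1, False
        if anchor is not None:
            rescued = mate_rescue(
                anchor, mate.sequence, self.index.reference, self.insert_model,
                self.scoring, self.min_score_frac,
            )
            if rescued.mapped:
                if anchor_is_1:
                    a1, a2 = anchor, rescued
                    a1.mapq = self._mapq_from(scores1, a1.score)
                    a2.mapq = min(a1.mapq, 60)
                    ru = round1
                else:
                    a1, a2 = rescued, anchor
                    a2.mapq = self._mapq_from(scores2, a2.score)
                    a1.mapq = min(a2.mapq, 60)
                    ru = round2
                return a1, a2, is_proper(a1, a2, self.insert_model), ru
        a1 = best1 if best1 is not None else AlignmentResult(mapped=False, read_len=len(r1.sequence))
        a2 = best2 if best2 is not None else AlignmentResult(mapped=False, read_len=len(r2.sequence))
        if a1.mapped:
            a1.mapq = self._mapq_from(scores1, a1.score)
        if a2.mapped:
            a2.mapq = self._mapq_from(scores2, a2.score)
        ru = round1 if a1.mapped else round2
        return a1, a2, False, ru

    def align_single(self, read: ReadRecord):
        """Align one single-end read; returns (result, round_used)."""
        for ri, rcfg in enumerate(self.rounds):
            cands = run_round(self.index, read, rcfg, self.budgets,
                              quality_floor=self.quality_floor)
            if not cands:
                continue
            best, scores = self._best_single(read, cands)
            if best is not None:
                best.mapq = self._mapq_from(scores, best.score)
                return best, ri
        return AlignmentResult(mapped=False, read_len=len(read.sequence)), None

    # -- SAM conversion -------------------------------------------------------

    def _to_local(self, res: AlignmentResult) -> tuple[str, int]:
        contig, local = self.index.reference.contig_of(res.ref_start)
        return contig, local

    def pair_to_sam(self, r1, r2, a1, a2, proper, round_used) -> list[SamRecord]:
        recs = []
        for read, res, mate_read, mate_res, first in (
            (r1, a1, r2, a2, True),
            (r2, a2, r1, a1, False),
        ):
            flag = FLAG_PAIRED | (FLAG_FIRST if first else FLAG_SECOND)
            if proper:
                flag |= FLAG_PROPER
            if not res.mapped:
                flag |= FLAG_UNMAPPED
            if not mate_res.mapped:
                flag |= FLAG_MATE_UNMAPPED
            if res.mapped and res.strand == "-":
                flag |= FLAG_REVERSE
            if mate_res.mapped and mate_res.strand == "-":
                flag |= FLAG_MATE_REVERSE
            recs.append(self._record(read, res, mate_res, flag, round_used))
        # TLEN: leftmost mate positive, rightmost negative
        if a1.mapped and a2.mapped and a1.contig == a2.contig:
            t = template_length(a1, a2)
            if a1.ref_start <= a2.ref_start:
                recs[0].tlen, recs[1].tlen = t, -t
            else:
                recs[0].tlen, recs[1].tlen = -t, t
        return recs

    def single_to_sam(self, read, res, round_used) -> SamRecord:
        flag = 0
        if not res.mapped:
            flag |= FLAG_UNMAPPED
        if res.mapped and res.strand == "-":
            flag |= FLAG_REVERSE
        rec = self._record(read, res, None, flag, round_used)
        return rec

    def _record(self, read, res, mate_res, flag, round_used) -> SamRecord:
        seq, qual = read.sequence, read.qualities
        if res.mapped and res.strand == "-":
            seq = revcomp(seq)
            qual = qual[::-1]
        tags = []
        if res.mapped:
            contig, local = self._to_local(res)
            pos = local + 1
            mapq = res.mapq
            cigar = res.cigar_string
            tags = [f"AS:i:{res.score}", f"NM:i:{res.edit_distance}"]
            if round_used is not None:
                tags.append(f"XR:i:{round_used}")
        elif mate_res is not None and mate_res.mapped:
            contig, local = self._to_local(mate_res)
            pos = local + 1
            mapq, cigar = 0, "*"
        else:
            contig, pos, mapq, cigar = "*", 0, 0, "*"
        rnext, pnext = "*", 0
        if mate_res is not None:
            if mate_res.mapped:
                mcontig, mlocal = self._to_local(mate_res)
                rnext = "=" if (contig == mcontig or contig == "*") else mcontig
                if contig == "*":
                    rnext = mcontig
                pnext = mlocal + 1
            elif res.mapped:
                rnext, pnext = "=", pos
        return SamRecord(
            qname=read.id,
            flag=flag,
            rname=contig,
            pos=pos,
            mapq=mapq,
            cigar=cigar,
            rnext=rnext,
            pnext=pnext,
            tlen=0,
            seq=seq,
            qual=_qual_string(qual),
            tags=tags,
        )


# ---- batch driver -----------------------------------------------------------


def _align_chunk(args):
    aligner, chunk = args
    out = []
    for r1, r2 in chunk:
        if r2 is None:
            res, ru = aligner.align_single(r1)
            out.append([aligner.single_to_sam(r1, res, ru)])
        else:
            a1, a2, proper, ru = aligner.align_pair(r1, r2)
            out.append(aligner.pair_to_sam(r1, r2, a1, a2, proper, ru))
    return out


def align_batch(batch: Batch, aligner: Aligner, workers: int = 1) -> list[SamRecord]:
    """Align one batch; per-pair results are identical for any worker count
    and records come back in input order."""
    if workers <= 1 or len(batch) < 2:
        grouped = _align_chunk((aligner, batch.pairs))
    else:
        n = len(batch.pairs)
        size = (n + workers - 1) // workers
        chunks = [batch.pairs[i : i + size] for i in range(0, n, size)]
        with ProcessPoolExecutor(max_workers=workers) as pool:
            grouped = []
            for part in pool.map(_align_chunk, [(aligner, c) for c in chunks]):
                grouped.extend(part)
    return [rec for group in grouped for rec in group]


def align_files(
    index: FMIndex,
    fastq_1,
    fastq_2=None,
    out_path=None,
    aligner: Aligner | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    workers: int = 1,
    command_line: str = "seedwave",
    log=None,
) -> dict:
    """Full pipeline: stream batches, align, write one SAM file.

    Returns summary counters (reads, mapped, proper pairs, per-round
    resolution counts).
    """
    aligner = aligner or Aligner(index)
    records: list[SamRecord] = []
    stats = {"reads": 0, "mapped": 0, "proper": 0, "by_round": {}}
    for batch in read_batches(fastq_1, fastq_2, batch_size):
        recs = align_batch(batch, aligner, workers)
        for rec in recs:
            stats["reads"] += 1
            if not rec.flag & FLAG_UNMAPPED:
                stats["mapped"] += 1
            if rec.flag & FLAG_PROPER:
                stats["proper"] += 1
            for tag in rec.tags:
                if tag.startswith("XR:i:"):
                    r = int(tag[5:])
                    stats["by_round"][r] = stats["by_round"].get(r, 0) + 1
        records.extend(recs)
        if log is not None:
            log(f"batch {batch.ordinal}: {len(batch)} pairs, "
                f"{stats['mapped']}/{stats['reads']} reads mapped, "
                f"round counts {dict(sorted(stats['by_round'].items()))}")
    header = {
        "contigs": [(n, len(s)) for n, s in index.reference.contigs],
        "command_line": command_line,
    }
    write_sam(records, header, out_path)
    return stats
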