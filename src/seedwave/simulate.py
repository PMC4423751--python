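"""Synthetic genomes, mutated donors, error-bearing read pairs, and
alignment-accuracy evaluation.

The generator emulates Illumina-style paired-end sequencing at desk
scale: a random reference, an optional donor carrying SNPs and short
indels (with exact donor->reference coordinate lift-over), and FR read
pairs with Gaussian insert sizes (default 500 +/- 25 bp) and independent
per-base substitution errors.  Every simulated read carries ground
truth in *reference* coordinates, so aligner output can be scored for
sensitivity (correct / all reads) and FDR (incorrect / aligned reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .pipeline import ReadRecord
from .reference import Reference, revcomp

_BASES = np.array(list("ACGT"))


# ---- genome -----------------------------------------------------------------


def generate_genome(
    length: int,
    n_contigs: int = 1,
    gc: float = 0.41,
    rng_seed: int = 0,
) -> Reference:
    """Random reference with the requested GC fraction, split into
    near-equal contigs named chr1..chrN.  Deterministic for a fixed seed."""
    if length < n_contigs or n_contigs < 1:
        raise ValueError("need length >= n_contigs >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be a fraction")
    rng = np.random.default_rng(rng_seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    contigs = []
    base = length // n_contigs
    for k in range(n_contigs):
        ln = base + (length % n_contigs if k == n_contigs - 1 else 0)
        seq = "".join(_BASES[rng.choice(4, size=ln, p=p)])
        contigs.append((f"chr{k + 1}", seq))
    return Reference(contigs)


# ---- donor ------------------------------------------------------------------


@dataclass
class Donor:
    """Mutated copy of a reference with exact coordinate lift-over.

    ``lift[contig][donor_pos]`` is the reference-local coordinate that a
    donor base projects to (inserted bases project to the next reference
    base).
    """

    reference: Reference
    genome: Reference
    variants: pd.DataFrame
    lift: dict[str, np.ndarray]


def mutate_genome(
    reference: Reference,
    snp_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    rng_seed: int = 0,
    max_indel: int = 3,
) -> Donor:
    """Plant SNPs and short indels; record every variant with both
    reference and donor coordinates."""
    for r in (snp_rate, ins_rate, del_rate):
        if not 0.0 <= r <= 0.1:
            raise ValueError("mutation rates must be in [0, 0.1]")
    rng = np.random.default_rng(rng_seed)
    donor_contigs = []
    lift: dict[str, np.ndarray] = {}
    rows = []
    for name, seq in reference.contigs:
        out: list[str] = []
        proj: list[int] = []
        i = 0
        n = len(seq)
        while i < n:
            u = rng.random()
            if u < del_rate and i + max_indel < n:
                ln = int(rng.integers(1, max_indel + 1))
                rows.append(
                    {"contig": name, "type": "del", "ref_pos": i,
                     "donor_pos": len(out), "ref_allele": seq[i : i + ln],
                     "alt_allele": ""}
                )
                i += ln
                continue
            if u < del_rate + ins_rate:
                ln = int(rng.integers(1, max_indel + 1))
                ins = "".join(_BASES[rng.integers(0, 4, size=ln)])
                rows.append(
                    {"contig": name, "type": "ins", "ref_pos": i,
                     "donor_pos": len(out), "ref_allele": "", "alt_allele": ins}
                )
                for ch in ins:
                    out.append(ch)
                    proj.append(i)
                # fall through: the anchor base itself is still emitted below
            if (u < del_rate + ins_rate + snp_rate and u >= del_rate + ins_rate
                    and seq[i] in "ACGT"):
                alt = _BASES[(("ACGT".index(seq[i])) + int(rng.integers(1, 4))) % 4]
                rows.append(
                    {"contig": name, "type": "snp", "ref_pos": i,
                     "donor_pos": len(out), "ref_allele": seq[i], "alt_allele": alt}
                )
                out.append(alt)
            else:
                out.append(seq[i])
            proj.append(i)
            i += 1
        donor_contigs.append((name, "".join(out)))
        lift[name] = np.array(proj, dtype=np.int64)
    variants = pd.DataFrame(
        rows, columns=["contig", "type", "ref_pos", "donor_pos",
                       "ref_allele", "alt_allele"]
    )
    return Donor(reference, Reference(donor_contigs), variants, lift)


def identity_donor(reference: Reference) -> Donor:
    """Donor identical to the reference (no variants)."""
    return mutate_genome(reference, 0.0, 0.0, 0.0, rng_seed=0)


# ---- read pairs -------------------------------------------------------------


def simulate_read_pairs(
    donor: Donor,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: int = 500,
    insert_sd: int = 25,
    subst_error_rate: float = 0.0,
    quality_profile: tuple[int, int, float] = (30, 10, 0.0),
    rng_seed: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """FR paired reads from the donor with ground truth in reference
    coordinates.

    ``quality_profile`` is (high_q, low_q, low_fraction): a constant
    high-quality profile with a configurable fraction of low-quality
    positions (to exercise quality-aware seed placement).
    """
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    rng = np.random.default_rng(rng_seed)
    genome = donor.genome
    lens = np.array([len(s) for _, s in genome.contigs], dtype=float)
    band_hi = insert_mean + 4 * insert_sd
    if lens.max() < band_hi:
        raise ValueError("donor contigs shorter than the insert band")
    usable = lens >= band_hi
    weights = np.where(usable, lens, 0.0)
    weights /= weights.sum()
    hq, lq, low_frac = quality_profile
    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    truth_rows = []
    for k in range(n_pairs):
        ci = int(rng.choice(len(lens), p=weights))
        name, seq = genome.contigs[ci]
        tlen = int(round(rng.normal(insert_mean, insert_sd)))
        tlen = max(read_len, min(tlen, len(seq)))
        start = int(rng.integers(0, len(seq) - tlen + 1))
        frag = seq[start : start + tlen]
        fwd_seq = frag[:read_len]
        rev_seq = revcomp(frag[-read_len:])
        fwd_start = int(donor.lift[name][start])
        rev_start = int(donor.lift[name][start + tlen - read_len])
        flip = bool(rng.random() < 0.5)

        def finish(s: str) -> tuple[str, list[int]]:
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            if subst_error_rate > 0:
                err = rng.random(read_len) < subst_error_rate
                if err.any():
                    idx = np.where(err)[0]
                    for i in idx:
                        cur = chr(arr[i])
                        choices = [b for b in "ACGT" if b != cur]
                        arr[i] = ord(choices[int(rng.integers(0, 3))])
            quals = np.full(read_len, hq, dtype=int)
            if low_frac > 0:
                quals[rng.random(read_len) < low_frac] = lq
            return arr.tobytes().decode(), list(quals)

        s1, q1 = finish(rev_seq if flip else fwd_seq)
        s2, q2 = finish(fwd_seq if flip else rev_seq)
        rid = f"sim{k}"
        reads1.append(ReadRecord(f"{rid}", s1, q1))
        reads2.append(ReadRecord(f"{rid}", s2, q2))
        if flip:
            row = {"id": rid, "contig": name, "start1": rev_start, "strand1": "-",
                   "start2": fwd_start, "strand2": "+"}
        else:
            row = {"id": rid, "contig": name, "start1": fwd_start, "strand1": "+",
                   "start2": rev_start, "strand2": "-"}
        truth_rows.append(row)
    truth = pd.DataFrame(
        truth_rows, columns=["id", "contig", "start1", "strand1", "start2", "strand2"]
    )
    return reads1, reads2, truth


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qualities) + "\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


# ---- evaluation -------------------------------------------------------------


@dataclass
class EvalReport:
    """Aggregate alignment-accuracy metrics.

    sensitivity = correctly aligned / all reads (the aligner emits one
    primary record per read, unmapped included, so the primary-record
    count is the simulated-read count); fdr = incorrectly aligned /
    aligned reads.
    """

    total_reads: int
    aligned: int
    properly_paired: int
    correctly_aligned: int
    incorrectly_aligned: int

    @property
    def sensitivity(self) -> float:
        return self.correctly_aligned / self.total_reads if self.total_reads else 0.0

    @property
    def fdr(self) -> float:
        return self.incorrectly_aligned / self.aligned if self.aligned else 0.0


def evaluate_alignments(
    sam_path: str | Path,
    truth: pd.DataFrame,
    tolerance: int = 5,
) -> EvalReport:
    """Score a SAM file against simulation truth.

    A mapped read is correct iff it reports the true contig and strand
    and its 0-based start is within ``tolerance`` of the truth.
    """
    by_id = truth.set_index("id")
    total = aligned = proper = correct = incorrect = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            total += 1
            if rec.query_name not in by_id.index:
                raise ValueError(f"read {rec.query_name!r} not present in truth")
            row = by_id.loc[rec.query_name]
            if rec.is_read2:
                t_start, t_strand = int(row["start2"]), row["strand2"]
            else:
                t_start, t_strand = int(row["start1"]), row["strand1"]
            if rec.is_proper_pair:
                proper += 1
            if rec.is_unmapped:
                continue
            aligned += 1
            strand = "-" if rec.is_reverse else "+"
            ok = (
                rec.reference_name == row["contig"]
                and strand == t_strand
                and abs(rec.reference_start - t_start) <= tolerance
            )
            if ok:
                correct += 1
            else:
                incorrect += 1
    return EvalReport(total, aligned, proper, correct, incorrect)
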