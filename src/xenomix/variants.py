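"""Minimal pileup-based diploid SNV caller with Phred-scaled quality.

Stands in for the samtools calling step of a resequencing pipeline: reads
are piled onto the reference, each covered column gets diploid genotype
likelihoods (ref/ref, ref/alt, alt/alt) under an independent-observation
binomial model with per-base error taken from base qualities, and a call
is emitted whenever the maximum-likelihood genotype is not homozygous
reference.  The call quality is the Phred-scaled posterior probability of
hom-ref, and calls are filtered at QUAL >= 13 by default (error
probability 10^-1.3 = 0.05012, the samtools default).

Indel calling is out of scope; evaluation in this package is SNV-level.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .align import AlignmentRecord
from .genomes import Genome, _BASE_INDEX
from .readsim import SimulatedRead

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_BASE_STR = "ACGT"


@dataclass
class PileupColumn:
    """Base observations at one reference position.

    ``base_counts`` holds per-base observation counts and ``base_quals``
    the mean Phred quality of the observations per base (exact for the
    flat-quality reads this package simulates).
    """

    chrom: str
    pos: int
    ref_base: str
    base_counts: dict[str, int]
    base_quals: dict[str, float]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass
class VariantCall:
    """A called SNV with diploid genotype and Phred-scaled quality."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str  # het | hom_alt
    qual: float

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele equals ref allele")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")


def phred_to_error_prob(q: float) -> float:
    """Phred score -> error probability, 10^(-q/10) (13 -> 0.05012)."""
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 10.0 ** (-q / 10.0)


def prob_to_phred(p: float) -> float:
    """Error probability -> Phred score, -10*log10(p)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("probability must be in (0, 1]")
    return -10.0 * math.log10(p)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def pileup(
    alignments: Iterable[AlignmentRecord],
    reads: dict[str, SimulatedRead],
    reference: Genome,
) -> Iterator[PileupColumn]:
    """Pile aligned read bases onto the reference, one column per covered
    position.

    Insertions contribute no reference base; deletions advance the
    reference without contributing.  Alignments must be mapped and unique;
    a CIGAR inconsistent with its read length raises, naming the read.
    """
    counts: dict[str, np.ndarray] = {}
    qualsum: dict[str, np.ndarray] = {}
    for chrom in reference.chroms:
        L = reference.length(chrom)
        counts[chrom] = np.zeros((4, L), dtype=np.int32)
        qualsum[chrom] = np.zeros((4, L), dtype=np.float64)
    for rec in alignments:
        if not rec.mapped:
            raise ValueError(f"unmapped record {rec.read_id} in pileup input")
        read = reads[rec.read_id]
        chrom = rec.chrom
        seq = read.seq_u8() if rec.strand == "+" else read.rc_u8()
        quals = (
            np.asarray(read.qualities, dtype=np.float64)
            if rec.strand == "+"
            else np.asarray(read.qualities, dtype=np.float64)[::-1]
        )
        ops = parse_cigar(rec.cigar)
        consumed = sum(n for n, op in ops if op in "MIS=X")
        if consumed != len(seq):
            raise ValueError(
                f"CIGAR {rec.cigar!r} inconsistent with read {rec.read_id} "
                f"(length {len(seq)})"
            )
        roff = 0  # read offset
        gpos = rec.pos  # reference position
        cc = counts[chrom]
        qq = qualsum[chrom]
        glen = cc.shape[1]
        for n, op in ops:
            if op in "M=X":
                lo, hi = gpos, min(gpos + n, glen)
                if hi > lo:
                    span = hi - lo
                    bidx = _BASE_INDEX[seq[roff : roff + span]].astype(np.intp)
                    pos_idx = np.arange(lo, hi)
                    np.add.at(cc, (bidx, pos_idx), 1)
                    np.add.at(qq, (bidx, pos_idx), quals[roff : roff + span])
                roff += n
                gpos += n
            elif op in "IS":
                roff += n
            elif op in "DN":
                gpos += n
    for chrom in reference.chroms:
        cc = counts[chrom]
        qq = qualsum[chrom]
        covered = np.flatnonzero(cc.sum(axis=0) > 0)
        ref_seq = reference.seq(chrom)
        for pos in covered:
            col_counts = {}
            col_quals = {}
            for b in range(4):
                c = int(cc[b, pos])
                if c:
                    base = _BASE_STR[b]
                    col_counts[base] = c
                    col_quals[base] = float(qq[b, pos]) / c
            yield PileupColumn(chrom, int(pos), ref_seq[pos], col_counts, col_quals)


# cached per-observation log10 probabilities keyed by rounded Phred score
_lp_cache: dict[tuple[float, bool], tuple[float, float, float]] = {}


def _log_probs(q: float, is_ref: bool) -> tuple[float, float, float]:
    """log10 P(observation | rr), P(|ra), P(|aa) for a ref or alt base."""
    key = (round(q, 3), is_ref)
    hit = _lp_cache.get(key)
    if hit is None:
        e = phred_to_error_prob(key[0])
        right = 1.0 - e
        wrong = e / 3.0
        het = 0.5 * right + 0.5 * wrong
        if is_ref:
            probs = (right, het, wrong)
        else:
            probs = (wrong, het, right)
        hit = tuple(math.log10(p) for p in probs)
        _lp_cache[key] = hit
    return hit


def call_snvs(
    columns: Iterable[PileupColumn], min_depth: int = 3
) -> list["VariantCall"]:
    """Diploid SNV calls from a pileup column stream (ordered by position).

    Only the most frequent non-reference allele is considered per column.
    QUAL is the Phred-scaled posterior of hom-ref under a uniform genotype
    prior; a call is emitted when the MAP genotype is het or hom-alt.
    """
    calls: list[VariantCall] = []
    for col in columns:
        depth = col.depth
        if depth < min_depth:
            continue
        ref = col.ref_base
        alts = [(c, b) for b, c in col.base_counts.items() if b != ref]
        if not alts:
            continue
        n_alt, alt = max(alts, key=lambda t: (t[0], -ord(t[1])))
        n_ref = col.base_counts.get(ref, 0)
        l_rr = l_ra = l_aa = 0.0
        if n_ref:
            lp = _log_probs(col.base_quals[ref], True)
            l_rr += n_ref * lp[0]
            l_ra += n_ref * lp[1]
            l_aa += n_ref * lp[2]
        lp = _log_probs(col.base_quals[alt], False)
        l_rr += n_alt * lp[0]
        l_ra += n_alt * lp[1]
        l_aa += n_alt * lp[2]
        liks = (l_rr, l_ra, l_aa)
        best = max(liks)
        if best == l_rr:
            continue
        lse = best + math.log10(sum(10.0 ** (l - best) for l in liks))
        qual = max(0.0, -10.0 * (l_rr - lse))
        genotype = "het" if l_ra >= l_aa else "hom_alt"
        calls.append(VariantCall(col.chrom, col.pos, ref, alt, genotype, qual))
    return calls


def filter_calls(calls: list[VariantCall], min_qual: float = 13.0) -> list[VariantCall]:
    """Keep calls with QUAL >= ``min_qual`` (inclusive; default 13)."""
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    return [c for c in calls if c.qual >= min_qual]


# ---------------------------------------------------------------------------
# VCF v4.2 (SNV sites with a single-sample GT column)
# ---------------------------------------------------------------------------

def write_vcf(calls: list[VariantCall], reference: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in reference.chroms:
            fh.write(f"##contig=<ID={chrom},length={reference.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            gt = "0/1" if c.genotype == "het" else "1/1"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
                f"{c.qual:.2f}\tPASS\t.\tGT\t{gt}\n"
            )


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt, qual = fields[:6]
            genotype = "het"
            if len(fields) >= 10 and fields[9].startswith("1/1"):
                genotype = "hom_alt"
            calls.append(
                VariantCall(chrom, int(pos) - 1, ref, alt, genotype, float(qual))
            )
    return calls
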