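"""Sample-genome mutation, read simulation with ground truth, and mixing.

The workflow mirrors how xenograft sequencing data arise: each reference
genome is first mutated at a configurable per-base rate (90% SNVs, 10%
indels by default) to produce the sampled individual's genome; fixed-length
reads with a uniform sequencing-error rate are then drawn from the mutated
genome; finally host and graft reads are mixed at a chosen ratio (e.g. 9:1
for 10% contamination, 1:1 for 50%).

Every read carries its full ground truth encoded in its name
(``origin:chrom_start_strand_nerrors_serial``, start in *reference*
coordinates), so alignments from any SAM-producing aligner remain scoreable.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .genomes import BASES, Genome, seq_to_u8, substitute, u8_to_seq, _apply_indel_events

logger = logging.getLogger(__name__)

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMPLEMENT[_a] = _b

_PROFILE_RE = re.compile(r"^m[LH]\.len\d{3}\.e[LH]$")


def revcomp_u8(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


@dataclass(frozen=True)
class VariantTruth:
    """A planted mutation, in reference coordinates (0-based, VCF-anchored)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # SNV | INS | DEL


@dataclass
class SimulatedRead:
    """A simulated read plus its truth record (encoded in ``read_id``)."""

    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        self._u8: np.ndarray | None = None
        self._rc: np.ndarray | None = None

    def seq_u8(self) -> np.ndarray:
        if self._u8 is None:
            self._u8 = seq_to_u8(self.sequence)
        return self._u8

    def rc_u8(self) -> np.ndarray:
        if self._rc is None:
            self._rc = revcomp_u8(self.seq_u8())
        return self._rc

    @property
    def truth(self) -> "ReadTruth":
        return parse_read_id(self.read_id)


class ReadTruth(NamedTuple):
    genome: str
    chrom: str
    start: int
    strand: str
    n_errors: int
    serial: int


def make_read_id(
    genome: str, chrom: str, start: int, strand: str, n_errors: int, serial: int
) -> str:
    return f"{genome}:{chrom}_{start}_{strand}_{n_errors}_{serial}"


def parse_read_id(read_id: str) -> ReadTruth:
    try:
        head, start, strand, n_err, serial = read_id.rsplit("_", 4)
        genome, chrom = head.split(":", 1)
        return ReadTruth(genome, chrom, int(start), strand, int(n_err), int(serial))
    except ValueError as exc:
        raise ValueError(f"read id {read_id!r} does not follow the truth codec") from exc


@dataclass(frozen=True)
class SimProfile:
    """One simulation setting: mutation rate, read length, error rate.

    Names follow the ``m{L,H}.len{050,100}.e{L,H}`` convention, e.g.
    ``mH.len100.eL`` = 1% mutation, 100 bp reads, 0.01% error.
    """

    mutation_rate: float
    read_length: int
    error_rate: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.name and not _PROFILE_RE.match(self.name):
            raise ValueError(f"profile name {self.name!r} violates the naming grammar")


@dataclass
class MutatedGenome:
    """A mutated sample genome with its planted-variant truth set.

    ``ref_pos[chrom]`` maps each sample-genome base back to its reference
    coordinate (inserted bases carry their anchor's coordinate), so reads
    drawn from the sample can be scored against reference alignments.
    """

    genome: Genome
    variants: list[VariantTruth]
    ref_pos: dict[str, np.ndarray]


def mutate_genome(
    genome: Genome,
    mutation_rate: float,
    snv_fraction: float = 0.9,
    seed: int = 0,
    indel_length_mean: float = 2.0,
    name: str | None = None,
) -> MutatedGenome:
    """Mutate a genome at ``mutation_rate`` per base (SNV w.p. ``snv_fraction``).

    Indels split evenly between insertions (random bases) and deletions,
    with geometric lengths.  Mutations swallowed by an earlier deletion are
    neither applied nor recorded, so replaying the truth list against the
    reference reproduces the mutated genome exactly.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    if not 0.0 <= snv_fraction <= 1.0:
        raise ValueError("snv_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms: dict[str, str] = {}
    ref_pos: dict[str, np.ndarray] = {}
    variants: list[VariantTruth] = []
    for chrom, seq_str in genome.chroms.items():
        seq = genome.seq_u8(chrom)
        L = len(seq)
        sites = np.flatnonzero(rng.random(L) < mutation_rate)
        is_snv = rng.random(len(sites)) < snv_fraction
        # pre-draw all randomness in site order for determinism
        raw_events: list[tuple[int, str, object]] = []
        for pos, snv in zip(sites, is_snv):
            pos = int(pos)
            if snv:
                shift = int(rng.integers(1, 4))
                raw_events.append((pos, "SNV", shift))
            elif rng.random() < 0.5:
                length = int(rng.geometric(1.0 / indel_length_mean))
                bases = rng.choice(BASES, size=length)
                raw_events.append((pos, "INS", bases))
            else:
                length = int(rng.geometric(1.0 / indel_length_mean))
                raw_events.append((pos, "DEL", length))
        # resolve overlaps: a deletion consumes downstream candidate sites
        applied: list[tuple[int, str, object]] = []
        cursor = -1
        for pos, kind, payload in raw_events:
            if pos <= cursor:
                continue
            if kind == "DEL":
                d = min(int(payload), L - 1 - pos)
                if d <= 0:
                    continue
                applied.append((pos, kind, d))
                cursor = pos + d
            else:
                applied.append((pos, kind, payload))
                cursor = pos
        snv_pos = np.array([p for p, k, _ in applied if k == "SNV"], dtype=np.int64)
        out = seq.copy()
        indel_events: list[tuple[int, str, object]] = []
        from .genomes import _BASE_INDEX  # local import to avoid cycle noise

        for pos, kind, payload in applied:
            ref_base = chr(seq[pos])
            if kind == "SNV":
                alt = chr(BASES[(int(_BASE_INDEX[seq[pos]]) + payload) % 4])
                out[pos] = ord(alt)
                variants.append(VariantTruth(chrom, pos, ref_base, alt, "SNV"))
            elif kind == "INS":
                ins_str = u8_to_seq(np.asarray(payload, dtype=np.uint8))
                variants.append(
                    VariantTruth(chrom, pos, ref_base, ref_base + ins_str, "INS")
                )
                indel_events.append((pos, "INS", payload))
            else:  # DEL of payload bases after the anchor
                d = int(payload)
                ref_str = u8_to_seq(seq[pos : pos + 1 + d])
                variants.append(VariantTruth(chrom, pos, ref_str, ref_base, "DEL"))
                indel_events.append((pos + 1, "DEL", d))
        new_seq, src = _apply_indel_events(out, indel_events)
        chroms[chrom] = u8_to_seq(new_seq)
        ref_pos[chrom] = src
    sample = Genome(name or genome.name, chroms)
    return MutatedGenome(sample, variants, ref_pos)


def apply_variants(genome: Genome, variants: list[VariantTruth]) -> Genome:
    """Independent sequential editor: replay a truth list onto a reference.

    Edits are applied right-to-left per chromosome so earlier coordinates
    stay valid.  Used as an oracle for :func:`mutate_genome`.
    """
    chroms = dict(genome.chroms)
    by_chrom: dict[str, list[VariantTruth]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, events in by_chrom.items():
        seq = chroms[chrom]
        for v in sorted(events, key=lambda v: v.pos, reverse=True):
            if seq[v.pos : v.pos + len(v.ref_allele)] != v.ref_allele:
                raise ValueError(f"ref allele mismatch at {chrom}:{v.pos}")
            seq = seq[: v.pos] + v.alt_allele + seq[v.pos + len(v.ref_allele) :]
        chroms[chrom] = seq
    return Genome(genome.name, chroms)


def error_phred(error_rate: float, cap: int = 40) -> int:
    """Flat Phred quality equivalent to a per-base error rate (capped)."""
    if error_rate <= 0:
        return cap
    return min(cap, round(-10.0 * math.log10(error_rate)))


def simulate_reads(
    genome: Genome,
    regions,
    read_length: int,
    error_rate: float,
    depth: float,
    seed: int = 0,
    ref_pos: dict[str, np.ndarray] | None = None,
) -> list[SimulatedRead]:
    """Draw error-bearing reads uniformly from ``regions`` of a genome.

    ``regions`` is ``"whole"`` or a list of ``(chrom, start, end)`` in the
    genome's own coordinates.  The read count is
    ``round(depth * total_region_length / read_length)``; start positions are
    uniform over valid starts, strands uniform, and each base is flipped to a
    different uniformly chosen base with probability ``error_rate``.
    Qualities are the flat Phred equivalent of the error rate.  When
    ``ref_pos`` maps are given (sample genome drawn from a mutated
    reference), truth starts are recorded in reference coordinates.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if regions == "whole":
        regions = [(chrom, 0, genome.length(chrom)) for chrom in genome.chroms]
    usable = []
    for chrom, start, end in regions:
        if end - start < read_length:
            logger.warning(
                "region %s:%d-%d shorter than read length %d; skipped",
                chrom, start, end, read_length,
            )
            continue
        usable.append((chrom, start, end))
    if not usable:
        return []
    total_len = sum(end - start for _, start, end in usable)
    n_reads = round(depth * total_len / read_length)
    rng = np.random.default_rng(seed)
    n_starts = np.array([end - start - read_length + 1 for _, start, end in usable])
    weights = n_starts / n_starts.sum()
    region_idx = rng.choice(len(usable), size=n_reads, p=weights)
    offsets = rng.random(n_reads)
    strands = rng.random(n_reads) < 0.5
    qual = error_phred(error_rate)
    quals = np.full(read_length, qual, dtype=np.int16)
    reads: list[SimulatedRead] = []
    for serial in range(n_reads):
        chrom, rstart, rend = usable[int(region_idx[serial])]
        start = rstart + int(offsets[serial] * (rend - rstart - read_length + 1))
        window = genome.seq_u8(chrom)[start : start + read_length]
        strand = "+" if strands[serial] else "-"
        read = window if strand == "+" else revcomp_u8(window)
        err_sites = np.flatnonzero(rng.random(read_length) < error_rate)
        n_err = len(err_sites)
        if n_err:
            read = substitute(rng, read, err_sites)
        truth_start = int(ref_pos[chrom][start]) if ref_pos is not None else start
        rid = make_read_id(genome.name, chrom, truth_start, strand, n_err, serial)
        reads.append(SimulatedRead(rid, u8_to_seq(read), quals))
    return reads


def mix_reads(
    host_reads: list[SimulatedRead],
    graft_reads: list[SimulatedRead],
    host_to_graft_ratio: tuple[int, int],
    total_reads: int,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Subsample and shuffle a host/graft read mixture at an exact ratio."""
    h, g = host_to_graft_ratio
    if h < 0 or g < 0 or h + g == 0:
        raise ValueError(f"invalid ratio {host_to_graft_ratio}")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    n_host = round(total_reads * h / (h + g))
    n_graft = total_reads - n_host
    if n_host > len(host_reads):
        raise ValueError(
            f"host pool too small: need {n_host}, have {len(host_reads)}"
        )
    if n_graft > len(graft_reads):
        raise ValueError(
            f"graft pool too small: need {n_graft}, have {len(graft_reads)}"
        )
    rng = np.random.default_rng(seed)
    host_idx = rng.choice(len(host_reads), size=n_host, replace=False)
    graft_idx = rng.choice(len(graft_reads), size=n_graft, replace=False)
    mixed = [host_reads[i] for i in host_idx] + [graft_reads[i] for i in graft_idx]
    order = rng.permutation(len(mixed))
    return [mixed[i] for i in order]


def effective_depth(total_depth: float, host_fraction: float) -> float:
    """Fold-coverage contributed by host reads after mixing (e.g. 60*0.9=54)."""
    if not 0.0 <= host_fraction <= 1.0:
        raise ValueError("host_fraction must be in [0, 1]")
    return total_depth * host_fraction


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Write reads as Sanger (Phred+33) FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[SimulatedRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.array(rec.letter_annotations["phred_quality"], dtype=np.int16)
        reads.append(SimulatedRead(rec.id, str(rec.seq), quals))
    return reads


def write_variant_table(variants: list[VariantTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvtype\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{v.vtype}\n")


def read_variant_table(path) -> list[VariantTruth]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, pos, ref, alt, vtype = line.rstrip("\n").split("\t")
            out.append(VariantTruth(chrom, int(pos), ref, alt, vtype))
    return out
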