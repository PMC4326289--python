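"""Synthetic reference genomes for xenograft contamination studies.

This module forges a pair of related reference genomes -- a "host" (human
surrogate) and a "graft-contaminant" (mouse surrogate) -- together with gene
annotations.  The two genomes are related by a divergence model with a lower
substitution rate inside coding exons than outside them, emulating the fact
that human and mouse are far more alike in coding sequence (~85% identity)
than in the rest of the genome.  Indels are placed outside exons so that
coding regions stay colinear between the two genomes.

Coordinates are 0-based half-open throughout; 1-based conventions appear only
at SAM/VCF boundaries elsewhere in the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII -> 0..3 base index (255 for anything else)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class PlacementError(ValueError):
    """Raised when the requested gene models cannot be placed on a genome."""


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class Genome:
    """A named genome: ordered chromosomes of A/C/G/T sequence."""

    name: str
    chroms: dict[str, str]

    def __post_init__(self) -> None:
        self._u8_cache: dict[str, np.ndarray] = {}
        for chrom, seq in self.chroms.items():
            if seq and set(seq) - set("ACGT"):
                bad = sorted(set(seq) - set("ACGT"))
                raise ValueError(f"chromosome {chrom!r} contains non-ACGT symbols {bad}")

    @property
    def chromosomes(self) -> list[tuple[str, str]]:
        return list(self.chroms.items())

    def seq(self, chrom: str) -> str:
        return self.chroms[chrom]

    def seq_u8(self, chrom: str) -> np.ndarray:
        arr = self._u8_cache.get(chrom)
        if arr is None:
            arr = seq_to_u8(self.chroms[chrom])
            self._u8_cache[chrom] = arr
        return arr

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())


@dataclass
class GeneModel:
    """A protein-coding gene: ordered, non-overlapping CDS intervals.

    The reading frame is anchored at the CDS start (5' end on the gene's
    strand); the total CDS length is a multiple of 3 so every base belongs
    to a complete codon.
    """

    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.cds_intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad CDS interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(f"total CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)


@dataclass
class DivergenceSpec:
    """Parameters relating the host genome to its diverged relative.

    Defaults put ~85% identity inside exons (the human/mouse coding
    similarity) and much lower identity outside, so that short reads from
    one genome only occasionally align to the other.
    """

    exonic_substitution_rate: float = 0.15
    nonexonic_substitution_rate: float = 0.35
    indel_rate: float = 0.02
    indel_length_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exonic_substitution_rate", "nonexonic_substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.indel_length_mean < 1.0:
            raise ValueError("indel_length_mean must be >= 1")


@dataclass
class GeneSpec:
    """Length distribution knobs for synthetic gene models (bases)."""

    cds_min: int = 900
    cds_max: int = 2100
    max_exons: int = 3
    exon_min: int = 200
    intron_min: int = 200
    intron_max: int = 800
    intergenic_min: int = 500
    intergenic_max: int = 5000


def generate_ancestor(
    total_length: int,
    n_chromosomes: int,
    gc_fraction: float = 0.41,
    seed: int = 0,
    name: str = "ancestor",
) -> Genome:
    """Draw an i.i.d. random genome with the requested GC content.

    The total length is split as evenly as possible across chromosomes
    named ``chr1``..``chrN``.  Deterministic given ``seed``.
    """
    if total_length < 0:
        raise ValueError(f"total_length must be >= 0, got {total_length}")
    if n_chromosomes < 0:
        raise ValueError(f"n_chromosomes must be >= 0, got {n_chromosomes}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    if n_chromosomes == 0:
        if total_length > 0:
            raise ValueError("cannot place positive total_length on zero chromosomes")
        return Genome(name, {})
    if total_length < n_chromosomes:
        raise ValueError(
            f"total_length {total_length} too small for {n_chromosomes} non-empty chromosomes"
        )
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = [at, gc, gc, at]  # A, C, G, T
    base_len, extra = divmod(total_length, n_chromosomes)
    chroms: dict[str, str] = {}
    for i in range(n_chromosomes):
        length = base_len + (1 if i < extra else 0)
        arr = rng.choice(BASES, size=length, p=probs)
        chroms[f"chr{i + 1}"] = u8_to_seq(arr)
    return Genome(name, chroms)


def _split_cds(rng: np.random.Generator, total: int, spec: GeneSpec) -> np.ndarray:
    """Split a CDS total into exon lengths, each >= spec.exon_min."""
    n_exons = int(rng.integers(1, spec.max_exons + 1))
    n_exons = max(1, min(n_exons, total // spec.exon_min))
    slack = total - n_exons * spec.exon_min
    parts = rng.multinomial(slack, np.full(n_exons, 1.0 / n_exons))
    return parts + spec.exon_min


def annotate_genes(
    genome: Genome,
    n_genes: int,
    cds_length_distribution: GeneSpec | None = None,
    seed: int = 0,
) -> tuple[list[GeneModel], list[tuple[str, int, int]]]:
    """Place non-overlapping gene models on a genome.

    Returns the gene models plus the exome region set (union of all CDS
    intervals, sorted, exportable as BED).  Raises :class:`PlacementError`
    when the genome is too short to hold ``n_genes`` genes.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return [], []
    if genome.total_length == 0:
        raise PlacementError("cannot annotate genes on an empty genome")
    spec = cds_length_distribution or GeneSpec()
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chroms)
    cursors = {c: 0 for c in chrom_names}
    genes: list[GeneModel] = []
    order = itertools.cycle(chrom_names)
    for _ in range(n_genes):
        total_cds = 3 * int(rng.integers(spec.cds_min // 3, spec.cds_max // 3 + 1))
        exon_lens = _split_cds(rng, total_cds, spec)
        intron_lens = rng.integers(spec.intron_min, spec.intron_max + 1, size=len(exon_lens) - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1))
        placed = False
        for chrom in itertools.islice(order, len(chrom_names)):
            start = cursors[chrom] + gap
            if start + span <= genome.length(chrom):
                intervals = []
                pos = start
                for i, elen in enumerate(exon_lens):
                    intervals.append((pos, pos + int(elen)))
                    pos += int(elen)
                    if i < len(intron_lens):
                        pos += int(intron_lens[i])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(chrom, strand, intervals))
                cursors[chrom] = start + span
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"genome too short to place {n_genes} genes (placed {len(genes)})"
            )
    exome = sorted(
        (g.chrom, start, end) for g in genes for start, end in g.cds_intervals
    )
    return genes, exome


def exon_mask(genome: Genome, chrom: str, annotations: list[GeneModel]) -> np.ndarray:
    """Boolean per-base mask of exonic (CDS) positions on one chromosome."""
    mask = np.zeros(genome.length(chrom), dtype=bool)
    for gene in annotations:
        if gene.chrom == chrom:
            for start, end in gene.cds_intervals:
                mask[start:end] = True
    return mask


def _apply_indel_events(
    seq: np.ndarray, events: list[tuple[int, str, object]]
) -> tuple[np.ndarray, np.ndarray]:
    """Apply (pos, kind, payload) indel events to a substituted sequence.

    ``DEL`` payload is the deletion length (bases pos..pos+len-1 removed);
    ``INS`` payload is a uint8 array inserted after the base at pos.
    Events falling inside an earlier deletion are skipped.  Returns the new
    sequence and, per new base, its source coordinate (inserted bases carry
    the coordinate of their anchor base).
    """
    pieces: list[np.ndarray] = []
    src: list[np.ndarray] = []
    cursor = 0
    L = len(seq)
    for pos, kind, payload in sorted(events, key=lambda e: e[0]):
        if pos < cursor or pos >= L:
            continue
        pieces.append(seq[cursor:pos])
        src.append(np.arange(cursor, pos, dtype=np.int64))
        if kind == "DEL":
            cursor = min(pos + int(payload), L)
        else:  # INS: keep anchor base, then inserted bases
            ins = np.asarray(payload, dtype=np.uint8)
            pieces.append(seq[pos : pos + 1])
            src.append(np.array([pos], dtype=np.int64))
            pieces.append(ins)
            src.append(np.full(len(ins), pos, dtype=np.int64))
            cursor = pos + 1
    pieces.append(seq[cursor:])
    src.append(np.arange(cursor, L, dtype=np.int64))
    return np.concatenate(pieces), np.concatenate(src)


def substitute(
    rng: np.random.Generator, seq: np.ndarray, sites: np.ndarray
) -> np.ndarray:
    """Replace bases at ``sites`` with a uniformly chosen different base."""
    out = seq.copy()
    n = int(sites.sum()) if sites.dtype == bool else len(sites)
    if n == 0:
        return out
    idx = _BASE_INDEX[out[sites]].astype(np.int64)
    shift = rng.integers(1, 4, size=n)
    out[sites] = BASES[(idx + shift) % 4]
    return out


def diverge(
    ancestor: Genome,
    annotations: list[GeneModel],
    spec: DivergenceSpec,
    name: str = "diverged",
    return_map: bool = False,
):
    """Evolve a related genome from the ancestor.

    Substitutions occur per base at the exonic rate inside CDS intervals and
    the (typically higher) non-exonic rate elsewhere; indels (geometric
    length) occur at ``indel_rate`` outside exons only, keeping coding
    regions colinear.  Deterministic given ``spec.seed``.

    With ``return_map=True`` also returns ``{chrom: src_pos}`` arrays
    mapping each diverged base back to its ancestor coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    chroms: dict[str, str] = {}
    maps: dict[str, np.ndarray] = {}
    for chrom, seq_str in ancestor.chroms.items():
        seq = ancestor.seq_u8(chrom)
        L = len(seq)
        mask = exon_mask(ancestor, chrom, annotations)
        rates = np.where(mask, spec.exonic_substitution_rate, spec.nonexonic_substitution_rate)
        sub_sites = rng.random(L) < rates
        out = substitute(rng, seq, sub_sites)
        indel_sites = np.flatnonzero((rng.random(L) < spec.indel_rate) & ~mask)
        events: list[tuple[int, str, object]] = []
        if len(indel_sites):
            p = 1.0 / spec.indel_length_mean
            lengths = rng.geometric(p, size=len(indel_sites))
            is_ins = rng.random(len(indel_sites)) < 0.5
            for pos, length, ins in zip(indel_sites, lengths, is_ins):
                if ins:
                    bases = rng.choice(BASES, size=int(length))
                    events.append((int(pos), "INS", bases))
                else:
                    events.append((int(pos), "DEL", int(length)))
        new_seq, src = _apply_indel_events(out, events)
        chroms[chrom] = u8_to_seq(new_seq)
        maps[chrom] = src
    genome = Genome(name, chroms)
    if return_map:
        return genome, maps
    return genome


def project_intervals(
    intervals: list[tuple[str, int, int]], maps: dict[str, np.ndarray]
) -> list[tuple[str, int, int]]:
    """Project source-coordinate intervals into derived coordinates.

    ``maps[chrom]`` is the non-decreasing per-derived-base source coordinate
    array produced by :func:`diverge` (or genome mutation).  Empty
    projections are dropped.
    """
    out = []
    for chrom, start, end in intervals:
        src = maps[chrom]
        lo = int(np.searchsorted(src, start, side="left"))
        hi = int(np.searchsorted(src, end, side="left"))
        if hi > lo:
            out.append((chrom, lo, hi))
    return out


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, name: str = "genome") -> Genome:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq).upper()
    return Genome(name, chroms)


def write_bed(intervals: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tcds_intervals\n")
        for g in genes:
            ivs = ",".join(f"{s}-{e}" for s, e in g.cds_intervals)
            fh.write(f"{g.chrom}\t{g.strand}\t{ivs}\n")


def read_gene_table(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"unrecognized gene table header in {path}")
        for line in fh:
            chrom, strand, ivs = line.rstrip("\n").split("\t")
            intervals = [
                (int(a), int(b)) for a, b in (iv.split("-") for iv in ivs.split(","))
            ]
            genes.append(GeneModel(chrom, strand, intervals))
    return genes
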