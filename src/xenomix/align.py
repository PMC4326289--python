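"""A small seed-and-extend read aligner with unique-best-match semantics.

Stands in for Bowtie2/BWA at desk scale.  Reads are seeded with exact
k-mer hits (both strands), candidate loci are scored by a banded
global-in-read / local-in-reference alignment with affine gap costs, and a
read is reported as aligned only when a single locus attains the best
score; ties across loci -- including the homologous-locus ties that arise
when a read fits two genomes in a combined index equally well -- leave the
read unmapped with MAPQ 0.

The index namespaces chromosome names as ``<genome>:<chrom>`` so that one
index can hold several genomes (the combined-reference strategy).
External aligners can be plugged in through :func:`ingest_sam`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pysam

from .genomes import Genome
from .readsim import SimulatedRead

NEG = np.float32(-1e9)


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding knobs.

    A gap of length g costs ``-(|gap_open| + g*|gap_extend|)``.  A read is
    "successfully aligned" when mapped, unique, and its score reaches
    ``floor(min_score_fraction * read_length * match)`` -- an end-to-end
    identity floor mimicking default aligner sensitivity.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    k: int = 15
    band: int = 10
    min_score_fraction: float = 0.6
    mapq_cap: int = 60
    max_seed_hits: int = 100

    def min_score(self, read_length: int) -> int:
        return math.floor(self.min_score_fraction * read_length * self.match)

    @property
    def ungapped_certain_mismatches(self) -> int:
        """Max mismatch count for which no gapped alignment can score higher."""
        # gapped alignments lose at least |gap_open| + |gap_extend| vs perfect
        gap_floor = -(self.gap_open + self.gap_extend)
        per_mismatch = self.match - self.mismatch
        return max(0, (gap_floor - 1) // per_mismatch)


@dataclass
class AlignmentRecord:
    """One read's (primary) alignment outcome against an index."""

    read_id: str
    ref_name: str | None
    pos: int
    strand: str
    score: int
    mapq: int
    cigar: str
    mapped: bool
    unique: bool
    second_score: float = float("-inf")
    reason: str | None = None

    @property
    def genome(self) -> str | None:
        if self.ref_name is None:
            return None
        return self.ref_name.split(":", 1)[0]

    @property
    def chrom(self) -> str | None:
        if self.ref_name is None:
            return None
        return self.ref_name.split(":", 1)[1]


def unmapped_record(read_id: str, reason: str | None = None) -> AlignmentRecord:
    return AlignmentRecord(
        read_id, None, -1, ".", 0, 0, "*", mapped=False, unique=False, reason=reason
    )


class SeedIndex:
    """Exact k-mer index over one or more genomes (namespaced chromosomes)."""

    def __init__(self, genomes: list[Genome], k: int):
        if k < 8:
            raise ValueError(f"k must be >= 8, got {k}")
        names = [g.name for g in genomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate genome names in {names}")
        self.k = k
        self.refs: list[tuple[str, np.ndarray]] = []
        self.genome_names = names
        self._kmers: dict[bytes, object] = {}  # value: packed int or list of them
        for genome in genomes:
            for chrom in genome.chroms:
                rid = len(self.refs)
                arr = genome.seq_u8(chrom)
                self.refs.append((f"{genome.name}:{chrom}", arr))
                self._add_sequence(rid, arr)

    def _add_sequence(self, rid: int, arr: np.ndarray) -> None:
        k = self.k
        kmers = self._kmers
        data = arr.tobytes()
        for pos in range(len(data) - k + 1):
            key = data[pos : pos + k]
            packed = (rid << 40) | pos
            cur = kmers.get(key)
            if cur is None:
                kmers[key] = packed
            elif isinstance(cur, int):
                kmers[key] = [cur, packed]
            else:
                cur.append(packed)

    def lookup(self, kmer: bytes) -> list[tuple[int, int]]:
        cur = self._kmers.get(kmer)
        if cur is None:
            return []
        if isinstance(cur, int):
            return [(cur >> 40, cur & 0xFFFFFFFFFF)]
        if len(cur) > 100:  # hyper-repetitive seed
            return []
        return [(p >> 40, p & 0xFFFFFFFFFF) for p in cur]

    def ref_name(self, rid: int) -> str:
        return self.refs[rid][0]

    def ref_lengths(self) -> dict[str, int]:
        return {name: len(arr) for name, arr in self.refs}

    @property
    def n_kmers(self) -> int:
        return len(self._kmers)

    def positions(self) -> dict[bytes, list[tuple[int, int]]]:
        """All indexed (rid, pos) per k-mer (test/introspection helper)."""
        return {key: self.lookup(key) for key in self._kmers}


def build_index(genomes: Genome | list[Genome], k: int = 15) -> SeedIndex:
    if isinstance(genomes, Genome):
        genomes = [genomes]
    return SeedIndex(list(genomes), k)


def seed_offsets(read_length: int, k: int) -> list[int]:
    """Seed start offsets: one every ``read_length // 4`` bases, clipped."""
    step = max(1, read_length // 4)
    offs = list(range(0, read_length - k + 1, step))
    return offs or [0]


# ---------------------------------------------------------------------------
# Banded affine-gap dynamic programming
# ---------------------------------------------------------------------------

def _banded_scores_batch(
    reads: np.ndarray, windows: np.ndarray, p: AlignParams
) -> np.ndarray:
    """Best semi-global score for each (read, window) pair; score only.

    ``reads`` is (N, L) uint8, ``windows`` is (N, W) uint8 with
    W = L + 2*band.  The read is aligned end-to-end; flanking window
    columns are free.  Row i of the band holds diagonals d = j - i.
    """
    n, L = reads.shape
    W = windows.shape[1]
    B = W - L + 1
    go = -p.gap_open  # positive costs
    ge = -p.gap_extend
    didx = np.arange(B, dtype=np.float32)
    sub0 = np.where(windows[:, 0:B] == reads[:, 0:1], p.match, p.mismatch).astype(np.float32)
    M = sub0
    Y = np.full((n, B), NEG, dtype=np.float32)
    X = _row_gap(M, didx, go, ge)
    for i in range(1, L):
        sub = np.where(windows[:, i : i + B] == reads[:, i : i + 1], p.match, p.mismatch)
        prev_best = np.maximum(np.maximum(M, X), Y)
        Y_new = np.full((n, B), NEG, dtype=np.float32)
        Y_new[:, :-1] = np.maximum(M[:, 1:] - go - ge, Y[:, 1:] - ge)
        M = prev_best + sub
        Y = Y_new
        X = _row_gap(M, didx, go, ge)
    return np.maximum(M, Y).max(axis=1)


def _row_gap(M: np.ndarray, didx: np.ndarray, go: float, ge: float) -> np.ndarray:
    """Within-row deletion state via a prefix-max (single gap-open charge)."""
    A = M + ge * didx
    run = np.maximum.accumulate(A, axis=1)
    X = np.full_like(M, NEG)
    X[:, 1:] = run[:, :-1] - go - ge * didx[1:]
    return X


def _banded_traceback(
    read: np.ndarray, window: np.ndarray, p: AlignParams
) -> tuple[int, int, str]:
    """Banded DP with traceback: (score, window start column, CIGAR)."""
    L = len(read)
    W = len(window)
    B = W - L + 1
    go = -p.gap_open
    ge = -p.gap_extend
    didx = np.arange(B, dtype=np.float32)
    M = np.empty((L, B), dtype=np.float32)
    X = np.empty((L, B), dtype=np.float32)
    Y = np.empty((L, B), dtype=np.float32)
    M[0] = np.where(window[0:B] == read[0], p.match, p.mismatch)
    Y[0] = NEG
    X[0] = _row_gap(M[0:1], didx, go, ge)[0]
    for i in range(1, L):
        sub = np.where(window[i : i + B] == read[i], p.match, p.mismatch)
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i] = prev + sub
        Y[i] = NEG
        Y[i, :-1] = np.maximum(M[i - 1, 1:] - go - ge, Y[i - 1, 1:] - ge)
        X[i] = _row_gap(M[i : i + 1], didx, go, ge)[0]
    ends = np.maximum(M[L - 1], Y[L - 1])
    d = int(np.argmax(ends))
    score = float(ends[d])
    state = "M" if M[L - 1, d] >= Y[L - 1, d] else "Y"
    i = L - 1
    ops: list[str] = []
    eps = 1e-3
    while True:
        if state == "M":
            ops.append("M")
            if i == 0:
                break
            prev_vals = (M[i - 1, d], X[i - 1, d], Y[i - 1, d])
            sub = p.match if window[i + d] == read[i] else p.mismatch
            target = M[i, d] - sub
            if abs(prev_vals[0] - target) < eps:
                state = "M"
            elif abs(prev_vals[1] - target) < eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
        elif state == "X":
            ops.append("D")
            if abs(M[i, d - 1] - go - ge - X[i, d]) < eps:
                state = "M"
            d -= 1
        else:  # Y
            ops.append("I")
            if abs(M[i - 1, d + 1] - go - ge - Y[i, d]) < eps:
                state = "M"
            d += 1
            i -= 1
    start_col = d
    ops.reverse()
    cigar = _compress_cigar(ops)
    return int(round(score)), start_col, cigar


def _compress_cigar(ops: list[str]) -> str:
    out = []
    prev, count = ops[0], 0
    for op in ops:
        if op == prev:
            count += 1
        else:
            out.append(f"{count}{prev}")
            prev, count = op, 1
    out.append(f"{count}{prev}")
    return "".join(out)


def _extract_window(ref: np.ndarray, nominal_start: int, width: int) -> np.ndarray:
    """Reference window with 0-sentinel padding outside chromosome bounds."""
    win = np.zeros(width, dtype=np.uint8)
    lo = max(0, nominal_start)
    hi = min(len(ref), nominal_start + width)
    if hi > lo:
        win[lo - nominal_start : hi - nominal_start] = ref[lo:hi]
    return win


# ---------------------------------------------------------------------------
# Read alignment
# ---------------------------------------------------------------------------

def align_reads(
    reads: list[SimulatedRead], index: SeedIndex, params: AlignParams | None = None
) -> dict[str, AlignmentRecord]:
    """Align a batch of reads; returns ``{read_id: AlignmentRecord}``.

    Candidates with at most one mismatch are scored without gaps (provably
    optimal under the scoring scheme); the rest go through the banded DP in
    one vectorized batch.  Winners whose optimal alignment is gapped get a
    traceback pass for position and CIGAR.
    """
    p = params or AlignParams()
    k = index.k
    certain_m = p.ungapped_certain_mismatches
    results: dict[str, AlignmentRecord] = {}
    # per read: list of [rid, strand, start, score or None, dp_job]
    pending: list[tuple[SimulatedRead, list]] = []
    dp_reads: list[np.ndarray] = []
    dp_wins: list[np.ndarray] = []
    for read in reads:
        L = len(read.sequence)
        if L < k:
            results[read.read_id] = unmapped_record(read.read_id, "read shorter than k")
            continue
        W = L + 2 * p.band
        cands: dict[tuple[int, str, int], list] = {}
        for strand, arr in (("+", read.seq_u8()), ("-", read.rc_u8())):
            data = arr.tobytes()
            for off in seed_offsets(L, k):
                for rid, pos in index.lookup(data[off : off + k]):
                    start = pos - off
                    key = (rid, strand, start)
                    if key not in cands:
                        cands[key] = [rid, strand, start, None, -1]
        if not cands:
            results[read.read_id] = unmapped_record(read.read_id, "no seed hits")
            continue
        cand_list = list(cands.values())
        for cand in cand_list:
            rid, strand, start = cand[0], cand[1], cand[2]
            ref = index.refs[rid][1]
            oriented = read.seq_u8() if strand == "+" else read.rc_u8()
            if 0 <= start and start + L <= len(ref):
                mism = int(np.count_nonzero(ref[start : start + L] != oriented))
                score = (L - mism) * p.match + mism * p.mismatch
                if mism <= certain_m:
                    cand[3] = score
                    continue
                cand[3] = score  # provisional; DP may improve it
            cand[4] = len(dp_reads)
            dp_reads.append(oriented)
            dp_wins.append(_extract_window(ref, start - p.band, W))
        pending.append((read, cand_list))
    if dp_reads:
        dp_scores = _banded_scores_batch(
            np.vstack(dp_reads), np.vstack(dp_wins), p
        )
    else:
        dp_scores = np.empty(0)
    for read, cand_list in pending:
        L = len(read.sequence)
        for cand in cand_list:
            if cand[4] >= 0:
                dp = int(round(float(dp_scores[cand[4]])))
                cand[3] = dp if cand[3] is None else max(cand[3], dp)
        cand_list.sort(key=lambda c: -c[3])
        best = cand_list[0]
        best_score = best[3]
        second = float("-inf")
        tie = False
        for cand in cand_list[1:]:
            same_locus = (
                cand[0] == best[0]
                and cand[1] == best[1]
                and abs(cand[2] - best[2]) <= 2 * p.band
            )
            if same_locus:
                continue
            # list is sorted by score, so the first distinct locus is second-best
            second = float(cand[3])
            tie = cand[3] >= best_score
            break
        rid, strand, start = best[0], best[1], best[2]
        ref = index.refs[rid][1]
        if tie:
            rec = unmapped_record(read.read_id, "multiple best loci")
            rec.score = best_score
            rec.second_score = float(best_score)
            results[read.read_id] = rec
            continue
        # position and cigar for the winner
        pos, cigar = start, f"{L}M"
        ungapped = None
        if 0 <= start and start + L <= len(ref):
            mism = int(np.count_nonzero(
                ref[start : start + L] != (read.seq_u8() if strand == "+" else read.rc_u8())
            ))
            ungapped = (L - mism) * p.match + mism * p.mismatch
        if ungapped is None or best_score > ungapped:
            oriented = read.seq_u8() if strand == "+" else read.rc_u8()
            win = _extract_window(ref, start - p.band, L + 2 * p.band)
            score_tb, start_col, cigar = _banded_traceback(oriented, win, p)
            pos = start - p.band + start_col
        gap = best_score - second if second > float("-inf") else float("inf")
        mapq = p.mapq_cap if gap == float("inf") else int(min(p.mapq_cap, 2 * gap))
        results[read.read_id] = AlignmentRecord(
            read.read_id,
            index.ref_name(rid),
            int(pos),
            strand,
            int(best_score),
            mapq,
            cigar,
            mapped=True,
            unique=True,
            second_score=second,
        )
    return results


def align_read(
    read: SimulatedRead, index: SeedIndex, params: AlignParams | None = None
) -> AlignmentRecord:
    """Align a single read (see :func:`align_reads`)."""
    return align_reads([read], index, params)[read.read_id]


def is_successful(rec: AlignmentRecord, read_length: int, params: AlignParams) -> bool:
    """The "successfully aligned" criterion: mapped, unique, score floor."""
    return rec.mapped and rec.unique and rec.score >= params.min_score(read_length)


# ---------------------------------------------------------------------------
# SAM emission and ingestion
# ---------------------------------------------------------------------------

def emit_sam(
    records: list[AlignmentRecord],
    ref_lengths: dict[str, int],
    path,
    reads: dict[str, SimulatedRead] | None = None,
) -> None:
    """Write primary alignment records as SAM (minimal @HD/@SQ header)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    ref_ids = {name: i for i, name in enumerate(ref_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            if rec.mapped:
                seg.flag = 16 if rec.strand == "-" else 0
                seg.reference_id = ref_ids[rec.ref_name]
                seg.reference_start = rec.pos
                seg.mapping_quality = rec.mapq
                seg.cigarstring = rec.cigar
                seg.set_tag("AS", rec.score)
            else:
                seg.flag = 4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if reads is not None and rec.read_id in reads:
                read = reads[rec.read_id]
                seg.query_sequence = read.sequence
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(q) + 33) for q in read.qualities)
                )
            out.write(seg)


def ingest_sam(path, known_refs: dict[str, int] | None = None) -> list[AlignmentRecord]:
    """Read primary alignments from a SAM file into AlignmentRecords.

    1-based SAM coordinates become 0-based internally (pysam already
    exposes 0-based ``reference_start``).  MAPQ 0 is interpreted as
    non-unique, matching this package's convention.
    """
    records: list[AlignmentRecord] = []
    n = 0
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            if known_refs is not None:
                for name in sam.references:
                    if name not in known_refs:
                        raise ValueError(f"SAM reference {name!r} not in registry")
            for seg in sam:
                n += 1
                if seg.is_secondary or seg.is_supplementary:
                    continue
                if seg.is_unmapped:
                    records.append(unmapped_record(seg.query_name))
                    continue
                score = seg.get_tag("AS") if seg.has_tag("AS") else 0
                mapq = seg.mapping_quality
                records.append(
                    AlignmentRecord(
                        seg.query_name,
                        seg.reference_name,
                        seg.reference_start,
                        "-" if seg.is_reverse else "+",
                        int(score),
                        mapq,
                        seg.cigarstring or "*",
                        mapped=True,
                        unique=mapq > 0,
                    )
                )
    except ValueError:
        raise
    except Exception as exc:  # pysam parse failures
        raise ValueError(f"malformed SAM record near line {n + 1}: {exc}") from exc
    return records
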