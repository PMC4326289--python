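"""The three read-handling strategies for contaminated xenograft data.

* **direct** -- map every read to the human reference only; contaminating
  mouse reads that cross-align become false positives downstream.
* **filtering** -- align to the mouse reference first, discard reads that
  align successfully, then map the remainder to the human reference;
  minimizes mouse leakage at the cost of losing human reads that resemble
  mouse sequence.
* **combined** -- align once against a union index of both genomes and
  assign each read to the genome holding its unique best-scoring locus;
  reads tied across (or within) genomes stay unaligned.

Also provides the alignment-count contamination estimator
(mouse-aligned / total-aligned).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .align import (
    AlignParams,
    AlignmentRecord,
    SeedIndex,
    align_reads,
    is_successful,
    unmapped_record,
)
from .readsim import SimulatedRead


@dataclass
class StrategyResult:
    """Per-read assignments of one strategy.

    The three sets partition the input reads: each read is human-aligned,
    mouse-aligned (for filtering: discarded), or unaligned.
    """

    strategy: str
    human_alignments: list[AlignmentRecord]
    mouse_alignments: list[AlignmentRecord]
    unaligned_ids: set[str]
    n_reads: int

    def check_partition(self) -> bool:
        ids = {r.read_id for r in self.human_alignments}
        ids |= {r.read_id for r in self.mouse_alignments}
        overlap = (
            {r.read_id for r in self.human_alignments}
            & {r.read_id for r in self.mouse_alignments}
        ) | (ids & self.unaligned_ids)
        total = len(self.human_alignments) + len(self.mouse_alignments) + len(self.unaligned_ids)
        return not overlap and total == self.n_reads

    @property
    def human_ids(self) -> set[str]:
        return {r.read_id for r in self.human_alignments}


def _split_by_success(
    reads: list[SimulatedRead],
    records: dict[str, AlignmentRecord],
    params: AlignParams,
) -> tuple[list[AlignmentRecord], set[str]]:
    good, bad = [], set()
    for read in reads:
        rec = records[read.read_id]
        if is_successful(rec, len(read.sequence), params):
            good.append(rec)
        else:
            bad.add(read.read_id)
    return good, bad


def run_direct(
    reads: list[SimulatedRead],
    human_index: SeedIndex,
    params: AlignParams | None = None,
) -> StrategyResult:
    """Map all reads directly to the human reference only."""
    params = params or AlignParams()
    records = align_reads(reads, human_index, params)
    good, bad = _split_by_success(reads, records, params)
    return StrategyResult("direct", good, [], bad, len(reads))


def run_filtering(
    reads: list[SimulatedRead],
    mouse_index: SeedIndex,
    human_index: SeedIndex,
    params: AlignParams | None = None,
    filter_min_score: int | None = None,
) -> StrategyResult:
    """Discard reads that align successfully to mouse, then map the rest.

    ``filter_min_score`` optionally tightens the discard rule beyond the
    aligner's own "successfully aligned" criterion.
    """
    params = params or AlignParams()
    mouse_records = align_reads(reads, mouse_index, params)
    kept: list[SimulatedRead] = []
    discarded: list[AlignmentRecord] = []
    for read in reads:
        rec = mouse_records[read.read_id]
        success = is_successful(rec, len(read.sequence), params)
        if success and (filter_min_score is None or rec.score >= filter_min_score):
            discarded.append(rec)
        else:
            kept.append(read)
    human_records = align_reads(kept, human_index, params)
    good, bad = _split_by_success(kept, human_records, params)
    return StrategyResult("filtering", good, discarded, bad, len(reads))


def run_combined(
    reads: list[SimulatedRead],
    combined_index: SeedIndex,
    params: AlignParams | None = None,
    host_name: str = "human",
) -> StrategyResult:
    """Align once against the union of both genomes; unique best wins."""
    params = params or AlignParams()
    records = align_reads(reads, combined_index, params)
    human, mouse, unaligned = [], [], set()
    for read in reads:
        rec = records[read.read_id]
        if is_successful(rec, len(read.sequence), params):
            (human if rec.genome == host_name else mouse).append(rec)
        else:
            unaligned.add(read.read_id)
    return StrategyResult("combined", human, mouse, unaligned, len(reads))


# ---------------------------------------------------------------------------
# Shared-alignment derivation (exact, used by the experiment runner)
# ---------------------------------------------------------------------------

def _score_pair(rec: AlignmentRecord) -> tuple[float, float]:
    """(best, second-best) scores implied by one per-genome record."""
    if rec.mapped:
        return float(rec.score), rec.second_score
    if rec.reason == "multiple best loci":
        return float(rec.score), float(rec.score)
    return float("-inf"), float("-inf")


def combine_records(
    rec_h: AlignmentRecord, rec_m: AlignmentRecord, params: AlignParams | None = None
) -> AlignmentRecord:
    """Union-index outcome derived from two single-genome alignments.

    Equivalent to aligning against one index holding both genomes: the
    overall best locus wins; the second-best score is the runner-up across
    both genomes; any tie leaves the read unmapped.
    """
    p = params or AlignParams()
    bh, sh = _score_pair(rec_h)
    bm, sm = _score_pair(rec_m)
    if bh == float("-inf") and bm == float("-inf"):
        return unmapped_record(rec_h.read_id, "no seed hits")
    if bh == bm:
        rec = unmapped_record(rec_h.read_id, "multiple best loci")
        rec.score = int(bh)
        rec.second_score = bh
        return rec
    winner, loser_best = (rec_h, bm) if bh > bm else (rec_m, bh)
    best, second_own = _score_pair(winner)
    second = max(second_own, loser_best)
    if second >= best:
        rec = unmapped_record(winner.read_id, "multiple best loci")
        rec.score = int(best)
        rec.second_score = second
        return rec
    gap = best - second if second > float("-inf") else float("inf")
    mapq = p.mapq_cap if gap == float("inf") else int(min(p.mapq_cap, 2 * gap))
    return AlignmentRecord(
        winner.read_id,
        winner.ref_name,
        winner.pos,
        winner.strand,
        winner.score,
        mapq,
        winner.cigar,
        mapped=True,
        unique=True,
        second_score=second,
    )


def run_all(
    reads: list[SimulatedRead],
    human_index: SeedIndex,
    mouse_index: SeedIndex,
    params: AlignParams | None = None,
    filter_min_score: int | None = None,
) -> dict:
    """Run all three strategies from one alignment pass per genome.

    Returns ``{"direct": ..., "filtering": ..., "combined": ...,
    "human_records": ..., "mouse_records": ...}``; the raw per-genome
    record maps support the align-everything-to-mouse contamination
    bookkeeping.  Results are identical to calling the individual
    ``run_*`` functions (verified in the test suite).
    """
    params = params or AlignParams()
    h_recs = align_reads(reads, human_index, params)
    m_recs = align_reads(reads, mouse_index, params)
    direct_good, direct_bad = _split_by_success(reads, h_recs, params)
    direct = StrategyResult("direct", direct_good, [], direct_bad, len(reads))

    filt_human, filt_mouse, filt_un = [], [], set()
    comb_human, comb_mouse, comb_un = [], [], set()
    host = human_index.genome_names[0]
    for read in reads:
        rh, rm = h_recs[read.read_id], m_recs[read.read_id]
        L = len(read.sequence)
        m_success = is_successful(rm, L, params)
        if m_success and (filter_min_score is None or rm.score >= filter_min_score):
            filt_mouse.append(rm)
        elif is_successful(rh, L, params):
            filt_human.append(rh)
        else:
            filt_un.add(read.read_id)
        merged = combine_records(rh, rm, params)
        if is_successful(merged, L, params):
            (comb_human if merged.genome == host else comb_mouse).append(merged)
        else:
            comb_un.add(read.read_id)
    filtering = StrategyResult("filtering", filt_human, filt_mouse, filt_un, len(reads))
    combined = StrategyResult("combined", comb_human, comb_mouse, comb_un, len(reads))
    return {
        "direct": direct,
        "filtering": filtering,
        "combined": combined,
        "human_records": h_recs,
        "mouse_records": m_recs,
    }


def estimate_contamination(n_mouse_aligned: int, n_human_aligned: int) -> float:
    """Mouse contamination fraction from alignment counts.

    ``n_mouse / (n_mouse + n_human)``; returns NaN when both counts are
    zero (undefined).
    """
    if n_mouse_aligned < 0 or n_human_aligned < 0:
        raise ValueError("alignment counts must be >= 0")
    total = n_mouse_aligned + n_human_aligned
    if total == 0:
        return math.nan
    return n_mouse_aligned / total
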