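"""Truth-based scoring of alignments and variant calls (FDR/FNR).

Three evaluation levels, each summarized as TP/FP/FN with
FDR = FP/(FP+TP) and FNR = FN/(FN+TP):

* **alignment** -- a human-origin read aligned to the human reference
  within a small positional tolerance of its true start (matching strand)
  is a TP; any read aligned to the human reference elsewhere -- including
  contaminating mouse reads -- is an FP; a human read without a correct
  human alignment is an FN.  A misplaced human read therefore counts once
  as FP and once as FN (it is both incorrectly aligned and not correctly
  aligned).
* **variant** -- called SNVs matched to planted SNVs on
  (chrom, pos, alt allele); planted indels are excluded from SNV scoring.
* **nonsynonymous** -- the variant-level comparison restricted to SNVs
  that change an encoded amino acid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .genomes import GeneModel, Genome
from .readsim import VariantTruth, parse_read_id
from .strategies import StrategyResult
from .variants import VariantCall

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    level: str = "alignment"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


def fdr(c: ConfusionCounts) -> float:
    """False discovery rate FP/(FP+TP); NaN when nothing was reported."""
    denom = c.fp + c.tp
    return math.nan if denom == 0 else c.fp / denom


def fnr(c: ConfusionCounts) -> float:
    """False negative rate FN/(FN+TP); NaN when there is no truth."""
    denom = c.fn + c.tp
    return math.nan if denom == 0 else c.fn / denom


def score_alignments(
    result: StrategyResult,
    pos_tolerance: int = 5,
    host_name: str = "human",
) -> ConfusionCounts:
    """Score a strategy's human-reference alignments against read truth.

    Truth is decoded from read names (reference-coordinate starts); the
    positional tolerance absorbs small leftmost-coordinate shifts caused
    by indels.
    """
    tp = fp = 0
    n_host = 0
    for rec in result.human_alignments:
        truth = parse_read_id(rec.read_id)
        if truth.genome == host_name:
            n_host += 1
        if (
            truth.genome == host_name
            and rec.genome == host_name
            and rec.chrom == truth.chrom
            and rec.strand == truth.strand
            and abs(rec.pos - truth.start) <= pos_tolerance
        ):
            tp += 1
        else:
            fp += 1
    for rec in result.mouse_alignments:
        if parse_read_id(rec.read_id).genome == host_name:
            n_host += 1
    for rid in result.unaligned_ids:
        if parse_read_id(rid).genome == host_name:
            n_host += 1
    fn = n_host - tp
    return ConfusionCounts(tp, fp, fn, "alignment")


def _in_regions(v: VariantTruth, regions) -> bool:
    if regions is None:
        return True
    return any(
        v.chrom == chrom and start <= v.pos < end for chrom, start, end in regions
    )


def score_variants(
    calls: list[VariantCall],
    truth: list[VariantTruth],
    regions: list[tuple[str, int, int]] | None = None,
) -> ConfusionCounts:
    """Match called SNVs against planted SNVs on (chrom, pos, alt).

    ``regions`` optionally restricts the truth set to the simulated
    regions (exome runs), so FNR reflects variants the reads could reach.
    """
    truth_keys = {
        (v.chrom, v.pos, v.alt_allele)
        for v in truth
        if v.vtype == "SNV" and _in_regions(v, regions)
    }
    call_keys = {(c.chrom, c.pos, c.alt_allele) for c in calls}
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    return ConfusionCounts(tp, fp, fn, "variant")


class EffectClassifier:
    """Classifies SNVs as non-synonymous / synonymous / non-coding.

    Builds a per-base map of CDS positions; codons are rebuilt
    strand-aware from the reference and translated with the standard
    genetic code.
    """

    def __init__(self, genes: list[GeneModel], reference: Genome):
        self.reference = reference
        self._cds_map: dict[tuple[str, int], tuple[int, int]] = {}
        self._gene_positions: list[list[int]] = []
        self._genes = genes
        for gi, gene in enumerate(genes):
            positions = [
                p for start, end in gene.cds_intervals for p in range(start, end)
            ]
            if gene.strand == "-":
                positions = positions[::-1]
            self._gene_positions.append(positions)
            for ci, p in enumerate(positions):
                self._cds_map[(gene.chrom, p)] = (gi, ci)

    def classify(self, chrom: str, pos: int, alt: str) -> str:
        hit = self._cds_map.get((chrom, pos))
        if hit is None:
            return "non_coding"
        gi, ci = hit
        gene = self._genes[gi]
        positions = self._gene_positions[gi]
        codon_start = 3 * (ci // 3)
        codon_pos = positions[codon_start : codon_start + 3]
        if len(codon_pos) < 3:
            raise ValueError(f"CDS position {chrom}:{pos} lies in an incomplete codon")
        seq = self.reference.seq(gene.chrom)
        if gene.strand == "+":
            ref_codon = "".join(seq[p] for p in codon_pos)
            alt_base = alt
        else:
            ref_codon = "".join(seq[p].translate(_COMP) for p in codon_pos)
            alt_base = alt.translate(_COMP)
        offset = ci % 3
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        if CODON_TO_AA[ref_codon] == CODON_TO_AA[alt_codon]:
            return "synonymous"
        return "non_synonymous"


def classify_variant_effect(call, genes: list[GeneModel], reference: Genome) -> str:
    """Effect of a single SNV (accepts any object with chrom/pos/alt_allele)."""
    clf = EffectClassifier(genes, reference)
    return clf.classify(call.chrom, call.pos, call.alt_allele)


def score_nonsynonymous(
    calls: list[VariantCall],
    truth: list[VariantTruth],
    classifier: EffectClassifier,
    regions: list[tuple[str, int, int]] | None = None,
) -> ConfusionCounts:
    """Variant scoring restricted to amino-acid-changing SNVs.

    FP counts called non-synonymous SNVs that were never planted; FN
    counts planted non-synonymous SNVs that were missed.
    """
    truth_keys = {
        (v.chrom, v.pos, v.alt_allele)
        for v in truth
        if v.vtype == "SNV" and _in_regions(v, regions)
    }
    truth_ns = {
        key for key in truth_keys if classifier.classify(key[0], key[1], key[2]) == "non_synonymous"
    }
    call_keys = {(c.chrom, c.pos, c.alt_allele) for c in calls}
    tp = len(call_keys & truth_ns)
    fp = sum(
        1
        for key in call_keys - truth_keys
        if classifier.classify(key[0], key[1], key[2]) == "non_synonymous"
    )
    fn = len(truth_ns - call_keys)
    return ConfusionCounts(tp, fp, fn, "nonsynonymous")


@dataclass
class AccuracyReport:
    """FDR/FNR per (strategy, level), with a no-contamination baseline row."""

    rows: dict[tuple[str, str], ConfusionCounts] = field(default_factory=dict)
    contamination: dict[str, float] = field(default_factory=dict)

    def add(self, strategy: str, counts: ConfusionCounts) -> None:
        self.rows[(strategy, counts.level)] = counts

    def get(self, strategy: str, level: str) -> ConfusionCounts:
        return self.rows[(strategy, level)]

    def fdr(self, strategy: str, level: str) -> float:
        return fdr(self.rows[(strategy, level)])

    def fnr(self, strategy: str, level: str) -> float:
        return fnr(self.rows[(strategy, level)])

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (strategy, level), c in sorted(self.rows.items()):
            records.append(
                {
                    "strategy": strategy,
                    "level": level,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "fdr": fdr(c),
                    "fnr": fnr(c),
                }
            )
        return pd.DataFrame(records)

    def render_text(self) -> str:
        frame = self.to_frame()
        lines = [frame.to_string(index=False, float_format=lambda v: f"{v:.4f}")]
        if self.contamination:
            lines.append("")
            lines.append("estimated contamination:")
            for strategy, frac in self.contamination.items():
                lines.append(f"  {strategy:>10s}: {100 * frac:.2f}%")
        return "\n".join(lines)
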