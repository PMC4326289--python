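"""Study configuration grid and end-to-end runner.

Reproduces the simulation design at desk scale: 8 parameter profiles
(mutation rate x read length x error rate, Table-1 style naming) crossed
with two human:mouse mixing ratios (9:1 and 1:1) and two region modes
(exome-only or whole genome) give 32 dataset configurations.  Each run
forges a surrogate genome pair, mutates samples, simulates and mixes
reads, applies the three handling strategies, calls SNVs, and scores all
three evaluation levels against ground truth, alongside a
no-contamination baseline.

Defaults are sized so a single run completes in about a minute on one
CPU: a 500 kb host genome over 2 chromosomes with ~50 genes (~15% coding)
and a perceived depth of 30x standing in for the original 60x.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AlignParams, build_index, emit_sam
from .evaluate import (
    AccuracyReport,
    EffectClassifier,
    score_alignments,
    score_nonsynonymous,
    score_variants,
)
from .genomes import (
    DivergenceSpec,
    Genome,
    annotate_genes,
    diverge,
    generate_ancestor,
    project_intervals,
    write_bed,
    write_fasta,
    write_gene_table,
)
from .readsim import (
    MutatedGenome,
    SimProfile,
    mix_reads,
    mutate_genome,
    simulate_reads,
    write_fastq,
    write_variant_table,
)
from .strategies import StrategyResult, estimate_contamination, run_all, run_direct
from .variants import call_snvs, filter_calls, pileup, write_vcf

logger = logging.getLogger(__name__)

MUTATION_RATES = {"L": 0.0, "H": 0.01}
ERROR_RATES = {"L": 0.0001, "H": 0.01}
READ_LENGTHS = (50, 100)
RATIOS = ((9, 1), (1, 1))
REGION_MODES = ("exome", "all")

DEPTH_SCHEMES = (
    ("54x:6x", 54.0, 6.0),
    ("30x:30x", 30.0, 30.0),
    ("60x:60x", 60.0, 60.0),
)


def profile_name(mutation_rate: float, read_length: int, error_rate: float) -> str:
    m = "L" if mutation_rate == 0 else "H"
    e = "L" if error_rate <= 0.0001 else "H"
    return f"m{m}.len{read_length:03d}.e{e}"


def enumerate_profiles() -> list[SimProfile]:
    """The 8 setting profiles: mutation {0, 1%} x length {50, 100} x error
    {0.01%, 1%}."""
    profiles = []
    for m, length, e in itertools.product("LH", READ_LENGTHS, "LH"):
        mut, err = MUTATION_RATES[m], ERROR_RATES[e]
        profiles.append(SimProfile(mut, length, err, profile_name(mut, length, err)))
    return profiles


def get_profile(name: str) -> SimProfile:
    for profile in enumerate_profiles():
        if profile.name == name:
            return profile
    raise KeyError(f"unknown profile {name!r}")


@dataclass(frozen=True)
class DepthScheme:
    """Effective host/graft depths, e.g. 54x:6x for 60x data at 9:1."""

    label: str
    host_depth: float
    graft_depth: float

    def __post_init__(self) -> None:
        if self.host_depth < 0 or self.graft_depth < 0:
            raise ValueError("depths must be >= 0")


@dataclass
class StudyConfig:
    """Everything one simulation run needs; fully seeded and reproducible."""

    profile: SimProfile
    region_mode: str = "all"
    ratio: tuple[int, int] = (1, 1)
    total_depth: float = 30.0
    seed: int = 0
    # surrogate genome forge
    genome_length: int = 500_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.41
    n_genes: int = 50
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    snv_fraction: float = 0.9
    # pipeline knobs
    align_params: AlignParams = field(default_factory=AlignParams)
    strategies: tuple[str, ...] = ("direct", "filtering", "combined")
    baseline: bool = True
    baseline_host_share_only: bool = False
    call_variants: bool = True
    filter_min_score: int | None = None
    pos_tolerance: int = 5
    min_qual: float = 13.0
    min_depth: int = 3

    def __post_init__(self) -> None:
        if self.region_mode not in REGION_MODES:
            raise ValueError(f"region_mode must be one of {REGION_MODES}")
        h, g = self.ratio
        if h < 0 or g < 0 or h + g == 0:
            raise ValueError(f"invalid ratio {self.ratio}")


def enumerate_datasets(
    profiles: list[SimProfile] | None = None, **overrides
) -> list[StudyConfig]:
    """The full grid: 8 profiles x 2 ratios x 2 region modes = 32 configs."""
    profiles = profiles if profiles is not None else enumerate_profiles()
    return [
        StudyConfig(profile=p, region_mode=mode, ratio=ratio, **overrides)
        for p in profiles
        for ratio in RATIOS
        for mode in REGION_MODES
    ]


def _subseed(master: int, label: str) -> int:
    tag = zlib.crc32(label.encode("ascii"))
    digest = np.random.SeedSequence([master, tag]).generate_state(1)[0]
    return int(digest) & 0x7FFFFFFF


@dataclass
class StudyReport:
    """Run outcome: accuracy rows per strategy/level plus bookkeeping."""

    config: StudyConfig
    accuracy: AccuracyReport
    n_reads: int
    n_truth_snvs: int
    counts: dict[str, dict[str, int]]
    timings: dict[str, float] = field(default_factory=dict)

    def render_text(self) -> str:
        header = (
            f"profile={self.config.profile.name} regions={self.config.region_mode} "
            f"ratio={self.config.ratio[0]}:{self.config.ratio[1]} "
            f"depth={self.config.total_depth}x reads={self.n_reads}"
        )
        return header + "\n" + self.accuracy.render_text()


def forge_genomes(config: StudyConfig):
    """Forge the surrogate genome pair + annotations for one config."""
    seed = config.seed
    host = generate_ancestor(
        config.genome_length,
        config.n_chromosomes,
        config.gc_fraction,
        seed=_subseed(seed, "ancestor"),
        name="human",
    )
    genes, exome = annotate_genes(host, config.n_genes, seed=_subseed(seed, "genes"))
    dspec = dataclasses.replace(config.divergence, seed=_subseed(seed, "diverge"))
    graft, graft_map = diverge(host, genes, dspec, name="mouse", return_map=True)
    return host, graft, genes, exome, graft_map


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute one full simulation run and score it.

    Stages: forge genomes -> mutate samples -> simulate + mix reads ->
    run strategies (one alignment pass per genome, exact strategy
    derivation) -> pileup + SNV calling -> three-level scoring.  Artifacts
    (FASTA/BED/FASTQ/SAM/VCF/TSV) are written when ``out_dir`` is given.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    seed = config.seed
    profile = config.profile
    L = profile.read_length

    host, graft, genes, exome, graft_map = forge_genomes(config)
    timings["forge"] = time.perf_counter() - t0

    t = time.perf_counter()
    human_sample = mutate_genome(
        host, profile.mutation_rate, config.snv_fraction, seed=_subseed(seed, "mut_h")
    )
    mouse_sample = mutate_genome(
        graft, profile.mutation_rate, config.snv_fraction, seed=_subseed(seed, "mut_m")
    )
    truth_snvs = [v for v in human_sample.variants if v.vtype == "SNV"]
    timings["mutate"] = time.perf_counter() - t

    # regions: reference coords for truth, sample coords for read simulation
    if config.region_mode == "exome":
        truth_regions = exome
        regions_h = project_intervals(exome, human_sample.ref_pos)
        graft_exome = project_intervals(exome, graft_map)
        regions_m = project_intervals(graft_exome, mouse_sample.ref_pos)
        region_len = sum(end - start for _, start, end in exome)
    else:
        truth_regions = None
        regions_h = "whole"
        regions_m = "whole"
        region_len = host.total_length

    t = time.perf_counter()
    h, g = config.ratio
    total_reads = round(config.total_depth * region_len / L)
    host_pool = simulate_reads(
        human_sample.genome,
        regions_h,
        L,
        profile.error_rate,
        depth=config.total_depth * 1.1,
        seed=_subseed(seed, "reads_h"),
        ref_pos=human_sample.ref_pos,
    )
    graft_share = g / (h + g)
    mouse_pool = (
        simulate_reads(
            mouse_sample.genome,
            regions_m,
            L,
            profile.error_rate,
            depth=config.total_depth * max(0.05, graft_share) * 1.2,
            seed=_subseed(seed, "reads_m"),
            ref_pos=mouse_sample.ref_pos,
        )
        if g > 0
        else []
    )
    mixed = mix_reads(host_pool, mouse_pool, (h, g), total_reads, seed=_subseed(seed, "mix"))
    timings["simulate"] = time.perf_counter() - t

    t = time.perf_counter()
    params = config.align_params
    human_index = build_index(host, params.k)
    mouse_index = build_index(graft, params.k)
    timings["index"] = time.perf_counter() - t

    t = time.perf_counter()
    outcome = run_all(mixed, human_index, mouse_index, params, config.filter_min_score)
    results: dict[str, StrategyResult] = {
        name: outcome[name] for name in config.strategies
    }
    if config.baseline:
        if config.baseline_host_share_only:
            n_base = round(total_reads * h / (h + g))
        else:
            n_base = total_reads
        baseline_reads = mix_reads(
            host_pool, [], (1, 0), n_base, seed=_subseed(seed, "baseline")
        )
        results["no_contamination"] = dataclasses.replace(
            run_direct(baseline_reads, human_index, params),
            strategy="no_contamination",
        )
    timings["align"] = time.perf_counter() - t

    reads_by_id = {r.read_id: r for r in mixed}
    if config.baseline:
        reads_by_id.update({r.read_id: r for r in baseline_reads})

    t = time.perf_counter()
    accuracy = AccuracyReport()
    classifier = (
        EffectClassifier(genes, host) if config.call_variants else None
    )
    calls_by_strategy: dict[str, list] = {}
    for name, result in results.items():
        accuracy.add(name, dataclasses.replace(
            score_alignments(result, config.pos_tolerance), level="alignment"
        ))
        if config.call_variants:
            columns = pileup(result.human_alignments, reads_by_id, host)
            calls = filter_calls(
                call_snvs(columns, config.min_depth), config.min_qual
            )
            calls_by_strategy[name] = calls
            accuracy.add(name, score_variants(calls, truth_snvs, truth_regions))
            accuracy.add(
                name, score_nonsynonymous(calls, truth_snvs, classifier, truth_regions)
            )
    timings["score"] = time.perf_counter() - t

    counts = {}
    n_mouse_ref_aligned = sum(
        1
        for read in mixed
        if outcome["mouse_records"][read.read_id].mapped
        and outcome["mouse_records"][read.read_id].unique
        and outcome["mouse_records"][read.read_id].score >= params.min_score(L)
    )
    for name, result in results.items():
        counts[name] = {
            "human_aligned": len(result.human_alignments),
            "mouse_aligned": len(result.mouse_alignments),
            "unaligned": len(result.unaligned_ids),
        }
        if name == "direct":
            # footnote convention: compare against aligning everything to mouse
            accuracy.contamination[name] = estimate_contamination(
                n_mouse_ref_aligned, len(result.human_alignments)
            )
        elif name in ("filtering", "combined"):
            accuracy.contamination[name] = estimate_contamination(
                len(result.mouse_alignments), len(result.human_alignments)
            )

    report = StudyReport(
        config=config,
        accuracy=accuracy,
        n_reads=len(mixed),
        n_truth_snvs=len(
            [v for v in truth_snvs if truth_regions is None or _in(v, truth_regions)]
        ),
        counts=counts,
        timings=timings,
    )
    if out_dir is not None:
        _write_artifacts(
            Path(out_dir), config, host, graft, genes, exome,
            human_sample, mixed, results, calls_by_strategy, report,
        )
    logger.info("run_study done in %.1fs: %s", time.perf_counter() - t0, timings)
    return report


def _in(v, regions) -> bool:
    return any(
        v.chrom == chrom and start <= v.pos < end for chrom, start, end in regions
    )


def run_depth_schemes(
    base: StudyConfig,
    schemes: tuple = DEPTH_SCHEMES,
    scale: float = 1.0,
) -> dict[str, StudyReport]:
    """Run the depth-variation experiment (54x:6x, 30x:30x, 60x:60x).

    ``scale`` shrinks every scheme's depth proportionally for desk-scale
    runs; labels are kept.
    """
    reports = {}
    for label, host_depth, graft_depth in schemes:
        scheme = DepthScheme(label, host_depth * scale, graft_depth * scale)
        config = dataclasses.replace(
            base,
            total_depth=scheme.host_depth + scheme.graft_depth,
            ratio=(round(host_depth), round(graft_depth)),
        )
        reports[label] = run_study(config)
    return reports


def _write_artifacts(
    out: Path,
    config: StudyConfig,
    host: Genome,
    graft: Genome,
    genes,
    exome,
    human_sample: MutatedGenome,
    mixed,
    results: dict[str, StrategyResult],
    calls_by_strategy,
    report: StudyReport,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(host, out / "human.fasta")
    write_fasta(graft, out / "mouse.fasta")
    write_bed(exome, out / "exome.bed")
    write_gene_table(genes, out / "genes.tsv")
    write_fastq(mixed, out / "reads.fastq")
    write_variant_table(human_sample.variants, out / "truth_variants.tsv")
    reads_by_id = {r.read_id: r for r in mixed}
    for name, result in results.items():
        ref_lengths = {
            f"{g.name}:{chrom}": g.length(chrom)
            for g in (host, graft)
            for chrom in g.chroms
        }
        emit_sam(
            result.human_alignments + result.mouse_alignments,
            ref_lengths,
            out / f"{name}.sam",
            reads=reads_by_id,
        )
        with open(out / f"{name}.unaligned.txt", "w") as fh:
            for rid in sorted(result.unaligned_ids):
                fh.write(rid + "\n")
        if name in calls_by_strategy:
            write_vcf(calls_by_strategy[name], host, out / f"{name}.vcf")
    report.accuracy.to_frame().to_csv(out / "accuracy.tsv", sep="\t", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(report.render_text() + "\n")
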