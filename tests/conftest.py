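"""Shared fixtures: small forged genome pairs and the (expensive)
qualitative-ordering study runs, computed once per session."""

from __future__ import annotations

import dataclasses

import pytest

import xenomix as xm
from xenomix.experiment import StudyConfig, get_profile, run_study


@pytest.fixture(scope="session")
def small_pair():
    """A 60 kb host genome with genes plus its diverged graft relative."""
    host = xm.generate_ancestor(60_000, 2, 0.41, seed=11, name="human")
    genes, exome = xm.annotate_genes(host, 8, seed=12)
    spec = xm.DivergenceSpec(seed=13)
    graft, graft_map = xm.diverge(host, genes, spec, name="mouse", return_map=True)
    return {
        "host": host,
        "graft": graft,
        "genes": genes,
        "exome": exome,
        "graft_map": graft_map,
        "divergence": spec,
    }


@pytest.fixture(scope="session")
def mixed_run(small_pair):
    """A mixed 1:1 read set with all three strategies run on it."""
    profile = get_profile("mH.len100.eL")
    host, graft = small_pair["host"], small_pair["graft"]
    hs = xm.mutate_genome(host, profile.mutation_rate, seed=21)
    ms = xm.mutate_genome(graft, profile.mutation_rate, seed=22)
    host_reads = xm.simulate_reads(
        hs.genome, "whole", 100, profile.error_rate, 4.0, seed=23, ref_pos=hs.ref_pos
    )
    graft_reads = xm.simulate_reads(
        ms.genome, "whole", 100, profile.error_rate, 4.0, seed=24, ref_pos=ms.ref_pos
    )
    reads = xm.mix_reads(host_reads, graft_reads, (1, 1), 4000, seed=25)
    params = xm.AlignParams()
    human_index = xm.build_index(host, params.k)
    mouse_index = xm.build_index(graft, params.k)
    outcome = xm.run_all(reads, human_index, mouse_index, params)
    return {
        "reads": reads,
        "params": params,
        "human_index": human_index,
        "mouse_index": mouse_index,
        "outcome": outcome,
        "truth_snvs": [v for v in hs.variants if v.vtype == "SNV"],
        "human_sample": hs,
    }


@pytest.fixture(scope="session")
def qualitative_reports():
    """Default-surrogate study runs backing the qualitative-findings suite.

    Per seed: a whole-genome 1:1 run, an exome-only 1:1 run (higher depth;
    the exome is small so this stays cheap and stabilizes variant calling),
    and a whole-genome 9:1 run for the contamination-sensitivity contrast.
    """
    base = StudyConfig(
        profile=get_profile("mH.len100.eL"), baseline=False
    )
    reports = {}
    for seed in (1, 2, 3):
        reports[(seed, "whole_1to1")] = run_study(
            dataclasses.replace(base, region_mode="all", ratio=(1, 1),
                                total_depth=24.0, seed=seed)
        )
        reports[(seed, "exome_1to1")] = run_study(
            dataclasses.replace(base, region_mode="exome", ratio=(1, 1),
                                total_depth=40.0, seed=seed)
        )
        reports[(seed, "whole_9to1")] = run_study(
            dataclasses.replace(base, region_mode="all", ratio=(9, 1),
                                total_depth=24.0, seed=seed)
        )
    return reports
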