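"""End-to-end drivers: dataset -> candidates -> genotypes -> filtered calls.

Also hosts the two simulated-experiment drivers used for validation: the
clonal-detection experiment (sSNV loci mixed with EAL artifact loci) and
the genotype-accuracy experiment (sSNV loci only, p_EAL = 0).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pysam

from clonecall.discovery import CandidateSite, VoteParams, discover_candidates
from clonecall.evaluation import (
    ClonalConfusion,
    GenotypeConfusion,
    classify_clonal_calls,
    genotype_confusion,
)
from clonecall.formats import GsnvRecord, SiteTable, load_gsnvs
from clonecall.genotyper import GenotypeParams, apply_site_filters, genotype_candidates
from clonecall.gsnv_filter import max_depth_threshold
from clonecall.simulator import SimParams, SimulationResult, simulate_experiment

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    candidates: list[CandidateSite]
    genotyped: SiteTable  # every candidate with per-sample genotypes
    calls: SiteTable  # after site-level filters
    bulk_mean_depth: float
    bulk_depth_cap: int


def estimate_bulk_depth(bulk_bam: str, gsnvs: Sequence[GsnvRecord]) -> float:
    """Mean bulk depth over (a subsample of) the gSNV anchor positions."""
    if not gsnvs:
        return 0.0
    picks = gsnvs[:: max(1, len(gsnvs) // 200)]
    depths = []
    with pysam.AlignmentFile(bulk_bam) as bulk:
        for g in picks:
            cov = bulk.count_coverage(g.contig, g.pos - 1, g.pos)
            depths.append(sum(col[0] for col in cov))
    return float(np.mean(depths))


def run_pipeline(
    cell_bams: Mapping[str, str],
    bulk_bam: str,
    gsnv_vcf: str,
    reference: str,
    vote_params: VoteParams | None = None,
    genotype_params: GenotypeParams | None = None,
    bulk_mean_depth: float | None = None,
) -> PipelineResult:
    """Discover, genotype and filter candidate sSNV sites for one dataset.

    The bulk depth cap applied at final filtering is derived from the mean
    bulk depth (measured at the gSNV anchors unless supplied).
    """
    vote_params = vote_params or VoteParams()
    genotype_params = genotype_params or GenotypeParams()
    gsnvs = load_gsnvs(gsnv_vcf)
    candidates = discover_candidates(cell_bams, bulk_bam, gsnvs, reference, vote_params)
    genotyped = genotype_candidates(candidates, cell_bams, genotype_params, bulk_bam=bulk_bam)
    if bulk_mean_depth is None:
        bulk_mean_depth = estimate_bulk_depth(bulk_bam, gsnvs)
    cap = max_depth_threshold(bulk_mean_depth)
    calls = apply_site_filters(genotyped, genotype_params, bulk_depth_cap=cap)
    return PipelineResult(
        candidates=candidates,
        genotyped=genotyped,
        calls=calls,
        bulk_mean_depth=bulk_mean_depth,
        bulk_depth_cap=cap,
    )


def run_on_simulation(
    sim: SimulationResult,
    vote_params: VoteParams | None = None,
    genotype_params: GenotypeParams | None = None,
) -> PipelineResult:
    return run_pipeline(
        sim.cell_bams, sim.bulk_bam, sim.gsnv_vcf, sim.reference, vote_params, genotype_params
    )


def simulate_and_call(
    params: SimParams,
    out_dir: str | None = None,
    vote_params: VoteParams | None = None,
    genotype_params: GenotypeParams | None = None,
) -> tuple[SimulationResult, PipelineResult]:
    """Simulate a dataset (in ``out_dir`` or a temp dir) and call it."""
    if out_dir is not None:
        sim = simulate_experiment(params, out_dir)
        return sim, run_on_simulation(sim, vote_params, genotype_params)
    with tempfile.TemporaryDirectory(prefix="clonecall-sim-") as tmp:
        sim = simulate_experiment(params, tmp)
        return sim, run_on_simulation(sim, vote_params, genotype_params)


def clonal_detection_experiment(
    p_eal: float,
    p_do: float,
    n_loci: int = 306,
    seed: int = 0,
    genotype_params: GenotypeParams | None = None,
) -> ClonalConfusion:
    """Experiment 1: detection of clonal sSNVs among EAL artifact loci."""
    params = SimParams(n_loci=n_loci, p_eal=p_eal, p_do=p_do, seed=seed)
    sim, result = simulate_and_call(params, genotype_params=genotype_params)
    return classify_clonal_calls(result.calls, sim.truth)


def genotype_accuracy_experiment(
    p_do: float,
    n_loci: int = 306,
    seed: int = 0,
    genotype_params: GenotypeParams | None = None,
) -> tuple[GenotypeConfusion, SimulationResult, PipelineResult]:
    """Experiment 2: genotype prediction per cell at sSNV-only loci."""
    params = SimParams(n_loci=n_loci, p_eal=0.0, p_do=p_do, seed=seed)
    sim, result = simulate_and_call(params)
    return genotype_confusion(result.genotyped, sim.truth), sim, result
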