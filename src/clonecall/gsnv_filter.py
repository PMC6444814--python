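"""Reduce a bulk variant-call VCF to high-confidence heterozygous gSNVs.

False gSNVs propagate directly into false phased calls downstream, so the
bulk VCF is filtered stringently: depth inside a conservative band, QUAL,
strand and read-placement balance, and an allele-fraction window consistent
with a germline heterozygote.  A separate screen removes gSNVs sitting in
regions whose pileup looks locally "too heterozygous" (a mappability
signature), and :func:`phasable_fraction` reports how much of the genome the
retained anchors can reach.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pysam

from clonecall.formats import BASES, GsnvRecord

log = logging.getLogger(__name__)

#: Human autosome names in both common styles; used as the default whitelist.
AUTOSOMES = frozenset(str(i) for i in range(1, 23)) | frozenset(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class BulkFilterThresholds:
    min_depth: int = 15
    max_depth: int = 55
    min_qual: float = 10.0
    min_reads_each_strand: int = 1
    min_reads_each_placement: int = 2
    min_alt_fraction: float = 0.20
    max_alt_fraction: float = 0.80

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth exceeds max_depth")
        if not (0 <= self.min_alt_fraction <= self.max_alt_fraction <= 1):
            raise ValueError("alt fraction bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class RegionScreenParams:
    window: int = 1000
    max_het_positions: int = 10
    het_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.het_fraction < 1:
            raise ValueError("het_fraction must be in (0, 1)")


def max_depth_threshold(mean_depth: float) -> int:
    """Conservative depth cap ``floor(d + 2.5*sqrt(d))`` for mean depth d.

    At a typical 40x bulk this yields 55; positions deeper than the cap are
    enriched for collapsed repeats and are not trusted.
    """
    if mean_depth < 0:
        raise ValueError("mean depth must be non-negative")
    return math.floor(mean_depth + 2.5 * math.sqrt(mean_depth))


def _info_scalar(rec, key: str) -> float | None:
    if key not in rec.info:
        return None
    v = rec.info[key]
    if isinstance(v, (tuple, list)):
        v = v[0]
    return float(v)


def filter_bulk_variants(
    vcf_path: str,
    thresholds: BulkFilterThresholds | None = None,
    whitelist: frozenset[str] | set[str] = AUTOSOMES,
) -> list[GsnvRecord]:
    """Filter a FreeBayes-style bulk VCF down to usable gSNV anchors.

    Requires INFO fields DP, AO, SAF/SAR (alt reads per strand) and RPR/RPL
    (reads placing the variant right/left); records missing any annotation
    are skipped with a warning.
    """
    t = thresholds or BulkFilterThresholds()
    out: list[GsnvRecord] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if rec.chrom not in whitelist:
                continue
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                continue
            if rec.ref not in BASES or alts[0] not in BASES:
                continue
            vals = {k: _info_scalar(rec, k) for k in ("DP", "AO", "SAF", "SAR", "RPR", "RPL")}
            if any(v is None for v in vals.values()) or rec.qual is None:
                log.warning("record %s:%d missing annotations; skipped", rec.chrom, rec.pos)
                continue
            dp = vals["DP"]
            if not (t.min_depth <= dp <= t.max_depth):
                continue
            if not rec.qual > t.min_qual:
                continue
            if vals["SAF"] < t.min_reads_each_strand or vals["SAR"] < t.min_reads_each_strand:
                continue
            if vals["RPR"] < t.min_reads_each_placement or vals["RPL"] < t.min_reads_each_placement:
                continue
            if dp == 0 or not (t.min_alt_fraction <= vals["AO"] / dp <= t.max_alt_fraction):
                continue
            out.append(GsnvRecord(rec.chrom, rec.pos, rec.ref, alts[0]))
    return out


def heterozygous_positions(
    bulk: pysam.AlignmentFile,
    contig: str,
    start0: int,
    end0: int,
    reference: str,
    het_fraction: float = 0.10,
) -> np.ndarray:
    """0-based positions in [start0, end0) where >``het_fraction`` of reads
    support a non-reference base.  ``reference`` is the sequence of the
    window itself (length end0-start0).  Uncovered positions never qualify.
    """
    counts = np.array(bulk.count_coverage(contig, start0, end0), dtype=float)  # 4 x L
    total = counts.sum(axis=0)
    ref_idx = np.array([("ACGT".index(b) if b in BASES else -1) for b in reference.upper()])
    valid = (total > 0) & (ref_idx >= 0)
    nonref = np.zeros_like(total)
    cols = np.where(valid)[0]
    nonref[cols] = total[cols] - counts[ref_idx[cols], cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, nonref / np.maximum(total, 1), 0.0)
    return start0 + np.where(valid & (frac > het_fraction))[0]


def screen_erroneous_regions(
    gsnvs: Sequence[GsnvRecord],
    bulk_path: str,
    reference_path: str,
    params: RegionScreenParams | None = None,
) -> list[GsnvRecord]:
    """Drop gSNVs whose centered 1-kb window holds too many het-like positions.

    A window crowded with part-fraction non-reference positions marks a
    region where reads from several genomic origins pile up; gSNVs there
    would phase reads to the wrong haplotype.
    """
    p = params or RegionScreenParams()
    half = p.window // 2
    kept: list[GsnvRecord] = []
    with pysam.AlignmentFile(bulk_path) as bulk, pysam.FastaFile(reference_path) as fa:
        for g in gsnvs:
            clen = fa.get_reference_length(g.contig)
            start0 = max(0, g.pos - 1 - half)
            end0 = min(clen, g.pos - 1 + half + 1)  # centered; edge ties included
            ref = fa.fetch(g.contig, start0, end0)
            het = heterozygous_positions(bulk, g.contig, start0, end0, ref, p.het_fraction)
            # the gSNV itself is heterozygous by construction; it does not
            # count against its own window
            n_het = int(np.sum(het != g.pos - 1))
            if n_het <= p.max_het_positions:
                kept.append(g)
    return kept


def phasable_fraction(
    gsnv_positions: Mapping[str, Sequence[int]],
    reach: int,
    contig_lengths: Mapping[str, int],
) -> float:
    """Fraction of the genome within ``reach`` bp of a gSNV.

    Positions are 1-based; windows [pos-reach, pos+reach] are clipped to
    their contig and overlapping windows are counted once.
    """
    total = sum(contig_lengths.values())
    if total == 0:
        return 0.0
    covered = 0
    for contig, positions in gsnv_positions.items():
        clen = contig_lengths[contig]
        intervals = sorted((max(1, p - reach), min(clen, p + reach)) for p in positions)
        cur_lo: int | None = None
        cur_hi = 0
        for lo, hi in intervals:
            if cur_lo is None:
                cur_lo, cur_hi = lo, hi
            elif lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
        if cur_lo is not None:
            covered += cur_hi - cur_lo + 1
    return covered / total
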