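"""Phased genotyping: tuple-pair resolution, per-sample calls, site filters.

Every phased fragment at a candidate site is one of four *tuples* — RR, RA,
AR, AA — where the first letter is the base at the candidate (sSNV) site
and the second the base at the anchoring gSNV (R = reference, A =
alternative).  A true heterozygous mutation is consistent with exactly one
tuple pair, {RR,AA} or {RA,AR}, fixed across the whole population; samples
vote for the pair their reads support and the consensus pair tp* defines
the *informative allele* (the haplotype the mutation rides on).  Genotypes
are then classified per sample from the tuple depths, requiring informative
-allele reads for every call, which removes the false negatives caused by
dropout of the mutated allele.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from clonecall.formats import (
    FragmentObservation,
    GenotypeState,
    GsnvRecord,
    SiteCall,
    SiteTable,
    extract_fragment_observations,
)
from clonecall.discovery import CandidateSite

log = logging.getLogger(__name__)

TP_RR_AA = "RR/AA"
TP_RA_AR = "RA/AR"


@dataclass(frozen=True)
class GenotypeParams:
    """Genotyping thresholds (defaults are the published operating point).

    phi: minimum total tuple depth for a sample to vote or be classified.
    rho: maximum minor/major tuple-pair depth ratio for a clean tp vote.
    lam: minimum internal balance of the winning tuple pair for a tp vote.
    kappa: minimum samples voting for tp*; doubles as the minimum number of
        mutated samples a reported site must have.
    omega: majority fraction required to finalize tp*.
    tau/theta: internal/external ratio thresholds of the genotype classes.
    psi: majority fraction across gSNVs for the aggregated genotype.
    sigma: minimum fraction of gSNVs qualified to vote.
    chi/xi: strict read-depth floors for low-depth (C3) unmutated/mutated
        support.
    """

    phi: int = 2
    rho: float = 0.01
    lam: float = 0.1
    kappa: int = 2
    omega: float = 0.90
    tau: float = 0.1
    theta: float = 0.9
    psi: float = 0.9
    sigma: float = 0.9
    chi: int = 1
    xi: int = 1
    max_conflict_samples: int = 0
    max_mutations_per_kb: int = 1
    min_unmutated_samples: int = 0
    min_mapq: int = 2
    min_baseq: int = 20

    def __post_init__(self) -> None:
        for name in ("rho", "lam", "omega", "tau", "theta", "psi", "sigma"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("phi", "kappa", "chi", "xi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TupleCounts:
    """Phased fragment depths of the four tuples at one (sample, gSNV)."""

    rr: int = 0
    ra: int = 0
    ar: int = 0
    aa: int = 0
    other: int = 0  # fragments showing a third base at either position

    @property
    def n_tot(self) -> int:
        return self.rr + self.ra + self.ar + self.aa

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.rr, self.ra, self.ar, self.aa)


@dataclass(frozen=True)
class TuplePairResolution:
    """Outcome of the population vote for the consensus tuple pair."""

    tp_star: str | None
    informative_gsnv_base: str | None  # "ref" or "alt"
    voter_count: int
    majority_fraction: float


def tuple_counts(
    observations: Iterable[FragmentObservation],
    site_ref: str,
    site_alt: str,
    gsnv: GsnvRecord,
) -> TupleCounts:
    rr = ra = ar = aa = other = 0
    for obs in observations:
        s = obs.base_at_site
        g = obs.base_at_gsnv
        if s == site_ref and g == gsnv.ref_base:
            rr += 1
        elif s == site_ref and g == gsnv.alt_base:
            ra += 1
        elif s == site_alt and g == gsnv.ref_base:
            ar += 1
        elif s == site_alt and g == gsnv.alt_base:
            aa += 1
        else:
            other += 1
    return TupleCounts(rr, ra, ar, aa, other)


def sample_tp_vote(c: TupleCounts, params: GenotypeParams) -> str | None:
    """One sample's vote for the tuple pair its reads support, or abstain.

    The two heterozygous-compatible pairs are compared by summed depth; the
    vote goes to the deeper pair only when the shallower pair is nearly
    absent (minor/major ratio below rho) and either the winning pair is
    internally balanced (above lam) or its variant-bearing tuple (AA or AR)
    is the single deepest tuple.  A depth tie between pairs abstains.
    """
    if c.n_tot <= params.phi:
        return None
    d_rraa = c.rr + c.aa
    d_raar = c.ra + c.ar
    if d_rraa == d_raar:
        return None
    if d_rraa > d_raar:
        tp, d_max, d_min, pair, variant = TP_RR_AA, d_rraa, d_raar, (c.rr, c.aa), c.aa
    else:
        tp, d_max, d_min, pair, variant = TP_RA_AR, d_raar, d_rraa, (c.ra, c.ar), c.ar
    if d_min / d_max >= params.rho:
        return None
    internal = min(pair) / d_max
    variant_is_max = variant == max(c.as_tuple()) and sorted(c.as_tuple())[-2] < variant
    if internal > params.lam or variant_is_max:
        return tp
    return None


def resolve_tp_star(votes: Sequence[str], params: GenotypeParams) -> TuplePairResolution:
    """Finalize tp* from per-sample votes (quorum kappa, majority omega).

    With tp* = {RR,AA} the informative allele is the gSNV-alt haplotype;
    with {RA,AR} it is the gSNV-ref haplotype.  Without a quorum or a
    sufficient majority, the allelic origin of the alternative base is
    unknown and no genotyping takes place at this gSNV.
    """
    n = len(votes)
    if n < params.kappa or n == 0:
        return TuplePairResolution(None, None, n, 0.0)
    tally = Counter(votes)
    tp, best = tally.most_common(1)[0]
    frac = best / n
    if frac < params.omega:
        return TuplePairResolution(None, None, n, frac)
    informative = "alt" if tp == TP_RR_AA else "ref"
    return TuplePairResolution(tp, informative, n, frac)


def _ratio(x: int, y: int) -> float:
    return 0.0 if x + y == 0 else min(x, y) / (x + y)


def classify_genotype(
    c: TupleCounts,
    tp_star: str | None,
    params: GenotypeParams,
    sample_tp: str | None = None,
) -> GenotypeState:
    """Per-(sample, gSNV) genotype from tuple depths given tp*.

    C1 states are supported by reads from both alleles, C2 states by reads
    from only the informative allele.  Conflicts arise three ways: the
    sample satisfies both C1 conditions at once; its own tuple-pair vote
    contradicts tp*; or it displays support for both a mutated and an
    unmutated genotype — reads from both states of the informative allele
    (above the chi/xi floors), the conflicting-haplotype signature of an
    alignment artifact.  Samples with only non-informative-allele reads
    stay `none`: their genotype cannot be determined.
    """
    if tp_star is None or c.n_tot <= params.phi:
        return GenotypeState.NONE
    if tp_star == TP_RR_AA:
        het_a, het_b = c.rr, c.aa
        unmut_inf, mut_inf = c.ra, c.aa
    else:
        het_a, het_b = c.ra, c.ar
        unmut_inf, mut_inf = c.rr, c.ar
    hom_a, hom_b = c.rr, c.ra
    d_i_het = _ratio(het_a, het_b)
    d_e_het = (het_a + het_b) / c.n_tot
    d_i_hom = _ratio(hom_a, hom_b)
    d_e_hom = (hom_a + hom_b) / c.n_tot

    het_c1 = d_e_het >= params.theta and d_i_het >= params.tau
    hom_c1 = d_e_hom >= params.theta and d_i_hom >= params.tau
    if het_c1 and hom_c1:
        return GenotypeState.CONFLICT
    if unmut_inf > params.chi and mut_inf > params.xi:
        return GenotypeState.CONFLICT
    if sample_tp is not None and sample_tp != tp_star:
        return GenotypeState.CONFLICT
    if het_c1:
        return GenotypeState.HET_C1
    if hom_c1:
        return GenotypeState.HOM_C1
    if d_i_het < params.tau and d_i_hom < params.tau:
        if d_e_het >= params.theta and d_e_hom < 1 - params.theta:
            return GenotypeState.HET_C2
        if d_e_hom >= params.theta and d_e_het < 1 - params.theta:
            return GenotypeState.HOM_C2
    return GenotypeState.NONE


def infer_low_depth_genotype(
    c: TupleCounts, tp_star: str | None, params: GenotypeParams
) -> GenotypeState:
    """C3 inference for samples below the tuple-depth gate.

    Any read from the informative allele is used: depth above chi of the
    unmutated informative tuple (RA under {RR,AA}, RR under {RA,AR})
    supports an unmutated genotype; depth above xi of the variant tuple
    (AA or AR) supports a mutated one; both at once is a conflict.
    """
    if tp_star is None:
        return GenotypeState.NONE
    if tp_star == TP_RR_AA:
        unmut, mut = c.ra, c.aa
    else:
        unmut, mut = c.rr, c.ar
    has_unmut = unmut > params.chi
    has_mut = mut > params.xi
    if has_unmut and has_mut:
        return GenotypeState.CONFLICT
    if has_unmut:
        return GenotypeState.HOM_C3
    if has_mut:
        return GenotypeState.HET_C3
    return GenotypeState.NONE


def aggregate_genotype(
    per_gsnv: Mapping[tuple[str, int], GenotypeState],
    counts_by_gsnv: Mapping[tuple[str, int], TupleCounts],
    tp_by_gsnv: Mapping[tuple[str, int], TuplePairResolution],
    params: GenotypeParams,
) -> GenotypeState:
    """Combine per-gSNV genotypes into one call for a (sample, site).

    Each gSNV with a resolved tp* and sufficient depth casts its genotype
    as a vote; `none` determinations abstain.  The modal genotype must
    carry a psi majority of the votes and the voters a sigma fraction of
    all gSNVs sharing reads with the site.  When no gSNV could vote *and*
    no gSNV saw depth above phi, the sparse-read C3 inference is used.
    """
    n_tot = sum(1 for k, c in counts_by_gsnv.items() if c.n_tot > 0)
    votes = [s for s in per_gsnv.values() if s is not GenotypeState.NONE]
    n_vot = len(votes)
    if n_vot > 0:
        (gt_max, n_max), *_ = Counter(votes).most_common(1)
        if n_max / n_vot < params.psi:
            return GenotypeState.CONFLICT
        if n_tot > 0 and n_vot / n_tot >= params.sigma:
            return gt_max
        return GenotypeState.NONE
    sufficient = any(
        c.n_tot > params.phi
        for k, c in counts_by_gsnv.items()
        if tp_by_gsnv.get(k) is not None and tp_by_gsnv[k].tp_star is not None
    )
    if sufficient:
        return GenotypeState.NONE
    inferred = {
        infer_low_depth_genotype(c, tp_by_gsnv[k].tp_star, params)
        for k, c in counts_by_gsnv.items()
        if tp_by_gsnv.get(k) is not None and tp_by_gsnv[k].tp_star is not None
    }
    inferred.discard(GenotypeState.NONE)
    if not inferred:
        return GenotypeState.NONE
    if GenotypeState.CONFLICT in inferred or len(inferred) > 1:
        return GenotypeState.CONFLICT
    return inferred.pop()


def genotype_candidates(
    candidates: Sequence[CandidateSite],
    cell_bams: Mapping[str, str],
    params: GenotypeParams | None = None,
    bulk_bam: str | None = None,
) -> SiteTable:
    """Genotype every candidate site in every cell (no site filters applied).

    For each (site, anchoring gSNV) the population first resolves tp*;
    samples are then classified per gSNV and the per-gSNV genotypes are
    aggregated.  Returns a :class:`SiteTable` with one row per candidate.
    """
    params = params or GenotypeParams()
    samples = list(cell_bams)
    handles = {s: pysam.AlignmentFile(p) for s, p in cell_bams.items()}
    bulk = pysam.AlignmentFile(bulk_bam) if bulk_bam else None
    try:
        sites: list[SiteCall] = []
        for cand in candidates:
            counts: dict[str, dict[tuple[str, int], TupleCounts]] = {s: {} for s in samples}
            tp_votes: dict[str, dict[tuple[str, int], str | None]] = {s: {} for s in samples}
            tp_by_gsnv: dict[tuple[str, int], TuplePairResolution] = {}
            for g in cand.gsnvs:
                for s in samples:
                    obs = extract_fragment_observations(
                        handles[s], cand.pos, g, sample=s,
                        min_mapq=params.min_mapq, min_baseq=params.min_baseq,
                    )
                    c = tuple_counts(obs, cand.ref, cand.alt, g)
                    counts[s][g.key] = c
                    tp_votes[s][g.key] = sample_tp_vote(c, params)
                votes = [v for s in samples if (v := tp_votes[s][g.key]) is not None]
                tp_by_gsnv[g.key] = resolve_tp_star(votes, params)

            site = SiteCall(cand.contig, cand.pos, cand.ref, cand.alt, gsnvs=list(cand.gsnvs))
            defined = {r.tp_star for r in tp_by_gsnv.values() if r.tp_star is not None}
            if len(defined) == 1:
                site.tp_star = defined.pop()
                site.informative_base = "alt" if site.tp_star == TP_RR_AA else "ref"
            for s in samples:
                per_gsnv = {
                    k: classify_genotype(
                        counts[s][k], tp_by_gsnv[k].tp_star, params, sample_tp=tp_votes[s][k]
                    )
                    for k in counts[s]
                    if tp_by_gsnv[k].tp_star is not None
                }
                site.genotypes[s] = aggregate_genotype(per_gsnv, counts[s], tp_by_gsnv, params)
                summed = [0, 0, 0, 0]
                for c in counts[s].values():
                    for i, v in enumerate(c.as_tuple()):
                        summed[i] += v
                site.tuple_depths[s] = tuple(summed)  # type: ignore[assignment]
            if bulk is not None:
                cov = bulk.count_coverage(cand.contig, cand.pos - 1, cand.pos)
                site.bulk_depth = int(sum(col[0] for col in cov))
            sites.append(site)
        return SiteTable(sites, samples)
    finally:
        for h in handles.values():
            h.close()
        if bulk is not None:
            bulk.close()


def apply_site_filters(
    table: SiteTable,
    params: GenotypeParams | None = None,
    bulk_depth_cap: int | None = None,
) -> SiteTable:
    """Site-level filters applied to the genotyped table.

    Drops sites with more than the allowed number of conflicting samples,
    sites whose bulk depth exceeds the conservative cap, sites not called
    mutated in at least kappa samples (the tool reports clonal variants
    only), and — last — every site inside a 1-kb span holding more than
    the allowed number of passing sites (such clusters mark poorly
    mappable regions, so no member of the cluster is trusted).
    """
    params = params or GenotypeParams()
    passing = [
        s
        for s in table
        if s.n_conflict <= params.max_conflict_samples
        and not (
            bulk_depth_cap is not None
            and s.bulk_depth is not None
            and s.bulk_depth > bulk_depth_cap
        )
        and s.n_mutated >= params.kappa
        and s.n_unmutated >= params.min_unmutated_samples
    ]
    # sliding 1-kb window over passing sites, per contig
    dropped: set[tuple[str, int]] = set()
    by_contig: dict[str, list[SiteCall]] = {}
    for s in passing:
        by_contig.setdefault(s.contig, []).append(s)
    for contig, sites in by_contig.items():
        sites.sort(key=lambda s: s.pos)
        j = 0
        for i in range(len(sites)):
            j = max(j, i)
            while j + 1 < len(sites) and sites[j + 1].pos - sites[i].pos < 1000:
                j += 1
            if j - i + 1 > params.max_mutations_per_kb:
                for k in range(i, j + 1):
                    dropped.add(sites[k].key)
    kept = [s for s in passing if s.key not in dropped]
    log.info(
        "site filters: %d candidates -> %d passing (%d density-dropped)",
        len(table), len(kept), len(dropped),
    )
    return SiteTable(kept, table.samples)
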