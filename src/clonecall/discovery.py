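"""Candidate sSNV discovery: per-sample voting for an alternative base.

Only bases observed in the same read or read pair as at least one gSNV are
considered, so that every observation can later be assigned to a haplotype.
For each gSNV an analysis window is defined by the reach of the fragments
covering it; within the window, each sample votes for an alternative base
when its phased read support passes the allele-fraction/depth rule, and a
candidate site is emitted when enough samples agree on the same base.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam

from clonecall.formats import BASES, GsnvRecord, fragment_base, _read_ok

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoteParams:
    """Discovery-stage thresholds.

    alpha: minimum alt/ref read ratio for a two-allele vote.
    beta: read-depth gate (total depth in the ratio branch, alt depth in
        the dropout branch).
    gamma: fraction of voters that must agree on the winning base.
    epsilon: minimum number of voters at a position.
    bulk_alt_fraction_max: positions where the bulk already shows the
        base above this fraction are treated as germline/noise, not sSNVs.
    """

    alpha: float = 0.2
    beta: int = 10
    gamma: float = 0.9
    epsilon: int = 2
    bulk_alt_fraction_max: float = 0.02
    min_mapq: int = 2
    min_baseq: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1 and 0 < self.gamma <= 1):
            raise ValueError("alpha and gamma must be in (0, 1]")
        if self.beta < 0 or self.epsilon < 0:
            raise ValueError("beta and epsilon must be non-negative")

    @property
    def min_alt_support(self) -> int:
        # smallest N_b that can ever yield a vote: the ratio branch needs
        # N_b >= alpha*(beta - N_b), the dropout branch N_b >= beta
        ratio_branch = math.ceil(self.alpha * self.beta / (1 + self.alpha) - 1e-12)
        return max(1, min(ratio_branch, self.beta))


@dataclass
class CandidateSite:
    """A position where the population voted for one alternative base."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    gsnvs: list[GsnvRecord] = field(default_factory=list)
    n_voters: int = 0
    tallies: dict[str, int] = field(default_factory=dict)
    alt_depth: dict[str, int] = field(default_factory=dict)
    ref_depth: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "contig": self.contig,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "gsnvs": [
                {"contig": g.contig, "pos": g.pos, "ref": g.ref_base, "alt": g.alt_base}
                for g in self.gsnvs
            ],
            "n_voters": self.n_voters,
            "tallies": self.tallies,
            "alt_depth": self.alt_depth,
            "ref_depth": self.ref_depth,
        }

    @classmethod
    def from_json(cls, d: Mapping) -> "CandidateSite":
        return cls(
            contig=d["contig"],
            pos=d["pos"],
            ref=d["ref"],
            alt=d["alt"],
            gsnvs=[GsnvRecord(g["contig"], g["pos"], g["ref"], g["alt"]) for g in d["gsnvs"]],
            n_voters=d["n_voters"],
            tallies=dict(d["tallies"]),
            alt_depth=dict(d["alt_depth"]),
            ref_depth=dict(d["ref_depth"]),
        )


def sample_vote(n_b: int, n_r: int, params: VoteParams) -> int:
    """One sample's vote for an alternative base with phased depths n_b/n_r.

    Votes 1 when both alleles are seen at sufficient fraction and depth, or
    when the alt allele alone is deep enough (reference dropout).  A zero
    reference depth with alt reads present counts as an infinite ratio.
    """
    if n_b <= 0:
        return 0
    ratio = math.inf if n_r == 0 else n_b / n_r
    if ratio >= params.alpha:
        return 1 if n_b + n_r >= params.beta else 0
    return 1 if n_b >= params.beta else 0


def consensus_alt_base(
    votes_by_sample: Mapping[str, Sequence[str]], params: VoteParams
) -> str | None:
    """Population-consensus alternative base, or None when undecided.

    ``votes_by_sample`` maps each qualified sample to the base(s) it voted
    for.  The winning base must carry at least ``gamma`` of the voters and
    there must be at least ``epsilon`` voters; an argmax tie is undecided.
    """
    voters = {s: bs for s, bs in votes_by_sample.items() if bs}
    n_voters = len(voters)
    if n_voters < params.epsilon:
        return None
    tally: dict[str, int] = {}
    for bs in voters.values():
        for b in set(bs):
            tally[b] = tally.get(b, 0) + 1
    best = max(tally.values())
    winners = [b for b, v in tally.items() if v == best]
    if len(winners) != 1:
        return None
    if best / n_voters >= params.gamma:
        return winners[0]
    return None


def _fragment_span(read: pysam.AlignedSegment) -> tuple[int, int]:
    """0-based half-open span of the sequenced fragment a read belongs to."""
    tlen = read.template_length
    if tlen > 0:
        return read.reference_start, read.reference_start + tlen
    if tlen < 0 and read.reference_end is not None:
        return read.reference_end + tlen, read.reference_end
    return read.reference_start, read.reference_end or read.reference_start


def define_analysis_windows(
    gsnvs: Sequence[GsnvRecord],
    bam_paths: Sequence[str],
    min_mapq: int = 2,
) -> dict[tuple[str, int], tuple[int, int]]:
    """Envelope (0-based half-open) of fragment spans overlapping each gSNV.

    gSNVs with no coverage anywhere get no entry (their windows are empty
    and the sites are skipped).
    """
    windows: dict[tuple[str, int], tuple[int, int]] = {}
    for path in bam_paths:
        with pysam.AlignmentFile(path) as bam:
            for g in gsnvs:
                g0 = g.pos - 1
                lo = hi = None
                for read in bam.fetch(g.contig, g0, g0 + 1):
                    if not _read_ok(read, min_mapq):
                        continue
                    s, e = _fragment_span(read)
                    lo = s if lo is None else min(lo, s)
                    hi = e if hi is None else max(hi, e)
                if lo is None:
                    continue
                cur = windows.get(g.key)
                windows[g.key] = (
                    (lo, hi) if cur is None else (min(cur[0], lo), max(cur[1], hi))
                )
    return windows


class _Fragment:
    """Phased fragment: read spans plus its mismatches against the reference."""

    __slots__ = ("intervals", "mismatches", "conflicted")

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int]] = []
        self.mismatches: dict[int, str] = {}
        self.conflicted: set[int] = set()

    def covers(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.intervals)

    def base_at(self, pos0: int, ref_base: str) -> str | None:
        if pos0 in self.conflicted or not self.covers(pos0):
            return None
        return self.mismatches.get(pos0, ref_base)


def _read_mismatches(
    read: pysam.AlignedSegment, ref_seq: str, ref_start0: int, min_baseq: int
) -> list[tuple[int, str]]:
    seq = read.query_sequence
    if seq is None:
        return []
    cig = read.cigartuples
    out: list[tuple[int, str]] = []
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        lo = read.reference_start - ref_start0
        ref_slice = ref_seq[lo : lo + len(seq)]
        if seq == ref_slice:
            return []
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.frombuffer(ref_slice.encode(), dtype=np.uint8)
        quals = read.query_qualities
        for q in np.nonzero(a != b[: len(a)])[0]:
            if quals is not None and quals[q] < min_baseq:
                continue
            base = seq[q]
            if base in BASES:
                out.append((read.reference_start + int(q), base))
    else:
        quals = read.query_qualities
        for q, r in read.get_aligned_pairs(matches_only=True):
            base = seq[q]
            if base != ref_seq[r - ref_start0] and base in BASES:
                if quals is None or quals[q] >= min_baseq:
                    out.append((r, base))
    return out


def _collect_fragments(
    bam: pysam.AlignmentFile,
    gsnv: GsnvRecord,
    ref_seq: str,
    ref_start0: int,
    ref_end0: int,
    params: VoteParams,
) -> dict[str, tuple[str, _Fragment]]:
    """Fragments phased to a gSNV: name -> (gSNV base, fragment mismatch map)."""
    g0 = gsnv.pos - 1
    names = set()
    lo, hi = g0, g0 + 1
    for read in bam.fetch(gsnv.contig, g0, g0 + 1):
        if _read_ok(read, params.min_mapq):
            names.add(read.query_name)
            s, e = _fragment_span(read)
            lo, hi = min(lo, s), max(hi, e)
    if not names:
        return {}
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for read in bam.fetch(gsnv.contig, max(lo, 0), hi):
        if read.query_name in names and _read_ok(read, params.min_mapq):
            by_name.setdefault(read.query_name, []).append(read)
    out: dict[str, tuple[str, _Fragment]] = {}
    for name, reads in by_name.items():
        gb = fragment_base(reads, g0, params.min_baseq)
        if gb is None or gb == "mate-disagreement":
            continue
        frag = _Fragment()
        per_read: list[dict[int, str]] = []
        for r in reads:
            s, e = r.reference_start, r.reference_end or r.reference_start
            s, e = max(s, ref_start0), min(e, ref_end0)
            if s >= e:
                continue
            frag.intervals.append((s, e))
            per_read.append(dict(_read_mismatches(r, ref_seq, ref_start0, params.min_baseq)))
        # mate-overlap handling per position: mismatch in one read must be
        # matched by every other read covering the same position
        for i, mm in enumerate(per_read):
            for pos0, base in mm.items():
                other_bases = {
                    m2.get(pos0, ref_seq[pos0 - ref_start0])
                    for j, m2 in enumerate(per_read)
                    if j != i and frag.intervals[j][0] <= pos0 < frag.intervals[j][1]
                }
                if other_bases and other_bases != {base}:
                    frag.conflicted.add(pos0)
                else:
                    frag.mismatches[pos0] = base
        out[name] = (gb, frag)
    return out


def discover_candidates(
    cell_bams: Mapping[str, str],
    bulk_bam: str,
    gsnvs: Sequence[GsnvRecord],
    reference_path: str,
    params: VoteParams | None = None,
) -> list[CandidateSite]:
    """Scan gSNV-anchored windows of all cells for consensus alternative bases.

    Returns candidate sites ordered by (contig, pos).  Every emitted site
    lies inside some gSNV's analysis window (its support comes from phased
    fragments), differs from all gSNV positions, and has a defined
    consensus base.
    """
    params = params or VoteParams()
    gsnv_positions = {(g.contig, g.pos - 1) for g in gsnvs}
    # (contig, pos0) -> sample -> fragment name -> base
    support: dict[tuple[str, int], dict[str, dict[str, str]]] = {}
    anchors: dict[tuple[str, int], dict[tuple[str, int], GsnvRecord]] = {}

    handles = {s: pysam.AlignmentFile(p) for s, p in cell_bams.items()}
    try:
        with pysam.FastaFile(reference_path) as fa:
            for g in gsnvs:
                clen = fa.get_reference_length(g.contig)
                per_sample: dict[str, dict[str, tuple[str, _Fragment]]] = {}
                lo = hi = None
                for sample, bam in handles.items():
                    g0 = g.pos - 1
                    spans = [
                        _fragment_span(r)
                        for r in bam.fetch(g.contig, g0, g0 + 1)
                        if _read_ok(r, params.min_mapq)
                    ]
                    if not spans:
                        continue
                    s = min(x for x, _ in spans)
                    e = max(x for _, x in spans)
                    lo = s if lo is None else min(lo, s)
                    hi = e if hi is None else max(hi, e)
                if lo is None:
                    continue
                lo, hi = max(0, lo), min(clen, hi)
                ref_seq = fa.fetch(g.contig, lo, hi).upper()
                for sample, bam in handles.items():
                    per_sample[sample] = _collect_fragments(bam, g, ref_seq, lo, hi, params)
                # prescreen: a position is worth tallying only if one sample
                # has enough same-base fragments to possibly cast a vote
                counts: dict[tuple[int, str, str], int] = {}
                for sample, frags in per_sample.items():
                    for _, (gb, frag) in frags.items():
                        for pos0, base in frag.mismatches.items():
                            if pos0 in frag.conflicted:
                                continue
                            counts[(pos0, base, sample)] = counts.get((pos0, base, sample), 0) + 1
                cand_pos = {
                    pos0
                    for (pos0, base, sample), n in counts.items()
                    if n >= params.min_alt_support and (g.contig, pos0) not in gsnv_positions
                }
                for pos0 in cand_pos:
                    key = (g.contig, pos0)
                    site = support.setdefault(key, {})
                    anchors.setdefault(key, {})[g.key] = g
                    ref_base = ref_seq[pos0 - lo]
                    for sample, frags in per_sample.items():
                        dest = site.setdefault(sample, {})
                        for name, (gb, frag) in frags.items():
                            b = frag.base_at(pos0, ref_base)
                            if b is not None and name not in dest:
                                dest[name] = b

        candidates: list[CandidateSite] = []
        with pysam.AlignmentFile(bulk_bam) as bulk, pysam.FastaFile(reference_path) as fa:
            for (contig, pos0), by_sample in sorted(support.items()):
                ref_base = fa.fetch(contig, pos0, pos0 + 1).upper()
                if ref_base not in BASES:
                    continue
                bulk_counts = np.array(
                    bulk.count_coverage(contig, pos0, pos0 + 1), dtype=float
                ).ravel()
                bulk_total = bulk_counts.sum()
                votes: dict[str, list[str]] = {}
                depths: dict[str, dict[str, int]] = {}
                for sample, frag_bases in by_sample.items():
                    tally: dict[str, int] = {}
                    for b in frag_bases.values():
                        tally[b] = tally.get(b, 0) + 1
                    depths[sample] = tally
                    n_r = tally.get(ref_base, 0)
                    voted = []
                    for b in BASES:
                        if b == ref_base:
                            continue
                        # a base already visible in the bulk is germline or a
                        # recurrent artifact, not a somatic candidate; two
                        # supporting reads are required so that a lone
                        # sequencing error in the bulk cannot veto a site
                        n_bulk_alt = bulk_counts["ACGT".index(b)]
                        if (
                            bulk_total > 0
                            and n_bulk_alt >= 2
                            and n_bulk_alt / bulk_total > params.bulk_alt_fraction_max
                        ):
                            continue
                        if sample_vote(tally.get(b, 0), n_r, params):
                            voted.append(b)
                    votes[sample] = voted
                alt = consensus_alt_base(votes, params)
                if alt is None:
                    continue
                site = CandidateSite(
                    contig=contig,
                    pos=pos0 + 1,
                    ref=ref_base,
                    alt=alt,
                    gsnvs=sorted(anchors[(contig, pos0)].values()),
                    n_voters=sum(1 for v in votes.values() if v),
                    tallies={
                        b: sum(1 for v in votes.values() if b in v)
                        for b in BASES
                        if b != ref_base and any(b in v for v in votes.values())
                    },
                    alt_depth={s: d.get(alt, 0) for s, d in depths.items()},
                    ref_depth={s: d.get(ref_base, 0) for s, d in depths.items()},
                )
                candidates.append(site)
        candidates.sort(key=lambda c: (c.contig, c.pos))
        log.info("discovered %d candidate sites from %d gSNVs", len(candidates), len(gsnvs))
        return candidates
    finally:
        for h in handles.values():
            h.close()
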