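"""On-disk formats and phase-informative fragment extraction.

Coordinate convention: every external interface (VCF, TSV, JSON, public
dataclass fields) is 1-based inclusive; pysam-facing internals are 0-based
half-open.  The conversion happens in this module and nowhere else.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

import pysam

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: Sentinel returned when the two mates of a pair overlap a position and
#: disagree on the base there; the whole fragment is then discarded.
MATE_DISAGREEMENT = "mate-disagreement"


class GenotypeState(str, enum.Enum):
    """Closed vocabulary of per-sample genotype states.

    C1: both alleles observed; C2: only the informative allele observed;
    C3: inferred from sparse reads below the tuple-depth gate.
    """

    HET_C1 = "het_C1"
    HOM_C1 = "hom_C1"
    HET_C2 = "het_C2"
    HOM_C2 = "hom_C2"
    HET_C3 = "het_C3"
    HOM_C3 = "hom_C3"
    CONFLICT = "conflict"
    NONE = "none"

    @property
    def is_mutated(self) -> bool:
        return self in (GenotypeState.HET_C1, GenotypeState.HET_C2, GenotypeState.HET_C3)

    @property
    def is_unmutated(self) -> bool:
        return self in (GenotypeState.HOM_C1, GenotypeState.HOM_C2, GenotypeState.HOM_C3)


@dataclass(frozen=True, order=True)
class GsnvRecord:
    """A phased heterozygous germline SNV anchoring an analysis window."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(f"gSNV bases must be A/C/G/T, got {self.ref_base}/{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"gSNV at {self.contig}:{self.pos} has ref == alt ({self.ref_base})")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


@dataclass(frozen=True)
class FragmentObservation:
    """One sequenced fragment's joint base readout at a site and a gSNV."""

    sample: str
    base_at_site: str
    base_at_gsnv: str
    fragment_id: str


class VcfParseError(ValueError):
    pass


def load_gsnvs(vcf_path: str, whitelist: set[str] | None = None) -> list[GsnvRecord]:
    """Read biallelic SNV records from a VCF into gSNV anchors.

    Multi-allelic and non-SNV records are skipped with a log line: the
    downstream tuple algebra is defined over exactly two gSNV bases.
    Records on contigs outside ``whitelist`` (if given) are dropped.
    """
    out: list[GsnvRecord] = []
    try:
        vcf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {vcf_path!r}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if whitelist is not None and rec.chrom not in whitelist:
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                log.info("skipping multi-allelic record %s:%d (ALT=%s)", rec.chrom, rec.pos, alts)
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                log.info("skipping non-SNV record %s:%d %s>%s", rec.chrom, rec.pos, ref, alt)
                continue
            out.append(GsnvRecord(rec.chrom, rec.pos, ref, alt))
    if not out:
        log.warning("no usable gSNV records loaded from %s", vcf_path)
    out.sort()
    return out


def write_gsnvs_tsv(gsnvs: Sequence[GsnvRecord], stream: TextIO) -> None:
    stream.write("contig\tpos\tref\talt\n")
    for g in gsnvs:
        stream.write(f"{g.contig}\t{g.pos}\t{g.ref_base}\t{g.alt_base}\n")


# ---------------------------------------------------------------------------
# Fragment handling


def _read_ok(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or read.mapping_quality < min_mapq
    )


def base_at(read: pysam.AlignedSegment, pos0: int, min_baseq: int = 0) -> str | None:
    """Base called by ``read`` at 0-based reference position, or None.

    Fast path for ungapped alignments; general path walks aligned pairs.
    """
    if read.reference_start is None or not (read.reference_start <= pos0 < (read.reference_end or -1)):
        return None
    cig = read.cigartuples
    seq = read.query_sequence
    if seq is None:
        return None
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:  # single M/=, ungapped
        qpos = pos0 - read.reference_start
    else:
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=True):
            if r == pos0:
                qpos = q
                break
        if qpos is None:
            return None
    quals = read.query_qualities
    if quals is not None and quals[qpos] < min_baseq:
        return None
    b = seq[qpos]
    return b if b in BASES else None


def fragment_base(reads: Sequence[pysam.AlignedSegment], pos0: int, min_baseq: int = 0) -> str | None:
    """Consensus base of a fragment (read pair) at a position.

    Returns the base if exactly one distinct base passes filters, None if
    no mate covers the position, and :data:`MATE_DISAGREEMENT` if the
    overlapping mates disagree (the fragment must then be discarded).
    """
    seen = {base_at(r, pos0, min_baseq) for r in reads}
    seen.discard(None)
    if not seen:
        return None
    if len(seen) > 1:
        return MATE_DISAGREEMENT
    return seen.pop()


def fetch_fragments(
    bam: pysam.AlignmentFile,
    contig: str,
    start0: int,
    end0: int,
    min_mapq: int = 2,
) -> dict[str, list[pysam.AlignedSegment]]:
    """Group passing reads overlapping [start0, end0) by fragment (query name)."""
    frags: dict[str, list[pysam.AlignedSegment]] = {}
    for read in bam.fetch(contig, start0, end0):
        if _read_ok(read, min_mapq):
            frags.setdefault(read.query_name, []).append(read)
    return frags


def extract_fragment_observations(
    bam: Union[str, pysam.AlignmentFile],
    site_pos: int,
    gsnv: GsnvRecord,
    sample: str = "",
    min_mapq: int = 2,
    min_baseq: int = 20,
) -> list[FragmentObservation]:
    """Joint base observations at a candidate site and a gSNV, per fragment.

    ``site_pos`` is 1-based and must lie on the gSNV's contig.  Each
    fragment covering both positions contributes at most one observation;
    fragments whose mates disagree at either position are discarded.
    """
    own = isinstance(bam, str)
    af = pysam.AlignmentFile(bam) if own else bam
    try:
        if not af.has_index():
            raise ValueError(f"alignment file {af.filename!r} is not indexed")
        site0 = site_pos - 1
        g0 = gsnv.pos - 1
        lo, hi = min(site0, g0), max(site0, g0) + 1
        obs: list[FragmentObservation] = []
        for name, reads in fetch_fragments(af, gsnv.contig, lo, hi, min_mapq).items():
            b_site = fragment_base(reads, site0, min_baseq)
            b_gsnv = fragment_base(reads, g0, min_baseq)
            if MATE_DISAGREEMENT in (b_site, b_gsnv):
                continue
            if b_site is None or b_gsnv is None:
                continue  # phasing requires the fragment to cover both positions
            obs.append(FragmentObservation(sample, b_site, b_gsnv, name))
        return obs
    finally:
        if own:
            af.close()


# ---------------------------------------------------------------------------
# Site table (final calls) and candidates JSON


@dataclass
class SiteCall:
    """One candidate sSNV site with per-sample genotypes and tuple depths."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    tp_star: str | None = None  # "RR/AA", "RA/AR" or None
    informative_base: str | None = None  # "ref" or "alt" (of the gSNV)
    gsnvs: list[GsnvRecord] = field(default_factory=list)
    genotypes: dict[str, GenotypeState] = field(default_factory=dict)
    # per sample: (N_RR, N_RA, N_AR, N_AA) summed over anchoring gSNVs
    tuple_depths: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    bulk_depth: int | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    def n_state(self, predicate) -> int:
        return sum(1 for s in self.genotypes.values() if predicate(s))

    @property
    def n_mutated(self) -> int:
        return self.n_state(lambda s: s.is_mutated)

    @property
    def n_unmutated(self) -> int:
        return self.n_state(lambda s: s.is_unmutated)

    @property
    def n_conflict(self) -> int:
        return self.n_state(lambda s: s is GenotypeState.CONFLICT)


class SiteTable:
    """Ordered collection of :class:`SiteCall`, unique by (contig, pos)."""

    def __init__(self, sites: Iterable[SiteCall] = (), samples: Sequence[str] = ()):
        self.sites: list[SiteCall] = sorted(sites, key=lambda s: s.key)
        seen = {s.key for s in self.sites}
        if len(seen) != len(self.sites):
            raise ValueError("duplicate (contig, pos) in site table")
        self.samples: list[str] = list(samples)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteCall]:
        return iter(self.sites)

    def __getitem__(self, i: int) -> SiteCall:
        return self.sites[i]


def _fmt_gsnvs(gsnvs: Sequence[GsnvRecord]) -> str:
    return ";".join(f"{g.contig}:{g.pos}:{g.ref_base}:{g.alt_base}" for g in gsnvs) or "."


def _parse_gsnvs(text: str) -> list[GsnvRecord]:
    if text == ".":
        return []
    out = []
    for part in text.split(";"):
        contig, pos, ref, alt = part.rsplit(":", 3)
        out.append(GsnvRecord(contig, int(pos), ref, alt))
    return out


def write_sites_tsv(table: SiteTable, stream: TextIO) -> None:
    """Emit the final phased call table as TSV (round-trip safe)."""
    cols = ["contig", "pos", "ref", "alt", "tp_star", "informative_base", "bulk_depth", "gsnvs"]
    for s in table.samples:
        cols += [f"{s}.gt", f"{s}.tuples"]
    stream.write("\t".join(cols) + "\n")
    for site in table:
        row = [
            site.contig,
            str(site.pos),
            site.ref,
            site.alt,
            site.tp_star or ".",
            site.informative_base or ".",
            "." if site.bulk_depth is None else str(site.bulk_depth),
            _fmt_gsnvs(site.gsnvs),
        ]
        for s in table.samples:
            gt = site.genotypes.get(s, GenotypeState.NONE)
            rr, ra, ar, aa = site.tuple_depths.get(s, (0, 0, 0, 0))
            row += [gt.value, f"{rr}:{ra}:{ar}:{aa}"]
        stream.write("\t".join(row) + "\n")


def read_sites_tsv(stream: TextIO) -> SiteTable:
    header = stream.readline().rstrip("\n").split("\t")
    fixed = ["contig", "pos", "ref", "alt", "tp_star", "informative_base", "bulk_depth", "gsnvs"]
    if header[: len(fixed)] != fixed:
        raise ValueError("unrecognized site TSV header")
    samples = [c[: -len(".gt")] for c in header[len(fixed) :: 2]]
    sites = []
    for line in stream:
        parts = line.rstrip("\n").split("\t")
        site = SiteCall(
            contig=parts[0],
            pos=int(parts[1]),
            ref=parts[2],
            alt=parts[3],
            tp_star=None if parts[4] == "." else parts[4],
            informative_base=None if parts[5] == "." else parts[5],
            bulk_depth=None if parts[6] == "." else int(parts[6]),
            gsnvs=_parse_gsnvs(parts[7]),
        )
        for i, s in enumerate(samples):
            gt = GenotypeState(parts[len(fixed) + 2 * i])
            depths = tuple(int(x) for x in parts[len(fixed) + 2 * i + 1].split(":"))
            site.genotypes[s] = gt
            site.tuple_depths[s] = depths  # type: ignore[assignment]
        sites.append(site)
    return SiteTable(sites, samples)


def write_candidates_json(candidates: Sequence[Mapping], stream: TextIO) -> None:
    json.dump(list(candidates), stream, indent=1, sort_keys=True)


def read_candidates_json(stream: TextIO) -> list[dict]:
    return json.load(stream)
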