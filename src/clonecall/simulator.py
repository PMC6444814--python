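"""Generative simulator: clonal sSNVs, EAL paralogs, allelic dropout.

The model builds a synthetic reference with well-separated two-site loci.
Each locus pairs a heterozygous gSNV ``G`` with a candidate sSNV site ``S``
11–50 bp away.  A population of two clones is simulated; at an sSNV locus
one randomly chosen clone is heterozygous at S (the mutation riding on a
random one of the two G haplotypes) and the other clone is homozygous
reference.  With probability ``p_eal`` a locus is instead an alignment
artifact (EAL): its own cells are homozygous reference, but reads from a
paralogous locus with the opposite state at S are mapped onto the same
coordinates, producing the conflicting-haplotype signature.  Whole-genome
amplification dropout is modelled per (cell, locus, allele): a dropped
allele emits no reads.  Coverage per surviving allele is either exactly
flat or negative-binomial ("empirical-like" amplification bias).

Reads are synthesized de novo from the haplotype sequences as proper
2x150 bp pairs whose site-covering read spans both G and S, with uniform
substitution errors.  The unamplified bulk is built from the germline
haplotypes (heterozygous G, reference S) with no dropout and no paralog
reads.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from clonecall.formats import BASES, GsnvRecord

log = logging.getLogger(__name__)

_OTHER = {b: [x for x in BASES if x != b] for b in BASES}


@dataclass(frozen=True)
class SimParams:
    """Study conditions of the simulated experiments.

    The defaults mirror the published setup: 306 loci, two clones of 10
    cells, G and S 11–50 bp apart, flat 30 reads per surviving allele (the
    even-coverage variant), 650 bp mean insert, 40x bulk.
    """

    n_loci: int = 306
    clone_sizes: tuple[int, ...] = (10, 10)
    p_eal: float = 0.0
    p_do: float = 0.0
    coverage_model: str = "flat"  # "flat" | "nb" (empirical-like stand-in)
    flat_coverage: int = 30
    nb_mean: float = 30.0
    nb_dispersion: float = 3.0
    gap_min: int = 11
    gap_max: int = 50
    read_length: int = 150
    insert_mean: int = 650
    insert_sd: int = 100
    base_error_rate: float = 0.001
    bulk_coverage_per_allele: int = 20
    locus_spacing: int = 3000
    contig: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_eal <= 1 and 0 <= self.p_do <= 1):
            raise ValueError("p_eal and p_do must be probabilities")
        if not 11 <= self.gap_min <= self.gap_max <= 50:
            raise ValueError("gSNV–sSNV gap must stay within [11, 50] bp")
        if any(n < 1 for n in self.clone_sizes):
            raise ValueError("clone sizes must be >= 1")
        if self.coverage_model not in ("flat", "nb"):
            raise ValueError("coverage_model must be 'flat' or 'nb'")

    @property
    def n_cells(self) -> int:
        return sum(self.clone_sizes)

    @property
    def cell_names(self) -> list[str]:
        return [f"cell_{i:02d}" for i in range(self.n_cells)]

    @property
    def clone_of(self) -> dict[str, int]:
        out, i = {}, 0
        for clone, size in enumerate(self.clone_sizes):
            for _ in range(size):
                out[f"cell_{i:02d}"] = clone
                i += 1
        return out


@dataclass(frozen=True)
class TrueLocus:
    """Ground-truth description of one simulated locus."""

    locus_id: int
    contig: str
    g_pos: int  # 1-based
    s_pos: int  # 1-based
    g_ref: str
    g_alt: str
    s_ref: str
    s_alt: str
    snv: int
    eal: int
    mutated_clone: int  # -1 when snv == 0
    snv_on_galt: int  # phase of the sSNV: 1 = on the G-alt haplotype; -1 n/a
    eal_on_galt: int  # phase of the paralog's S-alt; -1 when eal == 0


# allele indices: 0 = locus hap with G=ref, 1 = locus hap with G=alt,
# 2/3 = the same two haplotypes of the paralog (only when eal == 1)
N_ALLELES = 4


@dataclass
class TruthTable:
    """Simulator ground truth: loci, clone structure, per-allele dropout."""

    loci: list[TrueLocus]
    cells: list[str]
    clone_of: dict[str, int]
    dropout: dict[tuple[str, int, int], int] = field(default_factory=dict)

    def true_genotype(self, cell: str, locus: TrueLocus) -> str:
        if locus.snv == 1 and self.clone_of[cell] == locus.mutated_clone:
            return "het"
        return "hom"

    def locus_by_site(self) -> dict[tuple[str, int], TrueLocus]:
        return {(l.contig, l.s_pos): l for l in self.loci}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            row = dataclasses.asdict(l)
            for cell in self.cells:
                for a in range(N_ALLELES):
                    row[f"do_{cell}_a{a}"] = self.dropout.get((cell, l.locus_id, a), -1)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str, clone_of: Mapping[str, int]) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        locus_fields = [f.name for f in dataclasses.fields(TrueLocus)]
        loci = [TrueLocus(**{k: row[k] for k in locus_fields}) for _, row in df.iterrows()]
        cells = sorted({c[3:-3] for c in df.columns if c.startswith("do_")})
        t = cls(loci=loci, cells=cells, clone_of=dict(clone_of))
        for _, row in df.iterrows():
            for cell in cells:
                for a in range(N_ALLELES):
                    v = int(row[f"do_{cell}_a{a}"])
                    if v >= 0:
                        t.dropout[(cell, int(row["locus_id"]), a)] = v
        return t


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def build_locus_set(params: SimParams, rng: np.random.Generator) -> tuple[str, list[TrueLocus]]:
    """Synthetic reference sequence plus the ground-truth locus list.

    Loci are spaced far enough apart (> 2 kb) that analysis windows and the
    1-kb density filter cannot couple neighbouring loci.
    """
    margin = 2 * (params.insert_mean + 4 * params.insert_sd) + params.gap_max + 10
    length = params.n_loci * params.locus_spacing + 2 * margin
    seq = _random_sequence(rng, length)
    seq_list = list(seq)
    loci: list[TrueLocus] = []
    for i in range(params.n_loci):
        g0 = margin + i * params.locus_spacing
        gap = int(rng.integers(params.gap_min, params.gap_max + 1))
        s0 = g0 + gap if rng.random() < 0.5 else g0 - gap
        g_ref = seq_list[g0]
        g_alt = _OTHER[g_ref][rng.integers(0, 3)]
        s_ref = seq_list[s0]
        s_alt = _OTHER[s_ref][rng.integers(0, 3)]
        eal = int(rng.random() < params.p_eal)
        snv = 0 if eal else 1  # EAL loci carry no true sSNV
        mutated_clone = int(rng.integers(0, len(params.clone_sizes))) if snv else -1
        snv_on_galt = int(rng.random() < 0.5) if snv else -1
        eal_on_galt = int(rng.random() < 0.5) if eal else -1
        loci.append(
            TrueLocus(
                locus_id=i,
                contig=params.contig,
                g_pos=g0 + 1,
                s_pos=s0 + 1,
                g_ref=g_ref,
                g_alt=g_alt,
                s_ref=s_ref,
                s_alt=s_alt,
                snv=snv,
                eal=eal,
                mutated_clone=mutated_clone,
                snv_on_galt=snv_on_galt,
                eal_on_galt=eal_on_galt,
            )
        )
    return seq, loci


def sample_dropout(
    cells: Sequence[str], loci: Sequence[TrueLocus], p_do: float, rng: np.random.Generator
) -> dict[tuple[str, int, int], int]:
    """Independent Bernoulli(p_do) dropout per (cell, locus-or-paralog, allele)."""
    out: dict[tuple[str, int, int], int] = {}
    for locus in loci:
        n_alleles = N_ALLELES if locus.eal else 2
        for cell in cells:
            draws = rng.random(n_alleles) < p_do
            for a in range(n_alleles):
                out[(cell, locus.locus_id, a)] = int(draws[a])
    return out


def _haplotype_variants(locus: TrueLocus, cell_is_mutated: bool) -> list[dict[int, str]]:
    """Variant maps (0-based pos -> base) of the up-to-four allele haplotypes."""
    g0, s0 = locus.g_pos - 1, locus.s_pos - 1
    hap_ref: dict[int, str] = {}
    hap_alt: dict[int, str] = {g0: locus.g_alt}
    if locus.snv and cell_is_mutated:
        (hap_alt if locus.snv_on_galt == 1 else hap_ref)[s0] = locus.s_alt
    haps = [hap_ref, hap_alt]
    if locus.eal:
        p_ref: dict[int, str] = {}
        p_alt: dict[int, str] = {g0: locus.g_alt}
        (p_alt if locus.eal_on_galt == 1 else p_ref)[s0] = locus.s_alt
        haps += [p_ref, p_alt]
    return haps


def _coverage(params: SimParams, rng: np.random.Generator) -> int:
    if params.coverage_model == "flat":
        return params.flat_coverage
    r = params.nb_dispersion
    p = r / (r + params.nb_mean)
    return int(rng.negative_binomial(r, p))


@dataclass(frozen=True)
class ReadPair:
    """One synthesized proper pair; coordinates 0-based."""

    name: str
    covering_start: int
    mate_start: int
    covering_seq: str
    mate_seq: str
    covering_is_reverse: bool


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = _OTHER[chars[p]][rng.integers(0, 3)]
    return "".join(chars)


def generate_reads(
    cell: str,
    locus: TrueLocus,
    truth: TruthTable,
    params: SimParams,
    rng: np.random.Generator,
    ref_seq: str,
) -> list[ReadPair]:
    """Read pairs for one cell at one locus, honouring dropout and EAL.

    For each surviving allele, N fragments are drawn (N from the coverage
    model; the flat model emits exactly ``flat_coverage``), each with its
    site-covering read spanning both G and S and a mate at insert distance
    on a random side.  Paralog reads carry the locus's own coordinates —
    the defining artifact of an EAL locus.
    """
    mutated = truth.true_genotype(cell, locus) == "het"
    haps = _haplotype_variants(locus, mutated)
    g0, s0 = locus.g_pos - 1, locus.s_pos - 1
    lo_site, hi_site = min(g0, s0), max(g0, s0)
    L = params.read_length
    pairs: list[ReadPair] = []
    for a, variants in enumerate(haps):
        if truth.dropout.get((cell, locus.locus_id, a), 1) == 1:
            continue
        n = _coverage(params, rng)
        if n <= 0:
            continue
        region_lo = max(0, lo_site - 2 * (params.insert_mean + 4 * params.insert_sd))
        region_hi = min(len(ref_seq), hi_site + 2 * (params.insert_mean + 4 * params.insert_sd))
        hap = list(ref_seq[region_lo:region_hi])
        for p, b in variants.items():
            hap[p - region_lo] = b
        hap_str = "".join(hap)
        starts = rng.integers(hi_site - L + 1, lo_site + 1, size=n)
        inserts = np.clip(
            np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(int),
            2 * L + 10,
            params.insert_mean + 4 * params.insert_sd,
        )
        sides = rng.random(n) < 0.5
        for i in range(n):
            cstart = int(starts[i])
            insert = int(inserts[i])
            if sides[i]:  # fragment extends right; covering read is forward
                mstart = cstart + insert - L
                cov_rev = False
            else:  # fragment extends left; covering read is reverse
                mstart = cstart + L - insert
                cov_rev = True
            cseq = _apply_errors(hap_str[cstart - region_lo : cstart - region_lo + L],
                                 params.base_error_rate, rng)
            mseq = _apply_errors(hap_str[mstart - region_lo : mstart - region_lo + L],
                                 params.base_error_rate, rng)
            pairs.append(
                ReadPair(
                    name=f"{cell}:L{locus.locus_id}:a{a}:f{i}",
                    covering_start=cstart,
                    mate_start=mstart,
                    covering_seq=cseq,
                    mate_seq=mseq,
                    covering_is_reverse=cov_rev,
                )
            )
    return pairs


def _sam_lines(pair: ReadPair, contig: str, L: int) -> list[str]:
    qual = "F" * L
    c, m = pair.covering_start, pair.mate_start
    if not pair.covering_is_reverse:
        tlen = (m + L) - c
        f1, f2 = 99, 147  # covering = first, forward; mate reverse
        rows = [(pair.name, f1, c, pair.covering_seq, m, tlen),
                (pair.name, f2, m, pair.mate_seq, c, -tlen)]
    else:
        tlen = (c + L) - m
        f1, f2 = 83, 163  # covering = first, reverse; mate forward
        rows = [(pair.name, f1, c, pair.covering_seq, m, -tlen),
                (pair.name, f2, m, pair.mate_seq, c, tlen)]
    return [
        f"{name}\t{flag}\t{contig}\t{pos + 1}\t60\t{L}M\t=\t{mpos + 1}\t{tl}\t{seq}\t{qual}"
        for name, flag, pos, seq, mpos, tl in rows
    ]


def _write_bam(sam_lines: list[str], header: str, out_bam: str) -> None:
    sam_path = out_bam + ".tmp.sam"
    with open(sam_path, "w") as fh:
        fh.write(header)
        fh.write("\n".join(sam_lines))
        if sam_lines:
            fh.write("\n")
    pysam.sort("-o", out_bam, sam_path)
    pysam.index(out_bam)
    os.remove(sam_path)


@dataclass
class SimulationResult:
    params: SimParams
    truth: TruthTable
    out_dir: str
    reference: str  # FASTA path
    cell_bams: dict[str, str]
    bulk_bam: str
    gsnv_vcf: str
    truth_tsv: str


def _bulk_vcf_stats(bulk: pysam.AlignmentFile, locus: TrueLocus) -> dict[str, int]:
    g0 = locus.g_pos - 1
    dp = ao = saf = sar = rpr = rpl = 0
    for read in bulk.fetch(locus.contig, g0, g0 + 1):
        seq = read.query_sequence
        if seq is None or read.cigartuples is None:
            continue
        q = g0 - read.reference_start
        if not 0 <= q < len(seq):
            continue
        dp += 1
        if seq[q] == locus.g_alt:
            ao += 1
            if read.is_reverse:
                sar += 1
            else:
                saf += 1
            if q < len(seq) // 2:
                rpl += 1
            else:
                rpr += 1
    return dict(DP=dp, AO=ao, SAF=saf, SAR=sar, RPR=rpr, RPL=rpl)


def _write_gsnv_vcf(path: str, loci: Sequence[TrueLocus], bulk_path: str, contig: str, clen: int) -> None:
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig},length={clen}>\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n'
        '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">\n'
        '##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt observations on the forward strand">\n'
        '##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt observations on the reverse strand">\n'
        '##INFO=<ID=RPL,Number=A,Type=Integer,Description="Alt reads placed left of the variant">\n'
        '##INFO=<ID=RPR,Number=A,Type=Integer,Description="Alt reads placed right of the variant">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    with pysam.AlignmentFile(bulk_path) as bulk, open(path, "w") as fh:
        fh.write(header)
        for locus in sorted(loci, key=lambda l: l.g_pos):
            st = _bulk_vcf_stats(bulk, locus)
            info = ";".join(f"{k}={v}" for k, v in st.items())
            fh.write(
                f"{locus.contig}\t{locus.g_pos}\t.\t{locus.g_ref}\t{locus.g_alt}"
                f"\t2000\tPASS\t{info}\n"
            )


def simulate_experiment(params: SimParams, out_dir: str) -> SimulationResult:
    """Run the full generative model and materialize a dataset on disk.

    Produces indexed per-cell and bulk BAMs, the reference FASTA (+faidx),
    a gSNV VCF with FreeBayes-style annotations derived from the bulk
    alignments, and the ground-truth table as TSV.  Byte-identical outputs
    are produced for identical parameters (including the seed).
    """
    rng = np.random.default_rng(params.seed)
    os.makedirs(out_dir, exist_ok=True)
    ref_seq, loci = build_locus_set(params, rng)
    cells = params.cell_names
    truth = TruthTable(loci=loci, cells=cells, clone_of=params.clone_of)
    truth.dropout = sample_dropout(cells, loci, params.p_do, rng)

    ref_path = os.path.join(out_dir, "reference.fa")
    with open(ref_path, "w") as fh:
        fh.write(f">{params.contig}\n")
        for i in range(0, len(ref_seq), 80):
            fh.write(ref_seq[i : i + 80] + "\n")
    pysam.faidx(ref_path)

    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{params.contig}\tLN:{len(ref_seq)}\n"
    L = params.read_length

    cell_bams: dict[str, str] = {}
    cell_dir = os.path.join(out_dir, "cells")
    os.makedirs(cell_dir, exist_ok=True)
    for cell in cells:
        lines: list[str] = []
        for locus in loci:
            for pair in generate_reads(cell, locus, truth, params, rng, ref_seq):
                lines.extend(_sam_lines(pair, params.contig, L))
        bam_path = os.path.join(cell_dir, f"{cell}.bam")
        _write_bam(lines, header, bam_path)
        cell_bams[cell] = bam_path

    # unamplified bulk: germline haplotypes, no dropout, no paralog reads
    bulk_truth = TruthTable(loci=loci, cells=["bulk"], clone_of={"bulk": -1})
    bulk_params = dataclasses.replace(
        params, coverage_model="flat", flat_coverage=params.bulk_coverage_per_allele
    )
    bulk_lines: list[str] = []
    for locus in loci:
        germline = dataclasses.replace(locus, snv=0, eal=0, mutated_clone=-1,
                                       snv_on_galt=-1, eal_on_galt=-1)
        for a in range(2):
            bulk_truth.dropout[("bulk", locus.locus_id, a)] = 0
        for pair in generate_reads("bulk", germline, bulk_truth, bulk_params, rng, ref_seq):
            bulk_lines.extend(_sam_lines(pair, params.contig, L))
    bulk_path = os.path.join(out_dir, "bulk.bam")
    _write_bam(bulk_lines, header, bulk_path)

    vcf_path = os.path.join(out_dir, "gsnvs.vcf")
    _write_gsnv_vcf(vcf_path, loci, bulk_path, params.contig, len(ref_seq))

    truth_tsv = os.path.join(out_dir, "truth.tsv")
    truth.write_tsv(truth_tsv)
    pd.DataFrame(
        {"cell": cells, "clone": [params.clone_of[c] for c in cells]}
    ).to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)

    log.info(
        "simulated %d loci (%d sSNV, %d EAL) for %d cells into %s",
        len(loci), sum(l.snv for l in loci), sum(l.eal for l in loci), len(cells), out_dir,
    )
    return SimulationResult(
        params=params,
        truth=truth,
        out_dir=out_dir,
        reference=ref_path,
        cell_bams=cell_bams,
        bulk_bam=bulk_path,
        gsnv_vcf=vcf_path,
        truth_tsv=truth_tsv,
    )


def gsnv_records(loci: Sequence[TrueLocus]) -> list[GsnvRecord]:
    return sorted(GsnvRecord(l.contig, l.g_pos, l.g_ref, l.g_alt) for l in loci)
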