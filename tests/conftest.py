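"""Shared fixtures: hand-built alignments/VCFs and a small cached simulation."""

from __future__ import annotations

import os

import pysam
import pytest

from clonecall.pipeline import run_on_simulation
from clonecall.simulator import SimParams, simulate_experiment

CONTIG = "t"
CONTIG_LEN = 5000


@pytest.fixture()
def ref_fasta(tmp_path):
    """Deterministic small reference: repeating ACGT pattern."""
    seq = ("ACGT" * (CONTIG_LEN // 4 + 1))[:CONTIG_LEN]
    path = tmp_path / "ref.fa"
    with open(path, "w") as fh:
        fh.write(f">{CONTIG}\n")
        for i in range(0, CONTIG_LEN, 80):
            fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(str(path))
    return str(path), seq


def write_bam(path: str, reads: list[dict], contig: str = CONTIG, length: int = CONTIG_LEN) -> str:
    """Write an indexed BAM from read dicts (name, start, seq, plus overrides)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": length}]}
    reads = sorted(reads, key=lambda r: r["start"])
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for spec in reads:
            a = pysam.AlignedSegment()
            a.query_name = spec["name"]
            a.query_sequence = spec["seq"]
            a.reference_id = 0
            a.reference_start = spec["start"]
            a.mapping_quality = spec.get("mapq", 60)
            a.cigarstring = spec.get("cigar", f"{len(spec['seq'])}M")
            a.query_qualities = pysam.qualitystring_to_array(
                spec.get("quals", "F" * len(spec["seq"]))
            )
            a.flag = spec.get("flag", 0)
            if "mate_start" in spec:
                a.next_reference_id = 0
                a.next_reference_start = spec["mate_start"]
                a.template_length = spec.get("tlen", 0)
            bam.write(a)
    pysam.index(path)
    return path


@pytest.fixture()
def bam_factory(tmp_path):
    def make(reads: list[dict], name: str = "sample.bam", **kw) -> str:
        return write_bam(str(tmp_path / name), reads, **kw)

    return make


def write_vcf(path: str, rows: list[dict], contig: str = CONTIG, length: int = CONTIG_LEN) -> str:
    """Write a small uncompressed VCF with FreeBayes-style INFO fields."""
    contigs = dict.fromkeys([contig] + [r["contig"] for r in rows if "contig" in r])
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c},length={length}>" for c in contigs],
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##INFO=<ID=AO,Number=A,Type=Integer,Description="alt obs">',
        '##INFO=<ID=SAF,Number=A,Type=Integer,Description="alt fwd">',
        '##INFO=<ID=SAR,Number=A,Type=Integer,Description="alt rev">',
        '##INFO=<ID=RPL,Number=A,Type=Integer,Description="alt left">',
        '##INFO=<ID=RPR,Number=A,Type=Integer,Description="alt right">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in rows:
        info = ";".join(f"{k}={v}" for k, v in r.get("info", {}).items()) or "."
        lines.append(
            f"{r.get('contig', contig)}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}"
            f"\t{r.get('qual', 100)}\t.\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def vcf_factory(tmp_path):
    def make(rows: list[dict], name: str = "test.vcf", **kw) -> str:
        return write_vcf(str(tmp_path / name), rows, **kw)

    return make


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 30-locus two-clone dataset with both sSNV and EAL loci."""
    out = tmp_path_factory.mktemp("sim-small")
    params = SimParams(n_loci=30, p_eal=0.2, p_do=0.2, seed=7)
    return simulate_experiment(params, str(out))


@pytest.fixture(scope="session")
def small_sim_result(small_sim):
    return run_on_simulation(small_sim)
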