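# clonecall

Unsupervised discovery of **clonal somatic single-nucleotide variants
(sSNVs) in single cells** by read phasing against germline heterozygous
SNVs (gSNVs), with joint genotyping across the cell population, a
generative simulator with ground truth, and an evaluation harness.

## Who this is for

Single-cell whole-genome data require whole-genome amplification (WGA),
which introduces allelic dropout, amplification errors and — together with
ordinary short-read mapping — alignment artifacts from paralogous
sequence. For lineage tracing and phylogenetics of normal human cells,
where true somatic mutations are rarer than these artifacts, a caller must
be extremely conservative about false positives *and* must distinguish
"unmutated" from "no data". clonecall addresses exactly that setting:
clonally related cells from one individual, sequenced after WGA, together
with an unamplified bulk sample.

## The method in brief

Every base near a gSNV is phased: a fragment carrying both a candidate
site and a gSNV is one of four *tuples* RR/RA/AR/AA (first letter: base at
the candidate site; second: base at the gSNV). A true heterozygous
mutation is consistent with exactly one tuple pair — {RR,AA} or {RA,AR} —
across all cells. Calling proceeds in two stages:

1. **stats** — discover candidate sites: per cell, phased depths N_b, N_R
   vote for an alternative base b when N_b/N_R ≥ α and N_b+N_R ≥ β, or
   N_b ≥ β alone (reference dropout); a site is kept when ≥ ε cells vote
   and the winner holds a γ majority.
2. **analyze** — resolve the consensus tuple pair tp\* by a per-cell vote
   (quorum κ, majority ω); tp\* identifies the *informative allele*, the
   haplotype the mutation rides on. Genotypes are then classified per cell
   from internal/external tuple-depth ratios (d_I, d_E against τ, θ) into
   confidence classes C1 (both alleles seen), C2 (informative allele
   only — callable even under 100% dropout of the other allele) and C3
   (sparse reads). Cells showing both states of the informative allele
   are *conflicts* — the signature of an alignment artifact — and one
   conflicting cell discards the site. Cells with only
   non-informative-allele reads are left uncalled, never called
   homozygous: dropout of the mutated allele cannot produce a false
   unmutated genotype.

Site filters: bulk depth capped at ⌊d + 2.5√d⌋ of the mean bulk depth
(collapsed repeats), at most one call per kilobase, and a mutation in at
least κ (default 2) cells — only clonal variants are reported.

See `docs/methods.md` for the full model, parameters and limitations.

## Worked example

Simulate a small two-clone dataset (12 loci, 25% alignment-artifact loci,
30% allelic dropout), call it, and score it against the ground truth:

```
clonecall simulate --n-loci 12 --p-eal 0.25 --p-do 0.3 --seed 11 --out-dir data
BAMS=$(for b in data/cells/*.bam; do echo --bams $b; done)
clonecall stats $BAMS --bulk data/bulk.bam --gsnv data/gsnvs.vcf \
    --ref data/reference.fa --out candidates.json
clonecall analyze --candidates candidates.json $BAMS \
    --bulk data/bulk.bam --gsnv data/gsnvs.vcf --out calls.tsv
clonecall evaluate --calls calls.tsv --truth data/truth.tsv \
    --cells data/cells.tsv --out metrics.json
cat metrics.json
```

prints

```
{
 "tp": 8,
 "tn": 4,
 "fp": 0,
 "fn": 0,
 "unmatched_calls": 0,
 "sensitivity": 1.0,
 "specificity": 1.0,
 "fdr": 0.0
}
```

All 8 simulated clonal sSNVs were recovered (sensitivity 1.0, a locus
counts as detected when called mutated in ≥ 2 cells) and none of the 4
paralog-artifact loci was called (specificity 1.0, FDR 0.0): at this
dropout level most cells still display both haplotype states of the
artifact, which the conflicting-haplotype rule turns into site-discarding
conflicts. The call table itself is phased:

```
contig  pos    ref  alt  tp_star  informative_base
sim1    2176   G    C    RA/AR    ref
sim1    8180   G    A    RA/AR    ref
sim1    11125  A    G    RR/AA    alt
```

e.g. the variant at `sim1:11125` rides on the haplotype carrying the gSNV
*alternative* base, and each cell's genotype column (het/hom in classes
C1–C3, conflict, or none) is backed by its RR:RA:AR:AA tuple depths.

The same machinery is available as a library (`clonecall.simulator`,
`clonecall.discovery`, `clonecall.genotyper`, `clonecall.evaluation`,
`clonecall.pipeline`), e.g. `clonecall.pipeline.simulate_and_call(...)`
for one-call experiments, plus Ward clustering of cells from shared calls
and an FDR estimator based on biologically implausible genotype
distributions across known clones.

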