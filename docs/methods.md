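# Methods

## The calling model

clonecall targets clonal somatic single-nucleotide variants (sSNVs) in
whole-genome-amplified (WGA) single cells from one individual. WGA data
carry three dominant error modes: allelic dropout (one haplotype amplifies,
the other does not), amplification errors (private to one cell), and
alignment artifacts (EAL — reads from paralogous or structurally divergent
sequence piling onto one locus). The method neutralizes all three with one
device: every base observation at a candidate site is phased to a nearby
heterozygous germline SNV (gSNV) carried in the same read or read pair, so
each observation is attributed to a specific haplotype.

Notation: at a candidate site with reference base R and population
alternative base A, each phased fragment is one of four *tuples* —
RR, RA, AR, AA — first letter the base at the candidate site, second the
base at the gSNV. A true heterozygous mutation is consistent with exactly
one *tuple pair*, {RR,AA} or {RA,AR}, shared by every mutated cell; a true
homozygous-reference genotype shows {RR,RA}.

### Stage 1 — candidate discovery ("stats")

For each gSNV, an analysis window is the envelope of all fragments
covering it, across all cells. Within the window, a cell's phased depths
N_b (alternative base b) and N_R decide its vote for b:

* vote if N_b/N_R ≥ α and N_b + N_R ≥ β (both alleles visible, adequate
  variant fraction and depth), or
* vote if N_b/N_R < α but N_b ≥ β (reference dropout: deep alternative
  support alone). N_R = 0 with N_b > 0 counts as an infinite ratio.

A candidate site is emitted when at least ε cells vote and the winning
base holds at least a γ fraction of the voters (argmax ties are
undecided). Positions where the unamplified bulk itself shows the base
(above a 2% read fraction, with at least two supporting reads so a lone
bulk sequencing error cannot veto a site) are germline or recurrent
artifacts and are excluded, as are the gSNV positions themselves.

### Stage 2 — phased genotyping ("analyze")

Per candidate site and anchoring gSNV, each cell with tuple depth above φ
votes for the tuple pair its reads support: the deeper of the two
heterozygous-compatible pairs, accepted only if the shallower pair is
nearly absent (minor/major depth ratio < ρ) and the winner is internally
balanced (> λ) or its variant-bearing tuple (AA or AR) is the single
deepest tuple. The consensus pair tp\* is finalized with at least κ voters
and an ω majority; tp\* fixes the *informative allele* — the haplotype the
mutation rides on (gSNV-alt for {RR,AA}, gSNV-ref for {RA,AR}).

Genotypes are then classified per cell from the internal/external depth
ratios d_I, d_E of the heterozygous and homozygous tuple pairs:
both-allele calls (het_C1 / hom_C1: d_E ≥ θ and d_I ≥ τ),
informative-allele-only calls (het_C2 / hom_C2: both d_I < τ, the
supporting pair's d_E ≥ θ and the opposing pair's d_E < 1−θ), and
sparse-read calls (het_C3 / hom_C3: any informative-allele reads above
the ξ/χ floors when no gSNV reached the φ depth gate). A cell is a
*conflict* when both C1 conditions hold at once, when its own tuple-pair
vote contradicts tp\*, or when it shows informative-allele reads of both
states (> χ unmutated and > ξ mutated) — the conflicting-haplotype
signature of an alignment artifact. Cells with only
non-informative-allele reads are left uncalled, never called homozygous:
this is what eliminates false unmutated homozygotes under dropout of the
mutated allele. With several anchoring gSNVs, per-gSNV genotypes vote;
the modal genotype needs a ψ majority and the voters a σ fraction of the
gSNVs sharing reads with the site.

Site-level filters: no conflicting cells allowed (max 0), bulk depth at
the site capped at floor(d + 2.5·√d) of the mean bulk depth (collapsed
repeats run deep), at least κ mutated cells (only clonal variants are
reported), and at most one passing site per kilobase — a violating 1-kb
window is dropped entirely, since clustered calls mark poor mappability.

### Parameter defaults

α 0.2, β 10, γ 0.9, ε 2 (discovery); ρ 0.01, λ 0.1, κ 2, ω 0.9, τ 0.1,
θ 0.9, ψ 0.9, σ 0.9, χ 1, ξ 1 (genotyping); φ 2 (tuple-depth gate; κ and
φ are the knobs a user would sweep — κ is both the tp\* quorum and the
minimum number of mutated cells); mapping quality ≥ 2 and base quality
≥ 20 for any counted base. All are exposed in `RunConfig` and as CLI
flags. The printed condition for the tuple-pair vote compares the pair
depths as max/min; only the min/max orientation makes a 0.01 threshold
meaningful, and that is what is implemented. Likewise the het_C2 row is
implemented with d_I < τ: the C2 class is by definition supported by one
allele only (d_I of its pairs is then 0), and a > τ reading is
unsatisfiable — no depth vector with total ≤ 30 satisfies it.

## gSNV filtering

Bulk variant calls (FreeBayes-style annotations) are reduced to usable
anchors: autosomal biallelic SNVs, depth within [15, floor(d+2.5√d)],
QUAL strictly above 10, at least one alternative read on each strand
(SAF/SAR), at least two reads placing the variant on each side (RPR/RPL),
and alternative-allele fraction in [0.20, 0.80]. A region screen drops
gSNVs whose centered 1-kb bulk window contains more than 10 positions
with > 10% non-reference reads (the gSNV itself not counted): such
windows look "too heterozygous" and mark collapsed or divergent sequence.
`phasable_fraction` reports the genome fraction within a chosen reach
(650 bp by default, the mean library insert) of any retained gSNV.

## The simulator

The generative model reproduces the study conditions: a set of
well-separated two-site loci (gSNV G heterozygous everywhere; candidate
site S 11–50 bp away), two clones of 10 cells, a randomly chosen clone
heterozygous at each sSNV locus (mutation phased to a random G
haplotype), and with probability p_EAL an artifact locus instead: its own
cells homozygous reference at S, plus a paralogous locus with the
opposite state whose reads map to the same coordinates. Dropout is an
independent Bernoulli(p_DO) per (cell, locus-or-paralog, allele); a
dropped allele emits nothing. Coverage per surviving allele is exactly
30 fragments (flat model) or negative-binomial with configurable mean and
dispersion (the "empirical-like" stand-in for amplification bias). Reads
are proper 2×150 bp pairs, mean insert 650 bp, with uniform substitution
errors at 0.1%; the site-covering read always spans both G and S. The
unamplified bulk is built from the germline haplotypes at ~40× with no
dropout and no paralog reads, and doubles as the source of the annotated
gSNV VCF.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: chimeric WGA molecules and branching artifacts,
indels and structural variation beyond the paralog construct, GC and
mappability bias, real empirical coverage distributions (the original
study sampled donor reads and donor coverage, which are not
distributable), and paralogs that diverge at positions other than the
two sites. Real-data figures of merit (donor gSNV counts, genome
coverage fractions) are out of desk-scale reach; the real-data FDR
procedure (implausible genotype distributions across known clones) is
implemented and exercised on constructed matrices only.

## Evaluation

Experiment 1 (clonal detection): a locus is predicted when a reported
site at its S position is mutated in ≥ 2 cells; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) (denominator: artifact loci), FDR = FP/(FP+TP);
0/0 ratios are reported as missing. Experiment 2 (genotype accuracy,
p_EAL = 0): every (cell, locus) is binned into true/false/no-prediction
het and hom; conflicts count as no-prediction. Cell clustering uses the
shared-call distance (−1 per concordant, +1 per discordant site over
sites where both cells have calls; no shared sites → unknown), Ward
linkage, and a k=2 cut. The implausibility FDR estimator needs known
clone labels: sites mutated within one clone are plausible, sites
mutated in two clones with at least one unmutated cell are implausible,
cross-clone sites with no unmutated cell are excluded as likely germline.

## Numerical and design choices

* Ratios with zero denominators (d_I, d_E on empty pairs) evaluate to 0,
  failing every ≥ threshold — the conservative direction.
* Tuple-pair depth ties abstain from the tp vote; argmax ties in
  discovery leave the site undecided.
* Ward clustering requires proper distances: unknown pairwise entries are
  imputed as 0 (neutral) and the matrix is shifted by its minimum to be
  non-negative; rank order is preserved.
* The C3 path runs only when no anchoring gSNV reached tuple depth φ —
  a deep cell whose reads are all non-informative stays uncalled rather
  than being re-inferred from the same reads.
* A per-gSNV genotype of `none` abstains from the cross-gSNV vote rather
  than counting toward the ψ majority.
* Sites are reported when mutated in ≥ κ cells; requiring additionally an
  unmutated cell is available (`min_unmutated_samples`) but off by
  default, matching the published two-cells rule.
* Mate pairs disagreeing at a position discard the whole fragment there.
* Simulated loci are spaced 3 kb apart so windows and the 1-kb density
  filter cannot couple neighbours; the validation experiments use 306
  loci (the published locus count) for the dropout grids, 600 loci for
  the artifact/specificity condition, and 100 loci per seed for the
  clustering checks — sizes chosen to keep sampling error well inside the
  asserted bounds.

## Known limitations

Only sites phasable to a gSNV are analyzable (~50% of the genome at
typical heterozygosity and 650 bp inserts); unphased reads are never
used, including for C3 calls. Only biallelic SNVs are handled. The caller
assumes the cells are clonally related — it reports only variants shared
by ≥ κ cells and cannot type private mutations. Copy-number variation is
not modelled; the bulk depth cap is the only defence against it.
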