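# Methods

This note documents the models and numerical choices behind `pearpop`:
what each statistic computes, what the synthetic cohort generator does and
does not emulate, and where genuinely open design decisions were made.

## Genotype substrate

Every analysis operates on a samples × sites matrix of diploid
allele-dosage calls (0/1/2 alternate copies, or missing), restricted to
biallelic SNPs. Multi-allelic records and indels are skipped at VCF
ingestion, never split; half-calls count as missing. Site filtering keeps
sites whose missing-call fraction is *strictly* below the threshold
(default 0.5), optionally within every analysis group rather than
cohort-wide — the "common SNP" rule applied before cross-group scans.
Upstream read mapping and genotype calling are out of scope: the library
starts from called genotypes.

Coordinates are 1-based inclusive at the VCF/GFF3 surface, 0-based
half-open internally and in all BED output.

## Windowed statistics

Windows default to 10 kb (5-kb step for diversity profiles; non-overlapping
for selection and IBD scans), anchored at position 1 of each chromosome,
with the trailing partial window kept.

**θπ** uses the exact per-site configuration under missingness: with C
called allele copies and c alternate copies, per-site π = 2c(C−c)/(C(C−1)),
i.e. the mean difference over all C-choose-2 copy pairs with pairwise
deletion. The windowed value divides the summed π by the window length in
bp; a per-window callable-site count can be substituted when an effective
length is known (both conventions appear in the literature and the
denominator choice is reported with the output).

**θw and Tajima's D** need one sample size per window while missingness
makes C vary by site; the window uses the rounded harmonic mean of per-site
C. This is a documented approximation — Tajima's variance constants assume
fixed n — and is exact when there is no missingness. D is undefined (NaN)
for windows with S = 0 and at n = 2, where the variance expression
vanishes.

**F_ST** defaults to the Hudson/Bhatia estimator: per site,
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
den = p₁(1−p₂) + p₂(1−p₁), combined per window as the ratio of sums
(ratio of averages). Sites monomorphic for the same allele in both groups
contribute nothing; windows with no usable site are missing. Negative
estimates are reported, not clamped. Weir–Cockerham (1984) variance
components (using observed heterozygosity, r = 2) are available via
`estimator="wc84"`; on the default cohort the two track each other with
correlation > 0.95.

**ROD** = 1 − θπ_cul/θπ_wild per window, missing where θπ_wild = 0.

**Per-feature-class diversity** assigns every site to exactly one class by
the precedence CDS > UTR > intron > other-mRNA > intergenic, implemented by
painting each chromosome base-by-base (introns are mRNA spans minus the
exon union); the per-class denominator is the painted bp count.

**d/2T** converts a locus diversity d and a divergence time T (years) into
a per-site, per-year rate — the factor 2 counts the two lineages separating
the sampled alleles.

## Selection scans

A sweep window must simultaneously sit in the top 5% of F_ST, have
ROD > 0.5, and sit in the bottom 10% of Tajima's D — D of the cultivated
member of the compared pair, since domestication sweeps act on that
lineage (configurable). A balancing window needs the bottom 5% of F_ST,
top 5% of D and top 10% of θπ. Quantile cuts are computed genome-wide per
comparison; the qualifying set has size ⌈qN⌉ with ties at the cut included
and missing values excluded from N. A window missing any statistic never
qualifies (conservative). Qualifying windows adjacent on the grid merge
into maximal regions; no gap-bridging. Gene annotation lists any gene
overlapping a region by ≥ 1 bp on half-open intervals.

Admixed accessions (recognizable by their species label) are excluded from
scan groups, mirroring the practice of removing admixed genotypes before
sweep detection.

## IBD, AverIBD and painting

The p-distance between unphased diploids is the allele-content difference
|g_i − g_j|/2 averaged over co-called sites; two heterozygotes are at
distance 0 under this metric (the natural reading of p-distance for dosage
data). A window is evaluable with > 10 co-called SNPs and is IBD when
similarity > 0.95 (both strict). P_ij is the percentage of IBD windows
among *evaluable* windows; AverIBD averages P_ij over group × reference
pairs with self-pairs excluded (the formula is silent on both points;
these readings are documented here). Painting assigns each window of a
target accession to the donor pool containing its most similar member,
gated by the same similarity cut; ties and sub-threshold windows stay
unassigned.

## LD

Two-locus haplotype frequencies are estimated by EM over unphased
genotype pairs (only the double heterozygote is phase-ambiguous),
initialized at linkage equilibrium **and at both Fréchet extremes**, keeping
the highest-likelihood solution: the observed-data likelihood can be
bimodal in D, and the equilibrium start alone can converge to a local
maximum. Iteration stops at |Δ| < 1e-10 or 1000 iterations. r² and D′
follow from the converged frequencies. Site pre-filters: MAF ≥ 0.05,
genotyping rate ≥ 0.6, exact-HWE p ≥ 0.01 (conditional enumeration test),
pairs within 200 kb — the parameter set conventionally used for
orchard-crop panels. Decay profiles use 100-bp bins to 2 kb and 1-kb bins
beyond (pear LD collapses within hundreds of bp); the half-decay distance
is the midpoint of the first bin at or below half the *global* maximum of
the binned means, scanning left to right. For genome-scale inputs the
profile can thin eligible sites to an evenly spaced subset
(deterministic); thinning trades short-range pair density for speed and
should be disabled when the short-distance bins matter.

## Phylogeny

p-distances (above) feed a textbook neighbor-joining implementation:
Q-criterion pair selection with ties broken toward the lowest index pair,
standard branch-length and reduction formulas, negative branch lengths
clamped to zero. NJ is exact on additive matrices, which the tests use as
an oracle (and cross-check against dendropy's independent NJ). The
bootstrap resamples SNP sites with replacement (as multinomial site
weights), rebuilds NJ per replicate, and reports the majority-rule
consensus with percent bipartition support; branch lengths are carried
over from the full-data tree where its bipartitions survive. Trees are
dendropy objects; rooting by an outgroup is post-processing and off by
default.

## QTL colocalization

The observed statistic counts sweep windows intersecting ≥ 1 QTL interval.
The null re-places each chromosome's windows uniformly at random on its
10-kb grid (count preserved, slots drawn without replacement), keeping QTL
positions fixed — the QTLs are the biology, the sweep calls are what is
being tested. p = (1 + #{null ≥ observed})/(1 + N), one-sided for
enrichment; a circular-shift scheme that preserves window clustering is
available. 100,000 permutations reproduce full-scale practice; desk-scale
runs default to 2,000.

## The synthetic cohort generator

The generator produces the statistical structure the analyses assume, not
a demographic reconstruction:

* **Frequencies**: ancestral alternate-allele frequencies with density
  ∝ 1/p on [0.02, 0.98] (a truncated neutral-like spectrum), drifted to
  each region by a Balding–Nichols beta draw with F_region (default 0.3, a
  stand-in for the multi-million-year Asian/European divergence), then
  from wild to cultivated with F_status (default 0.09, chosen so the
  expected cultivated diversity loss matches the ~8.6% reduction of the
  genome-wide Asian diversities, since E[θπ_cul] = (1−F_status)·E[θπ_wild]).
* **Genotypes**: two independent allele copies per sample; uniform
  genotype dropout (default 5%) exercises pairwise-deletion code paths.
  Sites monomorphic across the cohort are dropped.
* **Sweeps**: inside a planted interval the target group's frequencies are
  pushed toward fixation of the major allele with strength `intensity`; a
  fraction (0.3) of sweep sites keep a thin minor-allele tail
  (U(0.01, 0.04)), representing post-sweep mutations. This makes the three
  sweep criteria fire together: θπ collapses (ROD → 1), differentiation
  from the wild group rises, and the residual rare variants drive D
  negative. The tail is dense enough that even a five-sample group retains
  a few segregating sites per 10-kb window — without it, windows with
  S = 0 have undefined D and are (correctly) disqualified by the scan.
* **Balanced locus**: a small number of haplotype classes at equal
  frequency in every group, with exactly half the classes carrying the
  alternate allele at each site — the deep-coalescence structure of a
  long-lived balanced polymorphism. Locus allele frequencies sit near 1/2,
  giving high θπ, Tajima's D above 2, and F_ST near 0.
* **IBD**: planted segments copy one sample's genotypes into another over
  an interval (before dropout, so co-called similarity is exactly 1).
* **Admixture**: one accession is a fixed-length block mosaic (default
  500 kb, random phase offset) copied from random donors of two cultivated
  pools; donor-group allocation is greedy on bp so the realized genome
  proportion matches the configured one to within half a block.
* **LD blocks** (optional, off by default): genotypes drawn through a
  founder-haplotype pool per block (default 6 founders / 2 kb), which
  produces r² decaying on the block-length scale; the default
  frequency model draws sites independently and therefore has *no* LD
  beyond what planted copying and finite samples induce.

Default scale: 2 chromosomes × 5 Mb, ~5 SNPs/kb, 22 + 1 accessions —
seconds on one CPU. The `TruthSet` records every planted feature in
BED-ready form and is the oracle for all recovery tests.

What passing tests on this cohort do **not** show: behaviour under real
linkage and recombination gradients, under population structure beyond the
two-level hierarchy, under genotyping error correlated with depth, or at
genome scale. The generator is a calibration instrument for the wiring of
the statistics, not evidence about any real pear panel.

## Calibration experiment sizes

The permutation-test uniformity check runs 200 repetitions of a
2,000-permutation test on a 2 × 50 Mb grid with 500 windows per
chromosome and QTLs covering half of each chromosome. The wide grid is
deliberate: the overlap count is integer-valued, and on a small grid its
point masses (~0.13) dominate the Kolmogorov–Smirnov distance to the
continuous uniform no matter how correct the test is; with the wider
support the discreteness contribution falls well below the KS critical
value at α = 0.01.

## Pipeline

`run_pipeline` executes simulate (or load) → filter → windowed stats →
sweep/balancing scans → LD → IBD + painting → bootstrap NJ tree → QTL
enrichment from one YAML config. A single global seed derives per-stage
seeds by hashing `seed:stage`; all outputs are plain text (VCF, TSV, BED,
GFF3, Newick, JSON) and the run manifest records parameters and SHA-256
hashes, so identical config + seed reproduces byte-identical artifacts. A
stage re-runs when any of its outputs is missing or an upstream stage
re-ran, so deleting one stage's outputs regenerates only it and its
dependents.

## Known limitations

* No coalescent or recombination-explicit simulation (msprime would be the
  tool for that); the generator trades realism for analytically checkable
  expectations.
* Tajima's constants under missingness use a single per-window n; windows
  with highly uneven per-site call counts are approximated.
* The windowed IBD rule is the similarity heuristic itself — no HMM
  segmentation — so single-window gaps inside true segments can appear at
  segment boundaries or low-SNP windows.
* LD-block detection (Gabriel intervals) is out of scope; D′ is computed
  and reported but unused downstream.
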