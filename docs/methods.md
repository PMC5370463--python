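# Methods

## Scope and model

`triadscan` implements a windowed genome scan for allelic admixture between
populations and a case-control scan for haplotypes associated with
domestication. All statistics operate on biallelic SNP dosages for diploid
samples; phasing, imputation, multiallelic sites and genotype-likelihood
calling are out of scope. Internal coordinates are 0-based half-open
everywhere; the VCF and GFF3 readers convert on ingest and writers convert
back.

## Site-level processing

**Singleton removal.** SNPs whose minor allele is carried by exactly one
accession are removed before any scan (they inflate terminal branches and
carry no population signal). The minor allele is the one with the smaller
allele count among non-missing calls; when counts tie, the site is removed
if either allele is private to a single accession. The filter is
idempotent and order-preserving.

**Polarization.** The ancestral allele at a site is the allele fixed among
non-missing outgroup calls. A heterozygous outgroup call counts as
polymorphic and drops the site — polarization must be unambiguous. Sites
where any population has fewer than `min_calls` (default 2) non-missing
allele calls are also dropped; frequencies from a single allele are
uninformative and destabilize f_d. Missing genotypes are excluded from
frequency denominators rather than imputed, so the per-site call count n_k
varies.

**Which sites feed which statistic.** π and d_XY are invariant under
relabelling of alleles, so they are computed from raw alternate-allele
frequencies over *all* sites with enough calls (π: ≥ 2 allele calls in the
population; d_XY: ≥ 1 in each population). Conditioning them on successful
outgroup polarization would make their denominators depend on outgroup
state — under an infinite-sites mutation model that exclusion biases π
upward by L/(L−dropped) — and an outgroup is not needed to define either
quantity. Only the pattern statistics (D, f_d) are restricted to the
polarized site set.

**Accessible length.** Upstream variant calling is assumed to keep only
positions covered in every accession, so positions absent from the variant
matrix count as covered and monomorphic: the default denominator of π and
d_XY is the window span minus sites unusable for that statistic
(`accessible="span"`). `accessible="variant"` normalizes by the usable
variant-site count instead, which is the right choice when no such
coverage guarantee holds.

## Window statistics

Windows are non-overlapping, default 5,000 bp, tiling each chromosome; a
short terminal window is retained. Windows with fewer than `min_snps`
(default 10) informative SNPs have every statistic set to missing but are
still emitted; they are excluded from outlier quantiles. The estimators:

* π = Σ n/(n−1) · 2p(1−p) / L (unbiased per-site heterozygosity).
* d_XY = Σ p_A(1−p_B) + p_B(1−p_A) / L.
* ABBA = (1−p1)p2p3(1−pO), BABA = p1(1−p2)p3(1−pO);
  D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA). The frequency weighting is used
  throughout; binary pattern counts are its fixed-allele special case.
* f_d = S(P1,P2,P3,O)/S(P1,P_D,P_D,O), S = Σ(ABBA−BABA), with P_D chosen
  per site as the higher-frequency role among {P2, P3}. f_d is reported
  missing (not 0) when the window's D < 0, following the estimator's
  published validity domain (configurable), or when the denominator is
  ≤ 0. In principle a window mixing sites with p1 > p2 ≥ p3 can push f_d
  slightly above 1 even with D ≥ 0; this does not occur under the
  simulator's genealogies and no clipping is applied.

**Genome-wide D** uses a block jackknife for its standard error. Blocks
are 1 Mb of consecutive windows, shrunk adaptively so that at least 20
blocks exist — on short simulated genomes a handful of blocks would make
the variance estimate itself too noisy to use.

## Introgression calling

A window is flagged when it belongs to the top 5% of defined f_d values
genome-wide AND its d_XY(P2,P3) is below the mean over all windows with
defined d_XY. The receptor–donor pair is the right one for both the flag
and the genome mean: gene flow makes P2 and P3 coalesce more recently than
the species split, so the d_XY reduction concentrates in that pair.

The f_d condition selects exactly ⌈0.05 · N_defined⌉ windows: the top-k by
f_d with ties at the boundary broken deterministically by genomic order.
This keeps the flagged count exact and reproducible on any input,
including degenerate tables where many windows tie.

Runs of at least 3 strictly adjacent flagged windows condense into blocks
(a single unflagged window breaks a run; `max_gap` relaxes this). Blocks
report member-window means, overlapping-gene counts (≥ 1 bp overlap,
half-open intervals) and the summed introgressed length. Outlier quantiles
are computed per triad, not pooled, since each comparison has its own f_d
scale.

The Kruskal–Wallis helper compares labeled d_XY window-value groups; if
every value is identical the statistic is undefined and (H=0, p=1) is
returned with a warning.

## Domestication scan

Domesticated accessions are cases, wild ones controls. Two log10 Bayes
factors per marker:

* **bf1** (single marker): Beta-binomial marginal likelihood of case and
  control allele counts under separate frequencies versus pooled,
  m(k, n) = B(k+a, n−k+b)/B(a, b) with prior Beta(1,1) by default,
  bf1 = log10[m_case · m_control / m_pooled]. Monomorphic markers return 0
  by convention. The statistic is exactly symmetric under label swap.
* **bf2** (local haplotype): diploid genotypes expand to two
  pseudo-haplotypes per sample (unphased heterozygotes get a random phase
  from a seeded generator; with mostly-inbred material heterozygosity is
  rare, so the impact is bounded and logged). Around each core marker the
  window of ±`flank` markers (default 10) is clustered by Hamming-distance
  k-medoids (k = 2) with deterministic farthest-point initialization and
  lowest-index tie-breaks. bf2 is the Beta-Bernoulli Bayes factor for
  per-cluster versus pooled case rates. Samples descending from one recent
  haplotype — the signature a sweep leaves in the cases — land in one
  cluster, loading it with case labels. Windows with fewer than two
  distinct haplotypes give bf2 = 0. Cluster assignments depend only on
  genotypes, so the permutation null reuses them, making label
  permutations cheap.

**Permutation null.** Case/control labels are shuffled preserving group
sizes; bf1/bf2 recomputed per permutation (default 1 permutation, as in
the published workflow). Suggested thresholds are the null maxima, or a
configurable quantile; the published fixed cutoffs (2COD: bf1 ≥ 3,
bf2 ≥ 3.5; DMA: bf1 ≥ 3.3, bf2 ≥ 3) are available as per-design defaults.

**Effect classification.** Each marker is classified against every
overlapping transcript: 5'/3' UTR by position; within CDS the codon is
rebuilt from the reference honoring strand and phase and the substituted
codon decides synonymous / nonsynonymous / stop_gained / stop_lost;
splice_site is the first or last 2 bases of an intron; otherwise intron or
intergenic. Conflicts across transcripts resolve by severity
(stop > splice > nonsynonymous > UTR > synonymous > intron). A transcript
whose CDS length is not divisible by 3 is flagged; its CDS markers cannot
be assigned a codon effect and are reported as synonymous with
`flagged=True`, so they never support a candidate (conservative).
"Regulatory region" means annotated UTRs only, not promoters.

**Candidate genes** need ≥ 2 markers that pass both Bayes-factor
thresholds (an either/or switch exists) and carry a qualifying category
(UTRs, nonsynonymous, splice site, stop gained/lost).

## Synthetic data

The generator reproduces the *structure* the scans key on, not any real
genome. Windows are independent (no intra-window recombination — matching
the per-window granularity of the statistics) and each draws one
genealogy:

* species: (((P1,P2):t12, P3):t123, O):tO;
* introgressed: P2 and P3 coalesce at t_admix < t12;
* discordant (incomplete lineage sorting, probability `p_ils`, split
  evenly between pairs (P2,P3) and (P1,P3)): the discordant pair coalesces
  *above* the species root at t123 + e1 and joins the third lineage after
  e2, with e1, e2 ~ Exp(θ_anc).

Branch lengths are expected substitutions/site; branch mutations are
Poisson(length × window span) under infinite sites at distinct integer
positions; within-population variation is a star tree adding
Poisson(θ_tip × span) private mutations per haplotype. Closed forms used
for calibration: E[π] = 2·θ_tip and E[d_XY] = branch path + 2·θ_tip. The
two discordant pair choices are equally likely, so genome-wide D has
expectation 0 without gene flow — Patterson's D is only defined where
discordant genealogies exist, so the D-calibration runs with p_ils > 0
while the d_XY closed-form calibration uses the pure species tree.
Introgressed windows are placed as contiguous tracts (geometric length,
mean 5 windows), the shape recombination leaves after a pulse and the
shape block condensation is built to find. Defaults: t12 = 0.01,
t123 = 0.02, tO = 0.05, t_admix = 0.002, θ_tip = 0.002, θ_anc = 0.002,
8 haplotypes per population.

Synthetic gene models put one gene per window (3 exons, 2 introns, CDS
length divisible by 3, alternating strand) so block annotation and effect
classification are exercised on both strands.

The domestication panel draws background derived-allele frequencies from a
U-shaped scaled Beta(0.4, 0.4) (mimicking a neutral frequency spectrum)
at ~12 markers/kb in genes (resequencing-scale density), and simulates
each sweep as: all case haplotypes identical to one founder haplotype
across the sweep span (gene body ± 1.5 kb of hitchhiked flank), controls
segregating; a fraction (0.35) of sweep-span markers are founder-marking
variants — derived on the founder but rare (frequency 0.02–0.15) among
controls — the hitchhiked variation a sweep drags to fixation. Default
panel: 50 genes, 3 sweeps, 6 case / 26 control haplotypes.

What the simulator does **not** model: within-window recombination and
mosaic genealogies, linkage between windows, background selection,
coalescent noise within populations (star tips are exchangeable),
sequencing error and missingness patterns, and realistic gene structure
beyond the fixed template. Passing tests therefore demonstrate estimator
correctness and the scans' ability to recover the designed signal
structure, not performance on real resequencing data.

## Numerical conventions

* All randomness flows from one seeded `numpy` generator per dataset;
  identical seeds give byte-identical output files.
* Mutation positions are drawn without replacement per window, so
  infinite-sites collisions cannot occur; if a window ever requests more
  mutations than positions, the surplus is skipped with a warning.
* f_d quantile ties: top-k selection, stable order by (chrom, start).
* k-medoids: ≤ 20 update iterations; every tie (initialization,
  assignment, medoid update) breaks to the lowest index.
* Kruskal–Wallis on all-constant input returns p = 1 with a warning
  rather than raising.
* Test and verification problem sizes — 500-window calibration genomes,
  a 1000-window recovery genome, a 50-gene sweep panel and a 150-gene
  null panel (~5,300 markers) — were chosen as the smallest sizes at
  which the 3-SE calibration bands and enrichment tests are stable.

## Known limitations

* The local-haplotype Bayes factor is a deterministic clustering stand-in
  for hidden-Markov haplotype inference; it shares the design (case
  sharing vs segregating controls, permutation calibration) but not the
  model, so its absolute values are not comparable to HMM-based Bayes
  factors — only to its own permutation null.
* bf2's clustering window is marker-count-based, not distance-based, so
  its genomic footprint varies with marker density.
* Direction of gene flow is fixed by the triad design (P3 → P2); the scan
  does not infer directionality or date events.
* π after singleton removal is deflated by construction; diversity
  comparisons should use the unfiltered matrix (`--keep-singletons`).
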