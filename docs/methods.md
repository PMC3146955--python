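# Methods

## Scope and data model

`sweepscan` operates on phased biallelic SNP panels held in a
`HaplotypePanel`: an int8 haplotype matrix (two rows per diploid), a variant
map (chromosome, 1-based position, ancestral-allele annotation, placement
flag) and a sample sheet with population labels. Input is phased VCF (read
via cyvcf2; `INFO/AA` supplies the ancestral allele) or a plain-text
`hap_tsv` dialect designed to be deterministic and diff-able. Non-autosomal
chromosomes (X/Y/MT) are dropped at read time; missing calls are allowed only
pre-phasing and are excluded by quality control.

Quality control produces two analysis datasets. The *LD dataset* (for r² and
|iHS|) removes samples with ≥ 5% missing genotypes, unplaced variants,
variants without a known ancestral allele, and variants with pooled
MAF < 0.05. The *F_ST dataset* keeps low-MAF and monomorphic loci, because
fixed differences carry most of the differentiation signal. Samples are
filtered before variants; removed variants are charged to the first matching
reason in the fixed order unplaced → no-ancestral → low-MAF so that report
counts reconcile exactly.

## |iHS|

EHH for a core allele at a target marker is the identical-pair probability
among carrier haplotypes over the closed interval from core to target;
widening the interval only refines the haplotype partition, so EHH is 1 at
the core and non-increasing outward (a property the tests verify against a
brute-force pair-enumeration oracle). iHH integrates EHH against physical
distance by the trapezoid rule on each side of the core, stopping at the
first marker where EHH < 0.05 and linearly interpolating the crossing
position; the integrand is the EHH curve itself down to the floor value at
the crossing. No genetic map is used: `ln(iHH_A/iHH_D)` is invariant under
any global rescaling of positions, so base pairs suffice for a chip panel
without a map.

Numerical and policy choices:

* **Chromosome ends.** If EHH never reaches the floor before the terminal
  marker, the default policy invalidates the record (reason `edge`) rather
  than integrating a systematically truncated area; a `truncate` policy is
  available.
* **Gaps.** An optional `max_gap_bp` invalidates cores flanking very large
  inter-marker gaps; it is off by default, since chip panels retain windows
  with multi-Mb gaps and the empirical standardization absorbs panel-wide
  effects.
* **Standardization.** Valid raw scores are standardized to mean 0 and
  variance 1 (n−1 denominator) within 20 equal-width derived-allele-frequency
  bins; bins with fewer than 10 records merge into their nearest occupied
  neighbour. Within-bin moments are exact to machine precision by
  construction; the acceptance script recomputes them from a full scan.
* Records with fewer than two carriers of either allele, or zero area, are
  invalid with explicit reasons and excluded from bin statistics.

Cross-validation (`split_half_validation`) splits individuals at random into
halves, scans each, and correlates |iHS| across SNPs valid in both halves.

## Bayesian F_ST

Each population's allele frequency gets its conjugate Beta posterior under a
non-informative prior — uniform Beta(1,1) by default, Jeffreys Beta(½,½) by
flag; the prior and the number of draws (default S = 500) are explicit
parameters because no canonical values exist. Joint frequency draws map
through the parametric definition `s_p²/(p̄(1−p̄))` with **population-variance
divisor r**, chosen so that complete opposite fixation (0, 1) gives exactly 1
and identical frequencies give exactly 0; when all populations are fixed for
the same allele the statistic is 0 by continuity. Posterior means and SDs
are plain draw summaries. Multi-population mode uses unweighted frequencies
(no sample-size weighting).

A consequence of the divisor-r definition worth stating: for r = 2
populations diverged under Balding–Nichols with parameter F, the per-locus
expectation of this statistic is approximately F/(2 − F), not F (at r = 2 the
between-population sample variance with divisor r estimates half the ensemble
variance). The recovery tests therefore compare the posterior means with a
Monte-Carlo oracle evaluated on the generator's true frequencies, and verify
the ensemble identity E[(p_k − p)²/(p(1−p))] = F directly; genome-wide means
are also checked to be strictly monotone in the generator's F.

`random_split_fst` implements the null comparison: one population split at
random into two pseudo-populations. The resulting per-locus posterior means
concentrate near zero but are intrinsically right-skewed (the statistic is a
non-negative ratio of quadratic forms), which matters for the clustering
step below.

## Mixture clustering

Per-locus F_ST posterior means are clustered with hand-written EM for
K-component univariate normal mixtures: quantile-based initial means with
per-restart jitter (10 restarts), a variance floor of 1e−6 against the
degenerate spike likelihood, convergence on relative log-likelihood change
< 1e−8, and a per-iteration monotonicity assertion (a decrease raises,
rather than being silently accepted). Components are reported sorted by
decreasing mean so "the first cluster" is always the most differentiated
fraction of loci. K is selected by AIC with 3K − 1 free parameters (K means,
K variances, K − 1 weights); ties break toward smaller K.

Because the null F_ST distribution is right-skewed, AIC on raw posterior
means typically prefers K > 1 even for undifferentiated data — the extra
components stack to model skew, and the *fitted density remains unimodal*.
The tests therefore distinguish the shape question (unimodal fitted density
on null data, bimodal on genuinely structured data, judged by density-peak
prominence) from the component-count question. Users comparing K across
panels should do the same rather than reading K literally as the number of
selection regimes.

## Windows, thresholds, overlap, enrichment

Window index is `floor((pos − 1)/500 kb)`; windows without SNPs are omitted,
not zero-filled, so conservation identities hold exactly (Σ n_snp·mean =
Σ per-SNP stat). The outlier threshold is the linear-interpolation empirical
quantile of window means (upper 5% for |iHS|, upper 2.5% for F_ST), with
strict `>` flagging so complete ties flag nothing; each population
comparison is thresholded separately. Overlap reporting intersects the
significant sets on a common window grid.

The enrichment test classifies each significant window midpoint by the
number of annotated genes in the 1-Mb bracket around it (clipped at
chromosome ends; partial overlap counts), samples random positions uniformly
with per-chromosome counts matched exactly to the significant windows, and
applies a Pearson χ² (1 df, no continuity correction) to the resulting 2×2
table. The gene-count cutoff defining "poor gene content" has no defensible
universal default and is a required parameter. Type-I behaviour is verified
by simulation: with uniformly placed windows the p-values stay near-uniform
over 500 replicates.

## Synthetic panel generator

The generator emulates the relevant features of a 50K-chip multi-breed
panel, not genealogical truth:

1. ancestral frequencies uniform on (maf_floor, 1 − maf_floor) — a chip
   ascertainment-flattened spectrum rather than a neutral site-frequency
   spectrum;
2. per-population frequencies from the Balding–Nichols Beta model with
   divergence F per population (panels spanning F ≈ 0.02–0.3 emulate the
   observed range from closely related to strongly diverged breed pairs);
3. per population, founder haplotypes drawn site-wise, then each sample
   haplotype generated as a founder mosaic with switch probability
   `1 − exp(−recomb_per_bp · gap)` between adjacent SNPs (default
   2e−7/bp), giving distance-decaying LD at O(n·m) cost;
4. sweeps injected by copying one carrier haplotype over random
   non-carriers around a core SNP until the target derived frequency is
   reached, each copy extending an Exponential(L_sweep) distance to either
   side — directly producing the long conserved haplotype that |iHS|
   detects, with controllable extent.

Ancestral alleles are known by construction (allele 0). All randomness
derives from a single seed; identical configurations give byte-identical
text fixtures. `suitable_core_pos` selects a core SNP with moderate derived
frequency (default 0.1–0.5) — a sweep acts on an allele that has not yet
risen, and injecting at an already-near-fixed core produces no signal.

What the generator does **not** emulate: coalescent genealogies and their LD
fine structure, mutation-rate or genotyping-error realism, ascertainment
bias beyond the flat frequency spectrum, admixture, and family structure.
Passing tests therefore demonstrate correctness of the statistics and power
against the *injected* signal class, not calibrated power for real breeds.

## Problem sizes and defaults

Defaults are chosen as desk-scale stand-ins for the chip setting: 2,000 SNPs
per 50–60 Mb chromosome (≈ the 40K-SNP genome-wide density), 50 diploids per
population, S = 500 posterior draws, 20 frequency bins (min 10 records),
EHH floor 0.05, 500-kb windows, 1-Mb enrichment brackets. Power and
recovery tests run at these sizes with 25–50 seeded replicates; the
acceptance script scans one 2,000-SNP panel. The CLI fans a single global
seed out to per-stage child seeds via `numpy.random.SeedSequence`.

## Known limitations

* iHS records near chromosome ends are conservatively excluded by default;
  panels with few long chromosomes lose proportionally more cores.
* The divisor-r parametric F_ST is downward-biased for the ensemble F at
  small r (see above); comparisons across panels with different numbers of
  populations should use the same r.
* EM restarts make the mixture fit reproducible under a seed but global
  optimality is not guaranteed for poorly separated components.
* The enrichment χ² treats the matched random positions as a fixed
  comparison sample, as the window counts are small relative to the genome;
  it does not model spatial autocorrelation of gene density.
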