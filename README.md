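# sweepscan

Genome scans for signatures of recent positive selection in multi-population
SNP-chip panels (livestock-scale: tens of thousands of phased autosomal
biallelic SNPs, 2–7 populations), combining two complementary statistics:

* **|iHS|** (integrated haplotype score) — a haplotype statistic sensitive to
  partial selective sweeps: a beneficial allele rising in frequency drags a
  long shared haplotype with it, so extended haplotype homozygosity (EHH)
  decays more slowly around the selected (derived) allele than around the
  ancestral allele at the same site.
* **Bayesian F_ST** — a site-frequency statistic sensitive to selection that
  has driven alleles to different frequencies in different populations, with
  locus-wise posterior distributions instead of point estimates, and
  normal-mixture clustering of the posterior means to expose groups of loci
  under different evolutionary regimes.

The package is aimed at population geneticists who want a tested, seeded,
end-to-end pipeline — including a synthetic-panel generator with injectable
sweeps, so every stage can be validated without access to proprietary
genotypes.

## The statistics

For a core SNP with ancestral/derived allele known, EHH at a marker is the
probability that two random haplotypes carrying the core allele are identical
over the interval from the core to that marker,

```
EHH = Σ_h C(c_h, 2) / C(c, 2)
```

over groups of identical sub-haplotypes among the `c` carriers. iHH is the
area under EHH versus distance, truncated by linear interpolation where EHH
crosses 0.05, summed over both sides; the unstandardized score is
`ln(iHH_A / iHH_D)`, standardized to mean 0 and variance 1 within
derived-allele-frequency bins. Large |iHS| marks unusually long haplotypes
around one of the two alleles.

The Bayesian F_ST draws each population's allele frequency from its conjugate
Beta posterior under a non-informative prior (uniform by default) and maps
each joint draw through the parametric definition

```
F_ST = s_p² / (p̄(1 − p̄)),   s_p² = (1/r) Σ_k (p_k − p̄)²
```

so that `(0, 1) → 1` (fixation for different alleles) and `(p, p) → 0`
exactly. Per-SNP statistics are averaged over non-overlapping 500-kb windows;
windows in the extreme upper empirical tail (5% for |iHS|, 2.5% for F_ST) are
flagged, overlaps between the two statistics are reported, and a Pearson χ²
test compares the gene content around significant windows with
chromosome-matched random positions.

## Worked example

Simulate a two-population panel (1,500 SNPs on a 50-Mb chromosome, 50
diploids per population, Balding–Nichols divergence F = 0.15), inject a
strong sweep in population 1, and run both scans:

```python
import numpy as np
from sweepscan import (SimConfig, SweepSpec, simulate_panel, inject_sweep,
                       qc_filter, LD_DATASET, ihs_scan, fst_scan, select_K,
                       window_average, empirical_threshold, overlap_signals)
from sweepscan.synthetic_data import suitable_core_pos

cfg = SimConfig(n_chrom=1, chrom_length_bp=50_000_000, n_snp_per_chrom=1500,
                n_pop=2, n_diploid_per_pop=50, bn_F_per_pop=(0.15, 0.15),
                seed=42)
panel, truth = simulate_panel(cfg)
core = suitable_core_pos(panel, "chr1", "pop1")
panel, truth = inject_sweep(panel, truth,
                            SweepSpec(pop="pop1", chrom="chr1", core_pos=core,
                                      f_target=0.8, L_sweep=1_000_000), seed=1)

pop1 = panel.take_samples(np.flatnonzero(panel.samples["population"] == "pop1"))
ld, _ = qc_filter(pop1, LD_DATASET)          # MAF >= 0.05, ancestral known
scan = ihs_scan(ld)                          # per-SNP standardized |iHS|
thr_i, flag_i = empirical_threshold(window_average(scan, "abs_ihs"), 0.05)

fst = fst_scan(panel, S=500, seed=2)         # locus-wise posterior F_ST
thr_f, flag_f = empirical_threshold(window_average(fst, "fst_mean"), 0.025)
print(overlap_signals(flag_i, flag_f))
```

Output (seed 42):

```
core: 24993755  realized sweep frequency: 0.8
LD dataset: 1222 SNPs after QC ({'low_MAF': 278})
|iHS| threshold 1.464 -> 5/93 significant windows
genome-wide mean posterior F_ST: 0.089
F_ST threshold 0.163 -> 3 significant windows
chrom  window    start      end     fst  abs_ihs
 chr1      50 25000001 25500000 0.22345  2.96664
```

The single window flagged by *both* statistics is the one containing the
injected sweep core at 25.0 Mb: its window |iHS| (2.97) and window F_ST
(0.223) both clear their empirical thresholds, and the core SNP itself scores
|iHS| = 3.46 against the scan's 95th percentile of 1.98. The hitch-hiked
allele-frequency shift in population 1 also drives the mixture clustering:
`select_K(fst["fst_mean"], K_max=4, seed=3)` picks several components whose
highest-mean cluster (mean 0.269) collects the most differentiated loci.

A command-line interface mirrors the library
(`sweepscan simulate | qc | ld | ihs | fst | cluster | windows | enrich |
report`); every subcommand writes TSV/BED/JSON outputs plus a manifest with
parameters and input checksums, and a single `--seed` reproduces a whole run.

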