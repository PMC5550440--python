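# hdgwas

Genome-wide dissection of heterosis in partial-diallel two-line hybrid
populations — hybrid rice being the motivating system, where male-sterile
maternal lines (PTGMS) are crossed to fertile restorer lines and the
better-paternal value (BPaV = F1 − Pat) is the heterosis measure that
matters to breeders, because the mother is sterile and cannot be grown for
comparison.

The package provides, as a library and a CLI:

* **A synthetic diallel generator** — inbred maternal and RIL-family
  paternal genomes, F1 assembly, and phenotypes from the F2 parametrization
  (genotypic values −a, d, +a) plus an infinitesimal polygenic background,
  with full ground truth for every planted QTL.
* **Genotype core** — PED/MAP and VCF I/O, sequential marker QC
  (missing ≤ 0.2, het ≤ 0.15, polymorphism, MAF ≥ 0.05), KNN imputation,
  F1 genotype construction from inbred parents, VanRaden kinship, genomic
  PCA, windowed heterozygosity, per-group MAF profiles.
* **Heterosis phenotypes** — BPaV, mid-parent heterosis
  MPV = F1 − (Pat+Mat)/2, and the diallel combining-ability decomposition
  GCA_i = ȳ_i· − ȳ·· and SCA_ij = ȳ_ij − ȳ·· − GCA_i − GCA_j on cross
  means, with rank-based inverse-normal phenotype normalization.
* **A forward-selection resampling GWAS engine** — mixed-model score tests
  whitened by leave-one-chromosome-out kinship, four inheritance codings
  (additive, dominance, recessive, overdominance), permutation-based
  genome-wide thresholds, and per-marker resample model inclusion
  probabilities (RMIP: the percentage of 80% subsamples whose forward
  selection included the marker), merged into signals with D′-hapblock QTL
  intervals.
* **QTL characterization** — the 15-sample three- vs two-genotype rule,
  joint additive+dominance regression with Stuber's |d/a| classes,
  hetero-/homo-superior calls, variance explained (single and AIC-filtered
  multi-QTL), and superior-allele provenance: which parental group carries
  the favorable allele and what fraction of F1 superior copies each group
  contributed.
* **Selection scans** — sliding-window Tajima's D (240 kb / 20 kb) per
  parental group, bottom-decile low-diversity regions, and QTL overlap
  counts.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

A small end-to-end run from a YAML config (two chromosomes, 48 F1s, one
additive+dominant QTL on chromosome 1 and one maternal-fixed overdominant
QTL with a selective sweep on chromosome 2):

```yaml
# run.yaml
seed: 5
simulation:
  n_maternal: 6
  n_paternal_families: 2
  lines_per_family: 4
  n_chromosomes: 2
  markers_per_chromosome: 120
  chrom_length: 24000000
  shared_ancestry: 0.6
  h2_polygenic: 0.2
  residual_sd: 0.5
  n_replicates: 2
  qtls:
    - {chromosome: 1, position: 12000000, additive_effect: 1.0, dominance_effect: 0.8}
    - {chromosome: 2, position: 6000000, additive_effect: 0.6, dominance_effect: 1.2,
       fixed_in: maternal, sweep_span: 2000000}
gwas: {n_resamples: 20, n_permutations: 60}
scan: {window: 2000000, step: 500000}
```

```
$ hdgwas run --config run.yaml --out run1/
$ cat run1/report/summary.tsv
category	n_qtls	n_three_genotype	n_two_genotype	n_hetero_superior	n_homo_superior	mean_variance_explained	n_large_effect
BPaV	2	0	2	1	1	0.231504108	2
F1	3	0	3	2	1	0.4167896891	3
SCA	1	0	1	1	0	0	0
```

Reading the table: the F1 GWAS recovered three signals (the two planted
QTLs plus a linked neighbour) explaining on average 42% of the trait; all
are two-genotype QTLs at this panel size because 48 F1s rarely give every
genotype class 15 members.  The maternal-fixed QTL is called
hetero-superior — its favorable allele segregates only in the restorers,
so heterozygotes outperform the homozygote class that the maternal allele
forces.  `run1/characterize/qtl_report.tsv` holds the per-QTL detail
(d/a, superior-allele ratios per group, parental contributions),
`run1/gwas/rmip_*.tsv` the per-marker RMIPs, and
`run1/scan/low_d_regions.bed` the bottom-decile Tajima's D regions per
parental group.  (At this toy panel size the swept maternal region is
fully monomorphic, so its D is undefined rather than negative; the sweep
signature needs the more diverse maternal pools exercised in the tests.)

Re-running the same config reproduces every output byte for byte; the
manifest (`run1/manifest.json`) records the seed, the thresholds actually
used and a SHA-256 for every file.

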