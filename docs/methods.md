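# Methods

`hdgwas` dissects heterosis in a partial-diallel two-line hybrid panel:
male-sterile maternal lines crossed to restorer paternal lines drawn from a
few recombinant-inbred (RIL) families.  This note documents the models, the
numerical choices, and what the synthetic populations do and do not
represent.

## The synthetic diallel

The generator exists so that every downstream stage is testable against a
known architecture; it reproduces the *statistical structure* the analysis
assumes, not rice biology.

**Genomes.**  Markers are evenly spaced on `n_chromosomes` chromosomes
(default 12 × 4300 over 30 Mb each, a chip-like raw panel).  Founder
allele frequencies are Beta(0.5, 0.5) truncated to [0.05, 0.95].  Every
founder haplotype copies a single shared ancestral consensus haplotype at a
fraction `shared_ancestry` of sites (default 0.9) and carries fresh
Bernoulli(p) draws elsewhere; this models the common elite breeding
background of both parental groups.  Each paternal RIL family descends from
two family founders; maternal lines are mosaics of a pool of
`n_maternal_founders` (default 3) haplotypes, giving the few-ancestor
maternal group its elevated allele-frequency divergence.  Mosaics use a
Poisson crossover process (`crossover_rate` per chromosome, default 1);
several selfing generations are collapsed into one mosaic draw, since the
downstream statistics depend on the block structure, not on its
generation-by-generation history.

With these defaults, per-F1 heterozygosity measured on the polymorphic
MAF ≥ 0.05 panel — the panel on which such figures are reported for real
two-line hybrid panels — falls in the observed 17.5–28.4% band.  The
`shared_ancestry` default was derived from the identity
E[mismatch] = (1 − s²)·2·E[p(1−p)] and then checked empirically; it is a
calibration to the stated study conditions, not a free dial.

**QTLs.**  A `QtlSpec` places an effect at the marker nearest its position
(with a warning if not exact).  Genotypic values follow the standard F2
parametrization: −a, d, +a for 0/1/2 copies of the alternate allele, a ≥ 0
by convention.  `fixed_in` forces one parental group monomorphic for the
reference allele (the alternate then segregates only in the other group),
which is what makes a locus a *two-genotype QTL* in the F1s.  `sweep_span`
additionally drags markers within the given radius toward the first founder
haplotype of the fixed group (each other founder copies it with
probability 0.9).  Near-fixation with rare leftover variants is what gives
a swept region its negative Tajima's D; fixing only the focal marker would
leave the windowed statistic untouched.

**Phenotypes.**  For one trait and one environment,

    y_ir = mean + Σ_q [ a_q·(x_q − 1) + d_q·1(x_q = 1) ] + u + e_ir

per replicate r.  The polygenic background u is an infinitesimal
marker-effects draw: i.i.d. standard-normal effects on every (centered)
marker, applied to parents and F1s alike and scaled so that
Var(u)/(Var(u) + residual_sd²) = `h2_polygenic` on the F1 panel.  Because u
is built from the same markers the analysis sees, its F1 covariance is
proportional to the realized-relationship matrix *by construction* — the
covariance the mixed model assumes.  (An earlier design drew u as a
multivariate normal on a bent combined parent+F1 GRM; its eigen-geometry
differed from the F1-panel kinship enough to make whitened scans
structurally anti-conservative, which is why the infinitesimal form is the
one shipped.)  With `residual_sd = 0` and `h2_polygenic = 0` the phenotype
is an exact deterministic function of genotype.

What the generator does **not** emulate: realistic rice LD maps and
recombination heterogeneity, ascertainment bias of chip markers (simulated
monomorphic sites are exactly monomorphic, so polymorphic-marker retention
is lower than on a real chip), epistasis, genotype-by-environment structure
beyond independent environment draws, and genotyping error.  Passing tests
therefore demonstrate correctness of the machinery under the assumed
structure, not performance guarantees on field data.

## Genotype handling

Coordinates are 1-based; windows are half-open `[start, start + W)`.
Marker QC is sequential and inclusive at the thresholds: missing rate
≤ 0.2 first, then heterozygous-call rate ≤ 0.15 among survivors, then
polymorphism, then MAF ≥ 0.05 on the F1 panel.  Parents are declared
inbred, so residual heterozygous parental calls are set missing before
imputation and excluded per site in haplotype-based statistics.

KNN imputation replaces a missing call with the mode of the k nearest
samples (mean absolute call difference over shared non-missing markers);
neighbour-rank ties break by sample order and mode ties by the smaller
call code, making the result deterministic.  An optional reference panel
contributes neighbours without being imputed.

F1 genotypes are the union of one allele from each inbred parent; a
heterozygous or missing parental call makes the F1 call missing.  Kinship
is the VanRaden frequency-weighted GRM, ZZ′/2Σp(1−p), eigenvalue-floored
at 1e-6; PCA scores are GRM eigenvectors scaled by the root eigenvalues
with the largest-magnitude loading made positive.

## Heterosis phenotypes

Replicates are averaged per sample × environment before any derivation and
environments are never pooled.  BPaV = F1 − Pat; MPV = F1 − (Pat + Mat)/2.
Combining abilities are method-of-moments on cross means: the grand mean is
the *unweighted* mean of observed cross means (the formulas are written on
cross means, so unbalanced diallels do not reweight parents by cross
count), GCA_i = ȳ_i· − ȳ··, and SCA_ij = ȳ_ij − ȳ·· − GCA_i − GCA_j,
assigned to every F1 of the cross.  On a complete balanced diallel the
group means of GCA and all SCA margins vanish to rounding error.

SNPP = GYPP/(PN × TGW/1000): TGW is a 1000-grain weight in grams, and the
division by 1000 converts it to a per-grain weight; without it SNPP is off
by three orders of magnitude against plausible seed counts.

Phenotype normalization is the rank-based inverse-normal transform with
the Blom offset, Φ⁻¹((r − 3/8)/(n + ¼)), ties averaged.  It serves the same
purpose as a learned monotone warp — Gaussian residuals for the mixed
model — while being closed-form and deterministic.  Each derived phenotype
(F1, BPaV, MPV, SCA) is normalized independently by default; the pipeline
exposes `gwas.normalize` to switch this off.

## The resampling GWAS engine

For each trait category the engine draws `n_resamples` random 80%
subsamples without replacement (300 at full scale; 50 in the scaled
desk-top mode used by the tests), runs a forward-selection mixed-model
GWAS on each under all four inheritance recodings — additive (0,1,2),
dominance (0,0,2), recessive (0,2,2), overdominance (0,1,0) — and reports
the resample model inclusion probability, RMIP = 100 × inclusions /
n_resamples, per marker per model, with the maximum over models used for
reporting.  SNPs at RMIP ≥ 5 are significant; same-chromosome significant
SNPs less than 800 kb apart with genotype-regression R² ≥ 0.2 are chained
(single linkage, transitive closure) into one signal whose lead is the
highest-RMIP member (ties: lower p, then lower position).

**Association test.**  y = Xβ + gb + u + e with u ~ N(0, σ²g·K).  The
heritability ratio is fit by 1-D bounded ML on the kinship eigenbasis, per
sub-dataset, against the intercept/user-covariate model only — genomic-PC
fixed effects (optional, `n_pcs`) span the top kinship eigendirections, and
estimating h² jointly with them is ill-posed (the fixed effects absorb the
relatedness signal and collapse ĥ² to zero).  Each chromosome is then
scanned whitened by its leave-one-chromosome-out (LOCO) kinship (Cholesky
of h²·K₋c + (1 − h²)·I), so a tested marker's own LD block does not sit in
the polygenic term and siphon off its signal; with `loco=False` and an
identity kinship the engine reduces exactly to plain forward-selection
regression, a reduction the tests verify against an independent OLS
implementation.  The statistic is the 1-df chi-square score test on
covariate-residualized whitened data; markers collinear with the covariate
set test at p = 1.

**Significance threshold.**  Computed once per trait on the full dataset
and reused across sub-datasets (per-subsample permutation would multiply
the cost three-hundred-fold for no change in the quantity being
estimated).  The permutation null permutes the whitened
covariate-residualized residuals — the quantities that are exchangeable
under the fitted model — re-residualizes (Freedman–Lane), and records the
minimum p across all markers *and all four models* per permutation, so the
threshold is familywise over models.  The threshold is a lower quantile of
these minima.  Two calibrations are available:

* `"scan"` — the quantile is the target FDR itself, so ~5% of null genome
  scans produce any hit;
* `"procedure"` (default) — the quantile is chosen by binomial inversion
  so that, under worst-case concentration of null hits on a single
  borderline marker across the overlapping subsamples, the probability
  that any marker reaches the RMIP threshold is the target FDR.  This is
  the calibration that makes the *reported SNP list* (RMIP ≥ 5), not just a
  single scan, a 5%-level decision.  Scan-level calibration leaves roughly
  one null run in ten with a reported marker, because a marker whose
  full-data p sits near the threshold recurs in many 80% subsamples.

**What "null" means.**  Type-I control is defined on traits with no
genetic component.  A polygenic-only trait is *not* null under the
infinitesimal model: every marker carries a tiny real effect, and LOCO
deliberately keeps chromosome-local background signal visible (that is
where its power comes from).  On such traits roughly a fifth of scaled
runs report a background-tagging marker; these are weak true associations
under the generative model, and the same epistemic status attaches to
low-RMIP findings on real data.

**Power.**  The scaled engine recovers a planted large-effect additive QTL
(realized R² ≈ 0.4, the magnitude of the largest QTLs reported for
heading date and seed number in two-line panels) at RMIP ≥ 50 within
500 kb in ≥ 90% of runs, and a purely overdominant QTL achieves its
maximum RMIP under the overdominance coding rather than the additive one.
A known limitation: in a diallel, a marker's information is carried by the
~15 founder alleles, not by the ~500 F1s, so additive QTLs explaining
~15% of variance but fully aligned with founder structure sit at the edge
of detectability after mixed-model correction — the structure-correction
power cost familiar from heading-date loci in rice panels.

**Pleiotropy re-runs** pass the matching original F1 phenotype as a fixed
covariate through the identical engine; a BPaV/SCA signal that disappears
is classified as mediated by the F1 phenotype.

## QTL characterization

Genotype classes count non-missing F1 calls at the lead SNP; a QTL is
three-genotype iff all three classes have ≥ 15 F1s (counting non-missing
calls only).  Three-genotype QTLs get a joint regression on the additive
(0,1,2) and dominance (0,1,0) codings with the top-10 genomic PCs as
covariates; a is the half-difference of homozygote means (minor-allele
homozygote high), d the heterozygote deviation from the homozygote
midpoint.  |d/a| is binned additive [0, 0.2), partial dominance
[0.2, 0.8], dominance (0.8, 1.2], overdominance > 1.2, with the sign
reported alongside.  If |â| < 1e-8 the ratio is undefined: the QTL is
called overdominant when d is significant, otherwise unclassified, and
flagged.  Two-genotype QTLs compare the heterozygote mean against the
observed homozygote class in the trait's favorable direction
(configuration: yield traits higher-is-better, heading date
lower-is-better); exact ties go conservatively to homo-superior.

Variance explained is the R² of the lead-SNP regression; multi-QTL totals
first residualize the phenotype on the top-10 PCs (family-effect removal),
filter lead SNPs by AIC forward–backward selection, and report the joint
R² on the residualized phenotype.

Superior-allele provenance: the superior allele is the favorable
homozygote's allele (three-genotype, or homo-superior two-genotype), or
the allele absent from the observed homozygote class (hetero-superior
two-genotype).  Because parents are inbred, each F1 allele copy has an
unambiguous parental origin, so the maternal- and paternal-derived
fractions of superior copies, the per-group superior-allele frequencies,
and the contribution class (female_only / male_only / both) are exact
counts over the cross table.

QTL intervals are D′-confidence haplotype blocks of the parental panel:
pairwise |D′| likelihood intervals on a 101-point grid with allele
frequencies at their MLEs; a pair is strong LD when CI = [CL, CU] has
CL ≥ 0.70 and CU ≥ 0.98, recombinant when CU < 0.90; a candidate interval
is a block when its outermost pair is strong and ≥ 95% of informative
pairs are strong.  The interval is the widest accepting block containing
the lead SNP (search bounded at 50 flanking markers), else the lead
position alone, flagged degenerate.

## Selection scan

Inbred lines contribute one haplotype each.  Windows are 240 kb sliding by
20 kb (each interior position covered 12 times); terminal short windows
are kept and flagged.  Per window, S, π, Watterson's θ_W = S/a₁ and
Tajima's D with the standard constants; D is undefined below 3 segregating
sites or 4 haplotypes.  A site enters when ≥ 4 haplotypes are observed;
with missing data π uses per-site observed counts and the variance
constants use the rounded mean observed count over segregating sites
(exact when data are complete, which the oracle tests require).
Low-diversity regions are windows at or below the group's 10th percentile
of defined D, merged when overlapping or adjacent; QTL overlap is
half-open interval intersection, counted per parental group.

## Pipeline

`hdgwas run` executes simulate → qc → derive → gwas → characterize → scan
→ report.  Every stage reads only the previous stages' files and writes
TSV/BED/JSON with a fixed float format and no timestamps; all randomness
descends from the master seed through named children, so re-running a
config is bit-identical and deleting any intermediate directory and
resuming reproduces it exactly (the manifest records SHA-256 of every
output).  One environment per run; cross-environment comparison is a
report-level join.

### Problem sizes used by the shipped checks

The acceptance-style checks run the engine in its scaled mode — 8 maternal
× 39 paternal lines (312 F1s), 12 × 167 ≈ 2000 markers, 50 resamples, 100
permutations — and the generator's full default (546 F1s, 51.6k raw
markers) only for structure properties (heterozygosity band, PCA family
recovery).  Dominance-ratio recovery uses 100 panels of 546 F1s on a
2-chromosome genome.  These sizes were chosen so the whole battery runs on
a laptop-class single core in minutes while leaving every qualitative
contrast (calibration vs power, maternal vs paternal diversity) intact.
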