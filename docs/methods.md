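# Methods

`ldgwas` implements an LD-centric post-processing chain for association
studies on structured inbred panels: corrected linkage disequilibrium,
decay-model fitting per recombination regime, per-SNP LD windows and genome
coverage, a leave-one-chromosome-out mixed-model scan, two LD-based rules
for grouping significant SNPs into QTLs, multi-technology concordance and
resampling, and a synthetic panel generator that makes every stage testable
without external data.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Genotypes and coordinates

Inbred-line genotypes are allelic doses: 0 and 1 for the two homozygotes,
0.5 for residual heterozygotes, `NaN` for missing.  Physical coordinates
are 1-based; intervals are closed `[start, end]` and overlap iff
`max(starts) <= min(ends)`.  The single exception is the BED export of LD
windows, which converts to 0-based half-open.  Genetic/physical projection
uses a shape-preserving monotone interpolant (PCHIP) through the map
anchors; the inverse direction inverts the same curve by bracketed root
search, so round trips are exact to the root tolerance (1e-3 bp), and
out-of-range queries extrapolate with the boundary slope.  QC filters
follow the usual thresholds for such panels (markers: het ≤ 0.15,
missing ≤ 0.20, MAF ≥ 0.01 for diversity work and 0.05 for association;
individuals: het ≤ 0.06, missing ≤ 0.10).  Filters are applied per
technology before panels are merged, since marker inventories are
technology-specific.

## Kinship and corrected LD

Three relatedness estimators: `K_Freq` (allele-frequency-weighted IBD,
`K_ij = (1/L) Σ_l (G_il − p_l)(G_jl − p_l)/(p_l(1−p_l))`, monomorphic
markers excluded), `IBS` (proportion of shared alleles), and `K_Chr`
(`K_Freq` on all chromosomes except the one being scanned, so the tested
locus cannot absorb its own effect).  Missing data are handled
pairwise-complete by default, with a mean-imputation switch used by the
bulk routines.  PCoA double-centers the distance `D = 1 − K_Freq`
(`B = −½ J D J`), keeps the positive axes, and clips negative eigenvalues
out of the percent-variance denominator only.

Corrected LD statistics are squared partial correlations.  `r2K` whitens
both dose vectors with the symmetric inverse square root of K (eigenvalues
floored at 1e-8) and projects out the whitened intercept; `r2S` projects
out admixture proportions (one column dropped against the intercept);
`r2KS` does both.  Two exact limits pin the construction down: `K = I`
reproduces plain `r2` to machine precision, and the statistic is invariant
to positive scaling of K.  Scalar calls use exact pairwise-complete
whitening on the jointly observed sub-matrix of K; the bulk pair routines
(decay fitting, LD matrices) mean-impute missing doses before whitening,
because per-pair re-whitening is quadratic in the number of pairs.

## LD decay and windows

The expected squared correlation at composite recombination parameter
`C = β·d` in a sample of n gametes follows the Hill–Weir drift expectation

    E(r²|C) = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))]

with the single slope β fitted by nonlinear least squares (log-β
parameterization, Levenberg–Marquardt) on sampled locus pairs.  Pairs are
drawn uniformly without replacement from all same-chromosome pairs within
1 cM whose two members fall in the same recombination class (HIGH > 0.5
cM/Mbp, LOW < 0.5 cM/Mbp, classified in non-overlapping 2-Mbp windows);
distance-zero pairs (duplicate positions across technologies) are
excluded.  n is the number of inbred lines (haploid-equivalent for a
homozygous panel); it is configurable.  Fits use raw pair values,
unweighted.  The LD extent at a target level (0.1/0.2/0.4) is the distance
where the fitted curve crosses it, found by bracketed root search (upper
bracket 10× the 99th percentile of pair distances, expanded if needed);
a curve starting below the target yields extent 0, an asymptote above it
an infinite sentinel.

Every SNP with MAF ≥ 5% gets an LD window: in LOW regions a physical
half-window equal to the bp extent; in HIGH regions a genetic half-window
(cM extent) projected back to bp through the map.  Windows are clipped to
the chromosome; infinite-extent windows span the marker's contiguous
region-class segment rather than the chromosome, to avoid saturating
coverage.  Genome coverage is the measure of the union of windows divided
by map length, physical and (after projecting union bounds) genetic;
profiles tile the chromosome at 20/100/500/2000 kbp.

## Mixed-model scan and multiple testing

For a marker on chromosome c: `y = μ + x·b + g + e` with
`g ~ N(0, σ²_g K_Chr(c))`, `e ~ N(0, σ²_e I)`.  The variance ratio
`δ = σ²_e/σ²_g` is REML-estimated once per chromosome under the null via
the spectral decomposition of `K_Chr(c)` (coarse grid then bounded Brent on
the profile REML); each marker is then tested by weighted least squares in
the rotated basis with the total variance re-profiled per marker, giving an
F(1, n−p) test.  Two consequences we rely on: with `K = I` the test reduces
*exactly* to the OLS F-test, and the per-marker cost after one
eigendecomposition is O(N).  Exact per-marker REML was implemented as a
check and changes nothing material on these panels, so the cheaper
per-chromosome fit is the default.  Lines missing the tested dose are
dropped for that marker only (sub-matrix solve).  Effects are reported for
the allele coded 1; p-values are floored at 1e-300.

The effective number of independent tests follows the eigenvalue method
(simpleM): per block of 200 consecutive markers, the number of leading
eigenvalues of the marker correlation matrix needed to reach 99.5% of the
trace, summed over blocks.  The Bonferroni threshold is
`−log10(α/M_eff)` with α = 0.05; two fixed analysis thresholds
(−log10 p = 5 discovery, 8 stringent) are used for cross-technology
comparisons.  Expected false positives are `M·situations·p`, rounded
half-up, and the implied FDR is expected/observed.  Note that
`−log10(0.05/15 780) = 5.4991` rounds to 5.50 under half-up rounding; a
printed value of 5.49 for that case is a truncation.

Calibration: the scan is exactly calibrated marginally (OLS limit) and
approximately calibrated genome-wide; genomic inflation is assessed on
pure-noise phenotypes averaged over draws.  A polygenic null drawn from the
*full* kinship is intrinsically inflated under leave-one-chromosome-out
correction when the genome has few chromosomes (each left-out chromosome
carries 17–50% of the background at desk scale, against ~10% in a
10-chromosome genome); this is a property of the LOCO design, not a defect
of the implementation.

## QTL grouping

Significant SNPs from all environments of a trait are pooled first, so a
QTL is one entity across environments.  `LD_win` takes connected components
of the LD-window overlap graph (sorted sweep; equals the transitive
closure) and sets QTL limits to the union span of member windows.  `LD_adj`
walks position-sorted significant SNPs and splits where the r2K between
adjacent SNPs is ≤ 0.5 (strictly greater keeps them joined; an undefined
value splits).  Peaks are the member with maximal −log10 p across
environments, ties broken by genomic order; `NbDiffEnv` counts environments
where any member passes the discovery threshold; the peak R² is the squared
correlation of peak doses with the phenotype in the peak's environment.
Colocalization between traits is physical-interval overlap.  Local
haplotypes within a QTL interval are average-linkage clusters of the simple
mismatch dissimilarity on doses (MAF-filtered), cut at k.

## Technology comparison and resampling

Concordance strata (homozygote/heterozygote) follow the *reference*
technology's call; the call rate is the fraction of reference-called
entries also called in the test panel, concordance the fraction of
jointly-called entries that agree — the statistic is deliberately
asymmetric.  The imputation merges: GBS5 keeps homozygous primary calls and
fills heterozygous/missing entries from the secondary panel; GBS4 turns
heterozygotes into missing first and then fills every gap.  MAF-scheme
resampling stratifies markers into five classes ((0–0.1] … (0.4–0.5]) and
draws to target class frequencies (largest-remainder rounding); the
`Low_MAF` scheme uses the mirror image (0.4, 0.4, 0.2, 0, 0) of the
`High_MAF` vector (0, 0, 0.2, 0.4, 0.4) — a source that prints the same
vector for both cannot mean it.  Density schemes allocate per-10-Mbp-window
quotas proportional to physical length, genetic length, or a reference
panel's empirical window counts.

## Synthetic panel generator

The generator is a founder-mosaic model chosen over a coalescent simulator
deliberately: it is desk-scale, dependency-free, and produces map-driven LD
with the two-regime structure the analysis needs.

* **Map**: each chromosome has a central low-recombination block (default
  40% of its length at 0.1 cM/Mbp) flanked by high-recombination arms
  (1.5 cM/Mbp).
* **Founders and structure**: a *shared* pool of founder haplotypes
  (default 6) drawn from Beta(0.4, 0.4) ancestral frequencies; the four
  admixture groups differ by their founder-usage weights (each group puts
  extra weight, default 0.3, on a key founder).  A shared pool is
  essential: disjoint per-group founder sets cap panel-wide r² near
  1/(total founders) and destroy usable LD.  The pool size sets the
  short-range r² ceiling (~1/(F−1)); 6 founders with the default mosaic
  density give genetic extents of ~0.02–0.03 cM and pericentromeric
  physical extents of ~350–450 kbp, the same order as real dent-panel
  estimates.
* **Mosaics**: each line is a segmental mosaic of founders with crossover
  counts Poisson in genetic length (default 200 crossovers per Morgan of
  accumulated history), placed uniformly on the cM scale and projected to
  bp — this is what stretches physical LD through the pericentromere.
* **Rare variants**: a configurable fraction of markers (default 0.35)
  carries a young mutation confined to a random sub-lineage of one founder,
  producing the L-shaped tail of the sequencing spectrum without disturbing
  the backbone LD.
* **Technologies**: array-like subsets sample markers with probability
  proportional to MAF (near-uniform spectrum, rare-allele depletion);
  sequencing-like subsets sample uniformly (keeping the L shape) with
  double weight in high-recombination regions, then apply symmetric
  genotype errors (1%), heterozygote under-calling (50% of residual hets
  become a random homozygote) and 63% missingness, in that order.
* **Phenotypes**: per environment, `y = Σ b_q x_q + u + e` with the
  polygenic term drawn with covariance proportional to the realized
  `K_Freq` and noise scaled to a target h² (default 0.6).  Planted-QTL
  effects are solved from target variance fractions v via
  `V_total = σ²_u/(h² − Σv)`.  Two deliberate conditioning choices: the
  background and noise draws are made orthogonal in-sample to the planted
  causal doses, so each QTL explains exactly its configured variance
  fraction (separating power measurement from effect-size sampling noise,
  which is large in structured panels); and the planted marker is the
  nearby common marker (MAF ≥ 0.2, ±2.5 Mbp) minimizing the kinship
  quadratic form x'Kx, because a structure-collinear "causal" marker
  measures confounding, not power.

What the generator does *not* emulate: demographic history (bottlenecks,
selection, migration), read-level sequencing artifacts, genotype-by-
environment interaction (environments differ by noise only), allelic
series, assembly errors, or reference-bias in marker discovery.  Tests that
pass on these panels therefore demonstrate the correctness and calibration
of the machinery under the stated statistical structure, not robustness to
every pathology of real data.

## Problem sizes

The bundled fixture (2 chromosomes × 30 Mbp, 5,000 markers, 120 lines,
2 environments, 8,000–15,000 pairs per decay fit) drives the
continuation-scale tests and the end-to-end pipeline, which completes in
well under a minute and is byte-reproducible from its manifest.  The
analysis scripts use the default desk-scale panel (3 chromosomes × 50 Mbp,
12,000 markers, 250 lines, 6 environments, 30,000 pairs × 5 sets per decay
fit).  Power and recovery experiments use 100 replicates of a 250-line,
1,500-marker panel with one 20%-variance QTL.  These sizes are the
package's chosen study conditions; all of them are plain config values.

## Known limitations

* The LOCO mixed model leaves the tested chromosome's polygenic background
  unmodeled by construction; with few chromosomes this shows up as genomic
  inflation against full-kinship polygenic nulls (see above).
* Bulk LD routines mean-impute missing doses; with heavy, non-random
  missingness the corrected LD can be attenuated relative to the exact
  pairwise-complete statistic.
* `LD_adj` inherits the usual fragilities of adjacency chains (marker
  order errors, genotyping errors at run boundaries); the package follows
  the windows rule for downstream summaries.
* The Hill–Weir fit assumes a single decay slope per chromosome ×
  recombination class; regions whose local LD deviates strongly from the
  class average get windows that are too wide or too narrow.
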