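# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results will want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All internal coordinates are 0-based, half-open base pairs; VCF and
HapMap-like inputs (1-based) are converted on read, and emitted BED is
0-based half-open. Genotypes are alternate-allele dosages in {0, 1, 2}
with −1 for missing, held in a `GenotypeMatrix` (lines × markers) whose
marker map is sorted by (chromosome, position) with unique ids. Physical
positions are stored in bp; Mb appears only in display columns (2-decimal
formatting).

## Synthetic panels

`simulate_panel` draws, for each marker, an ancestral frequency from
`ancestral_maf_dist` (default Uniform(0.05, 0.5), giving a spectrum that
supports a MAF > 0.05 filter), then a per-subpopulation frequency from the
Balding–Nichols Beta with mean equal to the ancestral frequency and
variance `F_k p(1−p)`. Balding–Nichols was chosen because it controls
differentiation with a single interpretable parameter per subpopulation;
`fst` may be a scalar or per-subpopulation vector (defaults in the
0.3–0.5 band typical of deeply structured domesticated rice). Each line
carries an inbreeding coefficient from `inbreeding_dist` (default
Beta(9, 1), mean 0.9 — a placeholder for "highly inbred accessions in
various stages of purification", not a measured value); at each marker
the line is homozygous-by-descent with probability `f`, else a
Hardy–Weinberg draw. Missing calls are uniform at random (default 1%).
Markers are evenly spaced and, deliberately, statistically independent
given the subpopulation frequencies: the generator reproduces
*population structure*, inbreeding, and introgression mosaics, but not
background linkage disequilibrium, allele-frequency clines within
subpopulations, or genotyping-error structure. Passing tests therefore
demonstrate correctness of the machinery under structure and admixture,
not performance under realistic LD.

`inject_introgressions` redraws calls inside donor intervals from the
donor subpopulation's frequencies with the line's own `f`, keeps missing
calls missing, and splits the truth-track intervals so each chromosome
remains exactly tiled. Overlapping events on one line are rejected.

`simulate_root_phenotypes` gives each line a latent tolerance
`base + subpop offset + Σ(dosage × effect) + N(0, residual_sd)` and draws
replicate growth around a control mean (Al replicates around
mean × tolerance) with a per-replicate coefficient of variation, for
three root classes driven by the same latent value. When
`target_subpop_r2` is set, the subpopulation offsets are rescaled by a
bisection on the realized one-way ANOVA R² of the latent values (the R²
is monotone in the offset scale, so the realized value matches the target
essentially exactly on the latent scale; replicate noise then dilutes the
R² observed on RRG).

`simulate_cross` simulates RIL genomes as two-state Markov chains over
markers with adjacent-marker recombinant fraction `R = 2r/(1+2r)` (the
selfed-line map expansion of the Haldane `r`); BILs use the same
expansion with stationary donor frequency 0.25 and a
stationarity-preserving switch kernel. This matches all two-point
distributions; higher-order interference is not modeled (Haldane was
chosen as the simplest defensible default).

## Tolerance indices

RRG is the ratio of arithmetic replicate means (Al over control) per root
class; no trimming. A zero control mean flags the index as undefined
rather than emitting a number. Group summaries use linear-interpolation
percentiles. Outliers use Tukey fences (outside Q1 − 1.5·IQR,
Q3 + 1.5·IQR within the line's group) — a documented convention, since no
numeric rule is standard for "highly tolerant outlier". Broad-sense
genetic fraction is computed as Var(line)/Var(total) from a line-replicate
one-way random-effects ANOVA (method of moments); the commonly printed
decomposition "VarG = VarG + Var(G×E) + error" is not usable as written,
so this explicit estimator is the package's definition.

## GWAS

MAF filtering is strict (`> 0.05`), computed on the non-missing calls of
the analyzed subset, and recomputed within each subpopulation subset.
IBS kinship is the pairwise mean shared-allele proportion
`1 − |g_i − g_j|/2` over jointly observed markers; it is symmetric with
unit diagonal, and eigenvalues are clipped at zero before REML (the
documented PSD shift). PCA covariates (default 4) come from the
eigendecomposition of the line-by-line covariance of centered,
marker-mean-imputed dosages.

The mixed model estimates (σ²_g, σ²_e) once per scan by REML on the
null (no-marker) model: the restricted likelihood is profiled in
δ = σ²_e/σ²_g on the spectrum of the covariate-projected kinship, with a
grid search (δ over e^[−10,10]) refined by bounded scalar minimization.
Per-marker tests are then GLS at those components — a deliberate
approximation to exact per-marker REML that is orders of magnitude faster
and accurate when individual markers explain little variance. With
identity kinship this reduces exactly to the naive OLS scan. Missing
genotypes are excluded per marker (the whitening transform is recomputed
on the observed subset), mean-imputed for PCA, and pairwise-excluded for
kinship. P-values are two-sided t statistics in all three models.
Within-subpopulation scans drop the PC covariates (no main structure axis
within a subpopulation) and recompute kinship in-subset; subsets below 30
lines are skipped.

Region calling merges significant markers (p < 1e−4, strict) within a
200-kb window — the same span as the candidate-gene window, chosen to
match the scale of LD decay in rice; region counts are therefore
properties of this merge rule. Candidate-window enrichment is the
significant fraction inside gene windows over the significant fraction in
the background (outside windows and outside any supplied QTL regions);
the upper-limit FDR is expected false positives at the threshold over the
observed significant count in windows. Genomic inflation λ is the median
association χ²(1) over its null median.

## QTL scans

Haley–Knott regression was chosen over EM maximum likelihood interval
mapping: on inbred populations the LOD profiles are near-identical and
the regression form permits fully vectorized permutations. Expected donor
dosage at each evaluation position conditions on the nearest informative
flanking markers under the two-state origin chain described above;
residual heterozygous calls are treated as missing (rare in RIL/BIL, and
this avoids a three-class model). BILs are analyzed as a two-class
population with prior class frequencies 0.75/0.25. Defaults: 1-cM step,
10-cM cofactor exclusion window, 5 forward-selected cofactor markers —
conventional CIM settings, since the original tool's settings are not
part of this package. The permutation threshold is the (1−α) quantile of
the maximum genome-wide interval-mapping LOD over seeded phenotype
permutations (default 1000), computed in one matrix product via
`LOD = −(n/2) log10(1−r²)`. LOD-1 support intervals are the contiguous
run around a peak with LOD ≥ peak − 1, reported at outermost positions.
Additive effects are in trait units per allele substitution, signed
toward the parent whose allele increases the trait.

## Local-ancestry HMM

States are single-subpopulation (homozygous-ancestry) states: the lines
are inbred, so admixture manifests as along-chromosome mosaics rather
than heterozygous ancestry. Emissions mix Hardy–Weinberg and
identical-by-descent components through the line's inbreeding
coefficient; missing calls emit 1. Transitions retain the state with
probability 1 − τ and switch to each other state with probability
τ/(K−1), independent of physical distance by default (τ init 0.01); a
distance-scaled variant (switch probability scaled by spacing relative to
the median gap) is available behind a flag, in which case τ is held
fixed.

EM fitting anchors the designated control lines by clamping their state
to their label throughout (not merely at initialization), which pins the
subpopulation frequencies and prevents label switching; frequencies are
initialized from control-line empirical frequencies. The E-step is the
scaled forward–backward algorithm, vectorized across lines. The M-step
augments the model with an explicit per-(line, marker)
identical-by-descent indicator, which makes every update closed form and
exact — subpopulation frequencies from posterior-weighted allele draws,
per-line f from the posterior IBD mean over observed markers, τ from
expected switch counts — so the observed-data log-likelihood is provably
non-decreasing at every iteration (the property the test suite asserts).
Frequencies are clipped to [1e−4, 1−1e−4] and f to [1e−6, 1−1e−6] to keep
emissions finite. Convergence: log-likelihood gain below `tol` (default
1e−4) or `max_iter` (default 50). The `seed` argument is reserved for EM
restarts; the default single deterministic initialization makes fits
reproducible without it.

Decoding is Viterbi with ties broken toward the lower state index;
interval boundaries sit at inter-marker midpoints, with terminal
intervals extended to chromosome ends. Ancestry fractions are bp-weighted
interval shares; a line is classified to a subpopulation (or varietal
group) iff its share is ≥ 0.80, else admixed. Introgression calls are
maximal non-majority runs with at least 5 markers and 100 kb of support
(both configurable); runs separated by even one majority marker stay
separate. The uniqueness filter retains an outlier line's call iff no
comparison line carries an overlapping (any-bp) same-donor call —
deliberately conservative — and groups retained calls into shared loci
whose consensus interval is the region common to all carriers (falling
back to the spanning interval if no common core exists).

A practical limit worth stating: boundary placement is only as precise as
the markers flanking the true breakpoint are informative. Under
Balding–Nichols frequencies at F_st ≈ 0.4 a substantial fraction of
markers have near-equal frequencies in donor and recipient
subpopulations, so even decoding with the true generating parameters
leaves the MAP boundary a few marker intervals off in a sizeable share of
simulations. Segments of a few hundred kb are detected essentially
always; their edges are typically resolved to within one to five marker
intervals, not to the single marker.

## Haplotypes and LD

Inbred homozygous calls are treated as haploid alleles; heterozygous
calls count as missing. Window haplotypes are exact allele-string groups
over fully called lines; a partially called line joins a group iff
exactly one group is compatible with its observed alleles, else it stays
unassigned (default minimum call fraction 0.8). Pairwise r² is the
squared Pearson correlation of haploid codes over pairwise-complete
lines; the LD decay distance is the lower edge of the first distance bin
(default 25 kb) whose mean r² drops below 0.2 — one documented convention
among several in use, and configurable. Haplotype variance explained
delegates to the one-way ANOVA R² on the carrier/non-carrier indicator
within the requested germplasm subset (minimum three lines on each side).

## Problem sizes in the test and acceptance runs

The shipped suites run at desk scale on one CPU: the K=5 ancestry panel
uses 250 lines × 5,000 markers; boundary-recovery replicates use
250 lines × 1,000 markers at 10-kb spacing on one chromosome (line count
drives frequency-estimation accuracy; genome length is scaled for
runtime); GWAS calibration uses 50 replicates of 125-line × 500-marker
panels; QTL null calibration uses 50 replicates with 1000-permutation
thresholds on 150-line crosses. These sizes are package choices balancing
statistical resolution against turnaround and are stated here so users
can scale them up.

## Known limitations

- No background LD in simulated panels (markers independent given
  subpopulation frequencies), so LD-decay analyses on simulated data are
  only meaningful within planted structures.
- EMMAX-style single variance-component estimation can be mildly
  anti-conservative under extreme confounding (a two-group panel where
  structure explains most of the trait), and, as in the original
  analyses, can over-correct signals aligned with structure.
- The HMM has no heterozygous-ancestry states and no recombination-map
  -aware transitions; phasing is out of scope.
- CIM permutation thresholds are computed on the interval-mapping
  statistic (cofactors would be re-selected under permutation; the
  interval-map threshold is the stable, conservative choice).
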