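# Methods

This note documents the statistical models implemented in `pipeqtl`, the
design of the synthetic panel the tests run on, the numerical choices, and
the limits of what the validation shows.

## Expression quantification

RT-qPCR yields a threshold cycle Ct per (line, biological replicate,
technical replicate, gene). Normalization follows the 2^ΔCt convention
against a set of reference genes: technical replicates are averaged on the
Ct scale first, then ΔCt = mean(reference technical-mean Cts) − target
technical-mean Ct, and the log2 relative expression equals ΔCt exactly.
Two conventions here were genuinely open and are fixed as follows:

* **Reference aggregation** is the arithmetic mean of reference Cts, which
  equals the geometric mean of the reference quantities — the dominant
  multi-reference qPCR convention.
* **Technical replicates** are averaged on the Ct scale before ΔCt; since
  Ct is the log-scale quantity, this is geometric-mean averaging of
  transcript quantities, the standard treatment of technical replicates.

A sample missing the target or any requested reference propagates as
missing rather than being silently dropped; samples with no usable Ct at
all are dropped with a warning.

Repeatability (often loosely called heritability in this setting) is
H = V_g/(V_g + V_e/n) from a one-way random-effects REML fit of
Expression ~ Genotype. `n` is the median replicate count per genotype
(3 in the intended design); V_g is truncated at zero. On balanced designs
the REML solution coincides with the ANOVA moment estimator
((MSB − MSW)/n, MSW), which the tests use as an independent oracle.

Group comparisons are nonparametric (Kruskal–Wallis omnibus with tie
correction; all pairwise Wilcoxon rank-sum tests, Holm-adjusted, starred at
0.1/0.05/0.01), and the trait PCA standardizes variables and uses case-wise
deletion, dropping constant traits with a warning.

## Mixed-model association scan

The single-locus model is Y = µ + Xβ + G + E with G ~ N(0, σ²_g K) and
E ~ N(0, σ²_e I), fitted per trait. Choices:

* **Kinship** is VanRaden method 1, K = ZZ′/(2Σp(1−p)) with Z the
  mean-imputed dosages centered at 2p. On a panel of inbred line-side
  dosages (values 0/2) the diagonal is ≈ 2 rather than 1; only the relative
  structure matters because σ²_g rescales. For each tested marker the
  kinship excludes the marker's chromosome (LOCO), so local signal cannot
  be absorbed into the polygenic term.
* **Variance components** are estimated by spectral REML: one
  eigendecomposition of K per (trait × chromosome), then a 1-D profile over
  log δ = log(σ²_e/σ²_g) on [−12, 12], initialized by a 65-point grid and
  refined by bounded Brent to 1e-8. This "P3D" estimate is reused for every
  marker of the chromosome; tests assert the exact per-marker REML refit
  (available via `ScanConfig(refit_per_marker=True)`) agrees with it within
  0.2 log10 p-value units on planted signals.
* **Per-marker test**: in the rotated basis the GLS estimate reduces to a
  weighted regression with weights 1/(λ_i + δ); the marker term gets a
  1-df F test with n − p − 1 residual df, and −log10 p is computed from the
  log survival function so scores of 40+ do not underflow. A marker
  collinear with the covariates (including itself when conditioned on) is
  emitted with missing statistics rather than dropped.
* **r²_LR** = 1 − exp(−(2/n)(LL₁ − LL₀)) with both likelihoods profiled at
  the shared δ, which reduces to 1 − RSS₁/RSS₀ in the whitened space and to
  the classical R² when K = I.
* **Filters/conventions**: MAF strictly > 0.05 enters the scan; the
  significance threshold is −log10 p ≥ 5; effects are reported per copy of
  the alternate allele by default, with a switch to report relative to the
  reference allele instead; heterozygous dosages are treated additively.

Conditional scans put marker dosages in the fixed-effect design. Subpanel
scans re-derive kinship and variance components on the retained lines; at
least 30 lines are required.

## eQTL definition

r²K whitens both dosage vectors by (K + εI)^(−1/2) (eigendecomposition;
ε = 1e-6 × the top eigenvalue guards null directions), projects out the
whitened intercept — the GLS analogue of centering — and squares the
Pearson correlation. With K = I this is exactly classical r².

Per significant SNP, the LD window scans outward up to 2 Mb on each side;
the boundary is the last marker with r²K ≥ 0.1 seen before 3 consecutive
markers fall below the threshold (`min_run`). The stop rule is this
package's concrete instantiation of window estimation — the threshold is
the method's published operating point, while `scan_radius_bp` and
`min_run` are exposed in `LDParams` because the original windowing
procedure is not fully specified; `min_run` > 1 bridges isolated low-LD
markers inside a block. Significant SNPs with overlapping windows merge
transitively; the eQTL interval is the union of member windows; the lead
SNP maximizes −log10 p with ties broken by smallest physical position.

Coordinates are 1-based inclusive internally (GFF3 convention); BED export
converts to 0-based half-open. Interval overlap at a single shared bp
counts as overlap. "Local" requires strict containment of the transcribed
gene interval in the eQTL interval; everything else is distant — the terms
deliberately avoid cis/trans mechanistic claims.

## Artifact QC

Reference-gene check: any eQTL interval overlapping a reference gene's
transcribed region raises a flag (no extra distance margin — the LD window
already embodies local LD extent), and any overlapping significant eQTL
triggers it, since no principled effect-size cutoff exists for "strong
enough to bias". Both corrections are provided; covariate adjustment is
the default recommendation because it keeps the expression data consistent
across traits, renormalization without the contaminated reference is the
alternative. Primer check: markers inside user-supplied primer intervals
partition lines into favorable homozygotes (kept), unfavorable homozygotes
and heterozygotes (masked); the favorable class defaults to the majority
homozygote and can be forced. QC only ever changes inputs — reference set,
covariate list, line mask — never statistics, so corrected runs replay
from the logged configuration.

## Reporter assay model

Each cell contributes log2(reporter/normalizer) total fluorescence; the
ratio cancels transformation efficiency, and scaling both channels leaves
it unchanged. The model is log2 ratio ~ background * indel with a random
intercept per bombardment experiment, REML-fitted by the same profiled
random-intercept engine as repeatability (exact Woodbury likelihood, 1-D
search over the variance ratio). Treatment coding uses B73/absent as
reference levels so the indel effect reads as the deviation its presence
causes. Wald t-tests use residual degrees of freedom — anticonservative in
principle with 3 experiments, but the measured null type-I error at the
design scale is 0.04–0.06; an ML likelihood-ratio alternative is provided.
With zero random-intercept variance the fit collapses to ordinary two-way
ANOVA, which the tests verify against an OLS oracle to 1e-6.

## Synthetic panel

The generator reproduces the statistical structure the analysis assumes,
not sequence-level biology:

* **Hybrids as line dosages.** The panel emulates inbred lines crossed to
  one common tester; with a common parent, between-hybrid variation reduces
  to line-side alleles, so dosages are simulated directly as mostly
  homozygous 0/2 with a small heterozygous rate (default 0.01) and
  missingness completely at random (default 0.01).
* **Structure** via Balding–Nichols: group frequencies are Beta draws
  around a shared ancestral frequency with differentiation parameter F
  (default 0.10; six groups with sizes 32/34/32/16/36/102 at the default
  252 lines). A pairwise Hudson Fst estimator recovers F, which the tests
  check at F = 0.3 within ±0.05.
* **LD** via a Gaussian copula: each line carries a latent AR(1) field
  along the chromosome with correlation exp(−d/L) (L = `ld_block_len_bp`,
  default 1 Mb), thresholded at the group-specific frequency quantile.
  Both the ancestral frequency and the group deviations are themselves
  smooth fields with the same length scale, because frequency mismatch
  between neighbouring markers otherwise caps attainable r² — the
  signature of real haplotype blocks is frequency-matched SNPs. Marker
  positions sit on a jittered grid, emulating the even genome coverage
  genotyping arrays are designed for. This construction gives exact group
  frequencies, strong local LD, and monotone decay with distance; a
  founder-haplotype copying scheme was considered and rejected because
  founder-pool drift inflates realized Fst by (1−F)/K and needs tiny pools
  for comparable LD.
* **Traits**: line effect = Σ effect × dosage + polygenic draw from
  N(0, σ²_g K/mean diag K) + line-level residual + optional group shifts.
  The kinship used is the panel's own realized kinship so the simulated
  background matches the model's assumption; unit-diagonal scaling makes
  σ²_g the per-line variance.
* **Assay layer**: target Ct = base − (line effect + biological noise) +
  technical noise, with biological sd 0.4 Ct and technical sd 0.15 Ct —
  typical magnitudes for careful SYBR assays; the data's own noise
  magnitudes are not recoverable, so these are package defaults exposed in
  `AssayArtifactConfig`. The ΔCt trait then inherits noise variance
  (1 + 1/n_ref)(sd_bio² + sd_tech²/n_tech) per biological replicate, which
  the tests use to size planted repeatabilities exactly. Artifacts: a
  reference gene may carry a genetic Ct shift per allele (the
  reference-gene eQTL mechanism), and a primer-site allele may shift or
  drop target Cts in carrier lines.

What the generator does **not** emulate: coalescent genealogies, selection,
recombination hotspots, sequence-level indels (structural variants are
presence/absence tables tagging a marker), amplification-efficiency
differences between primer pairs, or inter-plate batch effects. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to these unmodeled features of real data.

## Validation scenarios and problem sizes

The test suite and `scripts/acceptance.py` use desk-scale study sizes
chosen to mirror the target design while keeping each scenario in seconds:

* Demo mapping panel: 150 lines, 3 chromosomes × 500 markers over 12 Mb
  (≈ 24 kb spacing against a 1 Mb LD scale, matching the marker-per-LD-
  window ratio of a dense array panel), one local causal explaining ~50%
  of trait variance placed 431 bp upstream of a 2.5 kb gene — promoter-
  variant geometry — plus a weaker distant causal.
* Null calibration: 252 lines, 5 chromosomes × 500 markers; the polygenic
  background (σ²_g = 0.4 against residual 0.6) is drawn from the kinship
  of chromosome 5's markers, which remain inside every LOCO matrix except
  their own — as in a real scan, where the genome-wide kinship contains
  the causal loci — and type-I error is tallied over the 2,000 markers of
  the other four chromosomes. Excluding the background chromosome from the
  kinship instead leaves discrete group structure only partially absorbed
  by the random effect and visibly inflates λ; that variant is not a
  correct null for this model.
* Artifact scenarios: reference-gene shift of 2 Ct per allele (a strong
  artifact of the kind worth correcting; it induces a ~0.67 log2 trait
  bias per allele through three references), and a primer shift of +2 Ct
  in minor-homozygote carriers with the true architecture reduced to one
  distant eQTL.
* Reporter assay: 3 experiments × 40 cells per condition, residual sd 0.6,
  experiment sd 0.3, planted indel effect −0.5 on log2 ratio.

## Known limitations

* The P3D approximation understates per-marker variance-component
  uncertainty; exact refitting is available but ~100× slower.
* The Wald tests (GWAS F, assay t) use residual df, not Satterthwaite or
  Kenward–Roger corrections; with very few experiments the assay p-values
  are mildly anticonservative.
* r²K whitening uses the global kinship; no per-chromosome LD correction.
* The window stop rule can truncate a window at a genuine LD-block edge
  adjacent to the focal SNP; merged member windows mitigate this but a
  sparse marker map cannot resolve sub-spacing intervals.
* The eQTL merge is transitive, so long chains of marginally overlapping
  windows can fuse distinct signals on one chromosome; the conditional
  scan is the intended tool for dissecting such regions.
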