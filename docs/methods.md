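# Methods

This note documents the models, estimators and numerical choices behind
the package, in the order the pipeline runs them, together with the
assumptions of the synthetic-data generator and what passing tests on it
do and do not demonstrate about real data.

## Synthetic study design

The generator emulates a controlled-environment salinity screen of a
diverse inbred panel genotyped with a dense exome-style SNP assay.

**Genotypes.** Each chromosome carries `n_blocks_per_chrom` founder-
haplotype blocks.  Within a block every line inherits one of
`n_founder_haplotypes_per_block` (default 4) founder haplotypes intact
(no within-block recombination); blocks assort freely.  Founder
haplotypes are drawn under an infinite-sites model: each SNP arises once
on a random founder genealogy, so its carriers form a clade and any
within-block SNP pair shows at most three of the four two-locus
haplotypes (|D'| = 1 among founders).  This is the structure the
confidence-interval block caller is designed to recover; with iid random
founders, four-gamete pairs inside blocks fragment detection.
Subpopulation structure (default 3 subpopulations, divergence 0.10)
enters through Balding-Nichols-style Dirichlet draws of the founder
frequencies per subpopulation.  Lines are fully inbred: dosages are 0 or
2, with a small missing rate (default 1%).  Block spans are at most
800 kb and inter-block gaps exceed 1 MB by construction, so the 1 MB
window of the block caller never straddles two planted blocks.  Default
scale: 500 lines, 5 chromosomes x 100 blocks x 8-12 SNPs (~5,000 SNPs).

**Phenotypes.** Five latent salt-response traits (growth-rate deviate,
senescence rate, old-leaf Na+, young-leaf K+/Na+, young-leaf Na+) are
generated as `sqrt(h2) g + sqrt(1-h2) e`, where both the polygenic values
`g` and the environmental deviates `e` share one target correlation
matrix; its first row carries the published phenotypic correlations
(-0.61 senescence, -0.52 old-leaf Na+, +0.43 young-leaf K+/Na+, -0.20
young-leaf Na+), and the remaining entries are plausible values chosen
once for positive semi-definiteness.  Polygenic values are drawn with iid
effects on the centred founder-indicator (hapallele) columns, so the
VanRaden GRM model used by GREML downstream is correctly specified.
Planted QTL replace part of the polygenic signal:
`g' = sqrt((h2-v)/h2) g_perp + sqrt(v/h2) d_std`, where `d_std` is the
standardised carrier dosage of the chosen founder haplotype and `g_perp`
is the polygenic score orthogonalised against the planted dosages — under
population structure a random polygenic score correlates appreciably with
any structured marker, and without the orthogonalisation the realised
effect share wanders far from its nominal `v`.

Control composite area grows linearly at `b_c = 19,500 (1 + 0.08 x_c)`
area units/day (the control slope has its own h2, default 0.3); the salt
slope is `b_s = b_c (1 - s)` with susceptibility
`s = 0.38 - 0.12 z_growth` clipped to (0.02, 0.95).  Because `b_c`
cancels in `T_t/T_c`, the SSI inherits the heritability of the growth
latent almost exactly.  Top-view area is constant per plant and side
views are back-computed so the composite reproduces the linear curve;
multiplicative measurement noise (default 4% area, 5% ion/biomass)
attaches per observation.  Dry biomass is proportional to final
composite area; leaf ions are affine in their latents with floors at
biologically sensible minima.  A configurable fraction (default 3%) of
the most susceptible accessions dies: salt-treated area drops to zero
from a random timepoint.  Imaging days default to
(0, 3, 5, 7, 10, 12, 14, 17, 19, 21) after treatment with 2 replicates
per accession x treatment; the replication count is not fixed by the
study design the generator emulates, so it is a parameter.

**What the generator does not emulate.** Image segmentation error
structure, nonlinear (logistic) growth phases, genotype-by-environment
interaction across locations, spatial glasshouse effects, and realistic
wheat demography or recombination.  Tests passing on this generator show
the estimators recover the structure they assume; they do not certify
performance under model misspecification.

Realised phenotypic correlations sit ~10-15% below their targets: the
control-slope noise in `b_s = b_c(1-s)` attenuates correlations with the
growth trait by ~0.92, and the finite number of blocks (~500 effective
loci) adds sampling spread to the realised genetic correlations.  The
generator contract is ±0.15 at n >= 300, which these effects respect.

## Trait derivation

Composite area is `((A_side0 + A_side90)/2)^2 * A_top`, exactly as the
composite-area formula is printed (the squared side term makes it a
volume-like proxy; `digital_shoot_area(..., squared_side=False)` gives
the plain side x top product, but the default does not second-guess the
printed form).  Growth and senescence rates are per-plant OLS slopes over >= 3
strictly increasing imaging days; accession values are BLUEs — least
squares means from a fixed-accession-effect model with optional batch
covariate, reducing to replicate means in a balanced design.  A
random-slope mixed model would need per-day variance components the
design cannot identify from 2 replicates, so the per-plant-OLS + BLUE
reading is used.  Dead plants (final composite area 0) get growth rate 0
(a 100% loss) and growth rates are floored at 0; their senescence slope
uses only the timepoints while the plant was alive, because a vanished
plant has no non-green area and the post-death zeros would otherwise
produce spurious negative senescence.  SSI uses population means over
accession BLUEs; division-by-zero conditions yield missing values with a
log record.  Dead accessions' SSI is capped at the maximum among
surviving accessions for reporting.  Tolerance groups: SSI < 1.0 at
every observed location = tolerant, > 1.5 at every location =
susceptible, otherwise moderate; boundary values are moderate.

## LD and haplotype blocks

Two-locus haplotypes are read directly off inbred genotypes (each line =
one haplotype).  D' follows the standard normalisation
`D' = D / D_max`; its 90% CI comes from the multinomial likelihood of
the four haplotype counts evaluated on |D'| in {0, 0.001, ..., 1} with
allele frequencies fixed at observed values and the sign of D fixed at
its MLE.  The interval trims strictly less than 5% per tail using the
right-continuous CDF for the lower bound and the left-continuous one for
the upper bound — the discrete-quantile convention that keeps the upper
bound at 1 when the likelihood concentrates there (perfect LD).

Blocks: a candidate interval must have its outermost pair in strong LD
(CI low >= 0.70 and high >= 0.98), span <= 1 MB, and >= 95% of its
informative pairs (strong LD or strong recombination, CI high < 0.90) in
strong LD.  Candidates are accepted greedily by decreasing bp span,
leftmost first on ties, discarding overlaps; LD extending beyond 1 MB
therefore surfaces as multiple blocks.  The five constants are
configuration keys; only the 95% rule and the 1 MB cap are fixed by the
published method, the CI cutoffs being the standard defaults of the
confidence-interval approach.  A brute-force all-intervals oracle in the
test suite pins the implementation exactly on small panels.

Hapalleles are the distinct allele strings of lines with complete calls
in the block; lines missing any block SNP are missing for the whole
block (all-or-nothing; mean-dosage imputation happens only inside
GRM/scan arithmetic).  Columns below 1% carrier frequency are dropped;
blocks left with fewer than two alleles are dropped with a warning.

## Mixed-model association

The GRM is VanRaden's `W W' / (sum 2 p (1-p) (1+F))`, with `W` the
2p-centred dosages and `F` the panel inbreeding coefficient estimated
from the heterozygote deficit.  For fully inbred panels (F = 1) the
denominator is `sum 4 p (1-p)`, which keeps the mean diagonal near 1;
without the `(1+F)` factor the diagonal of an inbred GRM is ~2 and the
REML "h2" parameter no longer equals the trait heritability.  Kinship
for the scan comes from LD-pruned SNPs (greedy left-to-right pass,
5 MB window, r^2 > 0.2); the GREML/genetic-correlation GRM comes from
the Hap-matrix.  PCs are eigenvectors of the standardised-genotype Gram
matrix, signs fixed so the largest-magnitude loading is positive.

The scan is P3D/EMMAX: variance components are REML-estimated once on
the null model (intercept + 4 PCs + polygenic term) by profiling the
restricted likelihood in h2 over (0, 1) in the GRM eigenbasis (21-point
grid then bounded refinement).  Each marker is then tested by GLS with
the variance ratio fixed.  The per-marker Wald test uses the
marker-model weighted residual variance with `n - p - 1` degrees of
freedom (a t test), not a chi-square with null-fixed variance: this form
reduces *exactly* to OLS ANCOVA when K = I, is exact under Gaussianity,
and differs from the chi-square version only at third-decimal p-value
precision for n in the hundreds.  Zero-variance columns are skipped with
a log entry.  Inside cross-validation runs the marker rotation `U'G`
runs in float32 (threshold decisions only; the full-data scan stays
float64).

Genomic heritability is the REML h2 on the Hap-matrix GRM; traits below
0.2 are excluded from scanning (boundary retained).  Genetic
correlations use a Haseman-Elston-style cross-product regression in the
GRM eigenbasis — `E[y1~_i y2~_i] = sigma_g12 S_i + sigma_e12` fitted by
variance-weighted least squares — combined with per-trait REML
variances; the classic pairwise off-diagonal HE regression is
catastrophically noisy under subpopulation structure because
cross-product errors correlate across pairs sharing an individual,
whereas the eigenbasis form concentrates the information in the
high-eigenvalue structure axes.  r_g is clipped to [-1, 1] and reported
with r_g^2 (the published convention is ambiguous between the two, so
both appear).

## Stability selection and thresholds

Lines are partitioned into 5 near-equal folds, 20 times (fold sizes
differ by at most 1; all randomness flows from named substreams of one
master seed).  Each of the 100 runs rescans the ~80% training lines with
PCs and variance components re-estimated inside the run; kinship is the
row/column subset of the full-data GRM (the published procedure computed
kinship once, and per-run recomputation changes third-decimal p-values
at 100x the cost).  Per-run PCs are computed from the double-centred
subset of the full-panel Gram matrix — exact subsample centring with
full-panel column scaling — which is algebraically the PCA of the
subsample under fixed marker scaling and keeps 3,000 CV scans tractable.
A hapallele is stable when `-log10 p > 5` in strictly more than 50 of
the 100 runs (50 exactly fails).  The modified Bonferroni threshold is
`alpha / n_blocks` with the LD-block count as the effective number of
independent tests; stable associations failing it are retained and
flagged, never silently dropped.  An optional Benjamini-Hochberg column
is available for users wanting a literal FDR.

## QTL delineation and downstream

Association midpoints on a chromosome are single-linkage chained while
neighbour gaps are <= 4 MB; a chain may span up to 8 MB in total, beyond
which it splits recursively at its largest internal gap (leftmost on
ties) — the only reading consistent with both printed bounds.  Names use
floor(start/1 MB) and ceil(end/1 MB), collapsing to a single number
within one MB (QTL.2A.67 style).  Adjacent QTL closer than 20 MB are
cross-referenced as possibly one locus but never merged.  Carrier
enrichment across tolerance groups uses two-sided Fisher tests with a
Bonferroni summary over the tested hapalleles.  Novelty: a QTL within
10 MB edge-to-edge of any prior interval on the same chromosome is
*known*, else *novel*.

Gene tests take SNP-level summary statistics from an auxiliary EMMAX
scan over the SNPs in the candidate gene regions (the haplotype scan
itself produces no per-SNP statistics), then form
`T = sum_i [Phi^{-1}(p_i/2)]^2` over the >= 2 polymorphic SNPs within
gene +/- 2 kb.  The null is `sum_j lambda_j chi2_1` with lambda the
eigenvalues of the signed SNP correlation matrix from the same panel.
Tail probabilities use Imhof's inversion integral computed by a
vectorised midpoint rule — >= 24 points per oscillation period, stopping
when the oscillatory-tail truncation bound `envelope/theta'` falls below
1e-11 (scipy's adaptive quadrature fails on this integrand) — with a
Lugannani-Rice saddlepoint fallback for tails beyond the integrator's
reach (p < ~1e-10).  The saddlepoint carries a known few-percent
relative error on small spectra; equal-eigenvalue and rank-1 spectra use
the exact chi-square forms.  Significance is the strict p < 0.001 of the
method description (the discussion's 1e-5 figure is not implemented).
GO over-representation is a one-sided Fisher test against the reference
set with fold enrichment `(k/n)/(K/N)`; no multiple-testing correction
gates the reported p < 0.05 flag, matching the published reporting rule,
with a BH column alongside for transparency.

## Numerical choices and degenerate inputs

- REML clips GRM eigenvalues at 0; a near-identity kinship is flagged
  `degenerate` (components non-identifiable, weights unaffected).
- GRM construction mean-imputes missing dosages and errors on fully
  monomorphic input; a 1e-6 ridge stabilises Cholesky factorisations.
- SSI division-by-zero conditions, constant traits in correlations and
  zero-variance scan columns all yield missing values with log records,
  never exceptions.
- p-values are floored at the smallest positive double.
- Chromosomes with no qualifying block intervals return empty lists;
  empty stable-association sets propagate as empty QTL/gene tables.

## Problem sizes

The test suite and the acceptance script run the full design at 500
lines and ~5,000 markers: block-detection oracle equivalence on 200
random 12-SNP panels, null-calibration and power scans at 5,000
hapallele pseudo-markers, 100-run CV stability selection across 30
simulation replicates, and the end-to-end pipeline with two planted QTL
(10% and 8% variance on the tolerance index), chosen as the scale at
which the planted effects sit near the procedure's published operating
point while the whole suite stays desk-sized.

## Known limitations

- P3D fixes variance components at the null fit; markers with very large
  effects are slightly conservative (the exactness bound is tested).
- The saddlepoint fallback's few-percent tail error means gene p-values
  below ~1e-10 are approximate; significance calls at p < 0.001 are
  unaffected.
- HE-based genetic correlations are moment estimates; a bivariate REML
  backend would be more efficient and is a natural extension point.
- Block detection assumes biallelic, physically sorted markers; no
  statistical phasing is attempted (inbred panels only).
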