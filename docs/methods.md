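# Methods

This note documents the models, algorithms and design choices behind
`fcdecode`, in the spirit of a statistics-package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator produces two-group BOLD cohorts in which every distributional
choice is explicit, because the pipeline's validation rests on knowing the
ground truth.

**Signal model.** Each voxel time series is a stationary AR(1) process
x_t = φ x_{t−1} + √(1−φ²) ε_t with unit marginal variance (φ = 0.3 by
default; AR(1) is the minimal temporally correlated noise model and the
coefficient is configurable). Voxels of the two *planted* regions receive

    x_v = sgn_v · √|ρ| · L + √(1−|ρ|) · η_v,

where L and η_v are independent unit-variance AR(1) processes and sgn
carries ρ's sign in the second region, so the expected correlation between
any two planted voxels in different regions is exactly ρ. This gives an
analytically controlled effect size; the generator exposes
`planted_pair_correlation` as a direct sample-correlation readout, and the
calibration tests require the realized correlation within ±0.1 of ρ at
2000 timepoints.

**Nuisance structure.** A slow confound (AR(1), φ = 0.95) is carried by a
reserved ventricle block at amplitude `nuisance_amplitude` (default 0.5)
and bleeds into brain voxels at 20% of that amplitude; six motion traces
are smoothed random walks that couple into every voxel through small random
loadings (10% of the nuisance amplitude). These amplitudes are deliberately
modest so the planted correlation remains the dominant structured effect
(the shared-confound variance contribution is ~0.01), while still giving
the regression stage realistic collinear columns to remove. A constant
baseline of 100 mimics raw BOLD units.

**Geometry.** The default cohort is a scaled-down acquisition: 6 + 6
subjects, a 20×20×4 grid with 220 volumes at TR 1.2 s (so 200 remain after
trimming 20). The full-scale counterpart (23 + 19 subjects, ~100×100×24
voxels, 500 volumes) would change nothing methodologically. The voxel size
is (1, 1, 3) mm: the grid spans the same 2×2 cm field of view and 12 mm
slice stack as the acquisition it emulates, so down-sampling the matrix
means coarser voxels, and spatial parameters specified in millimetres
(smoothing FWHM) keep their physical meaning. Parcellations are built by
recursive proportional bisection into connected rectangular blocks; the
ventricle occupies a reserved corner block labelled as background.

**What the generator does not emulate.** Scanner artifacts (spikes are
injected only by dedicated test fixtures), slice-timing and motion
displacement (data are generated aligned — motion enters only through the
regressors), anatomical contrast, and spatial autocorrelation of the noise
(smoothness enters only through the smoothing stage). Passing tests
therefore demonstrate the statistical machinery under a known, idealized
generative model — not robustness to the full messiness of acquired data.

## Preprocessing

Fixed order: trim → despike → nuisance regression → spatial smoothing →
band-pass. Temporal artifact removal precedes the spatial/spectral
operations so that spikes and nuisance variance are not smeared before
they can be estimated, and filtering runs last so regression cannot
reintroduce out-of-band energy.

- **Trim**: drop the first 20 volumes (T1 equilibration), configurable.
- **Despike**: per voxel, quadratic least-squares trend; residual spread
  estimated robustly as 1.4826 × MAD; residual magnitudes s (in robust SDs)
  above c1 = 2.5 are mapped to c1 + (c2−c1)·tanh((s−c1)/(c2−c1)), capping
  at c2 = 4. The constants are exposed; nothing in the compressed region
  below c1 changes. Voxels whose residual spread is numerically zero
  (constant or exact-polynomial series) pass through unchanged.
- **Nuisance regression**: ordinary least squares of every in-mask voxel
  on [intercept | ventricular mean | 6 motion traces]. The intercept is
  always included — downstream correlations are mean-invariant and it makes
  the perfect-fit case exact. A pivoted-QR rank check rejects collinear
  designs and names the offending columns.
- **Smoothing**: per-volume Gaussian, σ_mm = FWHM/(2√(2 ln 2)) converted to
  voxel units per axis, mask-normalized (numerator and denominator both
  masked) so out-of-mask values never bleed in; out-of-mask voxels are left
  untouched. FWHM = 0 is the identity.
- **Band-pass**: order-2 Butterworth applied forward-backward (zero phase)
  per voxel, default window 0.01–0.1 Hz; a low cut of 0 degrades to a
  low-pass. The filter family and order are implementation choices exposed
  as parameters; the acceptance checks pin the contract (≥90% amplitude at
  0.05 Hz, ≤10% at 0.2 Hz for TR 1.2 s) rather than a specific transfer
  function.

Volume realignment ("motion correction") is intentionally out of scope:
synthetic data are generated aligned and motion influences the signal only
through the regressors.

## Connectivity statistics

**Global connectivity** is the self-excluded mean correlation of a voxel
with all other in-mask voxels, averaged in Fisher-z space and
back-transformed (tanh of the mean atanh r). Averaging in z space
variance-stabilizes the mean and matches the convention of reporting an
"r score". Correlations are clipped at |r| = 1−1e−7 before atanh;
zero-variance voxels are excluded from both target and reference sets and
logged. Brute-force equivalence (≤1e−10 on ≤30-voxel grids) is part of the
acceptance suite.

**Group inference** uses voxelwise two-sample pooled-variance t statistics
on Fisher-z maps with df = n_a + n_b − 2 from the actual group sizes. The
cluster-defining threshold defaults to the two-sided critical t at those df
and α = 0.05; it is a free parameter because published analyses sometimes
fix it by convention (e.g. a t(24) threshold of 2.06, which this package
reproduces as the critical value at 24 df) rather than derive it from the
cohort at hand.

**Cluster FWE correction** is nonparametric: suprathreshold voxels
(positive and negative separately, 6-connectivity/faces-only) form
clusters; group labels are permuted (exhaustively when the number of
distinct relabelings does not exceed `n_perm`, otherwise by seeded random
draws with an add-one correction), and each observed cluster's corrected p
is the fraction of relabelings whose maximum cluster extent reaches its
extent. Permutation is exact under exchangeability and requires no
smoothness estimation. Two practical properties matter at desk scale:

- *Discreteness*: with 4+4 subjects only 70 relabelings exist, so
  achievable p-values near 0.05 are coarse and tie-inflated, making the
  test conservative. The null-calibration experiments therefore use 5+5
  subjects (252 relabelings), which restores near-nominal behaviour.
- *Smoothness*: the maximum-extent null only discriminates when maps have
  spatial structure. On spatially independent maps nearly all suprathreshold
  clusters are singletons and the test can barely reject; the calibration
  cohorts run through the full preprocessing chain on 0.25 mm in-plane
  voxels so the 0.6 mm kernel induces realistic smoothness.

The family-wise false-positive rate over 200 null cohorts is required to
lie in [0.01, 0.12] around the nominal 0.05 (binomial tolerance).

**FDR** uses Benjamini–Hochberg step-up (via statsmodels) wherever multiple
hypotheses are reported together.

## Expression decoding

Regional expression energies (mean over a region's voxels of a per-gene
energy volume, or consumed directly as a genes × regions table) are
normalized per gene by the total over regions; genes with zero total are
dropped and logged rather than imputed — a probe with no signal carries no
ranking information and its normalization is undefined.

Two candidate-selection modes per region pair:

1. **Fixed threshold**: genes in the top ⌈qN⌉ (q = 0.20) of both regions'
   normalized values, with ties broken by gene id for determinism; each
   annotation set is tested with the hypergeometric upper tail of its
   overlap with this selection.
2. **Flexible threshold**: genes ranked by the sum of normalized values in
   the pair (the L1 score, which also favours strong single-region genes);
   each set is tested with the minimum-hypergeometric statistic — the
   minimum over all list prefixes of the hypergeometric tail — whose exact
   p-value is computed by a dynamic program over the lattice of
   (prefix length, targets seen) states: the probability, under uniformly
   random orderings, that a path enters the region where the tail is at
   most the observed minimum. The absorbed probability mass is accumulated
   directly, so extremely small p-values are sums of positive terms rather
   than a catastrophic 1−(1−p) cancellation. For lists of ≤8 genes the DP
   is verified against complete enumeration of orderings; for larger lists
   against 10,000-shuffle Monte Carlo within 3 standard errors.

The gene universe is the set of genes retained in the normalized matrix.
BH-FDR is applied across annotation sets within each mode. Specificity is
assessed by rerunning the decoding on randomly drawn region pairs
(excluding the focal pair) and comparing counts of significant sets; the
planted-effect recovery criterion requires the focal pair to beat the
median control strictly.

## Gene-set overlap

`build_contingency` cross-classifies an explicit gene universe by DEG and
risk-list membership (risk genes outside the universe are dropped with a
logged count — no default universe is ever invented, since both the p-value
and the odds ratio depend on it). The two-sided Fisher exact p sums, in log
space, hypergeometric point probabilities not exceeding the observed one
(the `fisher.test` convention; other two-sided conventions exist). The
odds ratio is the sample cross-product ratio ad/bc by default (+∞ when
bc = 0 with ad > 0, 0 when ad = 0 with bc > 0, NaN with a warning for
degenerate margins); the conditional-MLE estimate is available behind a
flag. Neither estimate is claimed to match any particular published value,
whose underlying universe is typically unstated.

## Numerical choices and degenerate inputs

- Correlation clipping at 1−1e−7 before atanh; despike robust-SD floor
  relative to signal magnitude; zero-variance voxels excluded and logged.
- Hypergeometric tails via log-gamma with max-factored summation; the mHG
  tie guard compares tails with 1e−9 relative slack.
- Ties in gene ranking always break by gene id ascending; cluster tables
  sort by extent descending; permutation draws use
  `numpy.random.default_rng` seeded explicitly everywhere.
- Infeasible requests (over-trimming, empty ROIs/seeds, rank-deficient
  designs, region counts exceeding voxels, overlaps exceeding set sizes)
  raise `ValueError` with the offending quantity named.

## Problem sizes

Default experiment sizes were chosen so the entire validation suite runs on
a single CPU in minutes: 6+6 subjects on a 20×20×4 grid for effect
recovery, 5+5 on 12×12×3 for the 200-cohort null calibration, 500 genes ×
40 regions with a 50-gene planted set (10 annotation sets) for decoding,
and a 2000-gene universe for the overlap demonstration. These sizes are
statements about the synthetic study design, and all are configurable.

## Known limitations

- The permutation cluster test is exact but coarse for very small cohorts;
  below ~5 subjects per group the achievable p-values may not reach 0.05.
- The mHG DP is O(N·B) per set; for genome-scale lists (N ~ 2×10⁴,
  B ~ 10³) a run takes seconds per set, not milliseconds.
- The generator's noise is temporally AR(1) and spatially white; empirical
  BOLD noise is neither, so calibration results transfer to real data only
  to the extent those assumptions are benign.
- No volume realignment, slice-timing, distortion or physiological-noise
  correction; no ICA or dynamic connectivity; no GO-graph propagation
  (annotation sets are taken as given).
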