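# Methods

This note documents the models, parameter choices and numerical
conventions behind `nemascore`, and what the synthetic validation does
and does not establish.

## Pillar tracking

Frames are bright-background grayscale images with pillars as dark
disks. Detection is Otsu thresholding, connected-component labelling,
an area band (¼–4× the nominal disk area) plus a solidity filter
(≥ 0.8) to reject speckle, and intensity-weighted centroids for
sub-pixel localization. This is a deliberate reimplementation choice:
it is fast, and on disk-like objects the weighted first moment is
accurate to well under a quarter pixel. Hough-type circle detection
would add cost without accuracy here.

Centroids are assigned to the nearest rest-lattice site; deflection is
`(centroid − rest) × pixel_size`. Conventions:

- Coordinates: x rightward, y downward, origin at the top-left pixel
  center; lattice indices 0-based (row, col).
- **Noise floor ε** = 0.5 px-equivalent (0.815 µm at 1.63 µm/px).
  Pillars below ε are "not in contact"; the per-frame maximum is taken
  over in-contact pillars only, and a frame with no contacts reports
  zero deflection with a null index. Real acquisition jitter motivates
  some floor; its exact value is our construct.
- Ties at the per-frame maximum break to the lowest (row, col)
  lexicographically.
- A centroid within half a pitch of two sites (including the exact
  midpoint tie) or two centroids contending for one site are flagged
  ambiguous. A deflection *exceeding* half the pitch raises an error:
  nearest-site assignment is then meaningless by construction. The
  boundary case |δ| = pitch/2 is the representable tie, so it is
  flagged rather than raised.
- The rest lattice comes from the arena configuration. (Estimating it
  from a worm-free first frame is possible but not needed for the
  synthetic arenas, whose geometry is known exactly.)

## Force model

Forces come from the stiffness of a base-clamped circular cantilever
loaded at the contact height z:

    compliance(z) = z³/(3EI) + z/(κGA),   I = πd⁴/64,  A = πd²/4,
    G = E/(2(1+ν)),  κ = 6(1+ν)/(7+6ν)  (circular section)

The shear term matters because the pillar is stout (h/d ≈ 2): for the
default geometry it contributes ~14% of the compliance. Pure bending is
available via `include_shear=False` and is the slender-pillar limit.

Defaults: E = 2.6 MPa, ν = 0.5 (typical cured 10:1 PDMS), contact
height = pillar tip (the softest, worst-case response; the true contact
point along the pillar is not observable in brightfield). All three are
configurable on `PillarArena` / the conversion functions. Absolute
forces in µN are model-dependent; every downstream quantity (Z-scores,
normalized scores, fold changes, ranks, regressions) depends only on
ratios and ranks across strains measured with the same model, and is
insensitive to this calibration.

## Strength statistic

f₉₅ is the 95th percentile of per-frame maximal forces over a
one-minute, 5 fps video (300 frames), using the linear-interpolation
percentile convention (fractional order-statistic position
1 + 0.95(n−1)); a length-1 trace returns its value. The convention is
fixed and tested against an independent sort-based oracle. f₉₅ is
normalized by the cube of body diameter (µN/µm³) to remove the strong
dependence of exertable force on girth; the per-strain summary for
scoring is the mean of per-worm normalized strengths with its standard
error. Strain-vs-WT comparisons use the two-sided Wilcoxon rank-sum
test (normal approximation, tie and continuity corrections); a pooled
sample with all values identical returns p = 1 with a warning.

## Burrowing

The endpoint statistic is the percent of loaded worms at the surface at
120 min, averaged over replicate wells with replicate-level SEM (a
single replicate reports SEM 0 with a warning). Counts are expected to
be non-decreasing (worms at the attractant stay); the reader warns on
violations. The strain × time analysis is a conventional fixed-effects
two-way ANOVA on replicate percentages — percentages, not raw counts,
because that is the quantity the curves display — requiring a complete
strain × time design with ≥ 2 replicates per cell.

For Z-scoring, the pipeline floors the wild-type endpoint SEM by the
pooled binomial standard error with Laplace smoothing
(`endpoint_binomial_sem`). With a few replicate wells of a strong
burrower, all wells can report identical counts, which would put a
degenerate 0 in the Z denominator; the binomial floor is the smallest
uncertainty consistent with counting n worms. This floor only engages
when replicate scatter collapses below sampling noise.

## Scoring

- **Z-score**: Z_j = (μ_j − μ_WT)/σ_WT per assay. **σ_WT is the
  wild-type standard error of the mean**, not the standard deviation —
  worth stating prominently since σ conventionally denotes an SD. Z
  therefore measures separation relative to the precision of the WT
  mean, and grows with WT sample size; this matches how the assay
  means are summarized (mean ± SEM).
- **Normalization**: each assay's Z vector is divided by max|Z| taken
  over all strains present including wild type. Rank order is
  preserved; the minimum is exactly −1 whenever the extreme strain is
  impaired. Strains better than WT (Z > 0) are not clamped; they map
  to positive normalized values.
- **MFS** = equal-weight sum of the two normalized Z-scores, in
  [−2, 0] for all-impaired panels. PCA (eigen-decomposition of the
  2×2 correlation matrix of the column-standardized Z matrix) is a
  diagnostic: its first component reports how much variation a single
  latent axis explains, and its loadings are flipped so both are
  non-negative (impaired strains project negative). With two
  standardized columns the loadings are exactly (1,1)/√2 whenever the
  assays correlate positively — the formal statement of "both assays
  weighted almost equally". A zero-variance column is degenerate:
  warning, variance explained reported as 1.
- **MDS**: sum of five site scores, each validated to [0, 3] in 0.5
  steps (half-points occur in real by-eye scoring). Range 0–15. The
  packaged fixture `fixtures/table2_mds.csv` transcribes a published
  21-strain table (five sites, printed MDS, and per-site provenance:
  69 scores from that study's staining, 36 from literature/unpublished
  reports); the test suite re-sums all 21 rows.

## Structure–function

MFS (y) is regressed on MDS (x) by OLS — function against structure,
matching the orientation in which the correlation is usually displayed.
All strains in the score table, wild type included, enter the fit by
default. 95% **prediction** intervals (not mean-confidence intervals)
are computed at each observed x from the residual variance, leverage,
and the t quantile on n−2 df. Exactly collinear data yield R² = 1 and
zero-width bounds, flagged degenerate with a warning. The R² of the
simple fit equals the squared Pearson correlation (asserted to 1e-10 in
tests). `coverage_check` reports the fraction of points inside the
bounds; on training points coverage runs slightly above nominal
(residuals are shrunk by (1−h) while the interval width carries
√(1+h)). Spearman correlation is the Pearson correlation of average
ranks, with an explicit error on constant input.

## Synthetic data generator

What it emulates, per strain profile (all driven by a shared latent
`health` ∈ [0, 1], all generators pure functions of parameters + seed
via `numpy.random.default_rng` / `SeedSequence.spawn`):

- **Force traces**: i.i.d. lognormal per-frame maximal forces with
  given mean and CV. Lognormal is a modelling choice — positive,
  right-skewed, matching the character of maximal-force series; real
  traces are also autocorrelated (gait periodicity), which is *not*
  emulated and does not affect a percentile statistic's target, only
  its effective sample size.
- **Burrowing**: each worm succeeds with probability
  `burrow_success`; succeeders arrive at the surface after an
  exponential time with rate `burrow_rate` (1/min). Two parameters map
  to the two observed behaviors: plateau level and rise speed. True
  endpoint fraction: success × (1 − exp(−rate·120)).
- **Site scores**: Gaussian noise on the latent per-site bias, rounded
  to 0.5 steps, clamped to [0, 3] — reproducing the half-point
  granularity of by-eye scoring.
- **Arena frames**: anti-aliased dark disks at rest+deflection
  positions on a bright background (230 vs 50 gray levels), additive
  Gaussian noise, 8-bit output. Worm bodies, cuticle texture and
  optics are out of scope; deflections beyond half the pitch are
  refused because tracking would be ambiguous by construction.

Default study conditions (chosen once as a realistic scale):
20 mutants + wild type with health spread over [0.05, 0.95]; strength
scale falling to 40% of WT for the sickest strain with CV 0.3 and
n = 25 worms of 300 frames each; burrowing success 0.1 + 0.9·health and
rate 0.01 + 0.06·health (worst strains plateau near 7% at 2 h, the
best near 100%), 3 wells × 30 worms scored every 15 min for 2 h;
site-score noise SD 0.25. Diameters are lognormal (CV 0.05) around
55–65 µm, shrinking mildly with illness.

Ground truth stored per strain: the mean of analyzer-computed per-worm
f₉₅ on the generated traces (so generator and analyzer agree by
construction), the analytic endpoint fraction, and the noise-free MDS.

**What passing synthetic tests shows — and does not.** Recovery of the
health ranking, the negative MFS-on-MDS slope, and near-equal PCA
loadings demonstrate that the pipeline's statistics are implemented
correctly and are mutually consistent under a one-factor world. They do
not show that real mutants follow a one-factor model (real assays are
expected to be only modestly rank-correlated), nor calibrate absolute
forces, nor validate the ordinal scoring against images.

## Validation scale

The repeated-study validation runs 200 simulated 20-mutant studies at
the default conditions and checks: negative structure–function slope in
≥ 95% of runs, PCA loadings within 0.1 of equal weights, and the mean
between-assay Spearman within 0.15 of its generator-implied value
(1.0 for the monotone default panel). The full-scale tracking check
renders 300 frames of a 10×10 arena with deflections up to a quarter
pitch and noise at 5% of the dynamic range, and requires every
recovered magnitude within 0.5 µm of truth.

## Known limitations

- The tracker assumes disk-like pillar images without a worm body
  occluding them; real-video segmentation is out of scope.
- Contact height is unobservable and defaults to the tip; absolute
  forces scale accordingly (ratios do not).
- The exponential-arrival burrowing model has no lag phase; real
  curves often do. The endpoint statistic is insensitive to this.
- With two assays, correlation-based PCA constrains loadings to equal
  magnitude; the informative diagnostic is the variance explained.
- σ_WT as SEM makes Z-scores grow with WT sample size; comparisons
  across studies require comparable WT n.
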