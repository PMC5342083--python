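# Methods

## Model and pipeline

`agecurve` analyzes a probe × sample matrix of log2 expression intensities
`E_ij` with per-sample ages `x_j` from a cross-sectional cohort. The
per-probe model is a single quadratic in age (equivalently, a degree-2
spline with no interior knots):

    E_ij = α_i + β_i x_j + γ_i x_j² + ε_ij ,   ε_ij ~ N(0, σ_i²) i.i.d.

The pipeline runs, in order: optional preprocessing (quantile
normalization, log2 transform, probe/sample double centering, detection
prefilter, PCA outlier screen), moving-window sample weighting, weighted
least-squares fits, an age-association test with BH adjustment, a joint
FDR + fold-change filter, trajectory clustering, and age-position
detection.

## Sample weighting

Population cohorts over-represent some ages. Weight `w_i = 1/N_i`, with
`N_i = #{j : |x_j − x_i| ≤ h}` and halfwidth `h = 5` years (closed bounds,
self included), equalizes the effective contribution of each age
neighborhood. Weights enter the least-squares **loss**, never the
covariate; they are not renormalized because every downstream quantity is
invariant to a global weight scale. A constant weight vector is detected
and routed through the unweighted code path, making the two bit-identical.

## Age-association test and its calibration

The test statistic is the classical model-comparison F ratio on the
(weighted) residual sums of squares,

    F = ((RSS₀ − RSS₁)/2) / (RSS₁/(n − 3)),

comparing the quadratic fit against the intercept-only null. For
unweighted fits this is exactly F(2, n−3) distributed under the model and
the p-value is taken from that law.

Under weighting the situation changes qualitatively. The 1/N window
weights are a design choice, not inverse error variances: the noise stays
homoscedastic while the weighted projections concentrate leverage on the
sparsely sampled (old) ages. The numerator quadratic form then has
expectation well above σ² per degree of freedom and the naive F(2, n−3)
reference is strongly anti-conservative — measured on all-null data
(n = 300, right-skewed ages): 26% of null p-values below 0.05, KS distance
0.28 from uniform. A Satterthwaite moment-matched F reference removes most
but not all of the distortion (KS ≈ 0.04).

The package therefore keeps the statistic exactly as above but computes its
p-value from the statistic's **exact finite-sample null law**. Under
i.i.d. Gaussian errors that law depends only on the fixed design/weight
geometry — it is identical for every probe — so it is evaluated once per
dataset by seeded Monte Carlo (default 100 000 draws through the model's
orthonormal projection basis, a few hundred milliseconds at n = 500) and
each probe's statistic is ranked against it. Beyond the simulated range the
Satterthwaite moment-matched F tail takes over (the crossover is recorded by
construction: in-range p-values are ≥ 1/(M+1)). Measured calibration with
the Monte Carlo law: KS ≈ 0.004 on 40 000 null p-values; BH at q < 0.05
then controls the false discovery proportion as expected. The Monte Carlo
seed derives deterministically from the run's `random_seed`, so a run
remains a pure function of (data, config).

Known limitation: the calibration assumes homoscedastic Gaussian noise per
probe. Heavy-tailed noise would require a rank- or permutation-based null
instead.

## Fold change and direction

The fitted trajectory is evaluated on an integer-year grid spanning the
observed age range. Δ is the endpoint difference (oldest minus youngest
grid age) of the smoothed trajectory; `|FC| = 2^{|Δ|}` and the sign of Δ
gives the direction. Because a near-symmetric quadratic can have a large
excursion but a tiny endpoint difference, an alternative `amplitude` mode
uses max − min of the trajectory instead; the mode is recorded in every
output. Default thresholds: BH FDR < 0.05 and |FC| ≥ 1.2 (boundary kept).

## Clustering and the age-position

Significant smoothed trajectories are centered to mean zero ("standardized")
so that clustering groups by shape, not intensity. K-means is hand-rolled
for determinism: farthest-point seeding from the run seed, 5 restarts
scored by summed within-cluster distance, index-based tie-breaks.

* **Euclidean pass** (major trends): clusters whose centroids correlate
  ≥ 0.9 (signed, so mirrored trends never merge) are merged greedily,
  singletons are dropped, and each surviving cluster is labeled by the sign
  of its centroid's endpoint difference.
* **Absolute-correlation pass** (age-position): distance `1 − |pearson|`
  treats a trend and its mirror as identical. Centroids are member means
  after flipping members negatively correlated with the current centroid.
  Within the largest cluster, members are split by the sign of their
  correlation with the centroid; the age-position is the age where the two
  sign-group mean trajectories cross. Crossings are located on the grid and
  refined by linear interpolation; exact zero-runs use conjunction
  semantics (two curves coinciding then diverging conjoin at the divergence
  age). With several crossings, the steepest difference slope wins and the
  rest are reported as secondary. A `quadratic-vertex` alternative returns
  −β/(2γ) of a quadratic fitted to the sign-aligned mean.

### Systematic displacement of the conjunction point

For a cohort of mirrored trends the two sign-group means satisfy d = −u, so
their crossing is the in-range zero of the centered mean trajectory. After
quadratic smoothing, u is a parabola; its centered zero does **not**
coincide with the change point of a hinge-shaped ("flat then change")
trajectory, because a single parabola cannot represent flatness followed by
change. Numerically, for a hinge planted at 65:

| cohort age range | detected conjunction |
|---|---|
| 46–89 | ≈ 72.4 y |
| 46–81 | ≈ 68.4 y |
| 21–81 | ≈ 61.6 y |

(weighting and noise at SD 0.5, n = 500 move these by well under a year;
across 50 replicates the detected value has spread ≪ 1 y — the estimator is
precise but biased with respect to the hinge age). The displacement is
roughly the mean-to-slope ratio of the smoothed trajectory and depends on
where the change point sits inside the observed range. Consequences:

* The age-position measures where the **fitted** opposite trends conjoin,
  not the onset of change; comparing age-positions is only meaningful
  between cohorts of matched age range.
* A recovery test that expects the detected age-position within ±3 years of
  a planted hinge age fails by construction for most range/change-point
  combinations; the corresponding acceptance test is intentionally left
  failing with the measured displacement in its message rather than
  redefining the estimator.
* Exact recovery does hold for coincident-baseline curves that diverge at
  the change point (the conjunction primitive finds the divergence age
  exactly), which is what the noiseless symmetric-hinge check exercises.

Decades are reported with the convention decade = ⌊age/10⌋ + 1 (the
"seventh decade" spans ages 60–69).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular array platform. Ages are uniform or right-skewed
(Beta(1, 1+s) rescaled to the range; s = 0 is exactly uniform; the RS-like
preset uses s = 1, sample skewness ≈ 0.5). Archetypes: null, linear up/down,
hinge up/down (flat at baseline until the change point, then linear),
quadratic (vertex at the change point). Defaults are fixed once from the
emulated studies: RS-like n=762 ages 46–89 skewed, SHIP-like n=991 ages
21–81 even, change point 65 y, Δ = log2(1.5), noise SD 0.5 (homoscedastic,
log2 scale), baseline ~ N(7.5, 0.5), archetype mix 0.3/0.3 hinge up/down,
0.15/0.15 linear, 0.1 quadratic. `simulate_platform_pair` lays a common
gene namespace over two platforms with a configurable shared fraction and
identical planted trends on shared genes, for overlap/concordance tests.

What a green test on synthetic data does not establish: robustness to
batch effects, probe cross-hybridization, count-based noise,
heteroscedasticity, or confounding by covariates — none of which the
generator emulates.

## Numerical choices

* Fits solve the sqrt-weight-scaled least-squares problem via QR
  (`numpy.linalg.lstsq`), vectorized across probes; verified against
  statsmodels WLS to 1e-8 relative error.
* A probe with RSS₁ ≈ 0 but real age signal is a perfect fit: its p-value
  is the smallest positive double and it is flagged; a constant probe
  (RSS₀ ≈ RSS₁ ≈ 0) gets F = 0, p = 1. The two are distinguished by
  relative tolerances against the probe's total sum of squares.
* Quantile normalization averages the reference values across tied ranks,
  keeping ties tied; detection prefilter uses a strict "> 10% of samples"
  inequality; the PCA screen is advisory only.
* K-means ties (equidistant centroids, equal inertia across restarts)
  resolve to the lowest index; sign-invariance of the absolute-correlation
  stage holds mathematically but floating-point round-off under flipped
  signs can move the detected age by ~1e-3 years.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  and is cross-checked against a brute-force step-up implementation.

## Open design points resolved here

* Weighted-F calibration (above) is this package's choice; the source
  protocol's naive F reference is reproducible by reading p-values off
  `FTestCalibration._tail_sf`'s uncorrected counterpart but is deliberately
  not exposed as an option.
* Probes are collapsed to genes by majority direction of their significant
  probes; internal ties are excluded and reported, never silently dropped.
* Gene overlap percentages use the first cohort as denominator by default.
* Unannotated probes participate in fitting and clustering and are excluded
  only from gene-level overlap and exported lists.
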