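# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and the choices made where the design was
genuinely open.

## The measurement chain

### Image standardization

Egg photographs are assumed linear (no gamma). Reflectance calibration
uses grey standards photographed in the same frame: with a single
standard (as with a 17% grey card) the map is gain-only,
`x → x·(R/m)` for measured value `m` and known reflectance `R`; with
two standards (e.g. patches of reflectance 36.2% and 19.8%) it is the
linear gain-plus-offset map through both (measured, reflectance)
points. Two-point calibration with equal measured values is degenerate
and raises. Gain-only for one standard and gain+offset for two is a
design choice: it uses exactly the information each protocol provides.
Output is clipped to [0, 1].

Greyscale is the green channel, which tracks the spectral sensitivity
of the avian double cones implicated in pattern processing. Eggs are
cut out, masked onto an artificial black background, and resampled
(bilinear — scale-stable for blob statistics) to the common analysis
scale of 29 px mm⁻¹; the mask bounding box is kept with a 5-px black
margin so keypoint detectors retain context. Only one side of each egg
is analysed.

### Feature detection

Keypoints come from scikit-image's SIFT (difference-of-Gaussians
detector, gradient-histogram descriptor). Three filters are applied on
top, all calibrated once against the synthetic generator's ground-truth
marking lists:

* **Boundary** — a keypoint must clear the mask edge by
  max(4 px, 1.0·σ); the artificial black edge otherwise contributes
  spurious coarse-scale responses.
* **Scale cap** — features with σ > 2.5 mm are discarded; they are
  responses to the masked egg outline itself, not to any marking.
* **Polarity** — only bright-on-dark extrema are kept (`bright_only`),
  since pigment markings are local intensity maxima; dark-gap responses
  between markings otherwise roughly double the count.

In-mask contrast is normalized before detection, making detection
exactly invariant to a constant intensity rescaling. Orientation and
cross-octave duplicates of one marking are collapsed by greedy
non-maximum suppression within max(2 px, 0.6·σ). Each surviving
keypoint is encoded as 132 numbers: the 128-bin descriptor (scaled to
[0, 1]) plus normalized x, y, scale and orientation. The 128 + 4 layout
is an interpretation — downstream traits need the geometry anyway.

### The six traits

For an egg with feature set F (|F| = n):

| trait | definition | degenerate case (n ≤ 1) |
|---|---|---|
| T1 | n | 0 or 1 |
| T2 | mean pairwise distance of feature positions ÷ egg major-axis length | 0 |
| T3 | SD/mean of feature scales (sample SD) | 0 |
| T4 | 1 − mean resultant length of orientations (circular variance, ∈ [0, 1]) | 0 |
| T5 | mean |∇I| over the mask interior (mask eroded 2 px so the boundary step does not contribute) | computed from pixels |
| T6 | best k-means silhouette on positions (k ∈ 2…8, clipped at 0) × mean within-cluster descriptor SD | 0 |

T2 measures dispersion across the egg: mean pairwise distance was
chosen over coordinate variance because it is rotation-invariant and
normalizes naturally by egg size. For T6, the clustering-tendency
factor is the silhouette width rather than the between-cluster variance
fraction: k-means explains a large variance fraction even for spatially
uniform points (for n = 30 in an ellipse, SSB/SST ≈ 0.77 uniform vs
0.73 clustered — it does not order the two), whereas the silhouette
increases with genuine spatial clustering. Fewer than 4 features, or a
non-positive best silhouette, set the tendency factor — and hence
T6 — to zero.

### The complexity score and its scale

Traits are min–max normalized against bounds fitted on a reference set
(clipped to [0, 1]; a constant trait maps to 0), combined as
`C = Σ wᵢuᵢ` with weights on the unit simplex, and floored at
ε = 0.01. Scores therefore lie in [ε, 1] and `log C` always exists.
Whether negative weights or unbounded scores should be allowed is an
open question; the simplex-plus-floor construction was chosen because
it guarantees positivity with a single interpretable knob. All
inference runs on `log C`: receivers perceive relative differences
(Weber's Law), and every downstream statistic is invariant to a
multiplicative rescaling of complexity (the trend intercept absorbs
ln c). Effect sizes back-transform to percentages via
`(exp(β) − 1)·100`.

Weights are fitted to egg-rejection experiments: maximize the 5-fold
cross-validated AUC of `rejected ~ |Δ log C|` between experimental egg
and host clutch, over softmax-reparameterized simplex weights, with
10 Nelder–Mead restarts under a fixed seed. AUC was preferred to
logistic likelihood because "best predicts rejection" is a ranking
criterion and AUC is threshold-free.

## Statistical models

### Temporal trends

`log C ~ species + year + species:year` by OLS, species coded host = 1
(so a positive species effect means hosts are more complex), year coded
0 (1970) to 50 (2020). Residual df = n − 4. A categorical variant
replaces year with a current-period indicator. Years 2003–2011 are
excluded from both periods (images from those years are not comparable
to the rest of the series), and excluded rows never enter a fit.

Hosts are far more variable than parasites, violating
homoscedasticity, so the authoritative intervals come from a
nonparametric bootstrap: rows resampled with replacement *within
species* (preserving the two sample sizes, which is what matters under
unequal variances; it also makes single-species replicates impossible),
the model refit per replicate via the normal equations, percentile 95%
intervals over 1,000 replicates. OLS t-based p-values are reported
alongside for reference. Percentile rather than BCa/basic intervals is
a convention choice.

### Mimetic fidelity

*All-pairs statistic.* Every (host, parasite) pair within a period
contributes `|Δ log C|`; pairing all combinations is valid because
parasites lay at random with respect to host phenotype. The pair count
(42,496 current pairs from 460 eggs) vastly exceeds the real degrees of
freedom, so uncertainty comes from a two-sample bootstrap: *eggs*, not
pairs, resampled with replacement within species; 500 replicates;
s.e.m. = SD of replicate means; CI = mean ± 2 s.e.m. The change between
periods is `(exp(m_hist − m_curr) − 1)·100` — **positive = differences
shrank = fidelity improved** — with a CI from applying the same
transform to paired replicates (both periods are bootstrapped under the
same run so their noise enters jointly).

*Discriminant.* A flexible discriminant with a single predictor and
equal priors reduces exactly to the 1-D pooled-variance linear rule:
threshold at the midpoint of the class means. The package implements
that rule directly rather than wrapping a general FDA engine — the
decision boundary is identical and every piece is testable (the
large-sample accuracy has the closed form Φ(|μ₁ − μ₂| / 2σ)). The
reported proportion is the in-sample fraction of all eggs assigned to
their true species (unbalanced: hosts outnumber parasites). Because
discriminant performance grows with n, current eggs are subsampled
*without* replacement to the historical sizes (82, 34) per iteration;
for the historical period itself such subsampling would be a no-op, so
its iterations use an ordinary bootstrap (with replacement) at the same
sizes. CIs are 2.5/97.5 percentiles over 1,000 iterations (percentile
rather than ±2 SE is a choice; the iteration distribution is available
either way).

## The synthetic generator

**Egg images.** Ellipse mask at 29 px mm⁻¹ (host default 18 × 13 mm),
uniform background reflectance 0.35, markings rendered additively as
anisotropic Gaussian blobs (lognormal sizes, von Mises orientations)
clipped at 1.0, host eggs plus smoothed random-walk "scribbles" —
parasite eggs never have scribbles, the diagnostic species difference.
Marking placement interpolates, via the `spatial_clustering` knob,
between uniform placement and a parent–offspring (Neyman–Scott-style)
process: each marking is cluster-born with probability equal to the
knob. This gives a single monotone control for T6. Optional
Matérn-style thinning (`min_separation_mm`) and a placement margin
support fixtures with well-separated, well-interior markings. Every
image ships with its ground-truth marking list; identical params + seed
are bit-identical.

**Population tables.** `log C` per egg is
Normal(intercept_s + slope_s·t, sd_s). Defaults: parasite intercept
−2.0, host intercept −2.0 + ln(1.58) (a 58% gap), both slopes
ln(1.005) (0.5%/yr, so the gap — and hence expected fidelity — is
constant over time), host SD 0.35 vs parasite SD 0.18, historical years
1980–1990, current 2012–2020, period sizes (82, 34) and (332, 128).
The residual SDs are not published quantities; 0.35/0.18 was chosen
once so that host variance clearly dominates and the all-pairs mean
lands near the reported magnitude (≈ 0.5 on the log scale), and is not
revisited. A clutch-level random effect is exposed conceptually but
defaults to zero — within-female variance components are unknown.

**Rejection trials.** Trait vectors for experimental egg and host
clutch are drawn from plausible marginal distributions; rejection is
Bernoulli with `logit p = −1.7 + 5.0·|Δ log C|` under a reference
equal-weight metric. The link was calibrated once so the
population-average rejection rate is ≈ 0.4, keeping both outcome
classes common for optimizer tests.

What the generator does *not* emulate: eggshell texture, ground colour
and fading (pattern measures are colour-independent by design),
clutch structure, nonrandom host choice, and any real covariance
between the six traits beyond what the image chain induces. Passing
tests therefore demonstrate that the measurement and inference chain
recovers known structure under controlled conditions — not that any
particular biological estimate is correct.

## Problem sizes and numerics

The shipped analyses use the study's sample sizes (576 eggs) and the
stated replicate counts (1,000 trend bootstrap, 500 fidelity bootstrap,
1,000 discriminant iterations). Simulation-based tests use 200
simulated datasets for CI coverage, 20 images per marking-count level
for metric-chain monotonicity, and 100×-inflated populations for
parameter recovery — sizes at which Monte-Carlo error is small relative
to the tolerances tested. The acceptance script reports model-based
quantities as means over 40 replicated populations (parameter
recovery), not a single draw.

Numerical conventions: sample SD (ddof = 1) for T3 and bootstrap
s.e.m.; ties in the discriminant (value exactly at threshold) go to
the higher-mean class; bootstrap refits solve the normal equations and
fall back to least squares on singular resamples; all randomness flows
through `numpy.random.default_rng` seeds, with stage-level substreams
derived from one global seed (SHA-256 in the CLI, `SeedSequence.spawn`
in the model objects).

## Known limitations

* Trait formulas are concrete reimplementation choices for one-line
  descriptions of each trait; they are not claimed to equal any prior
  toolchain's exact formulas.
* The detector's polarity filter assumes pigment is darker/brighter in
  a consistent direction per image; real museum photographs with mixed
  polarity would need `bright_only=False` and recalibration.
* The synthetic population draws years uniformly within each period;
  the true year composition of historical collections is unknown beyond
  being concentrated in the 1980s.
* No mixed-effects (clutch-level) models: one egg per clutch is
  assumed, matching the sampling design the statistics expect.
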