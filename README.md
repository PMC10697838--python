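# eggmimic

Quantitative analysis of egg-pattern complexity and mimetic fidelity in
brood parasite–host systems, built around the cuckoo finch
(*Anomalospiza imberbis*) and its host, the tawny-flanked prinia
(*Prinia subflava*). Hosts reject parasitic eggs that mismatch their own
egg "signatures", so parasites are selected to mimic host patterns and
hosts are selected to escape their mimics ("chase-away" evolution). This
package provides the full measurement-and-inference chain needed to test
whether pattern complexity changes over time in both species and whether
mimetic fidelity improves:

1. **Image standardization** — grey-standard normalization (one- or
   two-point), green-channel extraction, cut-out/masking, rescaling to
   29 px mm⁻¹ (`eggmimic.images`).
2. **Pattern features** — difference-of-Gaussians (SIFT) keypoints
   restricted to the egg mask, each encoded as a 132-entry descriptor
   (128 gradient-histogram bins + normalized x, y, scale, orientation)
   (`eggmimic.features`).
3. **Complexity metric** — six traits per egg: feature count *T1*,
   positional variation *T2*, scale variation *T3*, orientation
   variation *T4*, Redies change (mean intensity gradient) *T5*, and a
   clustering score *T6*. Complexity is a simplex-weighted combination
   of min–max-normalized traits, `C = Σ wᵢuᵢ ∈ [ε, 1]`, with weights
   chosen to maximize the cross-validated AUC with which
   `|Δ log C|` between an experimental egg and its host clutch predicts
   rejection (`eggmimic.metric`). All statistics use `log C` because
   hosts perceive complexity on a relative (Weber's-Law) scale; effects
   back-transform to percentages as `(exp(β) − 1)·100`.
4. **Trend analysis** — OLS of
   `log C ~ species + year + species:year` (year coded 0–50 from 1970,
   species host = 1) with a species-stratified case-resampling bootstrap
   (1,000 replicates, percentile CIs), plus a categorical
   historical (1970–2002) / current (2012–2020) variant
   (`eggmimic.trend`).
5. **Mimetic fidelity** — (a) the mean `|Δ log C|` over all
   host × parasite pairs per period with a two-sample bootstrap (500
   replicates, CI = mean ± 2 s.e.m.), and the between-period change
   `(exp(m_hist − m_curr) − 1)·100`; (b) an equal-prior discriminant on
   `log C` alone, with current eggs resampled to the historical sample
   sizes (82 host, 34 parasite) over 1,000 iterations
   (`eggmimic.fidelity`).

A synthetic-data module (`eggmimic.synthetic`) generates egg images with
ground-truth marking lists, population score tables with the study
system's structure (host complexity ≈ 58% above parasite, ≈ 0.5%/yr
upward drift, host variance ≫ parasite variance, period sample sizes
82/34 and 332/128), and egg-rejection trials — so the entire pipeline
runs and is testable with no external data.

## Worked example

```python
import numpy as np
from eggmimic import (
    ComplexityTrend, MimeticFidelity, PopulationConfig, generate_population,
)

records = generate_population(PopulationConfig(seed=1))   # 576 eggs
res = ComplexityTrend(records).fit()
print(res.summary())
ci = res.bootstrap(B=1000, seed=2)

fid = MimeticFidelity(records).fit(seed=3)
print(fid.summary())
```

prints

```
Complexity trend model (variant='year', n=576, df_resid=572)
log_complexity ~ species + year + interaction
term               coef(log)   percent        se       t         p
Intercept            -1.9973    -86.4%    0.0769  -25.97  8.57e-99
species               0.4131     51.1%    0.0915    4.51  7.76e-06
year                  0.0044      0.4%    0.0018    2.40    0.0169
species:year          0.0016      0.2%    0.0022    0.75     0.454
Mimetic fidelity
  historical: mean |dlog| = 0.473 (95% CI 0.404-0.542; 2788 pairs from 82+34 eggs)
  current:    mean |dlog| = 0.528 (95% CI 0.488-0.568; 42496 pairs from 332+128 eggs)
  fidelity increase = -5.3% (95% CI -12.8-2.5%)
  FDA correct: historical 81.2% (CI 74.1%-87.1%), current 80.2% (CI 73.3%-85.3%)
  FDA fidelity change = 1.0 points (95% CI -7.8-9.5)
```

The `species` row says host eggs in this draw are ~51% more complex than
parasite eggs (generating value 58%); the `year` row is the shared
yearly increase (~0.4% here, generating value 0.5%/yr); the
interaction tests whether the two species change at different rates.
The fidelity block reports the mean pairwise log-complexity difference
per period — its change between periods is ≈ 0 because the generator
holds the host–parasite gap constant — and the discriminant's
correct-assignment rate (high values = the two species are easy to tell
apart = low mimetic fidelity).

The image half of the pipeline works the same way from rendered eggs:

```python
from eggmimic import (
    EggPatternParams, generate_egg_image, detect_features, compute_traits,
)
egg, truth = generate_egg_image(EggPatternParams.host_preset(), seed=7)
features = detect_features(egg)        # SIFT keypoints inside the mask
traits = compute_traits(features, egg) # the six-trait vector
```

A `click` CLI orchestrates everything end to end
(`eggmimic simulate | extract | score | trends | fidelity | report`),
writing CSV artifacts plus a Markdown report stamped with the config
hash and seed.

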