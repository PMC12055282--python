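# occumix

Duration-adjusted binomial mixed models for behaviour occurrence in
variable-length observation windows.

## The problem

Camera-trap studies of wild animals score behaviour from short video clips:
an individual is visible for anywhere between a second and a minute, and the
analyst records whether a behaviour of interest (a pant hoot, piloerection,
swaying, ...) occurred at least once while the animal was in view. Longer
windows mechanically produce more "yes" responses, so raw occurrence
probabilities from windows of different lengths are not comparable. The
motivating application is chimpanzee tree-directed signalling — hand/foot
buttress drumming, stone throwing at trees, or both combined — where the
question is whether accompanying behaviours differ between the three
activity types, with repeated observations of the same individuals.

## The model

For event $j$ of individual $i$, observed for $T_{ij}$ seconds, the binary
response $y_{ij}$ (did the behaviour occur?) is modelled as

$$y_{ij} \sim \mathrm{Bernoulli}(p_{ij}), \qquad
\mathrm{logit}(p_{ij}) = \mathbf{x}_{ij}'\boldsymbol\beta + u_i +
\mathrm{logit}\!\big(O(B, T_{ij})\big),$$

where

- $\mathbf{x}_{ij}'\boldsymbol\beta$ is the fixed-effect part: an intercept
  plus two dummy contrasts for activity type (stone & drum vs drum, stone vs
  drum; drumming is the reference level);
- $u_i \sim \mathcal{N}(0, \sigma^2)$ is an individual random intercept;
- $O(B, T) = 1 - (1-B)^T$ is the probability that a behaviour with constant
  per-second occurrence probability $B$ happens at least once in $T$
  seconds. Its logit enters the linear predictor as an offset, putting
  windows of different length on a common footing.

$B$ is not known: it is estimated by maximizing the marginal likelihood,
profiled in an outer one-dimensional search while $(\boldsymbol\beta,
\sigma)$ are refitted inside (adaptive Gauss–Hermite quadrature over the
random intercept). Inference around the fit mirrors standard mixed-model
practice for this design:

- **activity-type effect**: likelihood-ratio test of the full model against
  the model with activity dropped (2 d.f.), both maximized over all their
  free parameters including $B$;
- **confidence limits**: parametric bootstrap — simulate responses from the
  fitted model at the original design points, refit with $B$ held at the
  point estimate, take 2.5/97.5 percentiles;
- **stability**: leave-one-individual-out refits ($B$ held constant), with
  the per-term min/max of the estimates reported alongside.

A synthetic ethogram generator (`occumix.simulate`) draws datasets from
exactly this model with known ground truth, so parameter recovery, type-I
error and interval coverage are all testable without field data.

## Worked example

Simulate a study-sized dataset (28 individuals, 5 events each, a true
stone-vs-drum contrast of 1.2 logits) and fit one model:

```bash
occumix simulate --n-individuals 28 --events-per-individual 5 \
    --sigma 1.0 --true-b 0.05 --beta 0.3 0.0 1.2 --seed 42 --out demo.csv
occumix fit --events demo.csv --behaviour pant_hoot --period before
```

prints

```
model pant_hoot_before: n = 140, individuals = 28
B_hat = 0.0783613   sigma_hat = 1.2092   loglik = -49.9567
  intercept  Est. = -0.518   SE = 0.856
  beh_st_dr  Est. =  0.742   SE = 0.932
  beh_st     Est. =  1.600   SE = 0.702
activity LRT: chi2 = 5.854, d.f. = 2, P = 0.05355
```

Reading the output: the per-second baseline rate is estimated at
$\hat B \approx 0.078$ (true 0.05), the between-individual SD at
$\hat\sigma \approx 1.21$ (true 1.0), and the stone-vs-drum contrast at
1.60 logits (true 1.2) with the likelihood-ratio test for the overall
activity effect near the 5% level — about what 140 events can resolve.
Standard errors for the intercept include the uncertainty in $\hat B$,
which is strongly anti-correlated with it.

The full battery — ten (behaviour, window) models with bootstrap limits and
leave-one-out ranges, written as per-model CSV blocks plus a combined
report and a seed-complete log — runs from a YAML config:

```bash
occumix report --show-config > config.yaml   # defaults, edit as needed
occumix report --config config.yaml --outdir results/
```

Library use mirrors the CLI: `simulate_dataset`, `profile_B`,
`lrt_activity`, `parametric_bootstrap`, `loo_stability`, `summarize`,
`run_pipeline`.

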