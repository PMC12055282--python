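# Methods

## Model

One record is one signalling event × one behaviour × one observation window
("before" or "after" the tree-directed activity). The response is binary:
did the behaviour occur at least once while the individual was visible? With
window length $T$ (integer seconds, 1–61 in the motivating design) the model
is a logistic mixed model,

$$\mathrm{logit}(p) = \beta_0 + \beta_1\,[\text{stone \& drum}] +
\beta_2\,[\text{stone}] + u_i + \mathrm{logit}\big(1-(1-B)^T\big),
\qquad u_i \sim \mathcal N(0, \sigma^2).$$

Activity type is dummy coded with drumming as the reference level. The
offset term is the logit of the probability that a process with constant
per-second occurrence probability $B$ fires at least once in $T$ seconds.
It satisfies the recursion $O(B,T) = O(B,T-1) + B\,(1-O(B,T-1))$, is zero at
$T=0$, equals $B$ at $T=1$, and increases in both arguments. With
$\beta = 0$ and $u = 0$ the model probability is exactly $O(B,T)$, so $B$ is
interpretable as the baseline per-second rate of the behaviour.

Assumptions worth stating: the per-second process underlying the offset is
homogeneous within a window (no burstiness), covariate effects act on the
window-level logit rather than on the per-second rate, and individuals
differ only through an additive intercept (no random slopes — with most
individuals observed under a single activity type, a random slope of
activity within individual is not identifiable, and none is offered).

An alternative printed form of the offset, $O = B^T$, is available as
`formula="printed"` for auditing only: it decreases with duration and cannot
represent exposure, so it is never the default.

## Estimation

The marginal likelihood integrates the random intercept out per individual
with **adaptive Gauss–Hermite quadrature**: nodes are centred at each
individual's conditional mode (found by a vectorized Newton iteration; the
log-joint is concave in $u$) and scaled by the conditional curvature.
The default is **30 nodes**, which keeps the quadrature error below
$\sim 10^{-7}$ against a dense-trapezoid oracle for $\sigma \le 2$; 20 nodes
were measured at $\sim 2\times10^{-6}$ near $\sigma = 2$, too coarse for the
accuracy this package promises. Beyond $\sigma \approx 2.5$ more nodes are
needed (pass `quadrature_nodes`/`nodes` explicitly). A brute-force
trapezoid integrator (`brute_force_marginal_loglik`, 20 001 points over
$\pm 10\sigma$) ships as the in-package oracle.

For fixed $B$, $(\beta, \log\sigma)$ are maximized by L-BFGS-B with analytic
gradients (posterior-expectation identities evaluated on the quadrature
nodes), from two deterministic starts: $\beta$ from an offset logistic
regression without random effect, $\sigma \in \{0.1, 1\}$; ties break to the
higher log-likelihood, then the smaller $\sigma$. The $\sigma = 0$ boundary
is handled by an explicit boundary fit (Newton–Raphson offset logistic
regression), which wins whenever the interior optimum fails to beat it.
Strict fits use `ftol = 1e-12`, `gtol = 1e-7`; bootstrap and leave-one-out
refits use a relaxed `ftol = 2.2e-9`, `gtol = 1e-5`, which is ample for
percentile and range summaries at a fraction of the cost.

**Profiling $B$** (`profile_B`): the profile log-likelihood
$L^*(B) = \max_{\beta,\sigma} \ell(\beta,\sigma;B)$ is evaluated on a
9-point grid on the logit-$B$ scale over $(0.001, 0.999)$, then refined by
bounded Brent minimization around the best grid point (`xatol = 1e-3` on the
logit scale); inner fits are warm-started along the search path. Constant
durations make the offset a constant that the intercept absorbs; this is
detected and flagged as a flat profile, as is a profile maximum at the
search bounds.

**Standard errors** come from the observed information. When $B$ was
profiled, the information matrix is taken over $(\beta, \sigma, B)$ jointly:
$\hat B$ and the intercept are strongly anti-correlated (around $-0.9$ in
the recovery experiments), and conditioning on $\hat B$ would understate
the intercept SE by a factor of 2–3. When $B$ is held fixed (bootstrap,
stability refits) the conditional information is the right one and is used.

**Likelihood-ratio test for activity type**: full vs reduced
(activity dropped), 2 d.f. (asserted against the design-matrix rank), with
$B$ re-optimized in both models so the test compares true profile maxima.
Internally both models are maximized jointly over
$(\beta, \log\sigma, \mathrm{logit}\,B)$ — the same maximum as the nested
profile, much cheaper — and the reduced optimum seeds the full model's
starts so nesting holds numerically. A fixed-$B$ variant is available for
sensitivity. $\chi^2$ values negative by less than $10^{-6}$ are clipped to
zero; larger violations raise. No multiple-testing correction is applied
across the battery.

**Parametric bootstrap**: responses are re-simulated from the fitted model
at the original design points (new intercepts per individual), and
$(\beta,\sigma)$ refitted with $B$ held at the point estimate — the offset
is then a known covariate, mirroring how the stability procedure holds $B$
constant. Confidence limits are 2.5/97.5 percentiles of the replicate
estimates. Replicates whose refit fails (degenerate responses, separation,
non-convergence) are dropped and counted, never imputed; more than 10%
failures flags the result unreliable. Re-profiling $B$ per replicate is
available (`refit_B=True`) but roughly an order of magnitude slower.

**Leave-one-individual-out stability**: each individual is dropped in turn,
the model refitted with $B$ fixed at the full-data estimate, and the
componentwise min/max of the estimates reported.

## Synthetic data

`simulate_dataset` draws from exactly the model above: it is the
distribution the fitter assumes, which makes recovery, size/power and
coverage experiments well-posed. Defaults mirror the motivating design
where it is known: integer durations uniform on 1–61 s (the design states
only the range, so uniform is a deliberate minimal choice), three activity
types with drumming most common (probabilities 0.5/0.15/0.35 — the field
frequencies are not published; chosen once as a realistic mix), 28
individuals, and per-individual event counts that may be supplied as a
vector to mimic the heavily unbalanced field design. A single
`numpy.random.default_rng` stream per dataset, seeded from the config,
makes every dataset bit-reproducible.

What the generator does *not* emulate: within-window behaviour sequencing,
camera triggering, visibility truncation correlated with behaviour, or
overdispersion beyond the random intercept. Passing tests therefore
demonstrate that the estimator recovers the model's own truth — not that
the model is correct for any particular field dataset.

A second mechanism (`mechanism="per_second"`) simulates each second of the
window as an independent Bernoulli draw on the per-second logit scale. It
coincides with the model-based generator exactly when the linear predictor
is zero and serves as a cross-check of the offset's derivation, not as a
default.

`simulate_study` produces a full study table — all six behaviours × both
windows, with event IDs pairing the windows — so the pipeline and the
combined-window collapse (response OR, durations summed) can run end to end
on synthetic data.

## Pipeline

`run_pipeline` fits the study's ten-model battery by default (pant hoot,
piloerection, sound surround, alert focus in both windows; swaying before
only; climax scream after only — the excluded combinations occurred almost
never in the field data), optionally adding collapsed-window models. Each
model gets profile → fit → LRT → bootstrap → stability → summary; one model
failing hard is recorded and the run continues. All randomness descends
from the single configured seed through spawned per-model streams assigned
in battery order, so results are byte-identical on re-run and unaffected by
earlier failures. The run log records per-model seeds, $\hat B$ and the
profile trace ($B$ being the reconstruction's most fragile element), plus
bootstrap/stability failure counts.

## Experiment sizes

The validation experiments (tests and `scripts/acceptance.py`) use: 100
datasets of 200 individuals × 10 events for recovery (40 in the script);
500 null replicates of 100 × 5 for test size (200 in the script) and
150/100 replicates for power; 200 datasets × 100 bootstrap replicates for
coverage (100 × 60 in the script), with the bootstrap scaled down from the
production default of 1000 replicates. Coverage simulations use a null
activity effect, letting the same run check both interval coverage of the
true contrast and the rate of false exclusions of zero.

## Known limitations

- Identification of $B$ rests entirely on duration variation; designs with
  near-constant windows yield a flat profile (flagged, not silently fit).
- Weak identification between $B$ and the intercept inflates both their
  sampling variances at study-sized data; the joint-information SEs account
  for this, but bootstrap intervals for the intercept remain wide.
- 30-node quadrature is validated for $\sigma \le 2$; larger random-effect
  SDs need more nodes.
- Percentile intervals are the only bootstrap CI offered (no BCa or
  studentized variants); they can fail to contain the point estimate in
  pathological cases, which is reported as a warning.
- Separation (|estimate| > 15 logits) is flagged, not regularized: the
  motivating analysis selected behaviours common enough to avoid it, and a
  penalized fallback would change the estimand silently.
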