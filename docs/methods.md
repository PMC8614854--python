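# Methods

This note records the statistical model behind `growthpf`, the choices made
where the design was genuinely open, and the limits of what the synthetic
benchmarks demonstrate.

## Signal model

Biomass back-scatter (AU) and dissolved oxygen (% of maximum) are rescaled
by constant factors (1000 and 10) and natural-log-transformed before any
modelling; all inference operates on that scale. A culture segment is
described by a Gompertz curve `y = k·exp(−exp(b − c·t))` or a Logistic
curve `y = k/(1 + exp(b − c·t))`. `k` is the asymptote on the transformed
scale (it may be ≤ 0, so it is not constrained positive), `b` a
dimensionless transition offset and `c` a rate in 1/h. Flipping the signs
of `b` and `c` mirrors the curve in time; the mirror axis is `t = b/c`
(direct algebra on the two functional forms — substituting `(−b, −c, t)`
gives the value at `2b/c − t`), and the declining convention `b<0, c<0` is
used for DO. Observations are the curve value plus iid Gaussian sensor
noise.

## The filter

State: `N` particles carrying `(k, b, c)`, with weights, a per-particle
observation-noise precision, and three scalar state-noise precisions
Λ (k), ν (b), γ (c). One update step per new measurement:

1. Append the point to the sliding sample window (length `W = 20`,
   dropping the oldest point beyond that).
2. Propagate each particle by Gaussian increments with variances
   `1/Λ, 1/ν, 1/γ`.
3. Weight each particle by the Gaussian likelihood of **all** windowed
   values under its curve and its own noise precision. Weights are
   computed in log space with max-subtraction; a fully degenerate weight
   vector falls back to uniform rather than propagating NaNs.
4. Resample (systematic by default; multinomial available). The realized
   propagation increments and the noise-precision statistics are carried
   through the same selection.
5. Update the state-noise precisions (below).

Forecasts are weighted ensemble means of the particle curves, with central
credible intervals from weighted quantiles (5–95% by default). Event
times come from the closed-form threshold crossing of each particle's own
curve — 95% of the particle's asymptote for harvest, 20% of the curve value
at the series start for critical DO — averaged over the particles that
cross, with the non-crossing weight fraction reported rather than imputed.

### State-noise adaptation

The precisions have Gamma(0.1, 1) hyperpriors. A history buffer keeps, for
each of the last `S = 10` updates, the count and sum of squares of the
random-walk increments realized by the particles that survived resampling.
Λ and ν are set to the conjugate posterior mean,
`(0.1 + n_incr/2) / (1 + Σd²/2)`; γ takes `mh_steps` (default 25)
Metropolis–Hastings steps against the same posterior density with the
multiplicative proposal `γ' = γ·u`, `u ~ Uniform(δ, 1/δ)`, `δ = 0.9`
(Hastings ratio `(shape−2)·log(γ'/γ) − rate·(γ'−γ)`). A single MH step per
update cannot track a posterior that concentrates far from the current
value — the proposal moves γ by at most a factor `1/δ ≈ 1.11` — so the
kernel is iterated; this changes mobility, not the target.

Selection couples the increments to the data: on stationary stretches the
surviving increments shrink and the precisions grow (stationary accuracy);
when the windowed likelihood disagrees with the ensemble, the survivors are
the particles that jumped furthest toward the data, the pooled squared
increments grow, and the precisions fall within a few updates (fast
tracking). Note the prior rate bounds each precision above by
`(0.1 + N·S/2)/1`; with `N = 1000` particles this floors the per-step
random-walk sd at about `√(2/NS) ≈ 0.014` per parameter.

The precisions are initialized at (100, 100, 100) — random-walk sd 0.1 —
rather than at the very diffuse prior mean (0.1, sd ≈ 3.2). Cold-start
exploration is the job of the initial particle spread, not of the random
walk: a sd-3 walk during the uninformative lag phase simply diffuses the
ensemble along the likelihood's flat directions (for the Logistic family
the asymptote can run away by an order of magnitude before any saturation
is seen). Warm starts additionally carry over the initializing fit's
converged precisions for the same reason.

### Observation noise

Each particle holds conjugate Gamma statistics `(a, b)` for the sensor
precision, initialized from a vague Jeffreys-type prior (1e-3, 1e-3) and
updated with the particle's one-step-ahead squared residual at every new
point; the statistics ride through resampling, so selection also acts on
noise beliefs. Three deliberate choices here:

- **Accumulated, not window-local.** Sensor noise is a static physical
  property; estimating it from the current window alone lets a structural
  break (a level step) masquerade as a transient burst of noise, which
  absorbs exactly the mismatch pressure the state-noise adaptation needs.
- **A 3σ gate.** A residual beyond three predictive standard deviations is
  not booked into the noise statistics — structural breaks must be resolved
  by the parameters.
- **Posterior-mean plug-in, not a Gamma draw.** A sampled precision creates
  a spurious selection channel: whenever the whole ensemble misfits, the
  lowest sampled precision acts as likelihood tempering and out-competes
  any parameter move (we measured a −0.96 correlation between log-weight
  and sampled precision after a level step), freezing the parameters. The
  plug-in mean removes that channel while keeping per-particle noise
  beliefs.
- A vague prior rate matters: with a rate of order 1 the posterior mean is
  capped near `n/2` pseudo-observations regardless of how small the
  residuals are, which flattens the likelihood exactly on the low-noise
  signals where precision is available.

## Static model and initialization

The static (time-invariant) model runs the identical update machinery over
a randomly permuted copy of a complete profile, re-permuted every sweep
(default cap 50 sweeps, early stop when all three posterior means move by
< 0.1% between sweeps; in practice 2–3 sweeps suffice). Because the sample
window then always spans the whole profile, the ensemble converges to a
single parameter set for the entire curve — on noiseless data it matches a
Levenberg–Marquardt fit to a small fraction of a percent. Cold starts draw
particles uniformly from data-derived ranges: the asymptote range brackets
the observed maximum, the rate magnitude spans ~1–20 transitions per
observed span with its sign from the overall trend, and the offset range
covers transition midpoints anywhere in the span.

## Evaluation framework

Predictions are scored only on strictly-future observations; once a sample
has updated the filter it is excluded from evaluation. `mse` divides the
squared-error sum by the number of future points so values are comparable
as the filter advances. Filter-vs-static comparisons use the paired
per-time squared residuals: the one-sided sign-flip permutation test draws
`K` sign vectors (default 10⁵; exhaustive enumeration below `n ≤ 12` on
request) and reports the fraction of replicate means *strictly* below the
observed mean — ties are not counted, and with continuous residuals they
have measure zero. `p = 0` is reported in tables as `< 1/K`.
Benjamini–Hochberg step-up q-values (via statsmodels) control the FDR
across splits; significance is declared at FDR < 0.05. `log(mse)` uses the
natural log. The rolling tracking diagnostic is the mean of squared
one-step-ahead errors over a trailing 15-sample window, with
partial-window values flagged.

The evaluation protocol pairs cultures the way the method is used:
the static competitor is fitted to a replicate culture grown under the
test culture's conditions (an idealized, strong competitor — such data
does not exist for a genuinely novel condition); the filter is warm-started
on cultures from *different* conditions and then filtered continuously
through the test culture, reporting at split fractions 0.3–0.8 (0.3–0.6
for DO, whose late values sit at the zero floor and make "predictions"
trivially accurate). Split boundaries are `floor(fraction · N)` sample
indices. Restarting the filter per split is not performed; predictions at
a split depend only on samples before it (verified by a truncation test).

## Synthetic benchmarks: what they emulate, and what they do not

The generator produces Gompertz/Logistic backbones on the transformed
scale with additive Gaussian noise, optional uniform sampling jitter,
additive level steps (sensor artefacts), and regime switches in the
parameters; a "continuous" mode re-solves the offset at a switch so
slowdowns preserve the signal value. DO profiles use the mirrored sign
convention with an optional floor imitating oxygen exhaustion. Default
study conditions, chosen once for realism:

- **Recovery / forecasting:** Gompertz `(k, b, c) = (2.0, 5.2, 0.8)`,
  12 h duration, 0.1 h sampling (121 points), noise sd 0.05 — a culture
  with a lag phase, growth through most of the run, and the 95% harvest
  crossing at ~85% of the run.
- **Step-tracking diagnostic:** Gompertz `(2, 3, 1)` over 18 h, noise sd
  0.005 (sub-1% back-scatter noise), +0.3 log-unit step at 10 h, during
  established growth — mirroring the real cultures where steps arrive
  after the state noise has converged.
- **Protocol cultures:** growth midpoint at ~40% of the run and the 95%
  crossing at ~69% (test `(2.0, 4.5, 0.9)`; static-model training
  `(1.6, 5.5, 1.1)`, every parameter ≥ 20% off; initialization cultures
  `(1.85, 4.7, 0.95)` and `(1.75, 4.3, 0.85)` — different from the test
  culture but similar in timing, as initialization should be).

What passing these benchmarks does **not** show: the generator draws noise
from the assumed Gaussian model, sampling is near-uniform, and regime
changes are clean parameter switches — real back-scatter signals have
heteroscedastic, occasionally heavy-tailed noise, autocorrelated sensor
drift, and metabolic transitions that are not instantaneous. Performance
numbers on synthetic data are therefore internal-consistency results, not
field accuracy claims.

## Known limitations

- **Logistic cold starts on pre-saturation data.** Until saturation is
  visible, a Logistic curve segment is compatible with an arbitrarily large
  asymptote (the quasi-exponential ridge), and a cold-started filter can
  follow that ridge far from any useful value. Warm-starting from a
  complete-profile fit — the intended workflow — avoids this; the Gompertz
  family, whose approach to the asymptote is sharper, is markedly more
  robust cold.
- **Windowed forgetting.** With a 20-sample window, parameters that the
  current window no longer constrains are held only by the state-noise
  precisions; over very long uninformative stretches they drift at the
  precision floor noted above.
- **Harvest timing near flat maxima.** The post hoc 95%-of-maximum rule
  becomes noise-sensitive when the smoothed signal is nearly flat at its
  maximum; on noisy plateaus the post hoc estimate can move by tens of
  minutes while the underlying curve crossing does not.
- The filter treats BM and DO channels independently; no joint model.
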