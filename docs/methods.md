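# Methods

## The model

The package estimates and projects the sex ratio at birth (SRB, male over
female live births) for a set of subnational regions observed irregularly by
heterogeneous data sources.  The SRB of region $r$ in calendar year $t$ is
decomposed additively on the ratio scale:

$$\mathrm{SRB}_{r,t} \;=\; \underbrace{b\, e^{\phi_{r,t}}}_{\text{natural level}}
\;+\; \underbrace{\delta_r\, \alpha_r(t)}_{\text{imbalance}}.$$

**Natural level.** $b$ is the national natural baseline, fixed at 1.063 (the
centre of the 1.03–1.07 band observed in populations without sex
selection).  $\phi_{r,t}$ is a stationary Gaussian AR(1) on the log scale —
autocorrelation $\rho \in (0,1)$, innovation sd $\sigma_\varepsilon$ — whose
stationary distribution $N(0, \sigma_\varepsilon^2/(1-\rho^2))$ anchors the
first year.  It represents genuine year-to-year fluctuation of regional
birth masculinity, not sampling noise.  By default $(\rho,
\sigma_\varepsilon)$ are shared across regions: six short series estimate an
autocorrelation poorly on their own, and pooled estimation borrows strength
(a config flag makes them region-specific).

**Imbalance.** $\delta_r \in \{0,1\}$ is a region-level Bernoulli detector
with prior probability $\pi_r \sim \mathrm{Beta}(1,1)$; one transition
episode per region, constant over time.  $\alpha_r(t)$ is the trapezoid
episode shape: zero up to the start year $\gamma_r$, linear rise over
$\lambda_{1r} > 0$ years to the maximum imbalance $\xi_r \ge 0$, a plateau of
$\lambda_{2r} \ge 0$ years, and a linear decline over $\lambda_{3r} > 0$
years back to zero.  The transition end year is
$\gamma_r + \lambda_{1r} + \lambda_{2r} + \lambda_{3r}$.  The imbalance is
additive on the ratio scale (the SRB is the *sum* of the two parts), so
$\xi$ is interpretable directly as excess SRB at the peak.

**Observation model.** Each observation carries a log-SRB $y_i$ with
sampling standard error $s_i$:

$$y_i \sim N\!\left(\log \mathrm{SRB}_{r_i, t_i},\; s_i^2 +
\sigma^2_{\mathrm{ns}, k_i}\right),$$

where $k_i$ indexes the source type (census, retrospective survey, annual
survey, facility survey) and $\sigma_{\mathrm{ns},k}$ is a non-sampling
error sd per source type, half-normal(0.02) a priori and estimated by
default (fixing it to zero recovers a sampling-error-only model).  The
likelihood on log-SRB with normal errors is the key distributional
assumption; it is natural because count-based sampling errors are
delta-method SEs of a log ratio, $\sqrt{1/m + 1/f}$.

**Hierarchical priors.** The five trapezoid parameters get truncated-normal
priors with *fixed* national-level means and spreads — the model treats the
national transition estimates as known hyperparameters rather than learning
them from six regions.  Defaults (all YAML-configurable):

| parameter | prior | truncation | rationale |
|---|---|---|---|
| $\gamma$ (start year) | $N(2001, 5^2)$ | [1980, 2030] | national inflation onset around the turn of the century |
| $\lambda_1$ (rise, yr) | $N(13, 5^2)$ | $>1$ | observed 12–15 year rises |
| $\lambda_2$ (plateau, yr) | $N(5, 4^2)$ | $\ge 0$ | short stagnation phase |
| $\lambda_3$ (decline, yr) | $N(18, 8^2)$ | $>1$ | declines slower than rises |
| $\xi$ (max imbalance) | $N(0.07, 0.03^2)$ | $\ge 0$ | peak SRBs 1.11–1.15 over a 1.063 baseline |

$\rho \sim U(0,1)$, $\sigma_\varepsilon \sim$ half-normal(0.02).  A
prior-predictive draw of the SRB trajectory under these defaults stays
within the plausible envelope of regional series (roughly 1.0–1.2 with
transitions peaking 2010–2020).

## Data handling

Observations enter as a table of (region, source, source type, survey year,
reference year, counts or SRB + SE).  Three preprocessing rules reflect how
multi-source SRB databases must be compiled:

* **25-year recall window**: retrospective birth-history surveys contribute
  only births within 25 years before the survey; older recall is sparse and
  unreliable.
* **Facility-survey restriction**: facility surveys that recorded only the
  most recent birth are restricted to the survey year itself; earlier years
  from such designs are biased upward by male-favouring stopping rules.
* **Sampling-error imputation**: annual surveys with unpublished designs
  get their missing SEs imputed as the *maximum* SE among same-region
  observations from known-design sources.  The maximum is a deliberate
  conservative choice (alternative: donor mean, configurable) — an
  understated SE would overweight precisely the sources whose precision is
  unknown.

Fractional reference years (a survey recording the previous 12 months is
assigned survey year − 0.5, and census age-0 counts likewise refer to the
preceding 12 months) map to the calendar year containing the time point,
i.e. `floor(reference_year)`; the latent grid is annual.  The grid runs from
the first to the last observed year, inferred from the data rather than
hard-coded.

## Inference

The sampler is Metropolis-within-Gibbs with adaptive random-walk steps
(batch adaptation toward 0.44 acceptance during warmup only; the kernel is
frozen for retained draws).  Default 4 chains, 2,000 warmup + 2,000 kept
sweeps; chain seeds are spawned deterministically from one master seed.

Per sweep:

1. **$\phi$ field** — single-site normal random walks in two vectorized
   odd/even-year passes (sites of one parity are conditionally independent
   given the other); two passes per sweep because they are cheap.
2. **Trapezoid parameters** — scalar random walks per parameter per region
   where $\delta_r = 1$; where $\delta_r = 0$ the likelihood is flat in the
   trapezoid, so the full conditional is the prior and is drawn exactly
   (this also keeps the detector's conditional well-defined, as in
   pseudo-prior schemes for mixture indicators).
3. **Detector** — exact Bernoulli conditional:
   $\Pr(\delta_r = 1 \mid \cdot) = \pi_r L_1 / (\pi_r L_1 + (1-\pi_r) L_0)$.
4. **$\pi_r$** — conjugate Beta update.
5. **AR(1) parameters** — centered random walks on $\mathrm{logit}(\rho)$
   and $\log \sigma_\varepsilon$, *plus* two non-centered interweaving
   moves: a joint scale move ($\sigma_\varepsilon' = c\sigma_\varepsilon$,
   $\phi' = c\phi$, prior and Jacobian cancel exactly) and a joint $\rho$
   move holding the standardized innovations fixed.  Without interweaving
   the coupling between $(\rho, \sigma_\varepsilon)$ and the ~270-dimensional
   $\phi$ field leaves them with effective sample sizes near single digits;
   with it their R-hat drops from >2 to ~1.02 at default settings.
6. **Non-sampling sds** — log-scale random walks.

An alternative **marginalized** detector scheme integrates $\delta_r$ out of
every likelihood evaluation (region likelihood
$(1-\pi_r)L_0 + \pi_r L_1$) and draws $\delta_r$ from its exact conditional
for reporting only.  Both schemes target the same posterior; their agreement
on $\Pr(\delta_r=1)$ (within 3 Monte-Carlo SEs on an intentionally ambiguous
two-region instance) is part of the acceptance suite.  The indicator scheme
is the default (faster per sweep at realistic data sizes); the choice is
recorded in the run manifest.

**Diagnostics.** Split R-hat and ESS (via arviz) on all continuous
parameters — $\pi$, trapezoid parameters, a spread of $\phi$ sites, AR(1)
and non-sampling sds.  A run is flagged converged iff every monitored R-hat
is finite and ≤ 1.05.  Non-convergence is flagged and logged, never
silently ignored; shortened-chain validation runs routinely sit at R-hat
1.05–1.15, which is accepted for replicated harness runs (posterior means
of the detector and trapezoid parameters are stable well before strict
convergence) but reported honestly in their manifests.

**Summaries.** A region is classified as undergoing a transition when its
posterior inflation probability is ≥ 0.95 (inclusive).  Transition
summaries (start year, SRB at start, peak year, SRB at peak, end year)
condition on $\delta_r = 1$ draws, since schedule parameters are undefined
when no transition exists; the peak year is reported as a point value (the
year maximizing the posterior-median trajectory).  Annual estimates are
unconditional pointwise medians and 2.5/97.5 percentiles.

## Projection

Each posterior draw is extended to the horizon (default 2050): $\phi$
continues its AR(1) recursion from the last estimated state with the
draw's own $(\rho, \sigma_\varepsilon)$, and the trapezoid is evaluated
deterministically through its decline.  Bands therefore widen after the
data period (parameter uncertainty + future innovations) and the median
returns to $b$ once sampled transitions end — for every region, including
those without transitions, whose full parameter uncertainty is propagated
too.

## Synthetic data

The generator mirrors the structure of the compiled Vietnamese regional
database and is the basis of all testing: six regions (codes NMM, RRD, NCC,
CH, SE, MKD) over 1975–2019; four regions with true transitions
($\gamma \approx 2001$, rises 12–15 years, $\xi$ 0.054–0.083, the strongest
peaking at 1.146) and two without; four census-like sources (6,500–230,000
births per region-year, magnitudes matching the 1989–2019 census rounds),
three retrospective-survey-like sources (140–500 births per region-year,
25-year windows), and fourteen annual-survey-like sources (3,500 births per
region-year, reported without sampling errors so imputation is exercised).
Natural fluctuation uses $\rho = 0.5$, $\sigma_\varepsilon = 0.006$
(stationary sd ≈ 0.7% of the SRB, consistent with the 1.03–1.07 natural
band).  Observation noise is binomial sampling of male births among the
planned totals — it reproduces the delta-method SE by construction and the
0.9–1.3 scatter of small-sample SRB observations, but deliberately omits
design effects (cluster sampling, weighting) and recall/reporting biases of
real surveys; a multiplicative design effect can be layered per source.
Passing tests therefore demonstrate correct inference *when the model and
noise mechanism are as assumed*, not robustness to design-based survey
error.

## Validation harnesses

* **Out-of-sample**: fit up to a cutoff year, score held-out later
  observations against the posterior predictive (one simulated replicate
  per draw, including sampling and non-sampling noise).  Reported: 95%
  prediction-interval coverage with an exact Clopper–Pearson interval,
  median absolute error of the predictive median on the SRB scale, sign of
  the median bias.
* **Parameter recovery**: repeated simulate-and-refit on the reference
  scenario; reported: detector classification accuracy at the 95% rule and
  95%-CI coverage of $\xi$, $\gamma$, and the end year (conditional on
  detector-on draws; absence of such draws counts as non-coverage).

At the shipped problem sizes (20 replicates, 2 chains of 600 kept sweeps
each) the harnesses run in a few minutes; accuracy is ~98% and coverages
sit at 0.95–1.0, i.e. the intervals are, if anything, slightly
conservative.

## Numerical choices and edge cases

* Likelihood constants ($-\tfrac12\log 2\pi$) are dropped inside the
  sampler; they cancel in every ratio and in the detector's conditional.
* $\lambda_2 = 0$ (no plateau) is a valid trapezoid; the peak is attained
  at a single point.
* The detector conditional is computed with log-sum-exp stabilized
  mixture weights; $\pi$ draws are clipped away from {0, 1} by 1e-9.
* Degenerate draws (all identical) produce zero-width credible intervals
  rather than errors.
* A region with no observations is fitted prior-only, with a logged
  warning; prior recovery of such runs is a test.
* Ties in the peak-year argmax resolve to the earliest year (numpy argmax
  convention).

## Known limitations

* One transition episode per region; recurring episodes are out of scope.
* No external covariates (fertility, ultrasound access) inform the start
  year — the calendar-year prior on $\gamma$ stands in for covariate-based
  timing, so start years are similar across regions by construction unless
  the data say otherwise.
* The decline duration $\lambda_3$ is weakly identified while a region is
  still on its plateau; its posterior (and hence the end-year CI) leans on
  the prior until post-peak data accumulate.
* Census SRBs are taken as provided; survival back-projection from age-0
  populations to births is upstream of this package.
* The record count of a compiled real database is authoritative over any
  printed per-source tally; the shipped source catalogue stores both
  without forcing agreement.
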