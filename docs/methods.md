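# Methods

## Scope and moving parts

`censuscast` forecasts the end-of-day census of a hospital unit from three
components: the current census C(t), simulated future arrivals, and
simulated future departures, combined through the accounting identity
C(t+k) = C(t) + ΣA − ΣD. Arrivals and departures are assumed independent on
the same day (reasonable while the unit runs below capacity); departures at
t+k depend on earlier arrivals only through the pseudo-subject mechanism, so
within each realization cumulative departures can never exceed the patients
present plus the arrivals simulated so far.

## Day and censoring conventions

Days are 0-based calendar integers. A patient admitted on day `a` with
length of stay L occupies the 11:59pm census on days `a … a+L−1`; day-of-stay
is `s = day − a` (0 on the admission day), and the departure is recorded on
day `a+L`, the first day the patient is absent. Under this convention the
departure indicator Y⁽ᵏ'ˢ⁾ = 1{LOS ≤ k+s} coincides exactly with "absent
from the census at end of day t+k". Same-day admission-and-discharge stays
(L = 0) are rejected, mirroring the >24-hour inclusion rule common in unit
registries. Whether a departing patient is removed before or after the
nightly snapshot is not observable from daily data; this package fixes the
reading above and applies it consistently to generation, labelling and
scoring, so all internal identities hold exactly.

A record viewed at a training cutoff is *censored*: a patient still present
after c days of stay contributes LOS > c, which determines Y⁽ᵏ'ˢ⁾ = 0
whenever c ≥ k+s and leaves the label undefined otherwise. Undefined labels
are dropped, never imputed. Severity scores whose collection day exceeds c
are hidden from the cutoff view, which is what makes the backtest leak-free
by construction.

## Arrival model

Seasonal Poisson autoregression with log link:
log μ_t = β₀ + Σ_k [φ_k cos(2πtω_k/T) + α_k sin(2πtω_k/T)] + Σ_i β_i A(t−i).
Both the cosine and sine coefficient of each harmonic are always estimated
(the pair is what makes the phase free); K = 1 harmonic is the default.
Estimation is conditional maximum likelihood by damped Newton iteration;
with the canonical link the analytic Hessian is the observed Fisher
information, and its inverse is the parameter covariance V_λ used by the
ensemble.

Choices a user can change, with defaults and reasons:

- **Order p** — BIC over p = 0…p_max (default p_max = 3), every candidate
  conditioned on the first p_max observations so likelihoods are comparable
  (effective n = T − p_max); ties break toward the smaller order.
- **Frequency ω** — integer cycles per series maximising the periodogram of
  the mean-centred series over candidates 1–8. This automates the visual
  ACF-inspection practice; the sample ACF is returned for plotting. On a
  series with no seasonality the argmax is noise — set `n_harmonics = 0`.
- **Frequency anchoring** — ω is stored as cycles per the series length at
  selection time, so the physical period T₀/ω (days) stays fixed when the
  model is refit on a longer expanding window.
- **Overflow guard** — the linear predictor is clipped to ±30 before
  exponentiation (an extreme multivariate-normal parameter draw could
  otherwise overflow); every clip is logged.

## Departure models

One logistic regression per (horizon k, stratum s), s ∈ {0,…,R−1, ≥R} with
R = 10 by default. Stratum 0 is included — newly admitted patients are in
the census and must be modelled — and the pooled ≥R stratum contributes one
row per (patient, stay-day) pair. Covariate sets follow collection-day
availability (s=0: birth weight, gestational age; s≥1: + day-1 scores;
s≥3: + day-3 score; s≥7: + day-7 score).

Numerical choices:

- Covariates are standardised internally (stored means/scales are applied at
  prediction time), and a ridge penalty of 1e-4 on non-intercept terms
  stabilises separated or nearly separated strata. The reported covariance
  V_β is the inverse penalised observed information.
- A stratum with fewer than 10 usable rows or no outcome variation pools
  downward with adjacent smaller-s strata (combined rows, the lowest
  stratum's covariate set); if even pooling to s=0 fails, an intercept-only
  model is used at the stratum's empirical event rate clamped to
  [1/(n+2), 1−1/(n+2)], with binomial-information variance on the logit
  scale. Every fallback is logged and flagged in the model diagnostics.
- The link is logit; probit/cloglog are deliberately not wired up.

## Ensemble procedure

For each realization r: draw λ⁽ʳ⁾ ~ MVN(λ̂, V_λ) and β⁽ʳ⁾⁽ᵏ'ˢ⁾ ~
MVN(β̂⁽ᵏ'ˢ⁾, V_β⁽ᵏ'ˢ⁾) independently across (k,s) blocks (no cross-model
covariance is estimated — a known limitation); simulate arrivals
sequentially with sampled counts feeding later lags; draw one Bernoulli
within-k departure indicator per in-unit patient; draw pseudo-subjects for
each intermediate day t+j (j = 1…k−1) — arrivals on day t+k itself cannot
have departed by t+k and draw nothing; apply the census identity.
Cumulative departures come directly from the within-k indicators, one draw
per at-risk individual, so daily double counting cannot arise; each horizon
is forecast with its own draws rather than by chaining intermediate
censuses.

Randomness discipline: one master seed; realization r uses child r of
`numpy`'s `SeedSequence.spawn`, so enlarging M extends the ensemble without
reshuffling earlier realizations, and a fixed seed reproduces results
bit-for-bit. In the backtest each origin's seed is derived deterministically
from the base seed and the origin day. Intervals are empirical 2.5/97.5
percentiles with numpy's linear interpolation between order statistics; the
point forecast is the median (mean available). An optional shared-uniform
coupling (one uniform per patient reused across horizons) enforces monotone
departures across horizons; it is off by default, matching the
per-horizon-independent procedure.

## Backtest

Expanding-window evaluation: at each test origin t the arrival series is
truncated at t, patient records are censored at t, and the census state is
rebuilt from the censored records. Refit cadence is configurable (1 day
reproduces the fully continuously-updating procedure; the packaged
validation uses 7 to keep a laptop-scale run in tens of seconds — between
refits the census state and labels still advance daily). The order and
frequency are selected once at the first origin and held fixed; coefficients
are re-estimated at each refit.

Metrics per horizon: MAPE — here the **mean absolute prediction error in
patient counts**, not a percentage (the name is kept for continuity with
the forecasting literature on this problem) — with a normal-approximation
95% CI on the absolute errors; empirical coverage of the 95% interval; and
the distribution of interval widths. The census-only comparator fits the
same seasonal PAR machinery to the census-count series (even though a
census is not a pure count-arrival process — that is the point of the
benchmark) and is scored through the identical code path.

## Synthetic data generator

The generator is the package's study environment: seasonal PAR(1) arrivals
(intercept 0.85, AR coefficient 0.05, one harmonic of amplitude
(0.15, 0.08) at 3 cycles per 550 days — about 2.7 admissions/day);
gestational age ~ N(34.6, 4.0²) rounded to completed weeks, birth weight
conditionally normal given gestational age with correlation 0.8 and
marginal (2418, 939.8²) grams; severity scores worse at younger gestation,
with a point mass at zero for the physiology score, the day-3 score damped
and the day-7 score inflated relative to day 1 (directional, invented
plumbing — not a clinical model). Length of stay follows a discrete-time
logistic hazard, logit h(j) = −2.60 + 0.10·log j + 0.13·(gestage − 34.6) +
0.15·(bweight − 2418)/1000 − 0.08·snap/10 − 0.15·main/1000 (day-3/day-7
scores entering once observable), capped at 120 days. This calibration
gives LOS mean ≈ 20, median ≈ 10, sd ≈ 25 and a steady-state census around
50 — a realistic mid-size unit. Because the hazard has closed-form
within-k departure probabilities (`true_departure_prob`), the stratified
logistic models are approximately well specified and recovery is testable.

What the generator does *not* emulate: clinical score dynamics beyond the
fixed collection days, correlated admissions (twins), weekday effects,
capacity feedback on admissions, and non-healthy discharge (death/transfer)
as a competing risk. Passing tests therefore demonstrate the method's
internal correctness and its calibration *when the model family is right*,
not performance on real unit data.

## Validation problem sizes

The packaged validation and the acceptance script use a 550-day history
(~1,450 admissions), a test window of 100 consecutive origins, weekly
refits, M = 200 realizations and horizons {1,3,5,7} — sizes chosen so a
full run completes in well under a minute on one CPU while every stratum
retains usable training rows. At these conditions the 5-day 95% interval
covers ≈94–96% of observed censuses and MAPE grows from ≈1.7 patients at
k=1 to ≈4.5 at k=7, with the census-only comparator's intervals clearly
wider at long horizons.

## Known limitations

- Departure-coefficient draws are independent across (k,s) blocks; joint
  uncertainty across horizons is understated.
- Log-linear autoregression on raw lagged counts can in principle be
  explosive for large positive coefficients; the clip guard bounds the
  damage but the model is intended for the small-coefficient regime
  observed in admission series.
- The MAPE confidence interval assumes approximately independent errors
  across origins; overlapping forecast windows induce correlation, so the
  CI is optimistic at long horizons.
- Intervals are not recalibrated against realised coverage; systematic
  arrival-model bias propagates to longer horizons.
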