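# Methods

## The model

`heatmort` analyses the short-term association between daily maximum
temperature and daily cause-specific death counts in a warm-season
(May–September) time-series design. For each cause of death, daily counts
$D_t$ are modelled with an overdispersed (quasi-) Poisson generalized
linear model with log link:

$$\log \mathbb{E}[D_t] = \beta_0 + \beta\,\max(0,\ L(T)_t - \theta)
  + \gamma^\top z_t, \qquad \operatorname{Var}[D_t] = \phi\,\mathbb{E}[D_t]$$

where

* $T_t$ is daily maximum temperature and $L$ a lag transform — same day
  (`lag0`, the default), single-day lag 1 or 2, or the moving average of
  lags 0–2 (`ma02`);
* $\theta$ is the **threshold temperature**, an empirical percentile
  (default the 90th) of the daily-maximum distribution over the study
  period; the *hockey-stick* term $\max(0, L(T)_t-\theta)$ is zero at or
  below the threshold and linear above it, so the model estimates a single
  above-threshold slope and no cold effect;
* $z_t$ are confounders: relative humidity and air pressure (linear),
  six day-of-week indicators (Sunday reference), a natural cubic spline in
  calendar time for the long-term trend, and optionally PM10 and O3;
* $\phi$ is estimated as Pearson $\chi^2/(n-p)$. Point estimates are
  Poisson maximum likelihood via IRLS; $\phi$ only rescales standard
  errors, never coefficients.

The relative risk per 1 °C above threshold is $RR = e^{\beta}$ with Wald
95 % limits $e^{\beta \pm 1.959964\,\hat{se}}$.

The burden side converts the fitted slope into day-level **attributable
fractions** $AF_t = (RR_t-1)/RR_t$ with $RR_t = e^{\beta \max(0, L(T)_t -
\theta)}$, and **attributable deaths** $AD = \sum_t AF_t D_t$ over the
analysis days. $AF_t$ is zero at or below the threshold, strictly below 1
(enforced in floating point by computing $-\mathrm{expm1}(-\beta x)$ and
clamping at the largest double below 1), and negative for protective
associations; negative AD is reported as-is and never folded into any
total. AD is reported as a percentage of the cause's own warm-season
deaths and of all-cause warm-season deaths; display percentages round
half-up to 2 dp while machine outputs keep full precision.

## Threshold resolution

$\theta$ is the empirical quantile of tmax over a basis window (default:
every day in the study period; a warm-season-only basis is available).
The default quantile convention is linear interpolation between order
statistics (R type 7), with the inverted-CDF (type 1) variant exposed for
matching other software. "Exceedance" is strict ($T > \theta$); ties at
$\theta$ carry zero excess either way. The exceedance census tabulates
$\theta$ and the day count for a percentile grid; counts are necessarily
non-increasing in the percentile.

## Cause taxonomy

Deaths are grouped by ICD-10 code *stems* (letter + two digits;
sub-decimal characters are truncated). Ranges are lexicographic spans
(`V01-Y98`), degenerate codes (`I50`), or bare letters (`S` = S00–S99).
Categories may overlap — intentional self-harm (X60–X84) also lies inside
the external-causes span — and each label is analysed as its own
independent count series, so per-cause results are deliberately
non-additive. The parent/child containment check (subcategory counts never
exceeding their main category) is applied only where the child's ranges
truly nest inside the parent's; presentation groupings (self-harm listed
under mental and behavioural disorders) are exempt.

## Synthetic data generator

No suitable daily mortality/weather panel is freely redistributable, so
validation runs on synthetic studies whose generative truth is known and
recoverable.

**Weather.** Daily maximum temperature is an annual sinusoid peaking on
1 August plus iid Gaussian noise:
$T_t = \mu + A\cos(2\pi(\mathrm{doy}_t - 213)/365.25) + \varepsilon_t$.
Defaults $\mu = 15$ °C, $A = 16.2$ °C, $\sigma = 3$ °C give a warm-season
mean of 26.5 °C, an overall range of roughly −10 to 40 °C and a marginal
90th percentile of ≈30.6 °C. A single sinusoid cannot also reproduce a
mid-latitude monsoon climate's flat-topped summer, so the sharper upper
tail places q90 about a degree above what a real flat-topped record with
the same warm-season mean would give; all analyses are relative to the
percentile, not the absolute temperature, so nothing downstream depends on
this. Mean and minimum temperature sit below the maximum by jittered
positive offsets (defaults 4.0 and 7.7 °C); humidity and pressure follow
their own seasonal cycles (humid summers, low summer pressure); PM10 and
O3 exist only from a configurable start year (default 2001), earlier days
missing — emulating a monitoring network that came online mid-study. The
calendar is real (Gregorian, leap days), so day-of-week effects are
honest.

**Threshold truth.** `true_threshold=None` (the default) resolves to the
90th percentile of the generative marginal tmax distribution, computed by
root-finding on the calendar-day normal-mixture CDF. The excess-mortality
regime therefore starts exactly at the percentile the analysis pipeline
estimates, which is the property parameter-recovery and sensitivity
studies need; an explicit value in °C can be set instead.

**Mortality.** For a cause at the top of the hierarchy the day-$t$ mean is
$\mu_t = b \cdot d_{w(t)} \cdot \exp(\eta t^* + c_h(h_t - 70) +
c_p(p_t - 1009) + \beta \max(0, T_t - \theta))$ with baseline $b$ (the
warm-season daily mean at reference covariates), day-of-week multipliers
$d$, a log-linear trend $\eta$ centred mid-study, and small humidity and
pressure coefficients. Counts are negative binomial with size $r =
\mu/(\phi-1)$ so the variance is exactly $\phi\mu$ (Poisson when
$\phi = 1$), drawn by inverting the CDF at one uniform variate per (day,
cause). The inverse-CDF construction makes counts a deterministic
monotone function of the per-day uniforms, so changing $\beta$ perturbs
*only* days above the threshold — sub-threshold days are bit-identical
across $\beta$ under the same seed, a property the test suite checks
exactly.

Causes with a declared parent are binomial thinnings of the parent's
realised count with share $b_{child}/b_{parent}$, guaranteeing
subcategory ≤ main category pairwise and inheriting the same relative
heat effect. Thinning shrinks the child's dispersion to
$1 + s(\phi - 1)$; rarer causes are thus closer to Poisson, which matches
how small counts behave in practice.

**Defaults.** 18 years starting 1992; ten causes spanning a common
baseline of 98.67 deaths/day down to a rare 0.07/day; $\beta = 0.0296$
(RR 1.03 per °C); $\phi = 1.5$; day-of-week multipliers within 2 % of 1;
trend +0.3 %/year; humidity +0.001 and pressure −0.0005 per unit on the
log scale. Published dispersion estimates for this design do not exist,
so $\phi = 1.5$ is a conventional mild-overdispersion choice, not an
empirical value.

**What the generator does not emulate:** mortality displacement
(harvesting), heat-wave duration effects, within-city spatial gradients
(urban heat islands), influenza winters, monsoon cloud capping of summer
maxima, and autocorrelated weather noise. Passing tests therefore
demonstrate that the estimator recovers a known log-linear
above-threshold effect under realistic marginal distributions and
confounding — not that any particular real-world estimate is correct.

## Numerical choices

* IRLS convergence: relative deviance change < 1e-8 or 100 iterations;
  non-convergence is flagged on the result, and the grid runner records
  failed cells in-row rather than aborting.
* Rank: the design is rejected at fit time if collinear, with the
  offending columns named. A degenerate-but-valid design (heat column all
  zero when no day exceeds θ) can be built and inspected but not fitted.
* Trend spline: patsy's natural cubic `cr` basis on a continuous day
  index over in-season days; the basis spans the constant, so one column
  is dropped and the trend contributes exactly
  `round(trend_df_per_year × years)` parameters beyond the intercept
  (default 1 df/year — the standard order of flexibility for multi-year
  time-series confounding when only a trend, not within-season
  seasonality, must be absorbed; within-season shape is left to the heat
  term).
* Lag transforms operate on temperature *before* thresholding, and days
  lacking full lag history (block starts, calendar gaps) are dropped and
  logged.
* Pollutant-adjusted fits restrict to the pollutant-covered date range;
  the sensitivity grid also re-reports the unadjusted model on the same
  window so the adjustment effect is isolated from the window change.
* LOWESS: non-robust single-pass local linear regression with tricube
  weights; span is the fraction of points per window (span 1.0 = all
  points). Chosen over the robustified variant because the RR-vs-AD
  scatter has few points and no heavy-tailed residuals; it is verified
  against a pointwise weighted-least-squares oracle and against the
  statsmodels implementation at span 1.0.
* Display rounding is half-up (Decimal), matching typeset tables;
  machine outputs are never rounded.

## Known limitations

* The threshold is taken as known in the variance calculation; the
  sampling variability of the empirical percentile slightly deflates
  reported standard errors (measured SE/SD ratio ≈ 0.96 in the recovery
  study), within the tolerance of the coverage checks but visible.
* No distributed-lag non-linear modelling; the four lag structures are
  fixed transforms.
* No uncertainty interval on attributable deaths.
* Each cause is fitted independently — no shrinkage, no multiplicity
  correction across causes or grid cells.
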