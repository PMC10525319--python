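# Methods

## Scope

stemflux analyses paired point-dendrometer records from conifer stems: an
over-bark sensor on the living phloem and an on-xylem sensor bearing on
the sapwood through an inserted screw.  The inner-bark series (IBV) is the
over-bark record minus the on-xylem record (XRV).  All processing assumes
a strictly regular 30-minute grid in local standard time (no DST shifts);
gaps are NaN values on the grid, never missing rows.

## Stem hydraulics model (synthetic data)

The simulator is a two-compartment resistance–capacitance stand-in for a
transpiring stem.  It is the minimal mechanism that produces the three
qualitative signatures the pipeline is built to measure — the
bark-behind-xylem lag, the ~10:1 bark:xylem amplitude ratio, and the
saturating amplitude–VPD relation — and is used as ground truth for
closed-loop tests, not as a claim about any particular stand.

Per 30-minute step (Δt = 0.5 h):

* Transpiration: `E = g_max · s(SR) · VPD / (1 + VPD/vpd_sat)`, with
  `s(SR) = clip(SR/sr_sat, 0, 1)` the light response of canopy
  conductance.  `sr_sat` (default 150 W m⁻²) is the saturating
  irradiance: stomatal conductance of conifers saturates well below full
  sun, so E is light-limited only at dawn, dusk and in deep shade.  E = 0
  at night (SR = 0); no nocturnal transpiration.
* Soil: `Ψ_soil = −k_soilpsi · (swc_ref − SWC)`.  The default
  `k_soilpsi = 0.02 MPa per vol %` keeps soil influence deliberately weak
  (≈ −0.6 MPa over the full SWC range): the drought-exposed pines being
  emulated buffer transpiration from stored stem water and deeper soil
  layers, and their xylem signal is dominated by atmospheric demand.
* Xylem node, quasi-steady (the xylem's own capacitance is negligible at
  this step size): `(Ψ_soil − Ψ_x)/r_soil + (Ψ_s − Ψ_x)/r_stor = E`
  solved for `Ψ_x` each step.
* Storage: exchange flow `q = (Ψ_s − Ψ_x)/r_stor`, explicit Euler update
  `W ← W − q·Δt`, `Ψ_s = Ψ_s0 + (W − W0)/c_stor`.  Water is in arbitrary
  units; only potentials and radii are physical.  The water balance
  `W(end) − W(0) = −Σ q·Δt` closes to round-off and is asserted on every
  run.
* Radii: `r_x = eps_x·(Ψ_x − Ψ_x(0))`;
  bark thickness `b = G(t) + eps_b·(Ψ_s − Ψ_s(0))` with `G` a Gompertz
  curve over day of year (default total 700 µm per season, midpoint day
  170, rate 0.035 d⁻¹ — the slow growth of a drought-limited pine).
* Measurement: thermal artifacts `α_x·T` (1.08 µm °C⁻¹, sensor + steel
  screw) and `α_b·T` (0.2 µm °C⁻¹, sensor body) are added to the true
  radii, plus Gaussian noise (0.5 µm) and Bernoulli gaps (1 %).  All
  randomness derives from one integer seed; identical seeds give bitwise
  identical output including gap placement.

### Lag and amplitude-ratio ground truth

The storage potential relaxes toward its hydraulic environment with
effective time constant `τ_s = (r_soil + r_stor)·c_stor`, so for a
sinusoidal diurnal forcing of period P = 24 h the bark trails the xylem by
the first-order phase delay `(P/2π)·arctan(2π τ_s/P)`
(`implied_lag_hours`).  With the defaults r_soil = 0.1, r_stor = 1.0,
c_stor = 2.0 (τ = r_stor·c_stor = 2 h) this evaluates to 1.996 h.  The
cross-correlation estimator recovers ≈ 1.65–1.78 h on simulated seasons;
the shortfall is real, not an estimator bug: the half-wave daytime forcing
carries 12-h and 8-h harmonics whose first-order delays are shorter than
the 24-h delay, and the peak of the cross-correlation is a
variance-weighted compromise.  The ±0.5 h recovery tolerance covers this.

The measured bark:xylem amplitude ratio recovers `eps_b/eps_x` times an
attenuation factor ≈ 0.9 (the storage low-pass shaves the diurnal peak),
≈ 9.2 noiseless and ≈ 8.4 with default noise for a true ratio of 10.

### Euler stability

The quasi-steady Ψ_x solve removes the stiffest mode; the remaining
storage update is stable for τ_s ≫ Δt.  A guard raises a numerical error
if |ΔΨ_x| exceeds 1 MPa in one step, advising a smaller step or larger
resistances.

## Weather generator

Temperature is a seasonal sinusoid (peaking around day 200) plus an AR(1)
day-to-day anomaly (φ = 0.7, σ = 3.5 °C) and a diurnal sinusoid peaking at
15:00, damped on cloudy days.  RH is anticorrelated with temperature
(slope 2.5 % per °C), raised on cloudy days and forced toward saturation
in rain; it is clipped to [5, 100] %.  SR follows a half-sine photoperiod
(8–16 h over the year), zero at night, reduced 75 % on cloudy days.  Rain
arrives as a daily Poisson process (0.45 events d⁻¹) with exponential
amounts (mean 4.7 mm), giving ≈ 350–450 mm per growing season.  Soil
water is a bucket: rain fills it (0.6 vol % per mm), exponential drainage
(4 % d⁻¹ of the plant-available store) empties it faster on high-VPD
days.  The defaults emulate a dry inner-alpine growing season: seasonal
means/maxima of daily T ≈ 15 / 30–36 °C, VPD ≈ 0.7 / 3–5 kPa,
precipitation ≈ 390–460 mm, SWC 5–33 vol %.

What the generator does *not* emulate: frontal weather sequences with
multi-day rain, freeze–thaw dynamics (winter is outside the analysis
window), topographic shading, dew formation, or humidity-driven swelling
of dead bark (the sensors being emulated sit on living tissue).  Passing
closed-loop tests therefore demonstrates correctness of the signal
processing under a plausible forcing, not that real records are this
clean.

## Preprocessing

* **VPD** uses the Magnus saturation curve
  `e_s = 0.6108·exp(17.27 T/(T + 237.3))` kPa; alternative standard
  parameterisations differ by < 1 % over 0–40 °C.
* **Thermal correction** subtracts `coeff·(T − T_ref)` — a warmer screw
  and sensor body inflate the raw reading.  Coefficients are fixed
  per-sensor constants (over-bark 0.2, on-xylem 1.08 µm °C⁻¹); the
  on-xylem value is taken as given, not re-derived from material
  expansion coefficients (the screw length is installation-specific).
  T_ref defaults to the first valid observation; only variations matter
  downstream, so the choice shifts an offset only (asserted by test).
  Double correction is a state error.
* **Decomposition** is exact subtraction on the shared grid; records are
  joined on identical timestamps, never interpolated.
* **Tree aggregation** re-zeroes each trace to its first valid reading,
  then takes the per-timestamp mean and standard error (SD/√n) over trees
  with data present.

## Daily metrics

Days are midnight-to-midnight; a day needs ≥ 90 % of its 48 records
(default) to report metrics, otherwise the row stays with nulls.  Extrema
times are clock hours with ties broken by earliest occurrence.  The daily
mean change is mean(day d) − mean(day d−1) assigned to day d.  The
growing season is April 1 – September 30.  By default the daily statistics
feeding the coupling stage are computed on the tree-mean trace; per-tree
tables are also written.

## Detrending

The seasonal trend is a hard spectral low-pass on the daily series: mean
removed, mirror-padded to twice the length (continuous at both ends,
symmetric under time reversal), Fourier components with period shorter
than `cutoff_days` zeroed, inverse transform truncated to the original
span.  Cutoffs of 10 days (residual analysis) and 25 days (seasonal
display) are the defaults.  Internal gaps up to 10 % are linearly bridged
for the transform only and re-masked on output; more gaps raise a
data-quality error.  A hard cutoff with mirror padding was chosen over
windowed designs for testability (exact pass/stop-band assertions); the
trade-off is mild ringing near sharp features, acceptable on daily series.

## Coupling statistics

* **Spearman ρ**: Pearson correlation of average ranks, pairwise deletion,
  p from the t approximation with n−2 df (p = 0 at |ρ| = 1), ≥ 5 pairs
  required.  No multiple-testing correction; significance stars at
  0.05/0.01/0.001.
* **Correlation table**: the three daily xylem metrics (max, mean, min)
  against T, VPD and RH daily max/mean/min plus daily precipitation total
  and mean SWC, growing season only.
* **Stepwise regression**: forward selection with backward elimination on
  partial-F p-values (entry 0.05, removal 0.10 — the conventional defaults
  of the commercial packages this mirrors; both configurable), iterated to
  a fixed point with cycle detection.  Coefficients are non-standardized;
  the full environmental pool of the correlation table is offered and
  selection chooses.  Perfect collinearity is detected and reported as an
  error naming the offending pair.
* **Amplitude fits**: least squares of daily amplitude on `ln(VPD_max)`
  (days with VPD_max ≤ 0.05 kPa excluded; ≥ 10 days required) with the
  linear fit's R² on the same days for comparison, plus Spearman ρ of the
  amplitude against each environmental variable.
* **Lag**: normalised cross-correlation of the inner-bark against the
  xylem 30-min series over their longest common gapless window (≥ 3
  days), lags ±12 h at 30-min resolution, parabolic refinement of the
  discrete peak; positive = bark lags xylem.  Both series are first
  high-passed by subtracting a centred 24-h rolling mean.  Calendar-day
  demeaning was considered and rejected: it leaves within-day drift (soil
  drying, growth) that both tissues share at zero lag, which biases the
  estimate low by ~0.5 h on simulated data.

## Problem sizes and reproducibility

The default simulated study is two growing seasons (549 days from April
1) of four trees — commensurate with the 516–549 growing-season days per
statistic of a three-year field campaign at desk scale.  The full
pipeline runs in seconds; `scripts/acceptance.py` reruns everything,
including 1,000-vector and 50-dataset oracle comparisons, in under a
minute.  All randomness flows from a single seed through per-stage
derived seeds; rerunning a stage from its on-disk inputs reproduces the
end-to-end bytes.

## Known limitations

* No osmotic regulation of the phloem: the model cannot produce opposite
  xylem/bark movements, and the pipeline does not test for them.
* No sap-flow output, multi-height sensors, or winter (freeze–thaw)
  dynamics.
* The correlation structure among environmental drivers (T, VPD, SR share
  the diurnal and seasonal cycle) means the regression models report
  association, not attribution.
* The stepwise fixed point is not guaranteed unique in pathological
  near-collinear pools; the oracle tests cover well-conditioned pools of
  up to five predictors.
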