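# stemflux

Point-dendrometer signal processing for conifer stems: decompose paired
over-bark and on-xylem radius records into **xylem (XRV)** and **inner-bark
(IBV)** radial variations, reduce them to daily metrics, strip seasonal
trends with an FFT low-pass filter, and quantify how tightly the two
tissues are hydraulically coupled and which environmental variables drive
the xylem signal.

The package is aimed at tree ecophysiologists working with 30-minute
dendrometer and microclimate records (air temperature T, relative humidity
RH, solar radiation SR, precipitation P, soil water content SWC).  It also
ships a **transpiration-driven two-compartment stem simulator** with known
ground truth, so the entire pipeline is testable without field data.

## The science in brief

Transpiration puts the xylem water column under tension.  Because the
lignified xylem is stiff and the living inner bark (phloem, cambium,
parenchyma) is soft, the xylem contracts little and early while the bark
contracts strongly and late: water is drawn radially out of the elastic
bark storage through an exchange resistance.  The pipeline quantifies the
three signatures of this passive hydraulic system:

* a **bark-behind-xylem time lag** of roughly two hours in the daily cycle,
* a **bark:xylem daily amplitude ratio** of roughly 10:1,
* tight rank correlation between the detrended (residual) XRV and IBV
  series, and a **saturating (logarithmic) relation** between the daily
  xylem amplitude and daily maximum vapour pressure deficit
  (VPD = e_s(T)·(1 − RH/100), Magnus form), reflecting the decline of
  canopy conductance at high VPD.

The simulator implements the minimal mechanism behind those signatures: a
resistance–capacitance network with transpiration
E = g_max·s(SR)·VPD/(1 + VPD/vpd_sat), a quasi-steady xylem node
(Ψ_soil − Ψ_x)/r_soil + (Ψ_s − Ψ_x)/r_stor = E, an elastic storage pool
W with Ψ_s = Ψ_s0 + (W − W0)/c_stor, radii following the potentials
(eps_x, eps_b µm MPa⁻¹), Gompertz seasonal growth on the bark, thermal
sensor artifacts (subtracted later at 0.2 and 1.08 µm °C⁻¹), noise and
gaps.  The storage time constant τ = r_stor·c_stor sets the lag;
eps_b/eps_x sets the amplitude ratio.

## Worked example

```python
from stemflux import default_simulation_config, run_pipeline

report = run_pipeline(default_simulation_config(seed=1, out_dir="demo"))
print(f"residual coupling rho = {report.residual_coupling.rho:.3f} "
      f"(n = {report.residual_coupling.n})")
print(f"bark-behind-xylem lag = {report.lag_hours:.2f} h")
print(f"amplitude ~ ln(VPD_max): R2 = {report.amplitude_fit.r2:.3f} "
      f"(linear fit R2 = {report.amplitude_fit.linear_r2:.3f})")
```

prints

```
residual coupling rho = 0.995 (n = 366)
bark-behind-xylem lag = 1.66 h
amplitude ~ ln(VPD_max): R2 = 0.894 (linear fit R2 = 0.811)
```

i.e. on the default two-season simulation (four trees, noise, gaps,
thermal artifacts) the detrended xylem and inner-bark series are tightly
rank-correlated over the 366 growing-season days, the inner bark trails
the xylem by about 1.7 h (the model's first-order prediction for
τ = 2 h is 2.0 h), and the logarithmic amplitude–VPD fit clearly beats a
straight line, as expected when canopy conductance saturates with VPD.
The same run writes `demo/` with every intermediate: `climate.csv`,
`dendro.csv`, `corrected.csv`, `daily_radius.csv`, `daily_climate.csv`,
`table1.csv` (growing-season climate summary), `residuals.csv`,
`table2.csv` (metric × environment Spearman matrix), `table3.csv`
(stepwise regression models), `fig6_fits.csv`, `coupling_report.json`
and `manifest.json`.

The same pipeline runs from the shell:

```bash
stemflux run-all --seed 1 --out-dir demo          # simulated stand
stemflux run-all --config myrun.yaml              # your own CSVs
```

A YAML config points either at a `simulate:` block or at `inputs:` with
`dendro_csv` (columns `timestamp, tree_id, position, radius_um`; position
is `overbark` or `xylem`) and `climate_csv` (columns `timestamp, t_air_c,
rh_pct, sr_wm2, p_mm, swc_volpct`).  Individual stages (`simulate`,
`preprocess`, `daily`, `detrend`, `couple`) can be re-run on the plain-CSV
intermediates.  To analyse the published field records (Zenodo record
8202893), export its tables to those two CSV layouts and point `inputs:`
at them; `--skip-thermal` is available in the `preprocess:` block if the
deposited traces are already temperature-corrected.

## Layout

* `src/stemflux/synthetic.py` — weather generator and stem simulator
* `src/stemflux/preprocess.py` — VPD, thermal correction, IBV decomposition, tree means
* `src/stemflux/daily.py` — daily radius/climate metrics, growing-season summary
* `src/stemflux/detrend.py` — FFT low-pass smoothing and residuals
* `src/stemflux/coupling.py` — Spearman, correlation table, stepwise OLS, log fit, lag
* `src/stemflux/pipeline.py`, `cli.py` — orchestration and the `stemflux` command
* `docs/methods.md` — model assumptions, parameter choices, limitations
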