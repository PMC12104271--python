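# phenohydro

Phenology-driven water requirement and suitability assessment for apple
orchards at site/county scale.

Dryland apple production depends on matching irrigation to the crop's
phenological calendar. This package chains the whole workflow:

1. **Flowering date** — an ensemble of four chilling/forcing phenology
   models driven by daily mean temperature:
   * *M1* (photothermal time): Σ (L_i/24)^k · max(T_i − T_b, 0) ≥ F\*
   * *Uniforc*: Σ 1/(1 + exp(b(T_i − c))) ≥ F\* (b < 0)
   * *Alternating*: degree-day forcing against a chill-day-relaxed
     requirement a + b·e^(c·CD)
   * *Unichill*: sequential chilling (bell-shaped response, Σ R_c ≥ C\*)
     then sigmoidal forcing (Σ R_f ≥ F\*)

   Each model is calibrated to observed flowering dates by basin-hopping
   RMSE minimisation (70/30 calibration/validation split); the member
   predictions are combined with normalised inverse-validation-RMSE
   weights w_m = (1/RMSE_m)/Σ(1/RMSE_k).
2. **Phenophase windows** — flowering–fruit setting, fruit expansion and
   coloring–maturity stages chained onto the flowering date with
   configurable durations (defaults 22/102/39 days).
3. **Crop coefficient** — a daily Kc curve anchored at 0.33 (dormancy),
   0.45 (end of green-up), 0.75 (flowering onset), 0.95 (mid-season
   plateau reached by fruit set).
4. **Reference evapotranspiration** — daily FAO-56 Penman–Monteith ET₀
   with every intermediate (vapour pressures, psychrometric constant,
   solar geometry, radiation balance) exposed for audit, including a
   strict "as-printed" variant of the contested formulas.
5. **Water balance** — per stage j: water requirement
   WR_j = Σ Kc(i)·ET₀(i); USDA-SCS daily effective precipitation
   (P_eff = P(4.17 − 0.2P)/4.17 below 8.2 mm, 4.17 + 0.1P above);
   irrigation requirement IWR_j = max(WR_j − P_eff,j, 0); suitability
   S_j = P_eff,j / WR_j classified into six bands from "Worst
   suitability" (S < 0.4) to "Excessive moisture" (S ≥ 2.0).

A seeded synthetic-data module generates multi-year site weather and
noisy flowering observations from known model parameters, so the whole
pipeline — including calibration as a parameter-recovery experiment — is
testable without any external data.

## Worked example

```python
import phenohydro as ph
from phenohydro.calibration import calibrate, ensemble_weights, split_observations
from phenohydro.pipeline import RunConfig, run_assessment, summarize

sites = ph.default_sites(6)                       # 30–42 °N belt
weather = {s.site_id: ph.generate_weather(s, range(1999, 2026),
                                          ph.climate_for_site(s, seed=3))
           for s in sites}
obs = ph.generate_flowering_obs(weather, "uniforc",
                                ph.DEFAULT_TRUE_PARAMS["uniforc"],
                                noise_sd=2.0, seed=7)
cal, val = split_observations(obs, 0.7, seed=11)
rep = calibrate("uniforc", cal, weather, iterations=100, seed=5,
                val_obs=val)
print(f"RMSE_c={rep.rmse_c:.2f} d  RMSE_v={rep.rmse_v:.2f} d  "
      f"F*={rep.params.f_star:.2f}")
```

prints

```
RMSE_c=1.92 d  RMSE_v=1.79 d  F*=41.51
```

i.e. with 2-day observation noise over ~150 site-years the calibration
and held-out errors match the injected noise. The fitted forcing
requirement lands above the generating truth (F\* = 35) on this
particular noise realisation — single fits wander the correlated
F\*–midpoint ridge of the sigmoid model even when the fit is at noise
level; the median over repeated seeds recovers F\* to a few percent
(see `docs/methods.md`). Feeding fitted parameters
and weights into `RunConfig` and `run_assessment(weather, cfg)` yields
one record per site, year and stage with `wr_mm`, `peff_mm`, `iwr_mm`,
`s` and the suitability class; `summarize` aggregates site means, grand
means and frequency histograms.

The same workflow is available from the shell:

```bash
phenohydro simulate-data --sites 6 --out data/
phenohydro fit --model all --obs data/observations.csv \
    --weather-dir data/weather --sites data/sites.csv --seed 1 --out fit.yaml
phenohydro run --weather-dir data/weather --sites data/sites.csv \
    --fit-report fit.yaml --out results/
phenohydro summarize --records results/assessments.csv --out results/
```

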