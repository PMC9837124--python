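# peatfire

Hydrology-informed fortnightly fire forecasting for tropical peatland and
mineral-soil landscapes.

Fires in equatorial peatlands (Riau-like settings: two dry seasons, heavy
drainage, deep organic soils) are controlled less by same-week weather
than by the slowly-evolving state of the soil column: the water table
depth (WTD) and near-surface moisture integrate months of rainfall,
evapotranspiration and artificial drainage. `peatfire` provides the whole
chain needed to test and exploit that mechanism at desk scale:

1. **A daily soil-column water balance** for stand-alone peat and mineral
   profiles (15 layers + a 2 cm litter mat by default). Moisture
   retention follows van Genuchten, θ(ψ) = θr + (θs−θr)[1+(αψ)ⁿ]^(−m)
   with m = 1−1/n and the Mualem conductivity closure; saturated
   conductivity comes from bulk-density pedo-transfer functions. Vertical
   flow is a conductivity-limited tipping bucket; lateral flow is a Darcy
   exchange q = K̄ (WTDx − WTD)/L with a fixed boundary water table WTDx
   representing the adjacent watershed or drainage canal (6 m under
   non-peat grids, 0.30–0.75 m under peat depending on land use). WTD is
   diagnosed as the top of the bottom-contiguous saturated zone; a cell
   is a *peatland grid* when all layers down to ≥ 0.3 m have organic
   matter > 65 %.
2. **Fortnight feature aggregation**: non-overlapping 14-day blocks from
   1 January; five weather aggregates + antecedent 4-week precipitation
   (6 features), optionally + mean WTD and near-surface moisture
   (8 features).
3. **Paired fire-count networks**: two 4-layer perceptrons
   ([6|8]–32–16–1, relu, MSE + Adam at 0.001, early stopping) trained
   with leave-one-year-out validation — ANN(WTHR) on weather only,
   ANN(WTHR+HYDROL) with the hydrology features added.
4. **Evaluation**: counts pooled per fortnight over peatland /
   non-peatland subsets; R², MAE and time-differenced R² (n_{t+1} − n_t);
   per-cell daily correlation of modelled vs observed moisture; and a
   Youden-J estimate of the WTD that best separates fire from no-fire
   fortnights.
5. **A seeded synthetic-data generator** reproducing the study setting —
   bimodal dry seasons, drought years, peat/mineral archetypes,
   land-use-dependent drainage, and Poisson fire counts gated at a known
   WTD threshold (0.4 m by default) — so every stage is testable without
   downloading reanalysis or satellite products.

## Worked example

```python
from peatfire.pipeline import run_synthetic_study, recover_fire_threshold, skill_contrast

study = run_synthetic_study(seed=1)          # 50 cells x 8 years, ~15 s
wtd = study.dataset.wtd.to_dataframe().reset_index()
wtd["landuse"] = wtd["cell"].map({c.cell_id: c.column.landuse.value for c in study.cells})
print(wtd.groupby("landuse").wtd.mean().round(2).to_string())

thr = recover_fire_threshold(1, study=study)
print(f"recovered fire threshold: {thr.depth:.2f} m (Youden J = {thr.youden_j:.2f})")
r2s = skill_contrast(study, replicate_seed=0)
print(f"pooled out-of-sample R2: weather-only {r2s['wthr']:.2f}, "
      f"weather+hydrology {r2s['wthr_hydrol']:.2f}")
```

prints

```
landuse
degraded_forest          0.28
industrial_plantation    0.44
non_peat_other           2.99
pristine_forest          0.25
smallholder              0.55
recovered fire threshold: 0.39 m (Youden J = 0.91)
pooled out-of-sample R2: weather-only 0.86, weather+hydrology 0.89
```

Read: pristine/degraded peat-swamp forest keeps the shallowest water
tables (~0.25–0.28 m), drained industrial plantations and smallholder
farmland progressively deeper (0.44, 0.55 m), and non-peat grids drain
toward their 6 m boundary. The Youden-J estimator recovers the
generator's 0.40 m fire-occurrence threshold to within a centimetre, and
the network that sees simulated hydrology beats the weather-only network
out of sample — the package's central claim, which holds in ≥ 9 of 10
seeded replicates (see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```bash
peatfire synth    --n-cells 50 --years 8 --seed 1 --out-dir run/
peatfire simulate --out-dir run/
peatfire features --out-dir run/ --seed 1
peatfire train    --out-dir run/ --mode wthr_hydrol --seed 1
peatfire evaluate --out-dir run/ --mode wthr_hydrol
```

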