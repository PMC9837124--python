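"""End-to-end synthetic study helpers: generate -> simulate -> aggregate
-> (optionally) attach fire counts, train and score.

These are the programmatic equivalents of chaining the CLI stages and are
what the recovery experiments (threshold estimation, skill contrast) run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import features as ft
from . import firemodel as fm
from . import orchestration as orch
from . import synthdata as sd

__all__ = ["SyntheticStudy", "run_synthetic_study", "recover_fire_threshold",
           "skill_contrast"]


@dataclass
class SyntheticStudy:
    truth: sd.SyntheticTruth
    cells: list
    forcing: dict
    dataset: object  # xarray.Dataset of daily hydrology
    daily: pd.DataFrame  # forcing + hydrology, long format
    records: pd.DataFrame  # fortnight aggregates (no fire counts)

    @property
    def classification(self) -> dict[str, str]:
        return {c.cell_id: c.classification for c in self.cells}


def run_synthetic_study(seed: int, n_cells: int = 50,
                        config: orch.RunConfig | None = None) -> SyntheticStudy:
    """Generate a synthetic grid and weather, run the water balance over
    the study years and aggregate to fortnight records."""
    truth = sd.SyntheticTruth(seed=seed)
    config = config or orch.RunConfig()
    cells = sd.gen_grid(truth, n_cells, config)
    forcing = sd.generate_forcing(truth, cells)
    ds = orch.run_grid(cells, forcing, config)
    hydro = (ds[["wtd", "theta_ns"]].to_dataframe().reset_index()
             .rename(columns={"cell": "cell_id", "time": "date"}))
    daily = pd.concat([f.assign(cell_id=cid) for cid, f in forcing.items()])
    daily = daily.merge(hydro, on=["cell_id", "date"])
    records = ft.aggregate_fortnights(daily)
    return SyntheticStudy(truth=truth, cells=cells, forcing=forcing,
                          dataset=ds, daily=daily, records=records)


def recover_fire_threshold(seed: int, n_cells: int = 50,
                           study: SyntheticStudy | None = None) -> ev.ThresholdResult:
    """One seed of the threshold-recovery experiment: generate synthetic
    fire counts from the simulated hydrology (occurrence gated at the
    generator's water-table threshold), then re-estimate that threshold
    from the pooled cell-fortnight series with Youden's J."""
    if study is None:
        study = run_synthetic_study(seed, n_cells)
    records = study.records.copy()
    counts = sd.gen_fire_counts(study.truth, records, seed=seed)
    return ev.estimate_wtd_threshold(records["mean_wtd"].to_numpy(),
                                     counts.to_numpy() > 0)


def skill_contrast(study: SyntheticStudy, replicate_seed: int) -> dict[str, float]:
    """Train both model variants on one replicate of synthetic fire
    counts and return the pooled out-of-sample R^2 per mode.

    Replicates share the simulated hydrology and differ in the Poisson
    count draw and the network initialisation seeds.
    """
    records = study.records.copy()
    records["fire_count"] = sd.gen_fire_counts(study.truth, records,
                                               seed=10_000 + replicate_seed)
    cls = study.classification
    out = {}
    for mode in ("wthr", "wthr_hydrol"):
        X, y, years = ft.build_design_matrix(records, mode)
        spec = fm.NetworkSpec(n_features=X.shape[1], seed=replicate_seed)
        _, oos = fm.train_loocv(X, y, years, spec)
        kept = records.dropna(subset=["sum_precip_prior_4wk"])
        idx = kept.set_index(["cell_id", "year", "step"])
        pooled = ev.pool_counts(pd.Series(oos, index=idx.index),
                                idx["fire_count"].astype(float), cls)
        whole = pooled["peatland_grid"].add(pooled["non_peatland_grid"],
                                            fill_value=0)
        out[mode] = ev.r2(whole["pred"], whole["obs"])
    return out
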