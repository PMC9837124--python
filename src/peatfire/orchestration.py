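"""Grid-scale runs: configuration, boundary assignment, spin-up and the
daily production loop over many stand-alone columns.

Cells never exchange water, so the runner batches them into elementwise
array operations; outputs are identical to running each cell alone and
invariant under cell ordering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import engine
from .hydrology import (
    ColumnState,
    HydrologyError,
    LandUse,
    SoilColumn,
    SoilLayer,
    classify_profile,
    pedotransfer_ksat,
    _pet_mm,
)

__all__ = [
    "GridCell",
    "RunConfig",
    "GapError",
    "SimulationError",
    "assign_boundary_wtdx",
    "spin_up",
    "run_grid",
    "read_forcing_csv",
    "read_grid_csv",
    "fit_retention_csv",
    "write_outputs",
]

FORCING_FIELDS = ("precip", "tair", "radiation", "rh", "wind")


class GapError(HydrologyError):
    """Forcing does not cover the requested period."""


class SimulationError(HydrologyError):
    pass


@dataclass(frozen=True)
class GridCell:
    cell_id: str
    lat: float
    lon: float
    column: SoilColumn
    classification: str = ""

    def classified(self) -> "GridCell":
        return dataclasses.replace(self, classification=classify_profile(self.column))


@dataclass
class RunConfig:
    """Run-wide settings.

    Boundary water tables (``wtdx``) are per-land-use defaults for
    peatland grids; non-peatland grids drain to a 6 m boundary except
    mangroves, which sit at the surface (tidal, no artificial drainage).
    """

    spin_up_years: int = 56
    production_start: str = "2008-01-01"
    production_end: str = "2015-12-31"
    sub_steps: int = 24
    seed: int = 0
    spin_drift_tol_m: float = 1e-3
    conservation_tol_m: float = 1e-6
    substep_refinement_tol_m: float = 0.02
    wtdx_non_peat: float = 6.0
    wtdx_mangrove: float = 0.0
    wtdx_peat: dict = field(default_factory=lambda: {
        "pristine_forest": 0.30,
        "degraded_forest": 0.35,
        "industrial_plantation": 0.60,
        "smallholder": 0.75,
        "mangrove": 0.0,
    })
    pft_coefficients: dict = field(default_factory=lambda: {
        "pristine_forest": 1.0,
        "degraded_forest": 0.95,
        "industrial_plantation": 1.05,
        "smallholder": 0.95,
        "mangrove": 1.0,
        "non_peat_other": 0.9,
    })

    def __post_init__(self) -> None:
        if self.spin_up_years < 0:
            raise ValueError("spin_up_years must be >= 0")
        if pd.Timestamp(self.production_start) > pd.Timestamp(self.production_end):
            raise ValueError("production period is not well-ordered")

    @property
    def production_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.production_start, self.production_end, freq="D")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; expected a subset of {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def assign_boundary_wtdx(landuse: LandUse, classification: str,
                         config: RunConfig | None = None) -> float:
    """Boundary water table depth (m below surface) for one cell.

    Non-peatland grids drain to 6 m; mangroves sit at 0 m; peatland grids
    take land-use defaults ordered forest < plantation < smallholder,
    reflecting progressively deeper artificial drainage.
    """
    config = config or RunConfig()
    landuse = LandUse(landuse)
    if landuse is LandUse.MANGROVE:
        return float(config.wtdx_mangrove)
    if classification == "non_peatland_grid":
        return float(config.wtdx_non_peat)
    if classification != "peatland_grid":
        raise ValueError(f"unknown classification {classification!r}")
    try:
        return float(config.wtdx_peat[landuse.value])
    except KeyError as exc:
        raise ValueError(
            f"no peatland boundary water table configured for land use {landuse.value!r}"
        ) from exc


def _check_forcing(df: pd.DataFrame, dates: pd.DatetimeIndex, cell_id: str) -> pd.DataFrame:
    dates = pd.DatetimeIndex(dates)
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.set_index("date").sort_index()
    missing = dates.difference(df.index)
    if len(missing):
        shown = ", ".join(str(d.date()) for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise GapError(f"cell {cell_id}: forcing missing {len(missing)} days: {shown}{more}")
    out = df.loc[dates, list(FORCING_FIELDS)]
    if (out["precip"] < 0).any():
        raise HydrologyError(f"cell {cell_id}: negative precipitation in forcing")
    if ((out["rh"] < 0) | (out["rh"] > 100)).any():
        raise HydrologyError(f"cell {cell_id}: relative humidity outside [0, 100] %")
    return out


def _forcing_arrays(cells: Sequence[GridCell], forcing: Mapping[str, pd.DataFrame],
                    dates: pd.DatetimeIndex, config: RunConfig):
    """(n, T) precipitation [m/d] and PET [m/d] arrays for a cell group."""
    precip = np.empty((len(cells), len(dates)))
    pet = np.empty_like(precip)
    for i, cell in enumerate(cells):
        if cell.cell_id not in forcing:
            raise GapError(f"no forcing provided for cell {cell.cell_id}")
        df = _check_forcing(forcing[cell.cell_id], dates, cell.cell_id)
        precip[i] = df["precip"].to_numpy() / 1000.0
        coeff = config.pft_coefficients[cell.column.landuse.value]
        pet[i] = _pet_mm(df["tair"].to_numpy(), df["radiation"].to_numpy(),
                         df["rh"].to_numpy(), df["wind"].to_numpy()) / 1000.0 * coeff
    return precip, pet


def spin_up(cell: GridCell, one_year_forcing: pd.DataFrame, config: RunConfig,
            initial: ColumnState | None = None) -> ColumnState:
    """Equilibrate one cell by repeating a single forcing year until the
    annual-mean WTD stops drifting (< ``spin_drift_tol_m`` per cycle) or
    ``spin_up_years`` cycles have run."""
    dates = pd.to_datetime(one_year_forcing["date"])
    if len(dates) < 365:
        raise GapError(f"spin-up forcing must cover >= 1 full year, got {len(dates)} days")
    batch = engine.ColumnBatch.from_columns([cell.column])
    if initial is None:
        state = engine.BatchState.initial(batch)
    else:
        state = engine.BatchState.from_states(batch, [initial])
    if config.spin_up_years == 0:
        return state.to_states(batch)[0]
    precip, pet = _forcing_arrays(
        [cell], {cell.cell_id: one_year_forcing},
        pd.DatetimeIndex(dates), config,
    )
    engine.spin_up_batch(batch, state, precip, pet, sub_steps=config.sub_steps,
                         max_years=config.spin_up_years,
                         drift_tol_m=config.spin_drift_tol_m)
    out = state.to_states(batch)[0]
    if not np.all(np.isfinite(out.theta)):
        raise SimulationError(f"non-finite state after spin-up of cell {cell.cell_id}")
    return out


def run_grid(cells: Sequence[GridCell], forcing: Mapping[str, pd.DataFrame],
             config: RunConfig | None = None) -> xr.Dataset:
    """Spin up and run every cell over the production period.

    Returns an xarray Dataset with dimensions ``(cell, time)`` holding
    daily water table depth (m below surface, positive down), near-surface
    moisture and the flux ledger terms.  ``wtd_signed`` carries the
    figure-facing convention (negative below the surface).
    """
    config = config or RunConfig()
    if len({c.cell_id for c in cells}) != len(cells):
        raise ValueError("cell_id values must be unique")
    cells = [c.classified() if not c.classification else c for c in cells]
    dates = config.production_dates
    n, T = len(cells), len(dates)
    vars_ = {k: np.empty((n, T)) for k in
             ("wtd", "theta_ns", "precip", "et", "lateral", "runoff", "delta_storage")}

    # batching needs equal layer counts; group, run, scatter back
    by_layers: dict[int, list[int]] = {}
    for i, cell in enumerate(cells):
        by_layers.setdefault(cell.column.n_layers, []).append(i)

    for idxs in by_layers.values():
        group = [cells[i] for i in idxs]
        batch = engine.ColumnBatch.from_columns([c.column for c in group])
        state = engine.BatchState.initial(batch)
        precip, pet = _forcing_arrays(group, forcing, dates, config)
        if config.spin_up_years > 0:
            engine.spin_up_batch(batch, state, precip[:, :365], pet[:, :365],
                                 sub_steps=config.sub_steps,
                                 max_years=config.spin_up_years,
                                 drift_tol_m=config.spin_drift_tol_m)
        # spin-up repeats the first production year, then the production
        # run continues from the equilibrated state
        out = engine.run_days(batch, state, precip, pet, sub_steps=config.sub_steps)
        if not np.all(np.isfinite(out["wtd"])):
            bad = [group[i].cell_id for i in
                   np.unique(np.nonzero(~np.isfinite(out["wtd"]))[0])]
            raise SimulationError(f"non-finite output for cells {bad}")
        for k in vars_:
            vars_[k][idxs, :] = out[k]

    ds = xr.Dataset(
        {k: (("cell", "time"), v) for k, v in vars_.items()},
        coords={
            "cell": [c.cell_id for c in cells],
            "time": dates,
            "lat": ("cell", [c.lat for c in cells]),
            "lon": ("cell", [c.lon for c in cells]),
            "landuse": ("cell", [c.column.landuse.value for c in cells]),
            "classification": ("cell", [c.classification for c in cells]),
        },
    )
    ds["wtd"].attrs["convention"] = "positive down (m below surface)"
    ds["wtd_signed"] = -ds["wtd"]
    ds["wtd_signed"].attrs["convention"] = "negative below surface (figure-facing)"
    return ds


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def read_forcing_csv(path) -> dict[str, pd.DataFrame]:
    """Long-format forcing CSV (cell_id, date, precip, tair, radiation,
    rh, wind) -> per-cell frames."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"cell_id", "date", *FORCING_FIELDS}
    if not required.issubset(df.columns):
        raise ValueError(f"forcing CSV must have columns {sorted(required)}")
    return {cid: g.drop(columns="cell_id").reset_index(drop=True)
            for cid, g in df.groupby("cell_id", sort=False)}


def read_grid_csv(profiles_path, config: RunConfig | None = None) -> list[GridCell]:
    """Soil-profile CSV, one row per (cell_id, layer_index) surface-down.

    Required columns: cell_id, layer_index, thickness_m, bulk_density,
    om_fraction, landuse, lat, lon.  Optional per-layer overrides:
    theta_r, theta_s, vg_alpha, vg_n, ksat.
    """
    config = config or RunConfig()
    df = pd.read_csv(profiles_path)
    cells = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("layer_index")
        layers = []
        for _, row in g.iterrows():
            is_peat = row["om_fraction"] > 0.65
            ksat = row["ksat"] if "ksat" in g.columns and pd.notna(row.get("ksat")) else \
                pedotransfer_ksat(row["bulk_density"], row["om_fraction"], is_peat)
            defaults = {"theta_r": 0.10 if is_peat else 0.05,
                        "theta_s": 0.85 if is_peat else 0.45,
                        "vg_alpha": 4.0 if is_peat else 3.6,
                        "vg_n": 1.45 if is_peat else 1.56}
            kw = {k: (row[k] if k in g.columns and pd.notna(row.get(k)) else v)
                  for k, v in defaults.items()}
            layers.append(SoilLayer(thickness=row["thickness_m"],
                                    bulk_density=row["bulk_density"],
                                    om_fraction=row["om_fraction"], ksat=ksat, **kw))
        landuse = LandUse(g["landuse"].iloc[0])
        column = SoilColumn(layers=tuple(layers), landuse=landuse)
        classification = classify_profile(column)
        column = column.with_boundary(assign_boundary_wtdx(landuse, classification, config))
        cells.append(GridCell(cell_id=str(cid), lat=float(g["lat"].iloc[0]),
                              lon=float(g["lon"].iloc[0]), column=column,
                              classification=classification))
    return cells


def fit_retention_csv(path) -> pd.DataFrame:
    """Fit van Genuchten parameters per (cell_id, layer_index) from a
    retention-sample CSV with columns cell_id, layer_index, psi_m, theta.

    Returns one row per layer with the fitted (theta_r, theta_s,
    vg_alpha, vg_n); layers whose samples are degenerate raise.
    """
    from .hydrology import fit_retention

    df = pd.read_csv(path)
    required = {"cell_id", "layer_index", "psi_m", "theta"}
    if not required.issubset(df.columns):
        raise ValueError(f"retention CSV must have columns {sorted(required)}")
    rows = []
    for (cid, idx), g in df.groupby(["cell_id", "layer_index"], sort=False):
        tr, ts, alpha, n = fit_retention(list(zip(g["psi_m"], g["theta"])))
        rows.append({"cell_id": cid, "layer_index": idx, "theta_r": tr,
                     "theta_s": ts, "vg_alpha": alpha, "vg_n": n})
    return pd.DataFrame(rows)


def write_outputs(ds: xr.Dataset, out_dir, stem: str = "hydrology") -> None:
    """NetCDF (scipy backend, NetCDF3) plus a long-format CSV mirror."""
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(out_dir / f"{stem}.nc", engine="scipy")
    df = (ds.drop_vars("wtd_signed").to_dataframe().reset_index()
          .rename(columns={"cell": "cell_id", "time": "date"}))
    df.to_csv(out_dir / f"{stem}.csv", index=False)
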