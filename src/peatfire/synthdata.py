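"""Seeded synthetic study setting: weather, soil grids, fire counts and
observation-like moisture series with known generating structure.

The generator emulates a Riau-like equatorial peatland province: roughly
2,500 mm of annual rainfall with a short dry season (mid-January to late
February) and a prolonged intense one (mid-June to late October), drought
years in which dry seasons deepen, a mixture of peat and mineral soil
columns under different land uses (and hence drainage boundary depths),
and fortnightly fire counts generated from the simulated hydrology
through a known water-table threshold, so that recovery of that threshold
and the skill gain from hydrology features are testable ground truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .hydrology import LandUse, SoilColumn, SoilLayer, classify_profile, pedotransfer_ksat
from .orchestration import GridCell, RunConfig, assign_boundary_wtdx

__all__ = ["SyntheticTruth", "gen_weather", "gen_grid", "gen_fire_counts",
           "gen_obs_moisture", "generate_forcing"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters; kept alongside generated data so recovery
    tests are self-validating.

    The fire generator draws fortnightly counts from
    ``Poisson(lambda_max * sigmoid((wtd - d_star)/sigmoid_width) * dryness)``
    where dryness scales linearly with near-surface drying.  ``d_star``
    anchors the fire-occurrence water-table threshold at 0.4 m; the small
    sigmoid width makes occurrence nearly threshold-like, matching the
    sharp switch seen between wet and drained fortnights.
    """

    seed: int = 0
    years: tuple[int, ...] = tuple(range(2008, 2016))
    drought_years: tuple[int, ...] = (2012, 2015)
    drought_multiplier: float = 0.6  # scales wet-day probability in drought years
    wet_prob_base: float = 0.65
    wet_prob_short_dry: float = 0.30  # mid-Jan to late Feb (doy 15-59)
    wet_prob_long_dry: float = 0.15  # mid-Jun to late Oct (doy 166-298)
    short_dry_window: tuple[int, int] = (15, 59)
    long_dry_window: tuple[int, int] = (166, 298)
    wet_day_mean_mm: float = 14.0
    wet_day_gamma_shape: float = 0.9
    # fire generator
    d_star: float = 0.40  # m, WTD fire-occurrence threshold
    sigmoid_width: float = 0.015  # m
    lambda_max: float = 6.0  # max expected counts per cell-fortnight
    dryness_theta_wet: float = 0.85  # near-surface moisture at which fires vanish
    dryness_theta_dry: float = 0.25  # moisture at which dryness saturates
    dryness_floor: float = 0.05
    # observation noise
    obs_noise_sigma: float = 0.05
    # grid composition
    peat_fraction: float = 0.6
    peat_landuse_mix: dict = field(default_factory=lambda: {
        "pristine_forest": 0.25, "degraded_forest": 0.15,
        "industrial_plantation": 0.35, "smallholder": 0.25,
    })

    def __post_init__(self) -> None:
        if self.d_star <= 0 or self.lambda_max <= 0:
            raise ValueError("d_star and lambda_max must be positive")
        if not 0 < self.drought_multiplier <= 1:
            raise ValueError("drought multiplier must be in (0, 1]")
        if not 0 <= self.peat_fraction <= 1:
            raise ValueError("peat_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _cell_rng(truth: SyntheticTruth, cell_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([truth.seed, stream, cell_index]))


def _wet_prob_profile(truth: SyntheticTruth, doy: np.ndarray) -> np.ndarray:
    p = np.full(doy.shape, truth.wet_prob_base)
    lo, hi = truth.short_dry_window
    p[(doy >= lo) & (doy <= hi)] = truth.wet_prob_short_dry
    lo, hi = truth.long_dry_window
    p[(doy >= lo) & (doy <= hi)] = truth.wet_prob_long_dry
    return p


def expected_annual_precip_mm(truth: SyntheticTruth) -> float:
    """Expected non-drought annual rainfall implied by the parameters."""
    doy = np.arange(1, 366)
    return float(_wet_prob_profile(truth, doy).sum() * truth.wet_day_mean_mm)


def gen_weather(truth: SyntheticTruth, cell_index: int = 0,
                years: Sequence[int] | None = None) -> pd.DataFrame:
    """Daily forcing for one cell over the study years (seeded, so the
    same (seed, cell) pair always yields the same series).

    Rain days follow a seasonal Bernoulli wet/dry process with
    gamma-distributed wet-day amounts; drought years scale the wet-day
    probability.  Temperature, radiation, humidity and wind co-vary with
    the rain process so that dry spells are warmer, sunnier and drier.
    """
    years = tuple(years) if years is not None else truth.years
    rng = _cell_rng(truth, cell_index, stream=1)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    p_wet = _wet_prob_profile(truth, doy)
    is_drought = np.isin(dates.year.to_numpy(), np.asarray(truth.drought_years))
    p_wet = np.where(is_drought, p_wet * truth.drought_multiplier, p_wet)
    wet = rng.random(len(dates)) < p_wet
    shape = truth.wet_day_gamma_shape
    amounts = rng.gamma(shape, truth.wet_day_mean_mm / shape, size=len(dates))
    precip = np.where(wet, amounts, 0.0)

    dryness = 1.0 - p_wet / truth.wet_prob_base  # 0 wet season .. ~0.8 deep dry
    tair = 26.5 + 1.8 * dryness + rng.normal(0.0, 0.6, len(dates))
    radiation = np.clip(15.0 + 6.0 * dryness - 4.0 * wet
                        + rng.normal(0.0, 1.5, len(dates)), 5.0, 28.0)
    rh = np.clip(88.0 - 18.0 * dryness + 5.0 * wet + rng.normal(0.0, 3.0, len(dates)),
                 40.0, 100.0)
    wind = np.clip(1.6 + 0.6 * dryness + rng.normal(0.0, 0.4, len(dates)), 0.1, 8.0)
    return pd.DataFrame({"date": dates, "precip": precip, "tair": tair,
                         "radiation": radiation, "rh": rh, "wind": wind})


def generate_forcing(truth: SyntheticTruth, cells: Sequence[GridCell]
                     ) -> dict[str, pd.DataFrame]:
    return {cell.cell_id: gen_weather(truth, i) for i, cell in enumerate(cells)}


# ---------------------------------------------------------------------------
# Soil archetypes
# ---------------------------------------------------------------------------

_PEAT_THICKNESS = (0.03, 0.03, 0.04, 0.05, 0.05, 0.05, 0.05,
                   0.10, 0.10, 0.10, 0.10, 0.15, 0.15, 0.25, 0.25)  # 1.50 m
_MINERAL_THICKNESS = (0.03, 0.03, 0.04, 0.05, 0.05, 0.10, 0.10, 0.15,
                      0.15, 0.20, 0.25, 0.30, 0.45, 0.55, 0.55)  # 3.00 m


def _peat_column(rng: np.random.Generator, landuse: LandUse) -> SoilColumn:
    layers = []
    n = len(_PEAT_THICKNESS)
    for i, thick in enumerate(_PEAT_THICKNESS):
        bd = (0.08 + 0.10 * i / (n - 1)) * rng.uniform(0.9, 1.1)
        theta_s = float(np.clip(0.95 - 0.6 * bd, 0.70, 0.93))
        layers.append(SoilLayer(
            thickness=thick, bulk_density=bd, om_fraction=0.90,
            theta_r=0.10, theta_s=theta_s, vg_alpha=4.0, vg_n=1.45,
            ksat=pedotransfer_ksat(bd, 0.90, is_peat=True),
        ))
    return SoilColumn(layers=tuple(layers), landuse=landuse)


def _mineral_column(rng: np.random.Generator, landuse: LandUse) -> SoilColumn:
    layers = []
    n = len(_MINERAL_THICKNESS)
    for i, thick in enumerate(_MINERAL_THICKNESS):
        bd = (1.15 + 0.35 * i / (n - 1)) * rng.uniform(0.95, 1.05)
        layers.append(SoilLayer(
            thickness=thick, bulk_density=bd, om_fraction=0.05,
            theta_r=0.05, theta_s=0.45, vg_alpha=3.6, vg_n=1.56,
            ksat=pedotransfer_ksat(bd, 0.05, is_peat=False),
        ))
    return SoilColumn(layers=tuple(layers), landuse=landuse)


def gen_grid(truth: SyntheticTruth, n_cells: int,
             config: RunConfig | None = None) -> list[GridCell]:
    """Grid cells on a 0.05-degree lattice with the configured peat /
    mineral mixture and land-use composition; every peat archetype
    classifies as a peatland grid and gets its land-use boundary water
    table, mineral cells drain to the deep non-peat boundary."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    config = config or RunConfig()
    mix = truth.peat_landuse_mix
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"peat land-use mixture must sum to 1, got {sum(mix.values())}")
    n_peat = round(truth.peat_fraction * n_cells)
    landuses: list[LandUse] = []
    acc = 0
    for j, (lu, frac) in enumerate(sorted(mix.items())):
        k = round(frac * n_peat) if j < len(mix) - 1 else n_peat - acc
        landuses += [LandUse(lu)] * k
        acc += k
    landuses += [LandUse.NON_PEAT_OTHER] * (n_cells - n_peat)

    cells = []
    side = int(np.ceil(np.sqrt(n_cells)))
    for i, lu in enumerate(landuses):
        rng = _cell_rng(truth, i, stream=2)
        column = _peat_column(rng, lu) if lu is not LandUse.NON_PEAT_OTHER \
            else _mineral_column(rng, lu)
        classification = classify_profile(column)
        column = column.with_boundary(assign_boundary_wtdx(lu, classification, config))
        cells.append(GridCell(
            cell_id=f"cell{i:03d}",
            lat=0.50 + 0.05 * (i // side), lon=101.50 + 0.05 * (i % side),
            column=column, classification=classification,
        ))
    return cells


# ---------------------------------------------------------------------------
# Fire counts and observation-like moisture
# ---------------------------------------------------------------------------

def fire_rate(truth: SyntheticTruth, wtd: np.ndarray, theta_ns: np.ndarray) -> np.ndarray:
    """Expected counts per cell-fortnight given mean WTD and moisture."""
    wtd = np.asarray(wtd, dtype=float)
    theta_ns = np.asarray(theta_ns, dtype=float)
    gate = 1.0 / (1.0 + np.exp(-(wtd - truth.d_star) / truth.sigmoid_width))
    dryness = np.clip(
        (truth.dryness_theta_wet - theta_ns)
        / (truth.dryness_theta_wet - truth.dryness_theta_dry),
        truth.dryness_floor, 1.0,
    )
    return truth.lambda_max * gate * dryness


def gen_fire_counts(truth: SyntheticTruth, records: pd.DataFrame,
                    seed: int | None = None) -> pd.Series:
    """Poisson fortnightly fire counts for records carrying ``mean_wtd``
    and ``mean_theta_ns`` columns (aligned with the records' index)."""
    lam = fire_rate(truth, records["mean_wtd"].to_numpy(),
                    records["mean_theta_ns"].to_numpy())
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 3]))
    return pd.Series(rng.poisson(lam), index=records.index, name="fire_count")


def gen_obs_moisture(theta: np.ndarray | pd.Series, sigma: float,
                     seed: int = 0) -> np.ndarray | pd.Series:
    """Observation-like moisture: truth plus iid gaussian noise, clamped
    to [0, 1].  ``sigma=0`` returns the input unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = np.asarray(theta, dtype=float)
    if sigma == 0:
        noisy = arr.copy()
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        noisy = np.clip(arr + rng.normal(0.0, sigma, arr.shape), 0.0, 1.0)
    if isinstance(theta, pd.Series):
        return pd.Series(noisy, index=theta.index, name=theta.name)
    return noisy
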