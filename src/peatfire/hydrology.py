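"""Single-column peat / mineral soil water balance.

A grid cell is represented by a stand-alone layered soil column topped by a
thin litter layer.  The column exchanges water vertically (precipitation,
evapotranspiration, tipping-bucket drainage between layers) and laterally
(Darcy exchange with a fixed boundary water table, WTDx, mimicking an
adjacent watershed or drainage canal).  The diagnosed water table depth
(WTD) is the depth below which every layer is saturated, and the
near-surface moisture is a thickness-weighted mean over the litter layer
and the top two soil layers (0-5 cm).

Moisture retention follows the van Genuchten closed form with the Mualem
conductivity closure; saturated conductivity comes from bulk-density based
pedo-transfer functions.  Depths and water-table depths are positive
downward (m below the surface); all fluxes are water depths in m per day.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LandUse",
    "SoilLayer",
    "SoilColumn",
    "ColumnState",
    "FluxLedger",
    "DailyForcing",
    "HydrologyError",
    "InvalidProfileError",
    "RetentionFitError",
    "PEAT_OM_THRESHOLD",
    "PEAT_DEPTH_REQUIREMENT",
    "FIELD_CAPACITY_HEAD",
    "WILTING_HEAD",
    "classify_profile",
    "theta_of_psi",
    "psi_of_theta",
    "k_unsat",
    "fit_retention",
    "pedotransfer_ksat",
    "potential_et",
    "step_day",
    "diagnose_wtd",
    "near_surface_moisture",
]

# Organic-matter fraction above which a layer counts as peat, and the
# minimum depth to which peat must extend for the whole cell to count as a
# peatland grid.
PEAT_OM_THRESHOLD = 0.65
PEAT_DEPTH_REQUIREMENT = 0.30  # m

# Field capacity at 3.3 kPa and wilting point at 1.5 MPa, expressed as
# suction heads in metres of water.
FIELD_CAPACITY_HEAD = 0.34  # m
WILTING_HEAD = 153.0  # m

# A layer counts as saturated for WTD diagnosis when theta >= SAT_TOL*theta_s.
SAT_TOL = 0.999

# Litter-layer constants: a thin, highly porous organic mat.
LITTER_THETA_S = 0.90
LITTER_THETA_R = 0.05
LITTER_FC = 0.30

# Default pedo-transfer coefficients: log10(ksat [m/d]) linear in bulk
# density, separate fits for peat and mineral soils, clamped to a
# physically plausible range.
PTF_PEAT = (2.2, 14.0)  # a, b in 10**(a - b*BD)
PTF_MINERAL = (1.2, 1.0)
KSAT_FLOOR = 0.001  # m/d
KSAT_CEILING = 50.0  # m/d


class HydrologyError(ValueError):
    """Base class for column configuration / simulation errors."""


class InvalidProfileError(HydrologyError):
    pass


class RetentionFitError(HydrologyError):
    pass


class LandUse(str, enum.Enum):
    PRISTINE_FOREST = "pristine_forest"
    DEGRADED_FOREST = "degraded_forest"
    INDUSTRIAL_PLANTATION = "industrial_plantation"
    SMALLHOLDER = "smallholder"
    MANGROVE = "mangrove"
    NON_PEAT_OTHER = "non_peat_other"


@dataclass(frozen=True)
class SoilLayer:
    """One horizontal slab of the column.

    Parameters
    ----------
    thickness : m
    bulk_density : Mg m-3 (dry)
    om_fraction : organic-matter mass fraction, 0-1
    theta_r, theta_s : residual / saturated volumetric moisture, m3 m-3
    vg_alpha : van Genuchten alpha, m-1
    vg_n : van Genuchten n, dimensionless (> 1)
    ksat : saturated hydraulic conductivity, m d-1 (lateral assumed equal)
    """

    thickness: float
    bulk_density: float
    om_fraction: float
    theta_r: float
    theta_s: float
    vg_alpha: float
    vg_n: float
    ksat: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidProfileError(f"layer thickness must be > 0, got {self.thickness}")
        if not 0 <= self.theta_r < self.theta_s <= 1:
            raise InvalidProfileError(
                f"need 0 <= theta_r < theta_s <= 1, got theta_r={self.theta_r}, theta_s={self.theta_s}"
            )
        if self.vg_n <= 1:
            raise InvalidProfileError(f"van Genuchten n must exceed 1, got {self.vg_n}")
        if self.ksat <= 0:
            raise InvalidProfileError(f"ksat must be > 0, got {self.ksat}")
        if not 0 <= self.om_fraction <= 1:
            raise InvalidProfileError(f"om_fraction must be in [0,1], got {self.om_fraction}")

    @property
    def is_peat(self) -> bool:
        return self.om_fraction > PEAT_OM_THRESHOLD


@dataclass(frozen=True)
class SoilColumn:
    """A stand-alone layered profile plus its lateral boundary condition.

    ``wtdx`` is the boundary water table depth (m below the surface,
    positive down) of the adjacent watershed/canal; ``lateral_length`` is
    the effective horizontal flow distance to that boundary.
    """

    layers: tuple[SoilLayer, ...]
    landuse: LandUse = LandUse.NON_PEAT_OTHER
    wtdx: float = 0.0
    lateral_length: float = 100.0
    litter_thickness: float = 0.02

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise InvalidProfileError("column has no soil layers")
        if self.wtdx < 0:
            raise InvalidProfileError(f"wtdx must be >= 0 (m below surface), got {self.wtdx}")
        if self.lateral_length <= 0:
            raise InvalidProfileError("lateral_length must be > 0")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_depth(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def with_boundary(self, wtdx: float) -> "SoilColumn":
        return replace(self, wtdx=wtdx)


@dataclass
class ColumnState:
    """Per-day prognostic state: layer moistures, litter moisture, ponded
    surface water and the diagnosed water table depth."""

    theta: np.ndarray  # (n_layers,), m3 m-3
    litter_theta: float = LITTER_FC
    ponded: float = 0.0
    wtd: float = 0.0

    def copy(self) -> "ColumnState":
        return ColumnState(self.theta.copy(), self.litter_theta, self.ponded, self.wtd)


@dataclass(frozen=True)
class FluxLedger:
    """Daily water budget of one column, all terms m of water per day.

    ``lateral_flux`` is signed positive for discharge out of the column
    (boundary water table deeper than the column's).  Conservation requires
    precip - et_actual - lateral_flux - runoff - delta_storage = 0.
    """

    precip: float
    et_actual: float
    lateral_flux: float
    runoff: float
    delta_storage: float

    @property
    def residual(self) -> float:
        return self.precip - self.et_actual - self.lateral_flux - self.runoff - self.delta_storage


@dataclass(frozen=True)
class DailyForcing:
    """One day of weather at one cell."""

    date: object  # datetime.date / pandas.Timestamp
    precip: float  # mm d-1
    tair: float  # degC
    radiation: float  # MJ m-2 d-1
    rh: float  # %
    wind: float  # m s-1


# ---------------------------------------------------------------------------
# Profile classification
# ---------------------------------------------------------------------------

def classify_profile(column: SoilColumn) -> str:
    """Classify a column as ``"peatland_grid"`` or ``"non_peatland_grid"``.

    A layer is peat when its organic-matter fraction exceeds 0.65.  The cell
    is a peatland grid when every layer whose top lies above 0.3 m depth is
    peat and those layers together reach at least 0.3 m.
    """
    if not column.layers:
        raise InvalidProfileError("cannot classify an empty profile")
    depth = 0.0
    peat_to = 0.0
    for layer in column.layers:
        if depth < PEAT_DEPTH_REQUIREMENT:
            if not layer.is_peat:
                return "non_peatland_grid"
            peat_to = depth + layer.thickness
        depth += layer.thickness
    if peat_to >= PEAT_DEPTH_REQUIREMENT:
        return "peatland_grid"
    return "non_peatland_grid"


# ---------------------------------------------------------------------------
# Retention and conductivity (van Genuchten / Mualem)
# ---------------------------------------------------------------------------

def _vg_theta(psi, theta_r, theta_s, alpha, n):
    psi = np.asarray(psi, dtype=float)
    m = 1.0 - 1.0 / n
    se = (1.0 + (alpha * psi) ** n) ** (-m)
    return theta_r + (theta_s - theta_r) * se


def theta_of_psi(layer: SoilLayer, psi: float) -> float:
    """Volumetric moisture at suction head ``psi`` (m of water, >= 0)."""
    if np.any(np.asarray(psi) < 0):
        raise HydrologyError(f"suction head must be >= 0, got {psi}")
    out = _vg_theta(psi, layer.theta_r, layer.theta_s, layer.vg_alpha, layer.vg_n)
    return float(out) if np.isscalar(psi) or np.ndim(psi) == 0 else out


def psi_of_theta(layer: SoilLayer, theta: float) -> float:
    """Inverse retention curve: suction head (m) at moisture ``theta``."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= layer.theta_r) or np.any(theta > layer.theta_s):
        raise HydrologyError(
            f"theta must lie in (theta_r, theta_s] = ({layer.theta_r}, {layer.theta_s}]"
        )
    m = 1.0 - 1.0 / layer.vg_n
    se = (theta - layer.theta_r) / (layer.theta_s - layer.theta_r)
    psi = (se ** (-1.0 / m) - 1.0) ** (1.0 / layer.vg_n) / layer.vg_alpha
    return float(psi) if psi.ndim == 0 else psi


def k_unsat(layer: SoilLayer, theta: float) -> float:
    """Mualem unsaturated conductivity (m d-1) at moisture ``theta``."""
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr < layer.theta_r - 1e-12) or np.any(theta_arr > layer.theta_s + 1e-12):
        raise HydrologyError(
            f"theta={theta} outside [{layer.theta_r}, {layer.theta_s}]"
        )
    m = 1.0 - 1.0 / layer.vg_n
    se = np.clip((theta_arr - layer.theta_r) / (layer.theta_s - layer.theta_r), 0.0, 1.0)
    k = layer.ksat * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    return float(k) if k.ndim == 0 else k


def fit_retention(samples: Sequence[tuple[float, float]]) -> tuple[float, float, float, float]:
    """Least-squares fit of (theta_r, theta_s, alpha, n) to (psi, theta) pairs.

    Needs at least four distinct suction heads spanning wet and dry
    conditions; raises :class:`RetentionFitError` for under-determined or
    degenerate sample sets.
    """
    pts = np.asarray(list(samples), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise RetentionFitError("samples must be (psi, theta) pairs")
    psi, theta = pts[:, 0], pts[:, 1]
    if len(np.unique(psi)) < 4:
        raise RetentionFitError(
            f"need >= 4 distinct suction heads, got {len(np.unique(psi))}"
        )
    if np.ptp(theta) < 1e-9:
        raise RetentionFitError("degenerate samples: all theta values equal")
    if np.any(psi < 0):
        raise RetentionFitError("suction heads must be >= 0")

    t_min, t_max = float(theta.min()), float(theta.max())
    psi_pos = psi[psi > 0]
    psi_scale = float(np.median(psi_pos)) if len(psi_pos) else 1.0
    p0 = [max(t_min - 0.02, 1e-4), min(t_max + 0.02, 0.999),
          1.0 / max(psi_scale, 1e-3), 1.5]
    bounds = ([0.0, t_max, 1e-3, 1.01], [max(t_min, 1e-3), 1.0, 100.0, 10.0])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = curve_fit(
            lambda p, tr, ts, a, n: _vg_theta(p, tr, ts, a, n),
            psi, theta, p0=p0, bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RetentionFitError(f"retention fit failed to converge: {exc}") from exc
    theta_r, theta_s, alpha, n = (float(v) for v in popt)
    if not theta_r < theta_s:
        raise RetentionFitError("fit produced theta_r >= theta_s")
    return theta_r, theta_s, alpha, n


def pedotransfer_ksat(bulk_density: float, om_fraction: float, is_peat: bool,
                      coeffs: tuple[float, float] | None = None) -> float:
    """Saturated conductivity (m d-1) from bulk density via a log-linear
    pedo-transfer function, clamped to [``KSAT_FLOOR``, ``KSAT_CEILING``].

    Separate default coefficient pairs are used for peat and mineral soils;
    within each soil kind ksat decreases with bulk density.
    """
    if bulk_density <= 0:
        raise HydrologyError(f"bulk density must be > 0, got {bulk_density}")
    a, b = coeffs if coeffs is not None else (PTF_PEAT if is_peat else PTF_MINERAL)
    k = 10.0 ** (a - b * bulk_density)
    return float(np.clip(k, KSAT_FLOOR, KSAT_CEILING))


# ---------------------------------------------------------------------------
# Potential evapotranspiration
# ---------------------------------------------------------------------------

def _pet_mm(tair, radiation, rh, wind):
    """FAO-56 style daily reference ET (mm d-1), vectorised.

    Net radiation is approximated as 0.77 * shortwave minus a constant
    2 MJ m-2 d-1 outgoing longwave term (floored at zero); soil heat flux
    is neglected at the daily step.
    """
    tair = np.asarray(tair, dtype=float)
    radiation = np.asarray(radiation, dtype=float)
    rh = np.asarray(rh, dtype=float)
    wind = np.asarray(wind, dtype=float)
    es = 0.6108 * np.exp(17.27 * tair / (tair + 237.3))  # kPa
    ea = es * rh / 100.0
    delta = 4098.0 * es / (tair + 237.3) ** 2  # kPa / degC
    gamma = 0.000665 * 101.3  # kPa / degC at sea level
    rn = np.maximum(0.77 * radiation - 2.0, 0.0)  # MJ m-2 d-1
    num = 0.408 * delta * rn + gamma * (900.0 / (tair + 273.0)) * wind * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * wind)
    return np.maximum(num / den, 0.0)


def potential_et(forcing: DailyForcing, pft_coefficient: float) -> float:
    """Potential ET (m d-1) = reference ET scaled by a land-cover coefficient."""
    if not 0 < pft_coefficient <= 2:
        raise HydrologyError(f"pft_coefficient must be in (0, 2], got {pft_coefficient}")
    if not 0 <= forcing.rh <= 100:
        raise HydrologyError(f"relative humidity must be in [0, 100] %, got {forcing.rh}")
    for name in ("precip", "tair", "radiation", "wind"):
        if not math.isfinite(getattr(forcing, name)):
            raise HydrologyError(f"non-finite forcing field {name}")
    return float(_pet_mm(forcing.tair, forcing.radiation, forcing.rh, forcing.wind)) / 1000.0 * pft_coefficient


# ---------------------------------------------------------------------------
# Daily step / diagnostics (delegating to the vectorised engine)
# ---------------------------------------------------------------------------

def step_day(column: SoilColumn, state: ColumnState, forcing: DailyForcing,
             pft_coefficient: float = 1.0, sub_steps: int = 24) -> tuple[ColumnState, FluxLedger]:
    """Advance one column by one day.

    Water enters as precipitation, leaves through moisture-limited ET,
    lateral Darcy exchange with the boundary water table and surface
    runoff; the returned ledger closes to machine precision.
    """
    from . import engine  # local import to avoid a cycle

    if forcing.precip < 0:
        raise HydrologyError(f"negative precipitation {forcing.precip} mm/d")
    batch = engine.ColumnBatch.from_columns([column])
    eng_state = engine.BatchState.from_states(batch, [state])
    pet_m = potential_et(forcing, pft_coefficient)
    ledger = engine.step_batch_day(
        batch, eng_state, precip_m=np.array([forcing.precip / 1000.0]),
        pet_m=np.array([pet_m]), sub_steps=sub_steps,
    )
    new_state = eng_state.to_states(batch)[0]
    return new_state, FluxLedger(
        precip=float(ledger["precip"][0]),
        et_actual=float(ledger["et"][0]),
        lateral_flux=float(ledger["lateral"][0]),
        runoff=float(ledger["runoff"][0]),
        delta_storage=float(ledger["delta_storage"][0]),
    )


def diagnose_wtd(column: SoilColumn, state: ColumnState) -> float:
    """Water table depth (m below surface): the top of the contiguous
    saturated zone extending to the column base.

    Within the deepest unsaturated layer the depth is interpolated
    linearly between field capacity (no saturation) and full saturation,
    so WTD varies continuously as the saturated zone grows.  A column with
    no saturated base returns the total depth; a fully saturated or ponded
    column returns 0.
    """
    from . import engine

    batch = engine.ColumnBatch.from_columns([column])
    wtd = engine.diagnose_wtd_batch(
        batch, state.theta[np.newaxis, :], np.array([state.ponded])
    )
    return float(wtd[0])


def near_surface_moisture(column: SoilColumn, state: ColumnState) -> float:
    """Thickness-weighted mean moisture of litter + top two soil layers
    (the model's 0-5 cm near-surface band)."""
    if column.n_layers < 2:
        raise HydrologyError("near-surface moisture needs at least two soil layers")
    t0 = column.litter_thickness
    t1 = column.layers[0].thickness
    t2 = column.layers[1].thickness
    num = t0 * state.litter_theta + t1 * state.theta[0] + t2 * state.theta[1]
    return float(num / (t0 + t1 + t2))
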