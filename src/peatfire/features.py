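"""Fortnightly aggregation of daily forcing and hydrology into the two
ANN design matrices.

Two-week steps are consecutive non-overlapping 14-day blocks counted from
1 January of each year; the short remainder at year end is dropped.  The
weather-only model (WTHR) sees five fortnight weather aggregates plus the
antecedent four-week precipitation total; the weather+hydrology model
(WTHR_HYDROL) adds fortnight-mean water table depth and near-surface
moisture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .orchestration import GapError

__all__ = [
    "FEATURES_WTHR",
    "FEATURES_WTHR_HYDROL",
    "STEPS_PER_YEAR",
    "fortnight_index",
    "aggregate_fortnights",
    "antecedent_precip",
    "build_design_matrix",
]

STEPS_PER_YEAR = 26
FEATURES_WTHR = [
    "mean_tair",
    "mean_radiation",
    "mean_wind",
    "mean_rh",
    "sum_precip_2wk",
    "sum_precip_prior_4wk",
]
FEATURES_WTHR_HYDROL = FEATURES_WTHR + ["mean_wtd", "mean_theta_ns"]
ANTECEDENT_DAYS = 28

_MEAN_FIELDS = {"tair": "mean_tair", "radiation": "mean_radiation",
                "wind": "mean_wind", "rh": "mean_rh",
                "wtd": "mean_wtd", "theta_ns": "mean_theta_ns"}


class ModeError(ValueError):
    pass


def fortnight_index(dates: pd.Series | pd.DatetimeIndex) -> pd.DataFrame:
    """Map dates to (year, step) fortnight labels; days past step 25 of a
    year (the 1-2 day remainder) get step -1 and are excluded."""
    dates = pd.DatetimeIndex(dates)
    step = (dates.dayofyear - 1) // 14
    step = np.where(step >= STEPS_PER_YEAR, -1, step)
    return pd.DataFrame({"year": dates.year, "step": step}, index=dates)


def aggregate_fortnights(daily: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a daily table to one row per (cell_id, year, step).

    ``daily`` needs columns cell_id, date, precip, tair, radiation, wind,
    rh and optionally wtd, theta_ns.  Means are taken over the 14 days of
    each block (precipitation is summed); a block with missing days raises
    :class:`GapError` naming the dates.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    fi = fortnight_index(df["date"])
    df["year"] = fi["year"].to_numpy()
    df["step"] = fi["step"].to_numpy()
    df = df[df["step"] >= 0]

    counts = df.groupby(["cell_id", "year", "step"])["date"].count()
    short = counts[counts != 14]
    if len(short):
        detail = []
        for (cid, year, step), have in short.head(5).items():
            block = df[(df.cell_id == cid) & (df.year == year) & (df.step == step)]
            expect = pd.date_range(f"{year}-01-01", periods=366, freq="D")[
                step * 14:(step + 1) * 14]
            missing = expect.difference(pd.DatetimeIndex(block["date"]))
            detail.append(f"{cid} {year} step {step}: missing "
                          + ", ".join(str(d.date()) for d in missing[:4]))
        raise GapError("incomplete fortnight blocks: " + "; ".join(detail))

    agg_spec = {"precip": ("precip", "sum")}
    for col, name in _MEAN_FIELDS.items():
        if col in df.columns:
            agg_spec[name] = (col, "mean")
    out = df.groupby(["cell_id", "year", "step"]).agg(**agg_spec).reset_index()
    out = out.rename(columns={"precip": "sum_precip_2wk"})

    ante = antecedent_precip(daily)
    out = out.merge(ante, on=["cell_id", "year", "step"], how="left")
    return out


def antecedent_precip(daily: pd.DataFrame) -> pd.DataFrame:
    """Precipitation summed over the 28 calendar days strictly before each
    fortnight block start, per cell.  Blocks with less than 28 days of
    history in the daily series are dropped (left NaN and removed by
    :func:`build_design_matrix` via the merge in aggregate_fortnights)."""
    df = daily[["cell_id", "date", "precip"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    rows = []
    for cid, g in df.groupby("cell_id", sort=False):
        s = g.set_index("date")["precip"].sort_index()
        rolled = s.rolling(window=ANTECEDENT_DAYS, min_periods=ANTECEDENT_DAYS).sum()
        fi = fortnight_index(s.index)
        starts = (
            pd.DataFrame({"year": fi["year"], "step": fi["step"]}, index=s.index)
            .query("step >= 0").reset_index().groupby(["year", "step"])["date"].min()
        )
        for (year, step), d0 in starts.items():
            prev = d0 - pd.Timedelta(days=1)
            if prev not in rolled.index or np.isnan(rolled.loc[prev]):
                continue  # insufficient history before this block
            rows.append((cid, year, step, float(rolled.loc[prev])))
    return pd.DataFrame(rows, columns=["cell_id", "year", "step", "sum_precip_prior_4wk"])


def build_design_matrix(records: pd.DataFrame, mode: str = "wthr_hydrol"
                        ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix (X), fire counts (y) and per-row year labels.

    ``mode`` is ``"wthr"`` (6 columns) or ``"wthr_hydrol"`` (8 columns;
    the first six are identical to WTHR).  Rows lacking antecedent
    precipitation history are dropped.  Standardisation happens per
    training fold inside the fire model, not here.
    """
    mode = mode.lower()
    if mode == "wthr":
        cols = FEATURES_WTHR
    elif mode == "wthr_hydrol":
        cols = FEATURES_WTHR_HYDROL
    else:
        raise ModeError(f"mode must be 'wthr' or 'wthr_hydrol', got {mode!r}")
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ModeError(f"records lack columns {missing} required for mode {mode!r}")
    recs = records.dropna(subset=["sum_precip_prior_4wk"])
    X = recs[cols].reset_index(drop=True)
    if "fire_count" in recs.columns:
        y = recs["fire_count"].to_numpy(dtype=float)
    else:
        y = np.full(len(recs), np.nan)
    years = recs["year"].to_numpy()
    return X, y, years
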