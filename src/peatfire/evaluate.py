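"""Skill metrics for fortnightly fire-count predictions and for daily
modelled-vs-observed near-surface moisture.

Counts are pooled per fortnight separately over peatland and non-peatland
grids before computing the coefficient of determination and mean absolute
error; temporal skill is assessed on first differences (n_{t+1} - n_t) of
the pooled series.  The water-table fire threshold is estimated by
maximising Youden's J over candidate depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "ThresholdResult",
    "EvaluationReport",
    "pool_counts",
    "r2",
    "mae",
    "time_difference",
    "estimate_wtd_threshold",
    "daily_correlation",
    "evaluate_predictions",
]

MIN_PAIRED_DAYS = 30
UNINFORMATIVE_J = 0.1


class AlignmentError(ValueError):
    pass


def pool_counts(predictions: pd.Series, observations: pd.Series,
                classification: dict[str, str]) -> dict[str, pd.DataFrame]:
    """Sum predicted and observed counts per fortnight over peatland and
    non-peatland subsets.

    Both inputs must share a (cell_id, year, step) MultiIndex.  Returns
    ``{"peatland_grid": df, "non_peatland_grid": df}`` where each frame is
    indexed by (year, step) with columns ``pred`` and ``obs``; subset sums
    add up to the whole-grid totals.
    """
    if not predictions.index.equals(observations.index):
        raise AlignmentError("predictions and observations must share a "
                             "(cell_id, year, step) index")
    df = pd.DataFrame({"pred": predictions, "obs": observations}).reset_index()
    df["subset"] = df["cell_id"].map(classification)
    if df["subset"].isna().any():
        missing = sorted(df.loc[df["subset"].isna(), "cell_id"].unique())
        raise AlignmentError(f"cells without classification: {missing[:5]}")
    out = {}
    for subset in ("peatland_grid", "non_peatland_grid"):
        sub = df[df["subset"] == subset]
        if sub.empty:
            warnings.warn(f"no cells in subset {subset!r}; empty pooled series")
            out[subset] = pd.DataFrame(columns=["pred", "obs"])
            continue
        out[subset] = sub.groupby(["year", "step"])[["pred", "obs"]].sum().sort_index()
    return out


def r2(pred, obs) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (may be negative)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observations have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(pred, obs) -> float:
    """Mean absolute error (counts per two-week step)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 1:
        raise ValueError("need equal-length non-empty series")
    return float(np.mean(np.abs(pred - obs)))


def time_difference(series) -> np.ndarray:
    """First differences n_{t+1} - n_t of a fortnightly series."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 points to difference")
    return np.diff(arr)


@dataclass(frozen=True)
class ThresholdResult:
    depth: float  # m below surface
    youden_j: float
    informative: bool

    def __float__(self) -> float:
        return self.depth


def estimate_wtd_threshold(wtd, events, candidates: np.ndarray | None = None
                           ) -> ThresholdResult:
    """Water-table depth best separating fire from no-fire fortnights.

    A fortnight is predicted 'fire' when its mean WTD is at or deeper than
    the candidate depth; the returned depth maximises Youden's J
    (sensitivity + specificity - 1) over a 0.00-1.00 m grid in 0.01 m
    steps, ties broken toward the shallower depth.  A maximum J below
    0.1 flags the estimate as uninformative (labels unrelated to WTD).
    """
    wtd = np.asarray(wtd, dtype=float)
    events = np.asarray(events, dtype=bool)
    if wtd.shape != events.shape:
        raise ValueError("wtd and event indicator must have equal length")
    n_pos = int(events.sum())
    if n_pos == 0 or n_pos == events.size:
        raise ValueError("both fire and no-fire fortnights are required")
    if candidates is None:
        candidates = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    pos = wtd[events]
    neg = wtd[~events]
    tpr = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= candidates[:, None]).mean(axis=1)
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (shallowest) tie
    return ThresholdResult(depth=float(candidates[best]), youden_j=float(j[best]),
                           informative=bool(j[best] >= UNINFORMATIVE_J))


def daily_correlation(modelled: pd.DataFrame, observed: pd.DataFrame,
                      classification: dict[str, str] | None = None
                      ) -> tuple[pd.Series, dict[str, float]]:
    """Per-cell Pearson correlation between daily modelled and observed
    near-surface moisture, with subset medians.

    ``modelled`` and ``observed`` are date-indexed frames with one column
    per cell.  Cells with under 30 paired days raise; constant series are
    excluded with a warning.  Medians are reported for 'all' and, when a
    classification mapping is given, per peatland / non-peatland subset.
    """
    common_cells = [c for c in modelled.columns if c in observed.columns]
    rs = {}
    for cell in common_cells:
        pair = pd.concat([modelled[cell], observed[cell]], axis=1, join="inner").dropna()
        if len(pair) < MIN_PAIRED_DAYS:
            raise ValueError(f"cell {cell}: only {len(pair)} paired days (< {MIN_PAIRED_DAYS})")
        a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            warnings.warn(f"cell {cell}: constant series, correlation undefined; excluded")
            continue
        rs[cell] = float(np.corrcoef(a, b)[0, 1])
    per_cell = pd.Series(rs, name="pearson_r")
    medians = {"all": float(per_cell.median())}
    if classification is not None:
        for subset in ("peatland_grid", "non_peatland_grid"):
            vals = per_cell[[c for c in per_cell.index
                             if classification.get(c) == subset]]
            medians[subset] = float(vals.median()) if len(vals) else float("nan")
    return per_cell, medians


@dataclass
class EvaluationReport:
    pooled_r2: dict[str, float] = field(default_factory=dict)
    pooled_mae: dict[str, float] = field(default_factory=dict)
    timediff_r2: dict[str, float] = field(default_factory=dict)
    per_year_r2: dict[str, dict[int, float]] = field(default_factory=dict)
    threshold: ThresholdResult | None = None

    def to_dict(self) -> dict:
        d = {"pooled_r2": self.pooled_r2, "pooled_mae": self.pooled_mae,
             "timediff_r2": self.timediff_r2, "per_year_r2": self.per_year_r2}
        if self.threshold is not None:
            d["wtd_threshold_m"] = self.threshold.depth
            d["wtd_threshold_j"] = self.threshold.youden_j
        return d


def evaluate_predictions(predictions: pd.Series, observations: pd.Series,
                         classification: dict[str, str]) -> EvaluationReport:
    """Pool counts by subset and compute R^2 / MAE on the pooled series
    plus time-differenced R^2, per subset and per validation year."""
    pooled = pool_counts(predictions, observations, classification)
    report = EvaluationReport()
    for subset, df in pooled.items():
        if len(df) < 3:
            continue
        report.pooled_r2[subset] = r2(df["pred"], df["obs"])
        report.pooled_mae[subset] = mae(df["pred"], df["obs"])
        report.timediff_r2[subset] = r2(time_difference(df["pred"].to_numpy()),
                                        time_difference(df["obs"].to_numpy()))
        years = {}
        for year, g in df.groupby(level="year"):
            if len(g) >= 3 and g["obs"].std() > 0:
                years[int(year)] = r2(g["pred"], g["obs"])
        report.per_year_r2[subset] = years
    return report
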