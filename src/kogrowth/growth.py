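"""Exponential growth-rate estimation from OD600 plate-reader curves.

The rate between two consecutive readings is ``mu_i = ln(C_{i+1}/C_i) /
(t_{i+1} - t_i)`` on blank-corrected ODs.  The reported exponential rate of
a curve is the mean of the best window of five consecutive interval rates:
the window with the largest mean and, among windows within 5% of that mean,
the smallest standard deviation — the rule a plate-reader screen uses to
land on the exponential phase without fitting a full growth model.

Replicates aggregate to a per-strain rate table, and two diagnostics probe
plate artefacts: the well-location trend of the growth maximum (carrying
capacity drifts with well position; the rate does not) and the rate-versus-
maximum correlation across strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, UndefinedStatisticError

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "IntervalRates",
    "interval_rates",
    "estimate_growth_rate",
    "aggregate_replicates",
    "well_bias_diagnostic",
    "rate_vs_max_correlation",
    "serpentine_index",
]

DEFAULT_FLOOR = 0.003  # OD above blank below which log-rates are meaningless


@dataclass
class GrowthCurve:
    """One well's OD600 time series."""

    strain: str
    medium: str
    replicate: int
    plate: str
    well: str
    times: np.ndarray   # hours, strictly increasing
    od: np.ndarray      # raw OD600, same length
    blank: float = 0.0  # per-plate blank offset

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise EstimationError("times and od differ in length")
        if self.times.size < 7:
            raise EstimationError(
                f"curve {self.strain}/{self.well}: need >= 7 time points "
                "(6 intervals) for a 5-rate window"
            )
        if not np.all(np.diff(self.times) > 0):
            raise EstimationError(f"curve {self.strain}/{self.well}: times not strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise EstimationError(f"curve {self.strain}/{self.well}: non-finite OD")

    @property
    def corrected(self) -> np.ndarray:
        return self.od - self.blank


@dataclass
class GrowthRateEstimate:
    strain: str
    medium: str
    replicate: int
    mu: float                   # h^-1; NaN when no growth
    window_start_index: int     # first interval of the selected 5-rate window; -1 if none
    window_sd: float
    max_od: float               # max blank-corrected OD of the curve
    no_growth: bool = False
    plate: str = ""
    well: str = ""


class IntervalRates(NamedTuple):
    t_mid: np.ndarray
    mu: np.ndarray
    valid: np.ndarray


def interval_rates(curve: GrowthCurve, floor: float = DEFAULT_FLOOR) -> IntervalRates:
    """Per-interval exponential rates ``ln(C_{i+1}/C_i)/(t_{i+1}-t_i)``.

    Intervals where either blank-corrected endpoint sits at or below the
    positivity floor are masked (``valid=False``, rate NaN): the log of a
    reading at the blank is noise, not growth.
    """
    c = curve.corrected
    dt = np.diff(curve.times)
    valid = (c[:-1] > floor) & (c[1:] > floor)
    if valid.sum() == 0 and c.size < 2:
        raise EstimationError("fewer than 2 valid points")
    mu = np.full(c.size - 1, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu[valid] = np.log(c[1:][valid] / c[:-1][valid]) / dt[valid]
    t_mid = 0.5 * (curve.times[:-1] + curve.times[1:])
    return IntervalRates(t_mid=t_mid, mu=mu, valid=valid)


_MEAN_SLACK = 0.05  # windows within 5% of the best mean compete on SD


def estimate_growth_rate(
    curve: GrowthCurve, window: int = 5, floor: float = DEFAULT_FLOOR
) -> GrowthRateEstimate:
    """Best-window exponential rate of one curve.

    Among all windows of ``window`` consecutive valid interval rates, the
    primary criterion is the maximal window mean; among windows whose mean is
    within 5% of that maximum, the minimal standard deviation wins; any
    remaining tie goes to the earliest window.  A curve with no valid window,
    or whose best window mean is <= 0, is flagged no-growth rather than given
    a rate.
    """
    rates = interval_rates(curve, floor=floor)
    max_od = float(np.max(curve.corrected))
    n_int = rates.mu.size
    candidates = []  # (start, mean, sd)
    for start in range(n_int - window + 1):
        sl = slice(start, start + window)
        if not rates.valid[sl].all():
            continue
        w = rates.mu[sl]
        candidates.append((start, float(w.mean()), float(w.std(ddof=1))))
    no_growth = GrowthRateEstimate(
        strain=curve.strain, medium=curve.medium, replicate=curve.replicate,
        mu=float("nan"), window_start_index=-1, window_sd=float("nan"),
        max_od=max_od, no_growth=True, plate=curve.plate, well=curve.well,
    )
    if not candidates:
        return no_growth
    best_mean = max(m for _, m, _ in candidates)
    if best_mean <= 0:
        return no_growth
    eligible = [c for c in candidates if c[1] >= best_mean * (1.0 - _MEAN_SLACK)]
    start, mean, sd = min(eligible, key=lambda c: (c[2], c[0]))
    return GrowthRateEstimate(
        strain=curve.strain, medium=curve.medium, replicate=curve.replicate,
        mu=mean, window_start_index=start, window_sd=sd, max_od=max_od,
        no_growth=False, plate=curve.plate, well=curve.well,
    )


def estimates_frame(estimates: Iterable[GrowthRateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": e.strain, "medium": e.medium, "replicate": e.replicate,
                "mu": e.mu, "window_start_index": e.window_start_index,
                "window_sd": e.window_sd, "max_od": e.max_od,
                "no_growth": e.no_growth, "plate": e.plate, "well": e.well,
            }
            for e in estimates
        ]
    )


def aggregate_replicates(estimates: Iterable[GrowthRateEstimate]) -> pd.DataFrame:
    """Per strain x medium mean rate, standard error and mean growth maximum.

    No-growth replicates are excluded (their count is kept in
    ``n_no_growth``); a strain whose replicates all failed to grow is absent
    from the table.  A single surviving replicate gets SE = 0 with
    ``degenerate_n=True``.
    """
    df = estimates_frame(estimates)
    if df.empty:
        raise UndefinedStatisticError("no estimates to aggregate")
    rows = []
    for (strain, medium), grp in df.groupby(["strain", "medium"], sort=True):
        grown = grp[~grp["no_growth"]]
        n = len(grown)
        if n == 0:
            continue
        mu = grown["mu"].to_numpy()
        se = float(mu.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "strain": strain,
                "medium": medium,
                "mu_mean": float(mu.mean()),
                "mu_se": se,
                "n": n,
                "n_no_growth": int(grp["no_growth"].sum()),
                "max_od_mean": float(grown["max_od"].mean()),
                "degenerate_n": n == 1,
            }
        )
    return pd.DataFrame(rows)


_ROWS = "ABCDEFGH"


def serpentine_index(well: str, n_cols: int = 12) -> int:
    """Serpentine well order: A1..A12, B12..B1, C1..C12, ...

    A fixed documented convention for the one-dimensional well index used by
    the location-bias diagnostic.
    """
    row = _ROWS.index(well[0].upper())
    col = int(well[1:]) - 1
    if not 0 <= col < n_cols:
        raise UndefinedStatisticError(f"column out of range in well {well!r}")
    return row * n_cols + (col if row % 2 == 0 else n_cols - 1 - col)


def well_bias_diagnostic(estimates: Iterable[GrowthRateEstimate]) -> pd.DataFrame:
    """Per-well means of mu and max OD with their trends along the plate.

    Returns the per-well table; the Spearman trend of each quantity against
    the serpentine well index is stored in ``attrs``:
    ``rho_mu, p_mu, rho_max_od, p_max_od``.
    """
    df = estimates_frame(estimates)
    df = df[~df["no_growth"]]
    if df["well"].nunique() < 2:
        raise UndefinedStatisticError("well trend undefined with < 2 wells")
    per_well = (
        df.groupby("well", sort=True)
        .agg(mu_mean=("mu", "mean"), max_od_mean=("max_od", "mean"), n=("mu", "size"))
        .reset_index()
    )
    per_well["well_index"] = per_well["well"].map(serpentine_index)
    per_well = per_well.sort_values("well_index").reset_index(drop=True)
    for col, tag in (("mu_mean", "mu"), ("max_od_mean", "max_od")):
        y = per_well[col].to_numpy()
        if np.ptp(y) == 0:
            raise UndefinedStatisticError(f"constant {tag}: well trend undefined")
        rho, p = stats.spearmanr(per_well["well_index"], y)
        per_well.attrs[f"rho_{tag}"] = float(rho)
        per_well.attrs[f"p_{tag}"] = float(p)
    return per_well


def rate_vs_max_correlation(rate_table: pd.DataFrame, medium: str) -> tuple[float, float]:
    """Spearman correlation across strains of mean rate vs mean growth maximum."""
    sub = rate_table[rate_table["medium"] == medium]
    if len(sub) < 3:
        raise UndefinedStatisticError("need >= 3 strains for a correlation")
    x = sub["mu_mean"].to_numpy()
    y = sub["max_od_mean"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
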