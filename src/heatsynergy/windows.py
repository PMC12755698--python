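"""Exposure windowing and percentile trimming.

The analysis exposure for a person-day is the daily maximum temperature on
that day (1-day window by default) and the mean PM2.5 over the day and the
two preceding days (3-day window). A day only enters the analysis when every
day of its window is present in the area's series. Extreme PM2.5 outliers are
excluded by trimming person-days whose windowed PM2.5 exceeds an empirical
percentile (default the 95th) of the pooled case + referent values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowSpec",
    "TrimSpec",
    "MissingCoverageError",
    "window_mean",
    "windowed_exposures",
    "compute_trim_threshold",
    "apply_trim",
]


class MissingCoverageError(KeyError):
    """A day of the requested exposure window is absent from the series."""


@dataclass(frozen=True)
class WindowSpec:
    """Lengths (in days, ending at the index day) of the exposure windows."""

    temp_window_days: int = 1
    pm_window_days: int = 3

    def __post_init__(self) -> None:
        if self.temp_window_days < 1 or self.pm_window_days < 1:
            raise ValueError("window lengths must be >= 1 day")


@dataclass(frozen=True)
class TrimSpec:
    """Quantile of pooled windowed PM2.5 used as the trimming threshold."""

    quantile: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("trim quantile must lie in (0, 1]")


def window_mean(values: pd.Series, date, k: int) -> float:
    """Mean of the ``k`` consecutive daily values ending at ``date``.

    ``values`` is a daily series indexed by date for a single area. Raises
    :class:`MissingCoverageError` when any of the ``k`` days is absent, so the
    caller can drop that person-day.
    """
    if k < 1:
        raise ValueError("window length must be >= 1")
    end = pd.Timestamp(date)
    days = pd.date_range(end - pd.Timedelta(days=k - 1), end, freq="D")
    try:
        window = values.loc[days]
    except KeyError as err:
        raise MissingCoverageError(f"window ending {end.date()} not fully covered") from err
    if window.isna().any():
        raise MissingCoverageError(f"window ending {end.date()} not fully covered")
    return float(window.mean())


def windowed_exposures(series: pd.DataFrame, spec: WindowSpec | None = None) -> pd.DataFrame:
    """Attach windowed exposures to every area-day of an exposure series.

    Returns ``area_id, date, tmax_w, pm25_w`` with NaN where the trailing
    window (which requires consecutive calendar days) is incomplete. The
    rolling means are computed per area on a contiguous daily grid, so gaps
    in a series invalidate the affected windows rather than silently
    shortening them.
    """
    spec = spec or WindowSpec()
    frames = []
    for aid, grp in series.groupby("area_id", sort=True):
        grp = grp.sort_values("date").set_index("date")
        full = grp.reindex(pd.date_range(grp.index.min(), grp.index.max(), freq="D"))
        out = pd.DataFrame(
            {
                "area_id": aid,
                "date": full.index,
                "tmax_w": full["tmax"].rolling(spec.temp_window_days).mean().to_numpy(),
                "pm25_w": full["pm25"].rolling(spec.pm_window_days).mean().to_numpy(),
            }
        )
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def compute_trim_threshold(values, q: float) -> float:
    """Empirical quantile (linear interpolation between order statistics)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a trim threshold from empty values")
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    return float(np.quantile(values, q, method="linear"))


def apply_trim(sets: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop person-days with windowed PM2.5 above ``threshold``.

    ``sets`` is the long-format matched-set table with columns including
    ``set_id, is_case, pm25_w``. Person-days over the threshold are removed;
    a matched set whose CASE day is removed is dropped entirely (a stratum
    without its case contributes nothing to the conditional likelihood), as
    is a set left without referents. Returns the trimmed table and a count
    ledger: ``{"rows_in", "dropped_trim", "dropped_empty_stratum", "rows_out"}``
    where ``dropped_trim`` counts rows over the threshold and
    ``dropped_empty_stratum`` counts surviving rows discarded because their
    set lost its case or all its referents.
    """
    rows_in = len(sets)
    over = sets["pm25_w"].to_numpy() > threshold
    kept = sets.loc[~over]

    case_alive = kept.groupby("set_id")["is_case"].sum()
    ref_alive = kept.groupby("set_id")["is_case"].apply(lambda c: (1 - c).sum())
    good = case_alive.index[(case_alive == 1) & (ref_alive >= 1)]
    out = kept[kept["set_id"].isin(good)].reset_index(drop=True)

    ledger = {
        "rows_in": rows_in,
        "dropped_trim": int(over.sum()),
        "dropped_empty_stratum": int(len(kept) - len(out)),
        "rows_out": len(out),
    }
    return out, ledger
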