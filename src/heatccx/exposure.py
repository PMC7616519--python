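"""Heatwave exposure calendars from daily maximum temperature series.

A county-specific heatwave is a maximal run of at least ``min_run``
consecutive calendar days on which daily maximum temperature strictly
exceeds the county's year-round baseline percentile threshold (default:
the 97.5th percentile of daily maxima over a multi-year baseline
period).  Every constituent day of a qualifying run is flagged as a
heatwave day.  Isolated exceedance days (runs shorter than ``min_run``)
are kept as a simpler sensitivity exposure, ``exceed_simple``.

The calendar carries four 0/1 flags per (county, date):

``hw_any``
    day belongs to a qualifying heatwave spell
``hw_first`` / ``hw_later``
    first day of a spell vs. second-and-later days
    (``hw_first + hw_later == hw_any``)
``exceed_simple``
    temperature exceeded the threshold, regardless of run length

Thresholds use the linear-interpolation quantile convention (type 7:
index ``h = 1 + (n-1) q/100`` on the sorted sample), recorded in the
output metadata because thresholds are sensitive to the convention.
Runs are broken by missing dates; temperatures are never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["baseline_percentile", "detect_heatwaves", "label_spell_days"]


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")


def baseline_percentile(
    climate: pd.DataFrame,
    baseline_years: tuple[int, int] | list[int],
    q: float = 97.5,
) -> pd.DataFrame:
    """Per-county year-round percentile thresholds of daily tmax.

    Parameters
    ----------
    climate
        Columns ``county``, ``date`` (datetime-like), ``tmax_c``.
    baseline_years
        Either an inclusive ``(start, end)`` pair or an explicit list of
        calendar years; all days of those years enter the sample
        (year-round, not summer-only).
    q
        Percentile in (0, 100).

    Returns
    -------
    DataFrame with columns ``county``, ``threshold_c`` plus metadata in
    ``.attrs`` (quantile, baseline span, interpolation method).
    Counties with no baseline data are excluded with a logged warning.
    """
    if not 0.0 < q < 100.0:
        raise ValueError(f"quantile q must be in (0, 100), got {q}")
    _require_columns(climate, ("county", "date", "tmax_c"), "climate")
    if len(climate) == 0:
        raise ValueError("empty climate table")

    dates = pd.to_datetime(climate["date"])
    if isinstance(baseline_years, (tuple, list)) and len(baseline_years) == 2 and not isinstance(
        baseline_years[0], (list, tuple)
    ):
        y0, y1 = int(baseline_years[0]), int(baseline_years[1])
        if y1 < y0:
            raise ValueError(f"inverted baseline year range ({y0}, {y1})")
        years = list(range(y0, y1 + 1))
    else:
        years = [int(y) for y in baseline_years]
    sub = climate.loc[dates.dt.year.isin(years)]
    if len(sub) == 0:
        raise ValueError(f"no climate data in baseline years {years[0]}-{years[-1]}")

    excluded = set(climate["county"].unique()) - set(sub["county"].unique())
    for c in sorted(excluded):
        logger.warning("county %s has no baseline data; excluded from thresholds", c)
    short = sub.groupby("county").size()
    for c in short.index[short < 365]:
        logger.warning("county %s has only %d baseline days (<365)", c, short[c])

    # pandas' default quantile interpolation is the type-7 linear rule
    thr = sub.groupby("county")["tmax_c"].quantile(q / 100.0).rename("threshold_c")
    out = thr.reset_index()
    out.attrs.update(
        quantile=q,
        baseline_start=int(min(years)),
        baseline_end=int(max(years)),
        method="linear",
    )
    return out


def _run_ids(county: np.ndarray, date: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Segment ids over rows sorted by (county, date).

    A new segment starts at a county change, a calendar gap, or a change
    in the ``active`` flag; consecutive active days therefore share an id.
    """
    n = len(active)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    new_seg = np.ones(n, dtype=bool)
    same_county = county[1:] == county[:-1]
    day_gap = (date[1:] - date[:-1]) / np.timedelta64(1, "D")
    contiguous = same_county & (day_gap == 1)
    new_seg[1:] = ~(contiguous & (active[1:] == active[:-1]))
    return np.cumsum(new_seg) - 1


def detect_heatwaves(
    climate: pd.DataFrame,
    thresholds: pd.DataFrame,
    min_run: int = 2,
    strict: bool = True,
) -> pd.DataFrame:
    """Build a heatwave calendar from daily tmax and county thresholds.

    ``strict=True`` implements exceedance as ``tmax > threshold`` (a tie
    at the threshold does not count); set ``strict=False`` for ``>=``.
    Runs are computed over calendar-contiguous days per county; missing
    dates break runs.  Returns a calendar with all four exposure flags
    (``label_spell_days`` is applied before returning).
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    _require_columns(climate, ("county", "date", "tmax_c"), "climate")
    _require_columns(thresholds, ("county", "threshold_c"), "thresholds")

    df = climate[["county", "date", "tmax_c"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    missing = set(df["county"].unique()) - set(thresholds["county"].unique())
    if missing:
        raise ValueError(f"no threshold for counties {sorted(missing)}")
    df = df.merge(thresholds[["county", "threshold_c"]], on="county", how="left")
    df = df.sort_values(["county", "date"], kind="stable").reset_index(drop=True)

    if strict:
        exceed = (df["tmax_c"].to_numpy() > df["threshold_c"].to_numpy())
    else:
        exceed = (df["tmax_c"].to_numpy() >= df["threshold_c"].to_numpy())

    seg = _run_ids(df["county"].to_numpy(), df["date"].to_numpy(), exceed)
    seg_len = np.bincount(seg)[seg]
    hw = exceed & (seg_len >= min_run)

    cal = df[["county", "date"]].copy()
    cal["hw_any"] = hw.astype(np.int8)
    cal["exceed_simple"] = exceed.astype(np.int8)
    cal.attrs.update(min_run=min_run, exceed_rule=">" if strict else ">=")
    return label_spell_days(cal)


def label_spell_days(calendar: pd.DataFrame) -> pd.DataFrame:
    """Add ``hw_first``/``hw_later`` labels to a calendar with ``hw_any``.

    Within each maximal spell the earliest day gets ``hw_first = 1`` and
    all subsequent days ``hw_later = 1``; outside spells both are 0.
    """
    _require_columns(calendar, ("county", "date", "hw_any"), "calendar")
    attrs = dict(calendar.attrs)
    cal = calendar.sort_values(["county", "date"], kind="stable").reset_index(drop=True)
    cal["date"] = pd.to_datetime(cal["date"])
    hw = cal["hw_any"].to_numpy().astype(bool)
    seg = _run_ids(cal["county"].to_numpy(), cal["date"].to_numpy(), hw)
    first_of_seg = np.ones(len(cal), dtype=bool)
    first_of_seg[1:] = seg[1:] != seg[:-1]
    cal["hw_first"] = (hw & first_of_seg).astype(np.int8)
    cal["hw_later"] = (hw & ~first_of_seg).astype(np.int8)
    cal.attrs.update(attrs)
    return cal
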