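"""Person-time, direct standardization, incidence rates, demographics.

The two encounter datasets are compared on a common population footing:

* the reference dataset's person-time at risk comes from annual census
  population counts (constant within each calendar year);
* the insured dataset's person-time comes from monthly enrollment (each
  day in month *m* is assigned that month's enrollee count).

Standardization re-weights insured stratum counts so that the insured
stratum shares match the reference population's shares within each
year::

    weight(s, y) = [P_ref(s, y) / sum_s P_ref(s, y)]
                 / [P_ins(s, y) / sum_s P_ins(s, y)]

which makes re-weighted insured shares equal reference shares exactly.
Incidence rates are expressed per million person-days by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BANDS",
    "split_age_15_19",
    "person_time_from_enrollment",
    "person_time_from_population",
    "standardization_weights",
    "standardize_counts",
    "incidence_rate",
    "demographic_ratio_table",
    "ratios_from_shares",
]

#: The seven adult age bands used throughout the analysis.
AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")

_STRATUM = ["county", "age_group", "sex"]

# Mapping from standard 5-year census bands to the analysis bands.  The
# 15-19 band is handled separately (partial split into 18-24).
_FIVE_YEAR_TO_BAND = {
    "20-24": "18-24",
    "25-29": "25-34", "30-34": "25-34",
    "35-39": "35-44", "40-44": "35-44",
    "45-49": "45-54", "50-54": "45-54",
    "55-59": "55-64", "60-64": "55-64",
    "65-69": "65-74", "70-74": "65-74",
    "75-79": "75+", "80-84": "75+", "85+": "75+",
}


def split_age_15_19(
    raw: pd.DataFrame,
    fraction: float = 0.4,
    mode: str = "deterministic",
    seed: int | None = None,
) -> pd.DataFrame:
    """Collapse 5-year census bands to the seven adult bands.

    Census counts come in 5-year bands with no split at age 18, so the
    18-24 analysis band is approximated by moving ``fraction`` (default
    0.4, i.e. 2 of the 5 single years) of the 15-19 band into 18-24; the
    remainder (ages 15-17) is excluded from the adult population.

    ``mode='deterministic'`` multiplies by ``fraction`` and rounds to
    the nearest integer; ``mode='sampled'`` draws Binomial(count,
    fraction) with ``seed``.  Moved + excluded persons always equal the
    original 15-19 band.

    Parameters
    ----------
    raw
        Columns ``county, age_group, sex, year, count`` with 5-year
        ``age_group`` labels (``15-19``, ``20-24``, ..., ``85+``).

    Returns
    -------
    DataFrame ``county, age_group, sex, year, count`` on the seven
    adult bands.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if mode not in ("deterministic", "sampled"):
        raise ValueError(f"mode must be 'deterministic' or 'sampled', got {mode!r}")

    df = raw.copy()
    teen = df["age_group"] == "15-19"
    teen_counts = df.loc[teen, "count"].to_numpy()
    if mode == "deterministic":
        moved = np.rint(teen_counts * fraction).astype(np.int64)
    else:
        rng = np.random.default_rng(seed)
        moved = rng.binomial(teen_counts.astype(np.int64), fraction)
    df.loc[teen, "count"] = moved
    df.loc[teen, "age_group"] = "18-24"

    adult = df["age_group"].isin(("18-24",) + tuple(_FIVE_YEAR_TO_BAND))
    df = df.loc[adult].copy()
    df["age_group"] = df["age_group"].map(lambda a: _FIVE_YEAR_TO_BAND.get(a, a))
    out = (
        df.groupby(["county", "age_group", "sex", "year"], as_index=False)["count"]
        .sum()
    )
    return out


def _expand_dates(date_range: tuple | pd.DatetimeIndex) -> pd.DatetimeIndex:
    if isinstance(date_range, pd.DatetimeIndex):
        return date_range
    start, end = date_range
    return pd.date_range(start, end, freq="D")


def person_time_from_enrollment(
    enrollment: pd.DataFrame,
    date_range,
    strict: bool = False,
) -> pd.DataFrame:
    """Daily person-time from monthly enrollment counts.

    Each date in month *m* of year *y* gets ``person_days`` equal to the
    enrollee count for (stratum, y, m).  A stratum-month missing from
    the enrollment table raises in strict mode; otherwise it contributes
    zero person-days with a warning.
    """
    dates = _expand_dates(date_range)
    days = pd.DataFrame({"date": dates})
    days["year"] = days["date"].dt.year
    days["month"] = days["date"].dt.month
    merged = days.merge(enrollment, on=["year", "month"], how="left")
    n_missing = merged["count"].isna().sum()
    if n_missing:
        if strict:
            raise ValueError(f"{n_missing} dates have no enrollment month")
        logger.warning("%d dates with no enrollment record; person-time set to 0", n_missing)
        merged = merged.dropna(subset=_STRATUM)
    out = merged[_STRATUM + ["date"]].copy()
    out["person_days"] = merged["count"].fillna(0.0).astype(float)
    if (out["person_days"] < 0).any():
        raise ValueError("negative enrollment counts")
    return out


def person_time_from_population(
    population: pd.DataFrame,
    date_range,
    strict: bool = False,
) -> pd.DataFrame:
    """Daily person-time from annual population counts (constant in year)."""
    dates = _expand_dates(date_range)
    days = pd.DataFrame({"date": dates})
    days["year"] = days["date"].dt.year
    merged = days.merge(population, on="year", how="left")
    n_missing = merged["count"].isna().sum()
    if n_missing:
        if strict:
            raise ValueError(f"{n_missing} dates have no population year")
        logger.warning("%d dates with no population record; person-time set to 0", n_missing)
        merged = merged.dropna(subset=_STRATUM)
    out = merged[_STRATUM + ["date"]].copy()
    out["person_days"] = merged["count"].fillna(0.0).astype(float)
    if (out["person_days"] < 0).any():
        raise ValueError("negative population counts")
    return out


def standardization_weights(
    insured: pd.DataFrame,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Year-specific re-weighting factors aligning insured to reference shares.

    weight(s, y) = ref_share(s, y) / ins_share(s, y).  Strata with zero
    insured population get weight 0 with a warning (their counts, which
    must then also be zero, are annihilated); a year with zero insured
    total raises.
    """
    ins = insured.groupby(_STRATUM + ["year"], as_index=False)["count"].sum()
    ref = reference.groupby(_STRATUM + ["year"], as_index=False)["count"].sum()

    ins_tot = ins.groupby("year")["count"].transform("sum")
    if (ins_tot == 0).any():
        bad = sorted(ins.loc[ins_tot == 0, "year"].unique())
        raise ValueError(f"zero insured population total in years {bad}")
    ins["ins_share"] = ins["count"] / ins_tot
    ref_tot = ref.groupby("year")["count"].transform("sum")
    if (ref_tot == 0).any():
        bad = sorted(ref.loc[ref_tot == 0, "year"].unique())
        raise ValueError(f"zero reference population total in years {bad}")
    ref["ref_share"] = ref["count"] / ref_tot

    merged = ref[_STRATUM + ["year", "ref_share"]].merge(
        ins[_STRATUM + ["year", "ins_share"]], on=_STRATUM + ["year"], how="outer"
    )
    merged["ins_share"] = merged["ins_share"].fillna(0.0)
    merged["ref_share"] = merged["ref_share"].fillna(0.0)
    zero = merged["ins_share"] == 0
    if zero.any():
        logger.warning(
            "%d strata-years have zero insured population; weight set to 0", int(zero.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(zero, 0.0, merged["ref_share"] / merged["ins_share"])
    out = merged[_STRATUM + ["year"]].copy()
    out["weight"] = w
    out.attrs["formula"] = "ref_share(s,y) / ins_share(s,y), year-specific"
    return out


def standardize_counts(counts: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Multiply crude stratum counts by standardization weights.

    Output counts are real-valued.  Every (county, age_group, sex, year)
    present in ``counts`` must have a weight.
    """
    df = counts.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    merged = df.merge(weights, on=_STRATUM + ["year"], how="left")
    if merged["weight"].isna().any():
        bad = (
            merged.loc[merged["weight"].isna(), _STRATUM + ["year"]]
            .drop_duplicates()
            .head(5)
            .to_dict("records")
        )
        raise ValueError(f"missing standardization weight for strata such as {bad}")
    merged["count"] = merged["count"] * merged["weight"]
    return merged.drop(columns=["weight", "year"])


def incidence_rate(
    counts: pd.DataFrame,
    person_time: pd.DataFrame,
    scale: float = 1e6,
    by: list[str] | None = None,
) -> float | pd.DataFrame:
    """Encounters per ``scale`` person-days, overall or per margin.

    ``by`` may list count-side columns (e.g. ``["cause",
    "encounter_type"]``); the denominator is always the total
    person-days of the table (person-time is not cause-specific).
    """
    total_pt = float(person_time["person_days"].sum())
    total_counts = float(counts["count"].sum())
    if total_pt <= 0:
        if total_counts > 0:
            raise ValueError("zero person-time with nonzero counts")
        total_pt = np.nan
    if by is None:
        return scale * total_counts / total_pt if total_pt == total_pt else 0.0
    g = counts.groupby(by, as_index=False)["count"].sum()
    g["rate"] = scale * g["count"] / total_pt
    return g.drop(columns="count")


def ratios_from_shares(insured, reference, decimals: int = 2):
    """Elementwise insured/reference ratio rounded for presentation.

    Zero reference shares yield NaN (ratio undefined).
    """
    ins = np.asarray(insured, dtype=float)
    ref = np.asarray(reference, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ref == 0, np.nan, ins / ref)
    return np.round(r, decimals)


def _annual_shares(pop: pd.DataFrame, key: str) -> pd.Series:
    """Percentage share of each ``key`` category per year, averaged over years."""
    per_year = pop.groupby(["year", key])["count"].sum()
    tot = pop.groupby("year")["count"].sum()
    shares = 100.0 * per_year / tot
    return shares.groupby(level=key).mean()


def demographic_ratio_table(
    insured: pd.DataFrame,
    reference: pd.DataFrame,
    decimals: int = 2,
) -> pd.DataFrame:
    """Population composition of the two datasets with between-dataset ratios.

    For each category (total population, % female, each age band, each
    county) the annual percentage shares are averaged across years, and
    the ratio column is insured share / reference share rounded to
    ``decimals`` (full precision kept in ``ratio_raw``).
    """
    if len(insured) == 0 or len(reference) == 0:
        raise ValueError("population tables must be nonempty")
    rows = []

    ins_tot = insured.groupby("year")["count"].sum().mean()
    ref_tot = reference.groupby("year")["count"].sum().mean()
    rows.append(("total", "population", ins_tot, ref_tot))

    ins_f = _annual_shares(insured, "sex").get("F", 0.0)
    ref_f = _annual_shares(reference, "sex").get("F", 0.0)
    rows.append(("sex", "% Female", ins_f, ref_f))

    for key, label in (("age_group", "% in "), ("county", "% in ")):
        ins_s = _annual_shares(insured, key)
        ref_s = _annual_shares(reference, key)
        for cat in ref_s.index:
            rows.append((key, label + str(cat), ins_s.get(cat, 0.0), ref_s.get(cat, 0.0)))

    out = pd.DataFrame(rows, columns=["category", "label", "insured", "reference"])
    out["ratio_raw"] = np.where(
        out["reference"] == 0, np.nan, out["insured"] / out["reference"]
    )
    out["ratio"] = out["ratio_raw"].round(decimals)
    return out
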