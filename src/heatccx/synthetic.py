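"""Synthetic study inputs with known ground-truth parameters.

Real claims and discharge datasets of this kind are restricted, so every
downstream stage is exercised on synthetic inputs that emulate their
structure:

* **Climate** — per-county daily maximum temperature as a seasonal
  sinusoid plus AR(1) noise, producing occasional multi-day heat
  spells; relative humidity correlated (by default negatively) with the
  temperature anomaly.
* **Populations** — an annual census-like reference population on the
  seven adult age bands, and a monthly enrollment table for an insured
  sub-population covering a few percent of it, with a younger age skew.
* **Encounters** — daily counts per (date, county, age band, sex,
  cause, encounter type, dataset) drawn from a gamma-mixed Poisson
  (negative binomial) whose mean is

  ``person_days x baseline_rate x rate_multiplier
  x exp(b_hw*hw + b_rh*RH + b_hol*holiday)``

  with the gamma mixture scaled so that variance/mean equals the
  ``overdispersion`` parameter at every mean (variance proportional to
  the mean, matching the quasi-Poisson variance function assumed by the
  downstream model).

All generators are deterministic given their seed; the pipeline derives
per-component seeds from one root seed via ``numpy`` seed sequences so
components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .population import AGE_BANDS

__all__ = [
    "ClimateParams",
    "EffectParams",
    "CoverageParams",
    "default_holidays",
    "generate_climate",
    "generate_population",
    "generate_encounters",
]

#: Approximate adult age-band shares of a large US state population.
DEFAULT_AGE_SHARES = {
    "18-24": 0.125, "25-34": 0.19, "35-44": 0.17, "45-54": 0.16,
    "55-64": 0.15, "65-74": 0.115, "75+": 0.09,
}

#: Between-dataset age-share ratios used to skew insured coverage young,
#: mirroring the composition gap between commercially insured enrollees
#: and the full state population.
DEFAULT_AGE_COVERAGE_SKEW = {
    "18-24": 0.66, "25-34": 1.10, "35-44": 1.26, "45-54": 1.16,
    "55-64": 1.01, "65-74": 0.79, "75+": 0.86,
}

# Eight fixed (month, day) holiday dates per year.  Real federal
# holidays float; a fixed synthetic list keeps the generator simple and
# the holiday covariate well-defined.
_HOLIDAY_MONTH_DAY = [
    (1, 1), (2, 15), (5, 31), (7, 4), (9, 7), (11, 11), (11, 25), (12, 25),
]


@dataclass
class ClimateParams:
    """Parameters of the per-county daily climate process.

    ``noise_sd`` is the AR(1) innovation standard deviation; the
    stationary anomaly s.d. is ``noise_sd / sqrt(1 - ar1_rho**2)``.
    ``county_spread`` adds a per-county uniform offset to ``mean_tmax``
    so thresholds genuinely differ by county.
    """

    mean_tmax: float = 26.0        # degC
    seasonal_amplitude: float = 9.0  # degC
    ar1_rho: float = 0.7
    noise_sd: float = 3.0          # degC, innovation sd
    rh_mean: float = 55.0          # percent
    rh_sd: float = 15.0            # percent
    rh_temp_corr: float = -0.4
    county_spread: float = 2.0     # degC, half-width of county offsets
    peak_doy: int = 197            # mid-July seasonal peak

    def validate(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError(f"ar1_rho must be in [0, 1), got {self.ar1_rho}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not -1.0 < self.rh_temp_corr < 1.0:
            raise ValueError(f"rh_temp_corr must be in (-1, 1), got {self.rh_temp_corr}")


@dataclass
class EffectParams:
    """Ground-truth log-linear effects of the encounter-count process.

    ``log_irr_hw`` maps dataset label to the heatwave log rate ratio
    (the downstream model's exposure coefficient; its between-dataset
    difference is the log ratio-of-IRRs).  ``log_rr_rh`` is per 1% RH on
    the percent scale; ``baseline_rate`` is encounters per person-day
    per cause; ``overdispersion`` is the variance/mean ratio of counts
    (1 = pure Poisson).
    """

    log_irr_hw: dict = field(
        default_factory=lambda: {"reference": float(np.log(1.1)),
                                 "insured": float(np.log(1.2))}
    )
    log_rr_rh: float = 0.005       # per 1% RH
    log_rr_holiday: float = -0.10
    baseline_rate: dict = field(default_factory=lambda: {"all-cause": 8e-4})
    overdispersion: float = 1.3
    ed_share: float = 0.7          # fraction of encounters that are ED-only

    def validate(self) -> None:
        if any(r < 0 for r in self.baseline_rate.values()):
            raise ValueError("baseline_rate must be >= 0")
        if self.overdispersion < 1.0:
            raise ValueError(f"overdispersion must be >= 1, got {self.overdispersion}")
        if not 0.0 <= self.ed_share <= 1.0:
            raise ValueError(f"ed_share must be in [0, 1], got {self.ed_share}")


@dataclass
class CoverageParams:
    """Insured coverage of the reference population, and utilization scale.

    Effective coverage of a stratum is ``coverage x age_multipliers[age]
    x sex_multipliers.get(sex, 1) x county_multipliers.get(county, 1)``,
    clipped to (0, 1].  ``rate_multiplier`` scales each dataset's
    baseline utilization (insured members typically utilize acute care
    at lower rates than the full population).
    """

    coverage: float = 0.034
    age_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_AGE_COVERAGE_SKEW))
    sex_multipliers: dict = field(default_factory=dict)
    county_multipliers: dict = field(default_factory=dict)
    rate_multiplier: dict = field(
        default_factory=lambda: {"reference": 1.0, "insured": 0.4}
    )

    def fraction(self, age_group: str, sex: str, county: str) -> float:
        f = (
            self.coverage
            * self.age_multipliers.get(age_group, 1.0)
            * self.sex_multipliers.get(sex, 1.0)
            * self.county_multipliers.get(county, 1.0)
        )
        return min(f, 1.0)

    def validate(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")
        for d, m in [("age", self.age_multipliers), ("sex", self.sex_multipliers),
                     ("county", self.county_multipliers)]:
            if any(v <= 0 for v in m.values()):
                raise ValueError(f"{d} coverage multipliers must be > 0")
        if any(v <= 0 for v in self.rate_multiplier.values()):
            raise ValueError("rate_multiplier must be > 0")


def default_holidays(years) -> list[pd.Timestamp]:
    """Eight fixed synthetic holiday dates per year."""
    return [pd.Timestamp(year=y, month=m, day=d)
            for y in years for (m, d) in _HOLIDAY_MONTH_DAY]


def generate_climate(
    counties,
    date_range,
    params: ClimateParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily tmax and RH per county over ``date_range``.

    tmax = county mean + seasonal sinusoid + AR(1) anomaly; RH is a
    Gaussian with correlation ``rh_temp_corr`` to the standardized
    anomaly, clipped to [0, 100] percent.  Deterministic given ``seed``.
    """
    params = params or ClimateParams()
    params.validate()
    counties = list(counties)
    if not counties:
        raise ValueError("empty county list")
    dates = _expand(date_range)
    if len(dates) == 0:
        raise ValueError("empty or inverted date range")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - params.peak_doy) / 365.25
    )
    burn = 200
    stat_sd = (
        params.noise_sd / np.sqrt(1.0 - params.ar1_rho**2)
        if params.noise_sd > 0
        else 0.0
    )

    frames = []
    for county in counties:
        offset = rng.uniform(-params.county_spread, params.county_spread)
        eps = rng.normal(0.0, params.noise_sd, size=n + burn)
        anomaly = lfilter([1.0], [1.0, -params.ar1_rho], eps)[burn:]
        tmax = params.mean_tmax + offset + seasonal + anomaly
        z = rng.normal(size=n)
        a_std = anomaly / stat_sd if stat_sd > 0 else np.zeros(n)
        rh = params.rh_mean + params.rh_sd * (
            params.rh_temp_corr * a_std
            + np.sqrt(1.0 - params.rh_temp_corr**2) * z
        )
        frames.append(
            pd.DataFrame(
                {
                    "county": county,
                    "date": dates,
                    "tmax_c": tmax,
                    "rh_pct": np.clip(rh, 0.0, 100.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_population(
    counties,
    years,
    coverage: CoverageParams | None = None,
    seed: int = 0,
    age_groups=AGE_BANDS,
    sexes=("F", "M"),
    mean_population: float = 3e5,
    enrollment_jitter: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference population (annual) and insured enrollment (monthly).

    County totals are lognormal around ``mean_population``; age/sex
    shares follow :data:`DEFAULT_AGE_SHARES` with a 50/50 sex split and
    a small deterministic annual drift.  Enrollment in a stratum-month
    is ``coverage fraction x reference count`` with multiplicative
    lognormal month-to-month jitter of s.d. ``enrollment_jitter``.  All
    counts are non-negative integers.
    """
    coverage = coverage or CoverageParams()
    coverage.validate()
    counties, years = list(counties), list(years)
    if not counties or not years:
        raise ValueError("counties and years must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    shares = {a: DEFAULT_AGE_SHARES.get(a, 1.0 / len(age_groups)) for a in age_groups}
    norm = sum(shares.values())

    pop_rows, enr_rows = [], []
    for county in counties:
        base = rng.lognormal(mean=np.log(mean_population), sigma=0.6)
        for age in age_groups:
            for sex in sexes:
                stratum0 = base * shares[age] / norm / len(sexes)
                frac = coverage.fraction(age, sex, county)
                for i, year in enumerate(years):
                    ref = int(round(stratum0 * (1.0 + 0.005 * i)))
                    pop_rows.append((county, age, sex, year, ref))
                    jit = rng.lognormal(0.0, enrollment_jitter, size=12) if enrollment_jitter > 0 else np.ones(12)
                    enr = np.rint(ref * frac * jit).astype(np.int64)
                    for month in range(1, 13):
                        enr_rows.append((county, age, sex, year, month, int(enr[month - 1])))

    population = pd.DataFrame(
        pop_rows, columns=["county", "age_group", "sex", "year", "count"]
    )
    enrollment = pd.DataFrame(
        enr_rows, columns=["county", "age_group", "sex", "year", "month", "count"]
    )
    return population, enrollment


def generate_encounters(
    calendar: pd.DataFrame,
    climate: pd.DataFrame,
    person_time: pd.DataFrame,
    effects: EffectParams | None = None,
    holidays=None,
    seed: int = 0,
    dataset: str = "insured",
    rate_multiplier: float | None = None,
) -> pd.DataFrame:
    """Daily stratum encounter counts for one dataset.

    The mean count of a (stratum, day, cause, type) cell is::

        person_days * baseline_rate[cause] * type_share
            * rate_multiplier * exp(b_hw*hw + b_rh*RH + b_hol*holiday)

    drawn gamma-mixed Poisson with variance/mean = ``overdispersion``.
    ``calendar``, ``climate`` and ``person_time`` must share their
    (county, date) keys.
    """
    effects = effects or EffectParams()
    effects.validate()
    if dataset not in effects.log_irr_hw:
        raise ValueError(f"no log_irr_hw for dataset {dataset!r}")
    if (person_time["person_days"] < 0).any():
        raise ValueError("negative person_time")

    day = person_time.merge(
        calendar[["county", "date", "hw_any"]], on=["county", "date"], how="left"
    ).merge(climate[["county", "date", "rh_pct"]], on=["county", "date"], how="left")
    if day[["hw_any", "rh_pct"]].isna().any().any():
        raise ValueError("person_time dates missing from calendar or climate")

    holiday_set = set(pd.to_datetime(holidays)) if holidays is not None else set()
    hol = day["date"].isin(holiday_set).to_numpy().astype(float)
    b1 = effects.log_irr_hw[dataset]
    eta = (
        b1 * day["hw_any"].to_numpy().astype(float)
        + effects.log_rr_rh * day["rh_pct"].to_numpy()
        + effects.log_rr_holiday * hol
    )
    if rate_multiplier is None:
        rate_multiplier = CoverageParams().rate_multiplier.get(dataset, 1.0)
    base_mu = day["person_days"].to_numpy() * np.exp(eta) * rate_multiplier

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    nu = effects.overdispersion
    frames = []
    type_shares = [("ED", effects.ed_share), ("INPATIENT", 1.0 - effects.ed_share)]
    for cause in sorted(effects.baseline_rate):
        for enc_type, share in type_shares:
            if share == 0.0:
                continue
            mu = base_mu * effects.baseline_rate[cause] * share
            counts = _overdispersed_poisson(rng, mu, nu)
            f = day[["county", "age_group", "sex", "date"]].copy()
            f["cause"] = cause
            f["encounter_type"] = enc_type
            f["count"] = counts
            frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "dataset", dataset)
    return out[
        ["dataset", "date", "county", "age_group", "sex", "cause", "encounter_type", "count"]
    ]


def generate_encounters_by_dataset(
    calendar, climate, person_time_by_dataset: dict, effects=None, holidays=None,
    seed: int = 0, rate_multiplier: dict | None = None,
) -> pd.DataFrame:
    """Counts for several datasets stacked into one table.

    ``rate_multiplier`` overrides the per-dataset utilization scale
    (defaults to :class:`CoverageParams` defaults).
    """
    frames = []
    ss = np.random.SeedSequence([seed, 3]).spawn(len(person_time_by_dataset))
    for s, (ds, pt) in zip(ss, sorted(person_time_by_dataset.items())):
        sub_seed = int(s.generate_state(1)[0] % (2**31))
        rm = rate_multiplier.get(ds) if rate_multiplier is not None else None
        frames.append(
            generate_encounters(
                calendar, climate, pt, effects=effects, holidays=holidays,
                seed=sub_seed, dataset=ds, rate_multiplier=rm,
            )
        )
    return pd.concat(frames, ignore_index=True)


def _overdispersed_poisson(rng: np.random.Generator, mu: np.ndarray, nu: float) -> np.ndarray:
    """Gamma-mixed Poisson with Var/E = nu exactly at every mean.

    lambda ~ Gamma(shape=mu/(nu-1), scale=nu-1) gives E[lambda]=mu and
    Var[lambda]=mu(nu-1), hence marginal count variance nu*mu.
    """
    mu = np.asarray(mu, dtype=float)
    if nu <= 1.0:
        return rng.poisson(mu)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(shape=mu[pos] / (nu - 1.0), scale=nu - 1.0)
    out = np.zeros(mu.shape, dtype=np.int64)
    out[pos] = rng.poisson(lam[pos])
    return out


def _expand(date_range) -> pd.DatetimeIndex:
    if isinstance(date_range, pd.DatetimeIndex):
        return date_range
    start, end = date_range
    return pd.date_range(start, end, freq="D")
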