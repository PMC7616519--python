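"""Space-time-stratified case-crossover conditional quasi-Poisson model.

Daily encounter counts ``N_ts`` (day *t*, stratum *s*) are modeled as
Poisson with log-linear covariate effects and a free intercept per
stratum, where a stratum is a (county, year, month, day-of-week) cell —
the time-stratified referent scheme: every day is compared only with
the other days sharing its county, calendar month and weekday.  The
stratum intercepts are eliminated by conditioning on the stratum totals
``n_s = sum_t N_ts``, leaving the multinomial (conditional) log
likelihood

    l(beta) = sum_s [ sum_t N_ts x_ts' beta  -  n_s log sum_t exp(x_ts' beta) ]

whose maximizer equals the profile Poisson MLE with one dummy per
stratum but costs only ``p`` parameters.  Overdispersion is handled
quasi-likelihood style: the Pearson dispersion

    phi = sum_ts (N_ts - mu_ts)^2 / mu_ts  /  (n_obs - n_strata - p)

scales the inverse-information covariance, with fitted means
``mu_ts = n_s softmax_s(X beta)``.  The residual degrees of freedom
count the eliminated stratum intercepts, matching the profile-
likelihood equivalence (and the convention of an unconditional fit with
explicit dummies).

The score equations only involve ``N`` linearly, so real-valued
(standardized) outcome counts are accepted unchanged.

Optimization is Newton-Raphson from ``beta = 0`` with step-halving; the
Hessian here is the exact (and expected) information, so iterations are
stable.  Convergence: max absolute score < 1e-8 or relative
log-likelihood change < 1e-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StratumData",
    "StrataSet",
    "FitResult",
    "StrataOptions",
    "NonIdentifiableError",
    "build_strata",
    "fit_conditional_poisson",
    "irr",
]

WARM_SEASON_MONTHS = (5, 6, 7, 8, 9)

#: Exposure variant -> calendar columns entering the design.
EXPOSURE_COLUMNS = {
    "hw_any": ["hw_any"],
    "first_later": ["hw_first", "hw_later"],
    "exceed_simple": ["exceed_simple"],
}


class NonIdentifiableError(ValueError):
    """A design column is constant within every stratum (absorbed by the
    eliminated stratum intercepts), so its coefficient has no
    information."""


@dataclass
class StratumData:
    """One case-crossover stratum: its days, outcomes and covariates."""

    key: tuple
    days: np.ndarray
    y: np.ndarray
    X: np.ndarray
    columns: list[str]


@dataclass
class StrataSet:
    """Packed strata: rows sorted by stratum index for segment reductions."""

    y: np.ndarray                  # (n,) outcome counts (may be real-valued)
    X: np.ndarray                  # (n, p) covariates
    stratum_idx: np.ndarray        # (n,) int, sorted, contiguous 0..S-1
    columns: list[str]
    keys: list[tuple] = field(default_factory=list)
    days: np.ndarray | None = None
    n_dropped_empty: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_strata(self) -> int:
        return int(self.stratum_idx[-1]) + 1 if len(self.stratum_idx) else 0

    def strata(self) -> list[StratumData]:
        """Materialize per-stratum views (for inspection and audit)."""
        starts = np.searchsorted(self.stratum_idx, np.arange(self.n_strata))
        ends = np.append(starts[1:], self.n_obs)
        out = []
        for s, (a, b) in enumerate(zip(starts, ends)):
            key = self.keys[s] if self.keys else (s,)
            days = self.days[a:b] if self.days is not None else np.arange(a, b)
            out.append(StratumData(key, days, self.y[a:b], self.X[a:b], self.columns))
        return out

    @classmethod
    def from_strata(cls, strata: list[StratumData]) -> "StrataSet":
        cols = strata[0].columns
        y = np.concatenate([np.asarray(s.y, dtype=float) for s in strata])
        X = np.vstack([np.asarray(s.X, dtype=float).reshape(len(s.y), -1) for s in strata])
        idx = np.concatenate(
            [np.full(len(s.y), i, dtype=np.int64) for i, s in enumerate(strata)]
        )
        days = np.concatenate([np.asarray(s.days) for s in strata])
        return cls(y=y, X=X, stratum_idx=idx, columns=list(cols),
                   keys=[s.key for s in strata], days=days)


@dataclass
class FitResult:
    beta: np.ndarray
    cov: np.ndarray                # dispersion-scaled
    columns: list[str]
    dispersion: float
    n_strata: int
    n_obs: int
    df: int
    converged: bool
    n_iter: int
    loglik: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, column: str) -> float:
        return float(self.beta[self.columns.index(column)])

    def se_of(self, column: str) -> float:
        return float(self.se[self.columns.index(column)])

    def to_dict(self) -> dict:
        return {
            "coefficients": {c: float(b) for c, b in zip(self.columns, self.beta)},
            "se": {c: float(s) for c, s in zip(self.columns, self.se)},
            "dispersion": float(self.dispersion),
            "n_strata": self.n_strata,
            "n_obs": self.n_obs,
            "df": self.df,
            "converged": self.converged,
            "iterations": self.n_iter,
            "loglik": float(self.loglik),
        }


@dataclass
class StrataOptions:
    """Selection and design options for strata construction."""

    cause: str | None = None
    encounter_type: str | None = None
    dataset: str | None = None
    age_groups: list[str] | None = None
    exposure: str = "hw_any"
    months: tuple = WARM_SEASON_MONTHS
    years: list[int] | None = None
    include_age_sex_in_stratum: bool = False
    strict: bool = True


def build_strata(
    counts: pd.DataFrame,
    calendar: pd.DataFrame,
    climate: pd.DataFrame,
    holidays=None,
    options: StrataOptions | None = None,
) -> StrataSet:
    """Assemble case-crossover strata from counts, exposure and climate.

    Counts are filtered by the options (cause, encounter type, dataset,
    age subset), summed over age-sex within county-day (unless age-sex
    is added to the stratum key), and joined onto the full calendar of
    analysis days so referent days with zero encounters are retained.
    Each county-day belongs to the stratum (county, year, month, ISO
    weekday); strata whose total count is zero are dropped (tallied in
    ``n_dropped_empty``) since they carry no conditional information.
    """
    options = options or StrataOptions()
    if options.exposure not in EXPOSURE_COLUMNS:
        raise ValueError(
            f"unknown exposure variant {options.exposure!r}; "
            f"choose from {sorted(EXPOSURE_COLUMNS)}"
        )
    exp_cols = EXPOSURE_COLUMNS[options.exposure]

    df = counts.copy()
    df["date"] = pd.to_datetime(df["date"])
    for col, val in (
        ("cause", options.cause),
        ("encounter_type", options.encounter_type),
        ("dataset", options.dataset),
    ):
        if val is not None and col in df.columns:
            df = df[df[col] == val]
    if options.age_groups is not None:
        df = df[df["age_group"].isin(options.age_groups)]

    group_cols = ["county", "date"]
    if options.include_age_sex_in_stratum:
        group_cols += ["age_group", "sex"]
    day_counts = df.groupby(group_cols, as_index=False)["count"].sum()

    # analysis-day frame: every county-date in the calendar within window
    days = calendar[["county", "date"] + exp_cols].copy()
    days["date"] = pd.to_datetime(days["date"])
    if options.years is not None:
        days = days[days["date"].dt.year.isin(options.years)]
    if options.months is not None:
        days = days[days["date"].dt.month.isin(options.months)]
    clim = climate[["county", "date", "rh_pct"]].copy()
    clim["date"] = pd.to_datetime(clim["date"])
    days = days.merge(clim, on=["county", "date"], how="left")
    if days["rh_pct"].isna().any():
        if options.strict:
            raise ValueError("calendar days missing climate (RH) records")
        days = days.dropna(subset=["rh_pct"])

    if options.include_age_sex_in_stratum:
        cells = day_counts[["age_group", "sex"]].drop_duplicates()
        days = days.merge(cells, how="cross")
    merged = days.merge(day_counts, on=group_cols, how="left")
    merged["count"] = merged["count"].fillna(0.0)

    out_of_calendar = len(day_counts.merge(days[group_cols], on=group_cols, how="left", indicator=True)
                          .query("_merge == 'left_only'"))
    if out_of_calendar and options.strict:
        raise ValueError(
            f"{out_of_calendar} count cells fall on days absent from the calendar window"
        )

    holiday_set = set(pd.to_datetime(holidays)) if holidays is not None else set()
    merged["holiday"] = merged["date"].isin(holiday_set).astype(float)

    merged["year"] = merged["date"].dt.year
    merged["month"] = merged["date"].dt.month
    merged["dow"] = merged["date"].dt.dayofweek + 1  # ISO: Monday = 1
    key_cols = ["county", "year", "month", "dow"]
    if options.include_age_sex_in_stratum:
        key_cols += ["age_group", "sex"]

    merged = merged.sort_values(key_cols + ["date"], kind="stable").reset_index(drop=True)
    stratum_total = merged.groupby(key_cols)["count"].transform("sum")
    nonempty = stratum_total > 0
    n_dropped = int(
        merged.loc[~nonempty, key_cols].drop_duplicates().shape[0]
    )
    if n_dropped:
        logger.info("dropped %d empty strata", n_dropped)
    merged = merged.loc[nonempty].reset_index(drop=True)
    if len(merged) == 0:
        raise ValueError("no nonempty strata in the analysis window")

    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(merged[key_cols]), sort=False
    )
    x_cols = exp_cols + ["rh_pct", "holiday"]
    return StrataSet(
        y=merged["count"].to_numpy(dtype=float),
        X=merged[x_cols].to_numpy(dtype=float),
        stratum_idx=codes.astype(np.int64),
        columns=list(x_cols),
        keys=list(uniques),
        days=merged["date"].to_numpy(),
        n_dropped_empty=n_dropped,
    )


def _as_strataset(strata) -> StrataSet:
    if isinstance(strata, StrataSet):
        return strata
    strata = list(strata)
    if not strata:
        raise ValueError("no strata to fit")
    return StrataSet.from_strata(strata)


def _segment_starts(idx: np.ndarray, n_seg: int) -> np.ndarray:
    return np.searchsorted(idx, np.arange(n_seg))


#: column names treated as exposures of interest by default: a degenerate
#: exposure is a hard error rather than a silently dropped column.
_EXPOSURE_LIKE = {"hw_any", "hw_first", "hw_later", "exceed_simple"}


def _is_exposure_name(name: str) -> bool:
    return name.removeprefix("dt_x_") in _EXPOSURE_LIKE


def fit_conditional_poisson(
    strata,
    columns: list[str] | None = None,
    exposure_columns: list[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    ridge: float = 1e-10,
) -> FitResult:
    """Maximize the stratum-conditioned log likelihood by Newton iteration.

    A column that is constant within every stratum carries no
    conditional information (it is absorbed by the eliminated stratum
    intercepts).  If such a column is an exposure of interest
    (``exposure_columns``; by default any heatwave/exceedance column or
    its dataset interaction) a :class:`NonIdentifiableError` is raised;
    otherwise the column is dropped with a warning, which leaves the
    remaining coefficients unchanged — the conditional likelihood is
    invariant to stratum-constant covariates.

    Parameters
    ----------
    strata
        A :class:`StrataSet` or list of :class:`StratumData`.
    columns
        Subset of design columns to fit (default: all).
    """
    ss = _as_strataset(strata)
    cols = list(ss.columns) if columns is None else list(columns)
    sel = [ss.columns.index(c) for c in cols]
    X = np.ascontiguousarray(ss.X[:, sel], dtype=float)
    y = np.asarray(ss.y, dtype=float)
    idx = ss.stratum_idx
    S = ss.n_strata
    n = X.shape[0]
    starts = _segment_starts(idx, S)

    n_s = np.add.reduceat(y, starts)                      # stratum totals
    m_s = np.diff(np.append(starts, n))                   # days per stratum

    # identifiability: within-stratum variation per column
    col_sum = np.add.reduceat(X, starts, axis=0)
    col_sumsq = np.add.reduceat(X * X, starts, axis=0)
    within_var = col_sumsq - col_sum**2 / m_s[:, None]
    total_within = within_var.sum(axis=0)
    scale = np.maximum(1.0, (X * X).sum(axis=0))
    dead = total_within / scale < 1e-12
    if dead.any():
        if exposure_columns is None:
            exposure_columns = [c for c in cols if _is_exposure_name(c)]
        bad = [c for c, d in zip(cols, dead) if d]
        bad_exposure = [c for c in bad if c in exposure_columns]
        if bad_exposure or len(bad) == len(cols):
            raise NonIdentifiableError(
                f"columns {bad_exposure or bad} are constant within every stratum; "
                "their effects are absorbed by the eliminated stratum intercepts"
            )
        logger.warning(
            "dropping stratum-constant covariates %s (no conditional information)", bad
        )
        keep = [i for i, d in enumerate(dead) if not d]
        cols = [cols[i] for i in keep]
        X = np.ascontiguousarray(X[:, keep])
    p = X.shape[1]

    beta = np.zeros(p)

    def _eval(b):
        eta = X @ b
        seg_max = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - seg_max[idx])
        denom = np.add.reduceat(w, starts)
        lse = seg_max + np.log(denom)
        ll = float(y @ eta - n_s @ lse)
        prob = w / denom[idx]
        mu = n_s[idx] * prob
        return ll, mu

    ll, mu = _eval(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score = X.T @ (y - mu)
        seg_mu_x = np.add.reduceat(mu[:, None] * X, starts, axis=0)    # (S, p)
        info = X.T @ (mu[:, None] * X) - (seg_mu_x / n_s[:, None]).T @ seg_mu_x
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        try:
            cond_ok = np.isfinite(np.linalg.cond(info)) and np.linalg.cond(info) < 1e12
        except np.linalg.LinAlgError:
            cond_ok = False
        if not cond_ok:
            logger.warning("ill-conditioned information; adding ridge jitter %.1e", ridge)
            info = info + ridge * np.eye(p)
        step = np.linalg.solve(info, score)
        # step-halving on the conditional log likelihood
        t = 1.0
        for _ in range(30):
            ll_new, mu_new = _eval(beta + t * step)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(ll_new - ll) <= ll_tol * (abs(ll) + 1.0):
            ll, mu = ll_new, mu_new
            converged = True
            break
        ll, mu = ll_new, mu_new
    if not converged:
        logger.warning("conditional Poisson fit did not converge in %d iterations", max_iter)

    # final information at the solution
    seg_mu_x = np.add.reduceat(mu[:, None] * X, starts, axis=0)
    info = X.T @ (mu[:, None] * X) - (seg_mu_x / n_s[:, None]).T @ seg_mu_x
    try:
        cov_unscaled = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        logger.warning("singular information at solution; ridge-inverting")
        cov_unscaled = np.linalg.inv(info + ridge * np.eye(p))

    df = n - S - p
    pearson = float(np.sum((y - mu) ** 2 / mu))
    if df > 0:
        dispersion = pearson / df
    else:
        logger.warning("saturated fit (df=%d); dispersion undefined, using 1", df)
        dispersion = float("nan")
    phi = dispersion if np.isfinite(dispersion) else 1.0
    cov = phi * cov_unscaled
    cov = (cov + cov.T) / 2.0

    return FitResult(
        beta=beta, cov=cov, columns=cols, dispersion=dispersion,
        n_strata=S, n_obs=n, df=df, converged=converged, n_iter=it, loglik=ll,
    )


def irr(fit: FitResult, column: str, z: float = 1.96) -> dict:
    """Incidence rate ratio exp(beta) with a Wald 95% CI for one column.

    The standard error comes from the dispersion-scaled covariance.
    """
    if column not in fit.columns:
        raise ValueError(f"column {column!r} not in fit ({fit.columns})")
    if not fit.converged:
        raise ValueError("fit did not converge; IRR not reported")
    b = fit.coef(column)
    se = fit.se_of(column)
    return {
        "irr": float(np.exp(b)),
        "ci_low": float(np.exp(b - z * se)),
        "ci_high": float(np.exp(b + z * se)),
        "beta": b,
        "se": se,
    }
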