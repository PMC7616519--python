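"""Shared fixtures: a small but complete synthetic study."""

import numpy as np
import pandas as pd
import pytest

from heatccx import (
    CoverageParams,
    EffectParams,
    baseline_percentile,
    default_holidays,
    detect_heatwaves,
    generate_climate,
    generate_population,
    person_time_from_enrollment,
    person_time_from_population,
)
from heatccx.synthetic import generate_encounters_by_dataset

COUNTIES = ["C000", "C001", "C002", "C003"]
BASELINE = (2000, 2003)
STUDY_YEARS = [2004, 2005]


def warm_season(years):
    return pd.DatetimeIndex(
        np.concatenate(
            [pd.date_range(f"{y}-05-01", f"{y}-09-30", freq="D").values for y in years]
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """Four counties, four baseline years, two study warm seasons."""
    climate = generate_climate(
        COUNTIES, (f"{BASELINE[0]}-01-01", f"{STUDY_YEARS[-1]}-12-31"), seed=7
    )
    thresholds = baseline_percentile(climate, BASELINE)
    calendar = detect_heatwaves(climate, thresholds)
    population, enrollment = generate_population(
        COUNTIES, STUDY_YEARS, CoverageParams(coverage=0.05), seed=7,
        mean_population=2e5,
    )
    window = warm_season(STUDY_YEARS)
    pt_ref = person_time_from_population(population, window)
    pt_ins = person_time_from_enrollment(enrollment, window)
    holidays = default_holidays(STUDY_YEARS)
    counts = generate_encounters_by_dataset(
        calendar, climate,
        {"reference": pt_ref, "insured": pt_ins},
        effects=EffectParams(), holidays=holidays, seed=7,
    )
    return {
        "climate": climate,
        "thresholds": thresholds,
        "calendar": calendar,
        "population": population,
        "enrollment": enrollment,
        "pt_ref": pt_ref,
        "pt_ins": pt_ins,
        "holidays": holidays,
        "counts": counts,
        "study_years": STUDY_YEARS,
    }


def random_strataset(rng, n_strata=20, n_cols=3, min_days=2, max_days=8,
                     columns=None, beta=None):
    """Random packed strata with Poisson outcomes and nonzero totals.

    Used both to exercise the conditional fitter and to feed the
    stratum-dummy GLM oracle.
    """
    from heatccx.ccx import StrataSet

    columns = columns or [f"x{i}" for i in range(n_cols)]
    beta = np.zeros(n_cols) if beta is None else np.asarray(beta, dtype=float)
    ys, Xs, idxs = [], [], []
    for s in range(n_strata):
        while True:
            m = rng.integers(min_days, max_days + 1)
            X = rng.normal(size=(m, n_cols))
            alpha = rng.normal(1.0, 0.5)
            mu = np.exp(alpha + X @ beta)
            y = rng.poisson(mu)
            if y.sum() > 0:
                break
        ys.append(y.astype(float))
        Xs.append(X)
        idxs.append(np.full(m, s))
    return StrataSet(
        y=np.concatenate(ys),
        X=np.vstack(Xs),
        stratum_idx=np.concatenate(idxs).astype(np.int64),
        columns=list(columns),
        keys=[(s,) for s in range(n_strata)],
    )


def statsmodels_dummy_poisson(ss):
    """Independent oracle: unconditional Poisson ML with one dummy per
    stratum, quasi-Poisson (Pearson) scaled covariance."""
    import statsmodels.api as sm

    S = ss.n_strata
    dummies = np.zeros((ss.n_obs, S))
    dummies[np.arange(ss.n_obs), ss.stratum_idx] = 1.0
    design = np.hstack([dummies, ss.X])
    fit = sm.GLM(ss.y, design, family=sm.families.Poisson()).fit(
        scale="X2", maxiter=300, tol=1e-12
    )
    p = ss.X.shape[1]
    return {
        "beta": fit.params[S:],
        "se": fit.bse[S:],
        "dispersion": float(fit.scale),
    }
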