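"""Configuration-driven end-to-end pipeline.

Stages run in order: simulate (or ingest CSVs) -> exposure calendar ->
person-time / standardization / incidence rates -> case-crossover
strata (restricted to the warm-season analysis window) -> per-dataset
fits -> combined rIRR comparison.  Every run writes a provenance
manifest (config hash, seeds, library versions, per-stage row counts)
sufficient to reproduce outputs byte-for-byte.

Configuration is a YAML file validated by pydantic models; exactly one
of ``synthetic`` (generation parameters) or ``inputs`` (CSV paths) must
be present.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__, synthetic
from .ccx import StrataOptions, build_strata, fit_conditional_poisson, irr
from .comparison import fit_rirr
from .exposure import baseline_percentile, detect_heatwaves
from .population import (
    demographic_ratio_table,
    incidence_rate,
    person_time_from_enrollment,
    person_time_from_population,
    standardization_weights,
    standardize_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline"]


class ClimateSection(BaseModel):
    mean_tmax: float = 26.0
    seasonal_amplitude: float = 9.0
    ar1_rho: float = Field(0.7, ge=0.0, lt=1.0)
    noise_sd: float = Field(3.0, ge=0.0)
    rh_mean: float = 55.0
    rh_sd: float = Field(15.0, ge=0.0)
    rh_temp_corr: float = Field(-0.4, gt=-1.0, lt=1.0)

    def to_params(self) -> synthetic.ClimateParams:
        return synthetic.ClimateParams(**self.model_dump())


class SyntheticSection(BaseModel):
    n_counties: int = Field(12, ge=1)
    baseline_years: tuple[int, int] = (1999, 2010)
    study_years: list[int] = Field(default_factory=lambda: [2018, 2019])
    mean_population: float = Field(3e5, gt=0)
    coverage: float = Field(0.034, gt=0.0, le=1.0)
    true_irr_reference: float = Field(1.1, gt=0)
    true_irr_insured: float = Field(1.2, gt=0)
    overdispersion: float = Field(1.3, ge=1.0)
    baseline_rate: dict[str, float] = Field(default_factory=lambda: {"all-cause": 8e-4})
    climate: ClimateSection = Field(default_factory=ClimateSection)


class InputPaths(BaseModel):
    climate: str
    population: str
    enrollment: str
    counts: str
    baseline_years: tuple[int, int] = (1999, 2010)
    study_years: list[int]


class ExposureSection(BaseModel):
    quantile: float = Field(97.5, gt=0.0, lt=100.0)
    min_run: int = Field(2, ge=1)
    strict_exceed: bool = True
    variant: str = "hw_any"


class ModelSection(BaseModel):
    cause: str | None = None
    encounter_type: str | None = "ED"
    age_groups: list[str] | None = None
    use_standardized: bool = False
    include_age_sex_in_stratum: bool = False


class PipelineConfig(BaseModel):
    seed: int = 0
    output_dir: str = "heatccx_out"
    synthetic: SyntheticSection | None = None
    inputs: InputPaths | None = None
    exposure: ExposureSection = Field(default_factory=ExposureSection)
    model: ModelSection = Field(default_factory=ModelSection)
    holidays: list[str] | None = None
    strict: bool = True

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")
        return self

    @property
    def study_years(self) -> list[int]:
        src = self.synthetic or self.inputs
        return list(src.study_years)

    @property
    def baseline_years(self) -> tuple[int, int]:
        src = self.synthetic or self.inputs
        return tuple(src.baseline_years)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def validate_config(raw: dict | PipelineConfig) -> dict:
    """Check a raw config mapping; return {'errors': [...], 'warnings': [...]}.

    Field/range violations and missing input files are fatal errors;
    unusual-but-legal settings produce warnings.
    """
    errors: list[str] = []
    warnings: list[str] = []
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        try:
            cfg = PipelineConfig.model_validate(raw)
        except ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(x) for x in err["loc"])
                errors.append(f"{loc}: {err['msg']}")
            return {"errors": errors, "warnings": warnings}

    b0, b1 = cfg.baseline_years
    if b1 < b0:
        errors.append(f"baseline_years: inverted range ({b0}, {b1})")
    if cfg.inputs is not None:
        for name in ("climate", "population", "enrollment", "counts"):
            p = Path(getattr(cfg.inputs, name))
            if not p.is_file():
                errors.append(f"inputs.{name}: file not found: {p}")
        if not errors:
            clim_years = pd.to_datetime(
                pd.read_csv(cfg.inputs.climate, usecols=["date"])["date"]
            ).dt.year
            lo, hi = int(clim_years.min()), int(clim_years.max())
            if b0 < lo or b1 > hi:
                errors.append(
                    f"baseline_years: ({b0}, {b1}) outside climate coverage ({lo}, {hi})"
                )
            missing = set(cfg.study_years) - set(clim_years.unique())
            if missing:
                errors.append(f"study_years: {sorted(missing)} missing from climate")
    else:
        if b1 >= min(cfg.study_years):
            warnings.append("baseline period overlaps study years")
    if cfg.exposure.quantile < 50:
        warnings.append("exposure.quantile below the median is unusual for heat")
    return {"errors": errors, "warnings": warnings}


def _holiday_dates(cfg: PipelineConfig) -> list[pd.Timestamp]:
    if cfg.holidays is not None:
        return [pd.Timestamp(h) for h in cfg.holidays]
    return synthetic.default_holidays(cfg.study_years)


def _warm_season_index(years) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(
        np.concatenate(
            [pd.date_range(f"{y}-05-01", f"{y}-09-30", freq="D").values for y in years]
        )
    )


def run_pipeline(config: PipelineConfig, output_dir: str | None = None) -> dict:
    """Execute all stages; write artifacts and a provenance manifest.

    Returns a result bundle with the rates table, per-dataset fit
    results, the comparison result and the manifest.
    """
    report = validate_config(config)
    if report["errors"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "heatccx": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": {},
        "warnings": report["warnings"],
    }
    counts_rows = manifest["row_counts"]
    years = config.study_years
    holidays = _holiday_dates(config)

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage = _stage("simulate" if config.synthetic else "ingest")
        if config.synthetic is not None:
            s = config.synthetic
            counties = [f"C{i:03d}" for i in range(s.n_counties)]
            ss = np.random.SeedSequence(config.seed).spawn(3)
            seeds = [int(x.generate_state(1)[0] % (2**31)) for x in ss]
            manifest["component_seeds"] = dict(zip(("climate", "population", "counts"), seeds))
            climate = synthetic.generate_climate(
                counties,
                (f"{s.baseline_years[0]}-01-01", f"{max(years)}-12-31"),
                s.climate.to_params(),
                seed=seeds[0],
            )
            population, enrollment = synthetic.generate_population(
                counties, years, synthetic.CoverageParams(coverage=s.coverage),
                seed=seeds[1], mean_population=s.mean_population,
            )
        else:
            climate = pd.read_csv(config.inputs.climate, parse_dates=["date"])
            population = pd.read_csv(config.inputs.population)
            enrollment = pd.read_csv(config.inputs.enrollment)
        counts_rows["climate"] = len(climate)
        counts_rows["population"] = len(population)
        counts_rows["enrollment"] = len(enrollment)

        stage = _stage("exposure")
        thresholds = baseline_percentile(climate, config.baseline_years, config.exposure.quantile)
        calendar = detect_heatwaves(
            climate, thresholds, config.exposure.min_run, config.exposure.strict_exceed
        )
        counts_rows["calendar"] = len(calendar)
        thresholds.assign(
            quantile=config.exposure.quantile,
            baseline_start=config.baseline_years[0],
            baseline_end=config.baseline_years[1],
            method="linear",
        ).to_csv(out / "thresholds.csv", index=False)
        calendar.to_csv(out / "calendar.csv", index=False)

        stage = _stage("population")
        window = _warm_season_index(years)
        pt_ref = person_time_from_population(population, window)
        pt_ins = person_time_from_enrollment(enrollment, window)
        annual_enroll = enrollment.groupby(
            ["county", "age_group", "sex", "year"], as_index=False
        )["count"].mean()
        weights = standardization_weights(annual_enroll, population)
        weights.to_csv(out / "weights.csv", index=False)
        demographics = demographic_ratio_table(annual_enroll, population)
        demographics.to_csv(out / "demographics.csv", index=False)
        counts_rows["person_time_reference"] = len(pt_ref)
        counts_rows["person_time_insured"] = len(pt_ins)

        if config.synthetic is not None:
            stage = _stage("simulate-counts")
            s = config.synthetic
            effects = synthetic.EffectParams(
                log_irr_hw={
                    "reference": float(np.log(s.true_irr_reference)),
                    "insured": float(np.log(s.true_irr_insured)),
                },
                baseline_rate=dict(s.baseline_rate),
                overdispersion=s.overdispersion,
            )
            counts = synthetic.generate_encounters_by_dataset(
                calendar, climate,
                {"reference": pt_ref, "insured": pt_ins},
                effects=effects, holidays=holidays, seed=seeds[2],
            )
        else:
            counts = pd.read_csv(config.inputs.counts, parse_dates=["date"])
        counts_rows["counts"] = len(counts)

        stage = _stage("rates")
        rates = []
        for ds, pt in (("reference", pt_ref), ("insured", pt_ins)):
            sub = counts[counts["dataset"] == ds]
            r = incidence_rate(sub, pt, by=["cause", "encounter_type"])
            r.insert(0, "dataset", ds)
            rates.append(r)
        ins_std = standardize_counts(counts[counts["dataset"] == "insured"], weights)
        r = incidence_rate(ins_std, pt_ins, by=["cause", "encounter_type"])
        r.insert(0, "dataset", "insured_standardized")
        rates.append(r)
        rates = pd.concat(rates, ignore_index=True)
        rates.to_csv(out / "rates.csv", index=False)

        stage = _stage("strata")
        opts = dict(
            cause=config.model.cause,
            encounter_type=config.model.encounter_type,
            age_groups=config.model.age_groups,
            exposure=config.exposure.variant,
            years=years,
            include_age_sex_in_stratum=config.model.include_age_sex_in_stratum,
            strict=config.strict,
        )
        strata_ref = build_strata(
            counts, calendar, climate, holidays, StrataOptions(dataset="reference", **opts)
        )
        ins_counts = ins_std if config.model.use_standardized else counts
        strata_ins = build_strata(
            ins_counts, calendar, climate, holidays, StrataOptions(dataset="insured", **opts)
        )
        counts_rows["strata_reference"] = strata_ref.n_strata
        counts_rows["strata_insured"] = strata_ins.n_strata
        counts_rows["dropped_empty_strata"] = (
            strata_ref.n_dropped_empty + strata_ins.n_dropped_empty
        )

        stage = _stage("fit")
        exposure_col = "hw_any" if config.exposure.variant == "hw_any" else (
            "exceed_simple" if config.exposure.variant == "exceed_simple" else "hw_first"
        )
        comparison = fit_rirr(strata_ref, strata_ins, exposure_column=exposure_col)
        for label, fit in (
            ("reference", comparison.fit_reference),
            ("insured", comparison.fit_insured),
        ):
            d = fit.to_dict()
            d["irr"] = irr(fit, exposure_col)
            with open(out / f"fit_{label}.json", "w") as fh:
                json.dump(d, fh, indent=2)
        with open(out / "comparison.json", "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "rates": rates,
        "demographics": demographics,
        "comparison": comparison,
        "manifest": manifest,
        "output_dir": str(out),
    }
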