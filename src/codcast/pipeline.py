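"""End-to-end orchestration: screening -> prediction -> skill -> attribution.

A run is described by one YAML config (see :class:`RunConfig`).  Two input
modes exist: ``synthetic`` (a bundled scenario generator realizes the
dataset at run time) and ``files`` (prepared ``year,value`` CSVs for each
role).  Outputs are machine-readable tables -- a lag-correlation table, a
skill/benchmark table, retrospective and future forecast CSVs, an
attribution profile, and a plain-text report -- all deterministic under a
fixed seed (no timestamps inside report files; logging goes to stderr).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CodcastError, ConfigurationError
from .lags import LagCorrProfile, lagged_correlation, peak_lag
from .regression import (
    DiagnosticsReport,
    Forecast,
    diagnose,
    fit_model,
    predict,
)
from .series import AnnualSeries, align, highpass, read_series, to_anomalies, \
    detrend_linear
from .skill import MetricSummary, SkillReport, anomaly_correlation, \
    benchmark_comparison, cross_validate
from .synthetic import ScenarioConfig, default_config, make_scenario, \
    write_scenario

__all__ = [
    "RunConfig",
    "load_dataset",
    "run_screening",
    "run_prediction",
    "error_attribution",
    "run_highpass_skill",
    "run_all",
]

logger = logging.getLogger("codcast")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"                  # "synthetic" | "files"
    scenario: dict = field(default_factory=dict)   # ScenarioConfig overrides
    series_paths: dict = field(default_factory=dict)  # role -> path (files mode)
    predictand: str = "TSB"
    # series screened for lagged correlations, in pathway order
    screen_predictors: list[str] = field(
        default_factory=lambda: ["AMO", "FSC", "BSO"])
    # predictors of the regression model; all share `lead` unless `leads`
    # gives one lead per predictor
    predictors: list[str] = field(default_factory=lambda: ["AMO"])
    leads: list[int] | None = None
    harvest: str | None = "HR"
    baseline: tuple[int, int] | None = None  # None: full predictand span
    lag_range: tuple[int, int] = (0, 10)
    lead: int = 7
    cv_n_iter: int = 500
    cv_fit_frac: float = 0.8
    benchmark_lags: list[int] = field(default_factory=lambda: list(range(1, 8)))
    n_surrogates: int = 300
    alpha: float = 0.05
    detrend_screening: bool = True
    detrend_prediction: bool = False
    highpass_cutoff: int = 5
    attribution_lag_range: tuple[int, int] = (0, 5)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        cfg = cls(**data)
        for key in ("baseline", "lag_range", "attribution_lag_range"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        if not (cfg.lag_range[0] <= cfg.lead <= cfg.lag_range[1]):
            raise ConfigurationError(
                f"lead {cfg.lead} outside lag search range {cfg.lag_range}"
            )
        if cfg.leads is not None and len(cfg.leads) != len(cfg.predictors):
            raise ConfigurationError(
                f"leads {cfg.leads} must match predictors {cfg.predictors}"
            )
        return cfg

    def model_leads(self) -> list[int]:
        """Per-predictor leads; a common ``lead`` unless ``leads`` is set."""
        if self.leads is not None:
            return [int(l) for l in self.leads]
        return [int(self.lead)] * len(self.predictors)

    def scenario_config(self, seed: int | None = None) -> ScenarioConfig:
        data = {**asdict(default_config()), **self.scenario}
        if seed is not None:
            data["seed"] = int(seed)
        return ScenarioConfig.from_dict(data)


def _config_hash(path: str | Path | None) -> str:
    if path is None:
        return "builtin-defaults"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_dataset(config: RunConfig, seed: int | None = None,
                 ) -> dict[str, AnnualSeries]:
    """Realize (synthetic mode) or read (files mode) all input series."""
    if config.mode == "synthetic":
        dataset, _ = make_scenario(config.scenario_config(), seed=seed)
        return dataset
    if config.mode != "files":
        raise ConfigurationError(f"unknown mode {config.mode!r}")
    dataset = {}
    for name, path in config.series_paths.items():
        if not Path(path).exists():
            raise ConfigurationError(f"series file not found: {path}")
    for name, path in config.series_paths.items():
        dataset[name] = read_series(path, name=name)
    return dataset


def _prepare(series: AnnualSeries, config: RunConfig,
             for_prediction: bool) -> AnnualSeries:
    if config.baseline is not None:
        series = to_anomalies(series, *config.baseline)
    else:
        finite_years = series.years[series.mask]
        series = to_anomalies(series, int(finite_years[0]),
                              int(finite_years[-1]))
    if for_prediction and config.detrend_prediction:
        series = detrend_linear(series)
    return series


def run_screening(config: RunConfig, dataset: dict[str, AnnualSeries],
                  seed: int | None = None) -> pd.DataFrame:
    """Lagged-correlation table of every predictor against the predictand
    (and against each other predictor further down the pathway)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(config.screen_predictors)
    rows = []
    for i_x, x_name in enumerate(names):
        # screen only against series further down the pathway, then the
        # predictand -- leads are defined as the predictor leading
        for y_name in names[i_x + 1:] + [config.predictand]:
            profile = lagged_correlation(
                dataset[x_name], dataset[y_name],
                l_min=config.lag_range[0], l_max=config.lag_range[1],
                detrend=config.detrend_screening,
                n_surrogates=config.n_surrogates, alpha=config.alpha,
                rng=rng,
            )
            lag, r = peak_lag(profile)
            i = int(np.flatnonzero(profile.lags == lag)[0])
            rows.append({
                "predictor": x_name, "predictand": y_name,
                "peak_lag": lag, "peak_r": r,
                "n": int(profile.n[i]),
                "p": float(profile.p[i]) if profile.p is not None else np.nan,
                "significant": bool(profile.significant[i])
                if profile.significant is not None else None,
            })
    return pd.DataFrame(rows)


def run_prediction(config: RunConfig, dataset: dict[str, AnnualSeries],
                   seed: int | None = None,
                   ) -> tuple[Forecast, Forecast, SkillReport,
                              DiagnosticsReport]:
    """Cross-validated skill + full-data model + retrospective and future
    forecasts with 95% prediction intervals and ensemble spread."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    predictand = _prepare(dataset[config.predictand], config, True)
    predictors = {n: _prepare(dataset[n], config, True)
                  for n in config.predictors}
    design = align(predictand, list(zip(
        (predictors[n] for n in config.predictors), config.model_leads())))
    cv = cross_validate(design, n_iter=config.cv_n_iter,
                        fit_frac=config.cv_fit_frac, seed=rng)
    rc = cross_validate(design, n_iter=config.cv_n_iter,
                        fit_frac=config.cv_fit_frac, seed=rng,
                        shuffle_predictors=True, label="RC")
    report = cv.report
    report.rc = {"r": MetricSummary.from_samples(rc.r_pred),
                 "beta": MetricSummary.from_samples(rc.beta_pred)}
    for lag in config.benchmark_lags:
        past = predictand.values_at(design.years - lag)
        now = predictand.values_at(design.years)
        ok = np.isfinite(past) & np.isfinite(now)
        if ok.sum() >= 3:
            report.benchmarks[f"LP{lag}"] = anomaly_correlation(
                now[ok], past[ok])
    model = fit_model(design)
    diagnostics = diagnose(model, alpha=config.alpha)
    forecast = predict(model, predictors,
                       last_observed_year=int(predictand.years[
                           predictand.mask][-1]))
    # attach cross-validation ensemble spread on design years
    spread_low = np.full(len(forecast.years), np.nan)
    spread_high = np.full(len(forecast.years), np.nan)
    common, fi, di = np.intersect1d(forecast.years, cv.years,
                                    return_indices=True)
    spread_low[fi] = cv.prediction_spread_low[di]
    spread_high[fi] = cv.prediction_spread_high[di]
    forecast.spread_low = spread_low
    forecast.spread_high = spread_high
    retrospective_mask = ~forecast.future
    retrospective = Forecast(
        provenance=forecast.provenance,
        years=forecast.years[retrospective_mask],
        prediction=forecast.prediction[retrospective_mask],
        pi_half=forecast.pi_half[retrospective_mask],
        ci_half=forecast.ci_half[retrospective_mask],
        future=forecast.future[retrospective_mask],
        spread_low=spread_low[retrospective_mask],
        spread_high=spread_high[retrospective_mask],
    )
    future = Forecast(
        provenance=forecast.provenance,
        years=forecast.years[~retrospective_mask],
        prediction=forecast.prediction[~retrospective_mask],
        pi_half=forecast.pi_half[~retrospective_mask],
        ci_half=forecast.ci_half[~retrospective_mask],
        future=forecast.future[~retrospective_mask],
    )
    # full-record (non-cross-validated) retrospective skill, labelled apart
    obs = predictand.values_at(retrospective.years)
    report.benchmarks["full_fit_r"] = anomaly_correlation(
        obs, retrospective.prediction)
    return retrospective, future, report, diagnostics


def error_attribution(retrospective: Forecast, observed: AnnualSeries,
                      harvest: AnnualSeries,
                      lag_range: tuple[int, int] = (0, 5),
                      n_surrogates: int = 300, alpha: float = 0.05,
                      seed: np.random.Generator | int | None = None,
                      ) -> LagCorrProfile:
    """Lagged correlation of harvest-rate anomalies with the prediction
    error (observed minus predicted).

    Harvest leading the error by l years; a persistent under-harvest that
    lets the stock outgrow the hydrography-based prediction shows up as a
    negative correlation.  Significance flags control the family-wise error
    over the scanned lag window (max-|r| surrogate null), since the profile
    is searched for a peak.
    """
    error_series = retrospective.as_series("prediction_error")
    obs_vals = observed.values_at(error_series.years)
    error_series = error_series.with_values(obs_vals - error_series.values)
    overlap = np.isfinite(
        harvest.values_at(error_series.years)) & error_series.mask
    if overlap.sum() < 15:
        raise CodcastError(
            f"attribution needs >= 15 overlapping years, have "
            f"{int(overlap.sum())}"
        )
    return lagged_correlation(
        harvest, error_series, l_min=lag_range[0], l_max=lag_range[1],
        detrend=False, n_surrogates=n_surrogates, alpha=alpha,
        multiplicity="max", rng=np.random.default_rng(seed),
    )


def run_highpass_skill(retrospective: Forecast, observed: AnnualSeries,
                       cutoff: int = 5) -> tuple[float, float]:
    """(unfiltered r, high-pass r) between prediction and observation.

    A large drop after high-pass filtering shows the skill lives on
    multi-year (low-frequency) time scales.
    """
    pred = retrospective.as_series("prediction")
    obs_vals = observed.values_at(pred.years)
    r_full = anomaly_correlation(obs_vals, pred.values)
    obs_series = pred.with_values(obs_vals, name="observed")
    r_high = anomaly_correlation(
        highpass(obs_series, cutoff).values,
        highpass(pred, cutoff).values,
    )
    return r_full, r_high


# -- full run --------------------------------------------------------------


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_all(config: RunConfig, seed: int, out_dir: str | Path,
            config_path: str | Path | None = None) -> dict:
    """Execute the whole analysis and write a machine-readable report set.

    Returns a dict of the headline quantities (also written to
    ``report.txt``).  Deterministic for fixed config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    data_seed, screen_seed, pred_seed, attr_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(4)]
    logger.info("codcast %s | seed=%d | config=%s", __version__, seed,
                _config_hash(config_path))

    dataset = load_dataset(config, seed=data_seed)
    if config.mode == "synthetic":
        write_scenario(dataset, out / "data")

    logger.info("screening %d predictors", len(config.screen_predictors))
    screening = run_screening(config, dataset, seed=screen_seed)
    _write_frame(screening, out / "screening.csv")

    logger.info("prediction with lead %d", config.lead)
    retro, future, report, diagnostics = run_prediction(
        config, dataset, seed=pred_seed)
    _write_frame(retro.to_frame(), out / "forecast_retrospective.csv")
    _write_frame(future.to_frame(), out / "forecast_future.csv")
    _write_frame(report.summary_frame(), out / "skill.csv")
    (out / "diagnostics.txt").write_text(diagnostics.to_text() + "\n",
                                         encoding="utf-8")

    observed = _prepare(dataset[config.predictand], config, True)
    r_full, r_high = run_highpass_skill(retro, observed,
                                        config.highpass_cutoff)

    attribution_peak: tuple[int, float] | None = None
    if config.harvest and config.harvest in dataset:
        profile = error_attribution(
            retro, observed, _prepare(dataset[config.harvest], config, False),
            lag_range=config.attribution_lag_range,
            n_surrogates=config.n_surrogates, alpha=config.alpha,
            seed=attr_seed,
        )
        _write_frame(profile.to_frame(), out / "attribution.csv")
        attribution_peak = peak_lag(profile)

    headline = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config_path),
        "cv_median_r_prediction":
            report.metrics["prediction"]["r"].median,
        "cv_median_beta_prediction":
            report.metrics["prediction"]["beta"].median,
        "cv_median_r_fitting": report.metrics["fitting"]["r"].median,
        "full_fit_r": report.benchmarks["full_fit_r"],
        "rc_median_r": report.rc["r"].median if report.rc else None,
        "r_unfiltered": r_full,
        "r_highpass": r_high,
        "durbin_watson": diagnostics.durbin_watson,
        "last_forecast_year": int(future.years[-1]) if len(future.years)
        else None,
        "attribution_peak_lag": attribution_peak[0]
        if attribution_peak else None,
        "attribution_peak_r": attribution_peak[1]
        if attribution_peak else None,
    }
    lines = [f"{k}: {v:.10g}" if isinstance(v, float) else f"{k}: {v}"
             for k, v in headline.items()]
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    logger.info("report written to %s", out / "report.txt")
    return headline
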