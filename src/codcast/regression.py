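"""Lag-l multiple linear regression forecast models and benchmarks.

The prediction model is

    y_i = a0 + a1 x_{i-l,1} + ... + an x_{i-l,n} + e_i

with all predictors leading the predictand by a common number of years l
(the lead is what makes the forecast a genuine l-years-ahead prediction:
the last observed predictor year supports a forecast l years beyond it).
Fitting is ordinary least squares; 95% prediction intervals use the
standard OLS predictive variance (residual variance plus the parameter-
uncertainty term) with a two-sided t quantile.

Also here: successive-residualization orthogonalization (multicollinearity
guard), residual diagnostics (Durbin-Watson, normality, homoscedasticity),
the lag-l persistence benchmark, and the random-chance (shuffled-predictor)
null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CodcastError, RankDeficiencyError, SeriesLengthError
from .series import AlignedDesign, AnnualSeries

__all__ = [
    "RegressionModel",
    "DiagnosticsReport",
    "Forecast",
    "fit_model",
    "orthogonalize_predictors",
    "diagnose",
    "durbin_watson",
    "predict",
    "persistence_forecast",
    "shuffle_design",
    "random_chance_model",
]

_DEGENERATE_TOL = 1e-10


@dataclass
class RegressionModel:
    """A fitted lag-l OLS prediction model."""

    predictand: str
    predictor_names: list[str]
    leads: list[int]
    intercept: float
    coef: np.ndarray
    resid_sd: float              # sqrt(SSR / (n - p - 1))
    df_resid: int
    training_years: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    xtx_inv: np.ndarray          # (p+1, p+1) inverse Gram of [1 X]
    cond: float
    orthogonalized: bool = False
    transform: np.ndarray | None = None

    @property
    def n_obs(self) -> int:
        return len(self.training_years)

    def linear_predict(self, X: np.ndarray) -> np.ndarray:
        """Point prediction for raw predictor rows (original space)."""
        A = np.column_stack([np.ones(len(X)), X])
        if self.orthogonalized and self.transform is not None:
            A = A @ self.transform
        return A @ np.concatenate([[self.intercept], self.coef])

    def to_text(self) -> str:
        lines = [
            f"predictand: {self.predictand}",
            "predictors: " + ", ".join(
                f"{n} (lead {l})" for n, l in zip(self.predictor_names,
                                                 self.leads)),
            f"intercept: {self.intercept:.10g}",
            "coefficients: " + ", ".join(f"{c:.10g}" for c in self.coef),
            f"residual_sd: {self.resid_sd:.10g}",
            f"n_training_years: {self.n_obs}",
            f"training_years: {self.training_years[0]}-"
            f"{self.training_years[-1]}",
            f"condition_number: {self.cond:.6g}",
            f"orthogonalized: {self.orthogonalized}",
        ]
        return "\n".join(lines)


@dataclass
class DiagnosticsReport:
    """Residual validity checks for a fitted model.

    The Durbin-Watson statistic is ~2 for independent residuals and
    ~2(1 - rho1) under lag-1 autocorrelation rho1.
    """

    durbin_watson: float
    resid_ac1: float
    normality_stat: float
    normality_p: float
    homoscedasticity_r: float
    homoscedasticity_p: float
    independent: bool
    normal: bool
    homoscedastic: bool
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return self.independent and self.normal and self.homoscedastic

    def to_text(self) -> str:
        lines = [
            f"durbin_watson: {self.durbin_watson:.4f}",
            f"residual_lag1_autocorr: {self.resid_ac1:.4f}",
            f"independent: {self.independent}",
            f"normality_shapiro_W: {self.normality_stat:.4f} "
            f"(p={self.normality_p:.4f}) -> normal: {self.normal}",
            f"homoscedasticity_r: {self.homoscedasticity_r:.4f} "
            f"(p={self.homoscedasticity_p:.4f}) -> "
            f"homoscedastic: {self.homoscedastic}",
        ]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


@dataclass
class Forecast:
    """Point predictions with 95% intervals and optional ensemble spread."""

    provenance: str
    years: np.ndarray
    prediction: np.ndarray
    pi_half: np.ndarray | None = None     # full predictive interval
    ci_half: np.ndarray | None = None     # parameter-uncertainty term only
    future: np.ndarray | None = None      # True beyond last predictand year
    spread_low: np.ndarray | None = None
    spread_high: np.ndarray | None = None
    notices: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "prediction": self.prediction}
        if self.pi_half is not None:
            data["pi_low"] = self.prediction - self.pi_half
            data["pi_high"] = self.prediction + self.pi_half
        if self.spread_low is not None:
            data["spread_low"] = self.spread_low
            data["spread_high"] = self.spread_high
        if self.future is not None:
            data["future"] = self.future
        df = pd.DataFrame(data)
        df["provenance"] = self.provenance
        return df

    def as_series(self, name: str | None = None) -> AnnualSeries:
        if len(self.years) and not np.all(np.diff(self.years) == 1):
            years = np.arange(self.years[0], self.years[-1] + 1)
            values = np.full(len(years), np.nan)
            values[self.years - self.years[0]] = self.prediction
        else:
            years, values = self.years, self.prediction
        return AnnualSeries(name=name or self.provenance, years=years,
                            values=values)


# -- fitting ---------------------------------------------------------------


def fit_model(design: AlignedDesign, min_extra_rows: int = 10,
              ) -> RegressionModel:
    """Ordinary least squares fit of the lag-l regression on a design.

    Requires at least ``n_predictors + min_extra_rows`` rows; residual SD
    uses the unbiased n - p - 1 denominator.
    """
    n, p = design.n_rows, design.n_predictors
    if n < p + min_extra_rows:
        raise SeriesLengthError(
            f"{design.predictand}: {n} rows < {p} predictors + {min_extra_rows}"
        )
    A = design.augmented()
    coef, _, rank, _ = np.linalg.lstsq(A, design.y, rcond=None)
    if rank < p + 1:
        raise RankDeficiencyError(
            f"{design.predictand}: design rank {rank} < {p + 1}; "
            "orthogonalize_predictors() or drop a predictor"
        )
    fitted = A @ coef
    resid = design.y - fitted
    df_resid = n - p - 1
    resid_sd = float(np.sqrt(resid @ resid / df_resid)) if df_resid > 0 else 0.0
    return RegressionModel(
        predictand=design.predictand,
        predictor_names=list(design.predictor_names),
        leads=list(design.leads),
        intercept=float(coef[0]),
        coef=coef[1:].copy(),
        resid_sd=resid_sd,
        df_resid=df_resid,
        training_years=design.years.copy(),
        fitted=fitted,
        residuals=resid,
        xtx_inv=np.linalg.inv(A.T @ A),
        cond=float(np.linalg.cond(A)),
        orthogonalized=design.orthogonalized,
        transform=None if design.transform is None else design.transform.copy(),
    )


def orthogonalize_predictors(design: AlignedDesign) -> AlignedDesign:
    """Successive residualization in listed predictor order.

    Predictor k is replaced by its residual after OLS (with intercept) on
    predictors 1..k-1, so the resulting columns are mutually uncorrelated.
    The affine map from the original augmented design is stored so fitted
    models can still be applied to raw predictor values.  Residualization
    is order dependent; the listed order is authoritative.
    """
    if design.n_predictors < 2:
        raise CodcastError("orthogonalization needs >= 2 predictors")
    A = design.augmented()
    n, k_total = A.shape
    M = np.eye(k_total)
    X_new = A.copy()
    degenerate: list[str] = []
    for k in range(2, k_total):  # column 0 is the intercept, 1 is untouched
        prev = X_new[:, :k]
        gamma, *_ = np.linalg.lstsq(prev, X_new[:, k], rcond=None)
        X_new[:, k] = X_new[:, k] - prev @ gamma
        M[:, k] = M[:, k] - M[:, :k] @ gamma
        if np.sqrt(np.mean(X_new[:, k] ** 2)) < _DEGENERATE_TOL:
            degenerate.append(design.predictor_names[k - 1])
    return AlignedDesign(
        predictand=design.predictand,
        predictor_names=list(design.predictor_names),
        leads=list(design.leads),
        years=design.years.copy(),
        y=design.y.copy(),
        X=X_new[:, 1:],
        orthogonalized=True,
        degenerate=degenerate,
        transform=M,
    )


# -- diagnostics -----------------------------------------------------------


def durbin_watson(residuals: np.ndarray, years: np.ndarray | None = None,
                  ) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2 over consecutive-year pairs.

    If *years* has gaps, the numerator only sums differences within
    consecutive-year runs (the denominator uses all residuals).
    """
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise SeriesLengthError("Durbin-Watson needs >= 2 residuals")
    if years is None:
        diffs = np.diff(e)
    else:
        years = np.asarray(years)
        consec = np.diff(years) == 1
        diffs = np.diff(e)[consec]
    return float(np.sum(diffs ** 2) / np.sum(e ** 2))


def _lag1_autocorr(e: np.ndarray, years: np.ndarray | None = None) -> float:
    if years is None:
        pairs = np.column_stack([e[:-1], e[1:]])
    else:
        consec = np.diff(np.asarray(years)) == 1
        pairs = np.column_stack([e[:-1][consec], e[1:][consec]])
    if len(pairs) < 3:
        return float("nan")
    a, b = pairs[:, 0], pairs[:, 1]
    denom = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
    return float(np.sum((a - a.mean()) * (b - b.mean())) / denom)


def diagnose(model: RegressionModel, alpha: float = 0.05,
             ) -> DiagnosticsReport:
    """Residual validity checks: independence (Durbin-Watson / lag-1
    autocorrelation), normality (Shapiro-Wilk) and homoscedasticity
    (correlation of |residual| with fitted value)."""
    e = model.residuals
    if len(e) < 15:
        raise SeriesLengthError(
            f"diagnostics need >= 15 residuals, have {len(e)}"
        )
    years = model.training_years
    notes: list[str] = []
    if np.any(np.diff(years) != 1):
        notes.append("training years have gaps; DW over consecutive runs only")
    dw = durbin_watson(e, years)
    ac1 = _lag1_autocorr(e, years)
    # approximate 2-sigma band for a sample autocorrelation of white noise
    independent = bool(abs(ac1) < 2.0 / np.sqrt(len(e)))
    w_stat, w_p = stats.shapiro(e)
    h_r, h_p = stats.pearsonr(np.abs(e), model.fitted)
    return DiagnosticsReport(
        durbin_watson=dw,
        resid_ac1=ac1,
        normality_stat=float(w_stat),
        normality_p=float(w_p),
        homoscedasticity_r=float(h_r),
        homoscedasticity_p=float(h_p),
        independent=independent,
        normal=bool(w_p > alpha),
        homoscedastic=bool(h_p > alpha),
        alpha=alpha,
        notes=notes,
    )


# -- prediction ------------------------------------------------------------


def predict(model: RegressionModel,
            predictors: dict[str, AnnualSeries],
            target_years: np.ndarray | None = None,
            last_observed_year: int | None = None) -> Forecast:
    """Apply a fitted model: yhat_i = a0 + sum_n an x_{i-l_n,n}.

    Target years default to every year for which all lagged predictors
    exist, up to ``last predictor year + l`` -- the forecasts beyond
    *last_observed_year* (default: last training year) are flagged future.
    95% prediction-interval half-widths come from the OLS predictive
    variance ``s^2 (1 + x0' (X'X)^-1 x0)``; the parameter-only term is also
    reported (``ci_half``).  Years with a missing lagged predictor are
    omitted with a notice.
    """
    for name in model.predictor_names:
        if name not in predictors:
            raise CodcastError(f"missing predictor series {name!r}")
    if target_years is None:
        first = min(int(predictors[n].start_year) + l
                    for n, l in zip(model.predictor_names, model.leads))
        last = max(int(predictors[n].end_year) + l
                   for n, l in zip(model.predictor_names, model.leads))
        target_years = np.arange(first, last + 1)
    target_years = np.asarray(target_years, dtype=int)
    rows = np.column_stack([
        predictors[n].values_at(target_years - l)
        for n, l in zip(model.predictor_names, model.leads)
    ])
    complete = np.isfinite(rows).all(axis=1)
    notices = []
    if not complete.all():
        omitted = target_years[~complete]
        notices.append(f"omitted years with missing lagged predictors: "
                       f"{omitted.tolist()}")
    years = target_years[complete]
    X = rows[complete]
    A = np.column_stack([np.ones(len(X)), X])
    if model.orthogonalized and model.transform is not None:
        A = A @ model.transform
    beta = np.concatenate([[model.intercept], model.coef])
    yhat = A @ beta
    q = np.einsum("ij,jk,ik->i", A, model.xtx_inv, A)
    tq = stats.t.ppf(0.975, model.df_resid) if model.df_resid > 0 else np.nan
    pi_half = tq * model.resid_sd * np.sqrt(1.0 + q)
    ci_half = tq * model.resid_sd * np.sqrt(q)
    cutoff = (int(model.training_years[-1]) if last_observed_year is None
              else last_observed_year)
    return Forecast(
        provenance=f"model:{model.predictand}",
        years=years,
        prediction=yhat,
        pi_half=pi_half,
        ci_half=ci_half,
        future=years > cutoff,
        notices=notices,
    )


def persistence_forecast(observed: AnnualSeries, lag_l: int) -> Forecast:
    """Lag-l persistence: the forecast for year i is the observation at
    i - l.  The no-skill dynamical benchmark; carries no interval."""
    if lag_l < 1:
        raise CodcastError(f"persistence lag must be >= 1, got {lag_l}")
    years = np.arange(observed.start_year + lag_l,
                      observed.end_year + lag_l + 1)
    pred = observed.values_at(years - lag_l)
    keep = np.isfinite(pred)
    return Forecast(
        provenance=f"LP{lag_l}",
        years=years[keep],
        prediction=pred[keep],
        future=years[keep] > observed.end_year,
    )


def shuffle_design(design: AlignedDesign, rng: np.random.Generator,
                   ) -> AlignedDesign:
    """Independently permute each predictor column across rows (the
    predictand is untouched), suppressing predictor-predictand relations."""
    X = design.X.copy()
    for j in range(X.shape[1]):
        X[:, j] = X[rng.permutation(design.n_rows), j]
    return replace(design, X=X, years=design.years.copy(),
                   y=design.y.copy())


def random_chance_model(design: AlignedDesign,
                        seed: np.random.Generator | int | None = None,
                        ) -> RegressionModel:
    """Fit after shuffling predictor columns: the null-skill (RC) model."""
    rng = np.random.default_rng(seed)
    return fit_model(shuffle_design(design, rng))
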