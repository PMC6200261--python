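"""Forecast skill metrics and the Monte-Carlo cross-validation engine.

Skill is measured two ways:

* the anomaly correlation r between observations and predictions, and
* the Brier score  beta = 1 - var(error) / var(observed)

(a deterministic variance-ratio score, not the probabilistic Brier score
that shares the name): beta -> 1 for small errors, beta = 0 when the error
variance equals the predictand variance (a climatological-mean forecast),
and beta < 0 for forecasts worse than climatology.

The cross-validation engine repeatedly (default 1000x) draws a uniform
random 80% of the design rows to fit the regression and scores both the
fitting rows and the held-out 20% prediction rows, reporting medians and
inter-quartile ranges.  The same protocol drives the random-chance null
(predictor columns re-shuffled every iteration) and sits beside lagged
persistence benchmarks for side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CodcastError, RankDeficiencyError
from .series import AlignedDesign, AnnualSeries
from .lags import _pearson

__all__ = [
    "SkillReport",
    "CrossValidationResult",
    "brier_score",
    "anomaly_correlation",
    "cross_validate",
    "benchmark_comparison",
    "subsample_skill",
]

_MIN_PREDICTION_ROWS = 3
_REDRAW_FACTOR = 10


def brier_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    """beta = 1 - var(observed - predicted) / var(observed), ddof=1 both."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ok = np.isfinite(o) & np.isfinite(p)
    o, p = o[ok], p[ok]
    if len(o) < 3:
        raise CodcastError(f"Brier score needs >= 3 pairs, have {len(o)}")
    var_o = o.var(ddof=1)
    if var_o == 0:
        raise CodcastError("Brier score undefined: observed variance is 0")
    return float(1.0 - (o - p).var(ddof=1) / var_o)


def anomaly_correlation(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between paired observations and predictions."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ok = np.isfinite(o) & np.isfinite(p)
    o, p = o[ok], p[ok]
    if len(o) < 3:
        raise CodcastError(f"correlation needs >= 3 pairs, have {len(o)}")
    if o.std(ddof=1) == 0 or p.std(ddof=1) == 0:
        raise CodcastError("correlation undefined: zero variance")
    return _pearson(o, p)


@dataclass
class MetricSummary:
    median: float
    q25: float
    q75: float

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "MetricSummary":
        s = samples[np.isfinite(samples)]
        if s.size == 0:
            return cls(float("nan"), float("nan"), float("nan"))
        return cls(float(np.median(s)), float(np.quantile(s, 0.25)),
                   float(np.quantile(s, 0.75)))


@dataclass
class SkillReport:
    """Median / IQR of r and beta over resamples, per period, plus
    benchmark skills assembled for side-by-side reporting."""

    label: str
    n_iterations: int
    fit_frac: float
    seed: int | None
    metrics: dict[str, dict[str, MetricSummary]]  # period -> metric -> summary
    n_redraws: int = 0
    benchmarks: dict[str, float] = field(default_factory=dict)
    rc: dict[str, MetricSummary] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for period, metrics in self.metrics.items():
            for metric, s in metrics.items():
                rows.append({"source": self.label, "period": period,
                             "metric": metric, "median": s.median,
                             "q25": s.q25, "q75": s.q75})
        for metric, s in self.rc.items():
            rows.append({"source": "RC", "period": "prediction",
                         "metric": metric, "median": s.median,
                         "q25": s.q25, "q75": s.q75})
        for name, value in self.benchmarks.items():
            rows.append({"source": name, "period": "full", "metric": "r",
                         "median": value, "q25": np.nan, "q75": np.nan})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        return self.summary_frame().to_string(
            index=False, float_format=lambda v: f"{v:.6g}")


@dataclass
class CrossValidationResult:
    report: SkillReport
    coefficients: np.ndarray          # (n_iter, p+1) incl. intercept
    years: np.ndarray                 # design row years
    prediction_spread_low: np.ndarray
    prediction_spread_high: np.ndarray
    r_fit: np.ndarray
    r_pred: np.ndarray
    beta_fit: np.ndarray
    beta_pred: np.ndarray
    dw_fit: np.ndarray


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        return float("nan")
    return _pearson(a, b)


def _safe_beta(o: np.ndarray, p: np.ndarray) -> float:
    if len(o) < 3 or o.var(ddof=1) == 0:
        return float("nan")
    return float(1.0 - (o - p).var(ddof=1) / o.var(ddof=1))


def cross_validate(design: AlignedDesign, n_iter: int = 1000,
                   fit_frac: float = 0.8,
                   seed: np.random.Generator | int | None = None,
                   shuffle_predictors: bool = False,
                   label: str | None = None) -> CrossValidationResult:
    """Monte-Carlo 80/20 cross-validation of the lag-l regression.

    Each iteration draws a uniform random ``fit_frac`` subset of the rows
    (without replacement, non-contiguous years allowed), fits by OLS, and
    computes r and beta on the fitting rows and on the held-out rows.  An
    iteration whose held-out set is smaller than 3 rows or whose fit subset
    is rank-deficient is redrawn (counted, with a hard limit).  With
    ``shuffle_predictors=True`` every iteration independently permutes each
    predictor column first -- the random-chance (RC) protocol.
    """
    n, p = design.n_rows, design.n_predictors
    if n < 20:
        raise CodcastError(f"cross-validation needs >= 20 rows, have {n}")
    rng = np.random.default_rng(seed)
    m = int(round(fit_frac * n))
    if m >= n or n - m < _MIN_PREDICTION_ROWS:
        raise CodcastError(
            f"fit_frac {fit_frac} leaves {n - m} prediction rows (< "
            f"{_MIN_PREDICTION_ROWS})"
        )
    A = design.augmented()
    y = design.y
    coefs = np.empty((n_iter, p + 1))
    r_fit = np.empty(n_iter)
    r_pred = np.empty(n_iter)
    beta_fit = np.empty(n_iter)
    beta_pred = np.empty(n_iter)
    dw_fit = np.empty(n_iter)
    pred_low = np.full(n, np.inf)
    pred_high = np.full(n, -np.inf)
    redraws = 0
    it = 0
    while it < n_iter:
        if redraws > _REDRAW_FACTOR * n_iter:
            raise RankDeficiencyError(
                f"exceeded {_REDRAW_FACTOR * n_iter} redraws "
                "(rank-deficient or degenerate subsets)"
            )
        if shuffle_predictors:
            Ait = A.copy()
            for j in range(1, p + 1):
                Ait[:, j] = Ait[rng.permutation(n), j]
        else:
            Ait = A
        perm = rng.permutation(n)
        fit_idx, pred_idx = perm[:m], perm[m:]
        coef, _, rank, _ = np.linalg.lstsq(Ait[fit_idx], y[fit_idx],
                                           rcond=None)
        if rank < p + 1:
            redraws += 1
            continue
        yhat = Ait @ coef
        rf = _safe_r(y[fit_idx], yhat[fit_idx])
        rp = _safe_r(y[pred_idx], yhat[pred_idx])
        if not (np.isfinite(rf) and np.isfinite(rp)):
            redraws += 1
            continue
        coefs[it] = coef
        r_fit[it] = rf
        r_pred[it] = rp
        beta_fit[it] = _safe_beta(y[fit_idx], yhat[fit_idx])
        beta_pred[it] = _safe_beta(y[pred_idx], yhat[pred_idx])
        # DW over the fit subset in year order (rows are already sorted)
        e_sorted = (y - yhat)[np.sort(fit_idx)]
        dw_fit[it] = float(np.sum(np.diff(e_sorted) ** 2)
                           / np.sum(e_sorted ** 2))
        np.minimum(pred_low, yhat, out=pred_low)
        np.maximum(pred_high, yhat, out=pred_high)
        it += 1
    report = SkillReport(
        label=label or ("RC" if shuffle_predictors else design.predictand),
        n_iterations=n_iter,
        fit_frac=fit_frac,
        seed=seed if isinstance(seed, int) else None,
        metrics={
            "fitting": {"r": MetricSummary.from_samples(r_fit),
                        "beta": MetricSummary.from_samples(beta_fit)},
            "prediction": {"r": MetricSummary.from_samples(r_pred),
                           "beta": MetricSummary.from_samples(beta_pred)},
        },
        n_redraws=redraws,
    )
    return CrossValidationResult(
        report=report,
        coefficients=coefs,
        years=design.years.copy(),
        prediction_spread_low=pred_low,
        prediction_spread_high=pred_high,
        r_fit=r_fit,
        r_pred=r_pred,
        beta_fit=beta_fit,
        beta_pred=beta_pred,
        dw_fit=dw_fit,
    )


def benchmark_comparison(design: AlignedDesign, observed: AnnualSeries,
                         persistence_lags: tuple[int, ...] = tuple(range(1, 8)),
                         n_iter: int = 1000, fit_frac: float = 0.8,
                         seed: np.random.Generator | int | None = None,
                         ) -> SkillReport:
    """Model skill vs random chance vs lagged persistence, side by side.

    RC runs inside the same cross-validation protocol (fitting split and
    shuffle both redrawn every iteration).  Persistence skill at lag l is
    the correlation of the observed series with itself shifted by l years,
    evaluated over the design's year span.
    """
    rng = np.random.default_rng(seed)
    cv = cross_validate(design, n_iter=n_iter, fit_frac=fit_frac, seed=rng)
    rc = cross_validate(design, n_iter=n_iter, fit_frac=fit_frac, seed=rng,
                        shuffle_predictors=True, label="RC")
    report = cv.report
    report.rc = {
        "r": MetricSummary.from_samples(rc.r_pred),
        "beta": MetricSummary.from_samples(rc.beta_pred),
    }
    years = design.years
    for lag in persistence_lags:
        past = observed.values_at(years - lag)
        now = observed.values_at(years)
        ok = np.isfinite(past) & np.isfinite(now)
        report.benchmarks[f"LP{lag}"] = (
            _safe_r(now[ok], past[ok]) if ok.sum() >= 3 else float("nan")
        )
    return report


def subsample_skill(observed: np.ndarray, forecast: np.ndarray,
                    frac: float = 0.8, n: int = 1000,
                    seed: np.random.Generator | int | None = None,
                    ) -> tuple[float, tuple[float, float]]:
    """Correlation of an externally supplied forecast with observations,
    with uncertainty from n random ``frac`` subsamples of the paired years.

    Returns ``(median_r, (q25, q75))``.
    """
    o = np.asarray(observed, dtype=float)
    f = np.asarray(forecast, dtype=float)
    ok = np.isfinite(o) & np.isfinite(f)
    o, f = o[ok], f[ok]
    if len(o) < 15:
        raise CodcastError(f"subsample skill needs >= 15 pairs, have {len(o)}")
    rng = np.random.default_rng(seed)
    m = int(round(frac * len(o)))
    rs = np.empty(n)
    for i in range(n):
        idx = rng.permutation(len(o))[:m]
        rs[i] = _safe_r(o[idx], f[idx])
    s = MetricSummary.from_samples(rs)
    return s.median, (s.q25, s.q75)
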