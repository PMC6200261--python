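"""Lagged cross-correlation screening and surrogate significance testing.

A predictor x *leads* a predictand y by l years when x in year t-l pairs
with y in year t.  The screen computes the Pearson correlation r(l) over all
complete pairs at every lag in a window, identifies the peak |r|, and
assesses significance with a random-phase (Fourier surrogate) test that
preserves the predictor's autocorrelation -- the appropriate null for red
ocean-climate series, where a naive t-test badly overstates significance.

Two multiplicity modes are offered for profile-level significance:

``"per-lag"``
    each lag tested on its own (the convention behind per-cell significance
    stars in a lag table);
``"max"``
    the null is the distribution of max |r| over the scanned lag window,
    controlling the family-wise error when the profile is searched for a
    peak (used by the error-attribution step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CodcastError, SeriesLengthError
from .series import AnnualSeries

__all__ = [
    "LagCorrProfile",
    "SignificanceResult",
    "lagged_correlation",
    "peak_lag",
    "phase_randomize",
    "phase_randomize_values",
    "significance_test",
]


@dataclass
class LagCorrProfile:
    """Correlations r(l) for *predictor* leading *predictand* by l years.

    Lags where the overlap is below the minimum are marked unavailable
    (NaN r) rather than silently dropped.
    """

    predictor: str
    predictand: str
    lags: np.ndarray
    r: np.ndarray
    n: np.ndarray
    p: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float = 0.05
    critical_r: float | None = None
    multiplicity: str = "per-lag"

    @property
    def available(self) -> np.ndarray:
        return np.isfinite(self.r)

    def r_at(self, lag: int) -> float:
        idx = np.flatnonzero(self.lags == lag)
        if idx.size == 0:
            raise KeyError(f"lag {lag} not in profile")
        return float(self.r[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        data = {"lag": self.lags, "r": self.r, "n": self.n}
        if self.p is not None:
            data["p"] = self.p
            data["significant"] = self.significant
        return pd.DataFrame(data)


@dataclass
class SignificanceResult:
    r: float
    p: float
    critical_r: float
    n_surrogates: int

    def __iter__(self):  # allow  p, crit = result[1:]  style unpacking
        return iter((self.p, self.critical_r))


def _aligned_pair(x: AnnualSeries, y: AnnualSeries, lag: int,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete (x_{t-lag}, y_t) pairs with their predictand years."""
    xv = x.values_at(y.years - lag)
    both = np.isfinite(xv) & y.mask
    return xv[both], y.values[both], y.years[both]


def _detrend(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    tc = t - t.mean()
    slope, intercept = np.polyfit(tc, v, 1)
    return v - (slope * tc + intercept)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.dot(a - a.mean(), b - b.mean()) / ((len(a) - 1) * sa * sb))


def lagged_correlation(x: AnnualSeries, y: AnnualSeries,
                       l_min: int = 0, l_max: int = 10,
                       detrend: bool = True, min_overlap: int = 10,
                       n_surrogates: int = 0, alpha: float = 0.05,
                       multiplicity: str = "per-lag",
                       rng: np.random.Generator | int | None = None,
                       ) -> LagCorrProfile:
    """Pearson r(l) of (x_{t-l}, y_t) over complete pairs for each lag.

    With ``detrend=True`` (the screening convention) each aligned segment is
    linearly detrended against year before correlating.  Lags with fewer
    than *min_overlap* complete pairs are marked unavailable.  If
    *n_surrogates* > 0 a random-phase significance test is attached (see
    module docstring for the two *multiplicity* modes).
    """
    if l_min > l_max:
        raise CodcastError(f"l_min {l_min} > l_max {l_max}")
    lags = np.arange(l_min, l_max + 1)
    r = np.full(len(lags), np.nan)
    n = np.zeros(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        xv, yv, yrs = _aligned_pair(x, y, int(lag))
        n[i] = len(xv)
        if len(xv) < min_overlap:
            continue
        if detrend:
            xv = _detrend(xv, yrs)
            yv = _detrend(yv, yrs)
        r[i] = _pearson(xv, yv)
    profile = LagCorrProfile(predictor=x.name, predictand=y.name, lags=lags,
                             r=r, n=n, alpha=alpha, multiplicity=multiplicity)
    if n_surrogates > 0:
        _attach_significance(profile, x, y, detrend=detrend,
                             n_surrogates=n_surrogates, alpha=alpha,
                             multiplicity=multiplicity,
                             rng=np.random.default_rng(rng))
    return profile


def peak_lag(profile: LagCorrProfile) -> tuple[int, float]:
    """Lag maximizing |r(l)|; ties break toward the smallest lag.

    Returns ``(lag, r)`` with the sign of r preserved.
    """
    avail = profile.available
    if not avail.any():
        raise CodcastError(
            f"{profile.predictor}->{profile.predictand}: no available lags"
        )
    absr = np.where(avail, np.abs(profile.r), -np.inf)
    idx = int(np.argmax(absr))  # argmax returns the first (smallest-lag) max
    return int(profile.lags[idx]), float(profile.r[idx])


# -- random-phase surrogates ----------------------------------------------


def phase_randomize_values(values: np.ndarray,
                           rng: np.random.Generator,
                           size: int | None = None) -> np.ndarray:
    """Fourier surrogates: same amplitude spectrum, uniform random phases.

    The zero-frequency (mean) component and, for even length, the Nyquist
    component are left untouched so the output is real with the original
    sample mean and an identical periodogram.  With ``size=None`` one
    surrogate is returned as a 1-D array, otherwise a ``(size, n)`` matrix.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise CodcastError("phase randomization expects a 1-D array")
    if not np.all(np.isfinite(v)):
        raise CodcastError(
            "surrogates require gap-free input; interpolate or restrict first"
        )
    n = len(v)
    if n < 8:
        raise SeriesLengthError(f"series too short for surrogates (n={n} < 8)")
    spec = np.fft.rfft(v)
    n_freq = len(spec)
    # indices whose phase is free: everything but DC and (even n) Nyquist
    hi = n_freq - 1 if n % 2 == 0 else n_freq
    m = 1 if size is None else size
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(m, hi - 1))
    surr_spec = np.tile(spec, (m, 1)).astype(complex)
    surr_spec[:, 1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    out = np.fft.irfft(surr_spec, n=n, axis=1)
    return out[0] if size is None else out


def phase_randomize(series: AnnualSeries,
                    seed: np.random.Generator | int | None = None,
                    ) -> AnnualSeries:
    """Random-phase surrogate of a gap-free :class:`AnnualSeries`."""
    rng = np.random.default_rng(seed)
    if not series.mask.all():
        raise CodcastError(
            f"{series.name}: surrogates require gap-free input"
        )
    return series.with_values(phase_randomize_values(series.values, rng),
                              name=f"{series.name}_surrogate")


def _surrogate_corr_matrix(x: AnnualSeries, y: AnnualSeries,
                           lags: np.ndarray, detrend: bool,
                           n_surrogates: int, rng: np.random.Generator,
                           ) -> np.ndarray:
    """|r| of surrogate-x vs y at each lag: shape (n_surrogates, n_lags).

    Surrogates are built on the predictor's full gap-free span, preserving
    its autocorrelation, then run through the same alignment/correlation
    path as the observed series.
    """
    if not x.mask.all():
        # restrict to the longest gap-free run
        finite = np.flatnonzero(x.mask)
        runs = np.split(finite, np.flatnonzero(np.diff(finite) > 1) + 1)
        best = max(runs, key=len)
        x = AnnualSeries(x.name, x.years[best], x.values[best], x.units)
    surr = phase_randomize_values(x.values, rng, size=n_surrogates)
    out = np.full((n_surrogates, len(lags)), np.nan)
    for j, lag in enumerate(lags):
        xv = np.full(len(y.years), np.nan)
        src_years = y.years - int(lag)
        inside = (src_years >= x.start_year) & (src_years <= x.end_year)
        both_template = inside & y.mask
        if both_template.sum() < 3:
            continue
        idx = src_years[both_template] - x.start_year
        yv = y.values[both_template]
        yrs = y.years[both_template]
        if detrend:
            yv = _detrend(yv, yrs)
        xs = surr[:, idx]
        if detrend:
            tc = (yrs - yrs.mean()).astype(float)
            tc_norm = tc / np.dot(tc, tc)
            xs = xs - xs.mean(axis=1, keepdims=True)
            xs = xs - np.outer(xs @ tc_norm, tc)
        else:
            xs = xs - xs.mean(axis=1, keepdims=True)
        yc = yv - yv.mean()
        denom = np.sqrt((xs ** 2).sum(axis=1) * (yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = (xs @ yc) / denom
    return out


def _attach_significance(profile: LagCorrProfile, x: AnnualSeries,
                         y: AnnualSeries, detrend: bool, n_surrogates: int,
                         alpha: float, multiplicity: str,
                         rng: np.random.Generator) -> None:
    surr = np.abs(_surrogate_corr_matrix(x, y, profile.lags, detrend,
                                         n_surrogates, rng))
    p = np.full(len(profile.lags), np.nan)
    avail = profile.available
    if multiplicity == "max":
        with np.errstate(invalid="ignore"):
            null = np.nanmax(surr, axis=1)
        ok = np.isfinite(null)
        null = null[ok]
        for i in np.flatnonzero(avail):
            p[i] = (1 + np.sum(null >= abs(profile.r[i]))) / (1 + len(null))
        profile.critical_r = float(np.quantile(null, 1 - alpha))
    elif multiplicity == "per-lag":
        for i in np.flatnonzero(avail):
            col = surr[:, i]
            col = col[np.isfinite(col)]
            if col.size == 0:
                continue
            p[i] = (1 + np.sum(col >= abs(profile.r[i]))) / (1 + col.size)
    else:
        raise CodcastError(f"unknown multiplicity mode {multiplicity!r}")
    profile.p = p
    profile.significant = np.where(np.isfinite(p), p <= alpha, False)


def significance_test(x: AnnualSeries, y: AnnualSeries, lag: int,
                      n_surrogates: int = 1000, alpha: float = 0.05,
                      detrend: bool = True,
                      seed: np.random.Generator | int | None = None,
                      ) -> SignificanceResult:
    """Random-phase test of the lag-*lag* correlation of x leading y.

    The null distribution of r is built by correlating phase-randomized
    surrogates of the predictor against the observed predictand at the same
    lag; two-sided p uses the standard +1 continuity correction,
    ``p = (1 + #{|r_surr| >= |r_obs|}) / (1 + n_surrogates)``.
    ``critical_r`` is the (1-alpha) quantile of |r_surr|.
    """
    rng = np.random.default_rng(seed)
    xv, yv, yrs = _aligned_pair(x, y, lag)
    if len(xv) < 10:
        raise SeriesLengthError(
            f"only {len(xv)} overlapping years at lag {lag} (need >= 10)"
        )
    if detrend:
        xv_d = _detrend(xv, yrs)
        yv_d = _detrend(yv, yrs)
    else:
        xv_d, yv_d = xv, yv
    r_obs = _pearson(xv_d, yv_d)
    surr = phase_randomize_values(xv, rng, size=n_surrogates)
    if detrend:
        tc = (yrs - yrs.mean()).astype(float)
        tc_norm = tc / np.dot(tc, tc)
        surr = surr - surr.mean(axis=1, keepdims=True)
        surr = surr - np.outer(surr @ tc_norm, tc)
    else:
        surr = surr - surr.mean(axis=1, keepdims=True)
    yc = yv_d - yv_d.mean()
    denom = np.sqrt((surr ** 2).sum(axis=1) * (yc ** 2).sum())
    r_surr = np.abs((surr @ yc) / denom)
    p = float((1 + np.sum(r_surr >= abs(r_obs))) / (1 + n_surrogates))
    return SignificanceResult(r=float(r_obs), p=p,
                              critical_r=float(np.quantile(r_surr, 1 - alpha)),
                              n_surrogates=n_surrogates)
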