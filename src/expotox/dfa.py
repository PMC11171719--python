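"""Seasonal decomposition and dynamic factor analysis of pollutant series.

Environmental channels are first split into trend + seasonal + remainder by
the classical additive moving-average decomposition (y_t = trend_t +
seasonal_t + remainder_t); the deseasonalized series (trend + remainder) is
then modelled with a dynamic factor analysis (DFA): a state-space model in
which the channels load on a small number of random-walk common trends,

    y_t = Z f_t + D x_t + eps_t,   eps_t ~ N(0, diag(R))
    f_t = f_{t-1} + eta_t,         eta_t ~ N(0, I_m)

estimated by EM (Kalman filter/RTS smoother E-step, closed-form M-step for
the loadings Z, regression coefficients D and observation variances R; the
transition is fixed at the identity with unit state noise for
identification).  The number of common trends m is selected by the Akaike
Information Criterion AIC = 2 m' - 2 ln L, with the Nash-Sutcliffe
efficiency Ceff = 1 - sum(o - s)^2 / sum(o - mean(o))^2 reported per channel
as the goodness-of-fit measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import seasonal_decompose as _sm_decompose


# ---------------------------------------------------------------------------
# classical additive decomposition


@dataclass
class DecompResult:
    """Per-channel additive decomposition; the identity
    observed = trend + seasonal + remainder holds exactly."""

    observed: pd.DataFrame
    trend: pd.DataFrame
    seasonal: pd.DataFrame
    remainder: pd.DataFrame
    period: int

    @property
    def deseasonalized(self) -> pd.DataFrame:
        return self.trend + self.remainder


def seasonal_decompose(series: pd.DataFrame | pd.Series,
                       period: int) -> DecompResult:
    """Classical additive decomposition of each channel.

    Trend is the centred moving average of window ``period`` (linearly
    extrapolated at the edges so the additive identity holds over the full
    span); seasonal is the re-centred period-position mean of the detrended
    series; remainder is the residual.
    """
    if isinstance(series, pd.Series):
        series = series.to_frame()
    if len(series) < 2 * period:
        raise ValueError("series length must be at least 2*period")
    trend, seas, resid = {}, {}, {}
    for col in series.columns:
        res = _sm_decompose(series[col], model="additive", period=period,
                            extrapolate_trend="freq")
        trend[col], seas[col], resid[col] = res.trend, res.seasonal, res.resid
    mk = lambda d: pd.DataFrame(d, index=series.index, columns=series.columns)
    return DecompResult(observed=series.copy(), trend=mk(trend),
                        seasonal=mk(seas), remainder=mk(resid), period=period)


def deseasonalize(result: DecompResult) -> pd.DataFrame:
    """Trend + remainder: the series with the seasonal component removed."""
    return result.deseasonalized


# ---------------------------------------------------------------------------
# fit metrics


def nse(observed, simulated) -> float:
    """Nash-Sutcliffe efficiency; 1 for a perfect fit, 0 for predicting the
    observed mean, unbounded below."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size < 2:
        raise ValueError("observed and simulated must be aligned, length >= 2")
    denom = np.sum((o - o.mean()) ** 2)
    if denom == 0:
        raise ValueError("Nash-Sutcliffe undefined for constant observations")
    return float(1.0 - np.sum((o - s) ** 2) / denom)


def aic(m_prime: int, log_likelihood: float) -> float:
    """AIC = 2 m' - 2 ln L for a model with m' free parameters."""
    if m_prime < 1:
        raise ValueError("m_prime must be >= 1")
    return 2.0 * m_prime - 2.0 * log_likelihood


# ---------------------------------------------------------------------------
# dynamic factor model (random-walk common trends, EM)


def _kalman_pass(y, Z, D, R, X, kappa):
    """Kalman filter + RTS smoother for the random-walk-trend model.

    Returns (loglik, smoothed means m x T, smoothed covariances T x m x m).
    Missing values are not supported (generators never produce them).
    """
    N, T = y.shape
    m = Z.shape[1]
    Im = np.eye(m)
    reg = (D @ X) if X is not None else np.zeros((N, T))

    mf = np.zeros((T, m))        # filtered means
    Pf = np.zeros((T, m, m))     # filtered covs
    mp = np.zeros((T, m))        # one-step predictions
    Pp = np.zeros((T, m, m))
    loglik = 0.0
    m_prev = np.zeros(m)
    P_prev = kappa * Im
    for t in range(T):
        if t == 0:
            m_pred, P_pred = m_prev, P_prev
        else:
            m_pred, P_pred = mf[t - 1], Pf[t - 1] + Im
        mp[t], Pp[t] = m_pred, P_pred
        v = y[:, t] - Z @ m_pred - reg[:, t]
        S = Z @ P_pred @ Z.T + np.diag(R)
        Sinv = np.linalg.inv(S)
        K = P_pred @ Z.T @ Sinv
        mf[t] = m_pred + K @ v
        Pf[t] = (Im - K @ Z) @ P_pred
        sign, logdet = np.linalg.slogdet(S)
        loglik += -0.5 * (N * np.log(2 * np.pi) + logdet + v @ Sinv @ v)

    ms = np.zeros((T, m))
    Ps = np.zeros((T, m, m))
    ms[-1], Ps[-1] = mf[-1], Pf[-1]
    for t in range(T - 2, -1, -1):
        J = Pf[t] @ np.linalg.inv(Pp[t + 1])
        ms[t] = mf[t] + J @ (ms[t + 1] - mp[t + 1])
        Ps[t] = Pf[t] + J @ (Ps[t + 1] - Pp[t + 1]) @ J.T
    return float(loglik), ms.T, Ps


@dataclass
class DFAResults:
    """Fitted dynamic factor model: estimates, fit measures, diagnostics."""

    model: "DynamicFactorTrends"
    loadings: pd.DataFrame           # channels x trends (Z)
    trends: pd.DataFrame             # common trends, T x m
    exog_coef: pd.DataFrame | None   # channels x regressors (D)
    noise_variances: pd.Series       # diagonal of R
    log_likelihood: float
    loglik_path: np.ndarray
    n_params: int
    converged: bool
    n_iter: int

    @property
    def aic(self) -> float:
        return aic(self.n_params, self.log_likelihood)

    @property
    def fitted(self) -> pd.DataFrame:
        """Smoothed fit Z f_t (+ D x_t), on the standardized scale."""
        fit = self.trends.to_numpy() @ self.loadings.to_numpy().T
        if self.exog_coef is not None:
            fit = fit + self.model._X.T @ self.exog_coef.to_numpy().T
        return pd.DataFrame(fit, index=self.model.endog.index,
                            columns=self.model.endog.columns)

    @property
    def ceff(self) -> pd.Series:
        """Per-channel Nash-Sutcliffe efficiency of the smoothed fit."""
        y = self.model._y
        f = self.fitted.to_numpy().T
        return pd.Series(
            [nse(y[i], f[i]) for i in range(y.shape[0])],
            index=self.model.endog.columns, name="ceff")

    def summary(self) -> str:
        lines = [
            "Dynamic factor analysis (random-walk common trends, EM)",
            f"  channels: {self.loadings.shape[0]}   common trends: "
            f"{self.loadings.shape[1]}   observations: {self.trends.shape[0]}",
            f"  log-likelihood: {self.log_likelihood:.3f}   "
            f"AIC: {self.aic:.3f}   params: {self.n_params}",
            f"  EM iterations: {self.n_iter}   converged: {self.converged}",
            "", "  Loadings:", self.loadings.round(3).to_string(),
            "", "  Per-channel Nash-Sutcliffe efficiency:",
            self.ceff.round(3).to_string(),
        ]
        return "\n".join(lines)


class DynamicFactorTrends:
    """Dynamic factor model with m random-walk common trends.

    Parameters
    ----------
    endog : DataFrame
        Deseasonalized channels (time x channels).  Standardized to zero
        mean and unit variance before estimation unless ``standardize`` is
        False (conventional for factor models).
    m_trends : int
        Number of common trends (1 <= m <= number of channels).
    exog : DataFrame, optional
        Explanatory channels entering the observation equation.
    """

    def __init__(self, endog: pd.DataFrame, m_trends: int,
                 exog: pd.DataFrame | None = None, standardize: bool = True,
                 diffuse_scale: float = 1e2):
        if not 1 <= m_trends <= endog.shape[1]:
            raise ValueError("m_trends must be in [1, n_channels]")
        self.endog = endog
        self.m_trends = m_trends
        self.exog = exog
        self.standardize = standardize
        self.diffuse_scale = diffuse_scale
        y = endog.to_numpy(float).T
        if standardize:
            self._mean = y.mean(axis=1, keepdims=True)
            self._sd = y.std(axis=1, keepdims=True)
            y = (y - self._mean) / self._sd
        self._y = y
        if exog is not None:
            x = exog.to_numpy(float).T
            x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
            self._X = x
        else:
            self._X = None

    def fit(self, max_iter: int = 500, tol: float = 1e-6,
            seed: int = 0) -> DFAResults:
        """Run EM to convergence of the log-likelihood (absolute tolerance
        ``tol``, iteration cap ``max_iter``; non-convergence returns the best
        iterate with ``converged=False``)."""
        y = self._y
        N, T = y.shape
        m = self.m_trends
        X = self._X
        k = 0 if X is None else X.shape[0]
        rng = np.random.default_rng(seed)

        # init loadings from principal components, small jitter to break ties
        u, s, vt = np.linalg.svd(y, full_matrices=False)
        Z = u[:, :m] * (s[:m] / np.sqrt(T)) + 0.01 * rng.standard_normal((N, m))
        D = np.zeros((N, k)) if k else None
        R = np.full(N, 0.5)

        path = []
        converged = False
        for it in range(max_iter):
            ll, ms, Ps = _kalman_pass(y, Z, D, R, X, self.diffuse_scale)
            path.append(ll)
            if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
                converged = True
                break
            # M-step: regress y on [f; x] with expected moments
            S_ff = ms @ ms.T + Ps.sum(axis=0)
            S_yf = y @ ms.T
            if k:
                S_fx = ms @ X.T
                S_xx = X @ X.T
                G = np.block([[S_ff, S_fx], [S_fx.T, S_xx]])
                H = np.hstack([S_yf, y @ X.T])
                W = H @ np.linalg.inv(G)
                Z, D = W[:, :m], W[:, m:]
                C = np.vstack([ms, X])
            else:
                W = S_yf @ np.linalg.inv(S_ff)
                Z = W
                C = ms
            resid = y - W @ C
            # E[(y - W c)^2] adds the smoothed state covariance term
            cov_term = np.einsum("ij,tjk,ik->i", W[:, :m], Ps, W[:, :m])
            R = (np.sum(resid ** 2, axis=1) + cov_term) / T
            R = np.maximum(R, 1e-8)

        ll, ms, Ps = _kalman_pass(y, Z, D, R, X, self.diffuse_scale)
        path.append(ll)
        n_params = N * m + N * k + N
        return DFAResults(
            model=self,
            loadings=pd.DataFrame(Z, index=self.endog.columns,
                                  columns=[f"trend_{j+1}" for j in range(m)]),
            trends=pd.DataFrame(ms.T, index=self.endog.index,
                                columns=[f"trend_{j+1}" for j in range(m)]),
            exog_coef=None if not k else pd.DataFrame(
                D, index=self.endog.columns, columns=list(self.exog.columns)),
            noise_variances=pd.Series(R, index=self.endog.columns),
            log_likelihood=ll,
            loglik_path=np.asarray(path),
            n_params=n_params,
            converged=converged,
            n_iter=len(path) - 1,
        )


def fit_dfa(deseasonalized: pd.DataFrame, m_trends: int,
            exog: pd.DataFrame | None = None, **fit_kw) -> DFAResults:
    """Convenience wrapper: build and fit a ``DynamicFactorTrends`` model."""
    return DynamicFactorTrends(deseasonalized, m_trends, exog=exog).fit(**fit_kw)


def select_trends(deseasonalized: pd.DataFrame, m_candidates,
                  exog: pd.DataFrame | None = None, **fit_kw
                  ) -> tuple[int, pd.DataFrame, dict[int, DFAResults]]:
    """Fit each candidate trend count and choose the AIC minimiser
    (ties broken toward the smaller m).

    Returns (chosen m, report table with AIC and mean Ceff per candidate,
    dict of fitted results).
    """
    cands = list(m_candidates)
    if not cands:
        raise ValueError("candidate list must be non-empty")
    fits = {m: fit_dfa(deseasonalized, m, exog=exog, **fit_kw) for m in cands}
    report = pd.DataFrame({
        "m": cands,
        "aic": [fits[m].aic for m in cands],
        "log_likelihood": [fits[m].log_likelihood for m in cands],
        "mean_ceff": [fits[m].ceff.mean() for m in cands],
    }).set_index("m")
    best = min(sorted(cands), key=lambda m: (fits[m].aic, m))
    return best, report, fits


def simulate_trend_panel(n_channels: int, m_trends: int, n_obs: int,
                         noise_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Simulate a panel driven by ``m_trends`` random-walk common trends:
    y_t = Z f_t + noise, for testing trend-count recovery."""
    rng = np.random.default_rng(seed)
    f = np.cumsum(rng.standard_normal((m_trends, n_obs)), axis=1)
    Z = rng.uniform(0.5, 1.5, size=(n_channels, m_trends))
    Z *= rng.choice([-1.0, 1.0], size=Z.shape)
    y = Z @ f + rng.normal(0.0, noise_sd, size=(n_channels, n_obs))
    return pd.DataFrame(y.T, columns=[f"ch{i+1}" for i in range(n_channels)])
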