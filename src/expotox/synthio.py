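"""Synthetic environmental series and linked health-examination panels.

The generators emulate the two data sources the pipeline consumes: a
time-indexed multichannel environmental monitoring table (pollutant and
meteorology channels such as PM2.5, SO2, temperature) and a
health-examination table (one row per exam record, a numeric feature block
plus binary indicator-positivity labels and a timestamp).  Every downstream
stage is testable against these panels because the exposure–indicator
structure is planted with a known sign and strength.

Each environmental channel follows the additive structure

    y_t = baseline + trend_slope * t + A * sin(2*pi*t/period + phase) + e_t

with Gaussian noise ``e_t`` — i.e. exactly the trend + seasonal + remainder
split the decomposition stage assumes.  Indicator positivity is Bernoulli
with a logistic dose–response on the standardized trailing-window mean of a
chosen exposure channel; the slope is calibrated by root finding so that the
Pearson correlation between window-mean exposure and positivity matches a
requested value (e.g. the three-positive / one-negative / one-null sign
pattern of the reference cohort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


class UnachievableCorrelationError(ValueError):
    """Requested exposure–indicator correlation exceeds what a logistic
    dose–response can produce at the given base positivity."""

    def __init__(self, requested: float, achievable: float):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"planted correlation {requested:+.3f} is unachievable; the "
            f"logistic link tops out at |r| ~= {achievable:.3f} for this "
            "base positivity"
        )


@dataclass
class EnvGenConfig:
    """Configuration for the environmental-series generator.

    Per-channel parameters may be given as a scalar (broadcast to all
    channels) or a mapping ``{channel: value}``.
    """

    n_days: int = 730
    channels: tuple[str, ...] = (
        "pm25", "so2", "temperature", "humidity", "light", "wind", "wqi",
    )
    period: int = 365
    trend_slope: float | dict = 0.0
    seasonal_amplitude: float | dict = 10.0
    noise_sd: float | dict = 2.0
    baseline: float | dict = 50.0
    start: str = "2019-01-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_days <= 0 or self.period <= 0:
            raise ConfigError("n_days and period must be positive")
        if self.n_days < 2 * self.period:
            raise ConfigError("n_days must be at least 2*period")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channel names must be unique")
        for name in ("trend_slope", "seasonal_amplitude", "noise_sd", "baseline"):
            val = getattr(self, name)
            if np.isscalar(val):
                setattr(self, name, {c: float(val) for c in self.channels})
            else:
                missing = set(self.channels) - set(val)
                if missing:
                    raise ConfigError(f"{name} missing channels: {sorted(missing)}")
        for c in self.channels:
            if self.noise_sd[c] < 0 or self.seasonal_amplitude[c] < 0:
                raise ConfigError("noise_sd and seasonal_amplitude must be >= 0")


@dataclass
class EnvSeries:
    """Observed multichannel environmental series plus its true components."""

    observed: pd.DataFrame
    trend: pd.DataFrame
    seasonal: pd.DataFrame
    noise: pd.DataFrame

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.observed.index

    @property
    def channels(self) -> list[str]:
        return list(self.observed.columns)

    def to_csv(self, path) -> None:
        out = self.observed.copy()
        out.index.name = "date"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EnvSeries":
        obs = pd.read_csv(path, index_col="date", parse_dates=True)
        zeros = obs * 0.0
        return cls(observed=obs, trend=zeros.copy(), seasonal=zeros.copy(),
                   noise=zeros.copy())


def generate_env(cfg: EnvGenConfig) -> EnvSeries:
    """Simulate the environmental monitoring table.

    Each channel is baseline + linear trend + sinusoidal seasonal cycle of
    the configured period (with a per-channel phase, evenly spaced over the
    cycle so channels are not degenerate copies) + iid Gaussian noise.
    Reproducible for a fixed seed; the true components are returned alongside
    the observed series.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_days, dtype=float)
    index = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    trend, seasonal, noise, obs = {}, {}, {}, {}
    for i, c in enumerate(cfg.channels):
        phase = 2.0 * np.pi * i / max(len(cfg.channels), 1)
        trend[c] = cfg.baseline[c] + cfg.trend_slope[c] * t
        seasonal[c] = cfg.seasonal_amplitude[c] * np.sin(
            2.0 * np.pi * t / cfg.period + phase)
        noise[c] = rng.normal(0.0, cfg.noise_sd[c], size=cfg.n_days)
        obs[c] = trend[c] + seasonal[c] + noise[c]
    mk = lambda d: pd.DataFrame(d, index=index, columns=list(cfg.channels))
    return EnvSeries(observed=mk(obs), trend=mk(trend), seasonal=mk(seasonal),
                     noise=mk(noise))


@dataclass
class IndicatorSpec:
    """One planted indicator: name, target exposure–positivity Pearson r,
    and marginal positivity rate."""

    name: str
    planted_r: float
    base_positivity: float

    def __post_init__(self):
        if not -1.0 <= self.planted_r <= 1.0:
            raise ConfigError("planted_r must lie in [-1, 1]")
        if not 0.0 < self.base_positivity < 1.0:
            raise ConfigError("base_positivity must lie in (0, 1)")


@dataclass
class HealthGenConfig:
    """Configuration for the linked health-examination panel."""

    n_records: int = 5000
    n_features: int = 100
    indicators: tuple[IndicatorSpec, ...] = (
        IndicatorSpec("CKMB", 0.435, 0.18),
        IndicatorSpec("LDH", 0.254, 0.20),
        IndicatorSpec("CRP", 0.481, 0.38),
        IndicatorSpec("CYFRA21_1", -0.597, 0.22),
        IndicatorSpec("NSE", 0.0, 0.10),
    )
    label_dependence: float = 0.3
    exposure_channel: str = "pm25"
    exposure_window_days: int = 7
    feature_label_loading: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 100:
            raise ConfigError("n_records must be at least 100")
        if self.n_features <= 0 or self.exposure_window_days <= 0:
            raise ConfigError("n_features and exposure_window_days must be positive")
        if not 0.0 <= self.label_dependence <= 1.0:
            raise ConfigError("label_dependence must lie in [0, 1]")
        self.indicators = tuple(
            i if isinstance(i, IndicatorSpec) else IndicatorSpec(*i)
            for i in self.indicators
        )


@dataclass
class HealthTable:
    """Exam records: numeric feature block, binary multi-label indicator
    block, timestamps, and (when generated) the true window-mean exposure."""

    features: pd.DataFrame
    labels: pd.DataFrame
    timestamps: pd.Series
    exposure: pd.Series | None = None
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.features)

    @property
    def label_names(self) -> list[str]:
        return list(self.labels.columns)

    def to_csv(self, path) -> None:
        out = pd.concat(
            [self.timestamps.rename("date"), self.features,
             self.labels.add_prefix("label_")], axis=1)
        out.index.name = "record_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "HealthTable":
        df = pd.read_csv(path, index_col="record_id", parse_dates=["date"])
        label_cols = [c for c in df.columns if c.startswith("label_")]
        feat_cols = [c for c in df.columns if c not in label_cols + ["date"]]
        return cls(features=df[feat_cols],
                   labels=df[label_cols].rename(
                       columns=lambda c: c[len("label_"):]).astype(int),
                   timestamps=df["date"])


def _window_mean_exposure(env: EnvSeries, channel: str, dates: pd.DatetimeIndex,
                          window_days: int) -> np.ndarray:
    """Trailing window-mean of one channel ending at each record date."""
    series = env.observed[channel]
    rolled = series.rolling(window_days, min_periods=window_days).mean()
    return rolled.reindex(dates).to_numpy()


def _point_biserial(z: np.ndarray, p: np.ndarray) -> float:
    """Expected Pearson r between z and Y ~ Bernoulli(p(z)), given the
    realized sample of z (Y independent across records given p)."""
    pbar = p.mean()
    cov = np.mean(z * p) - z.mean() * pbar
    var_y = np.mean(p * (1.0 - p)) + np.var(p)
    if var_y <= 0:
        return 0.0
    return cov / np.sqrt(np.var(z) * var_y)


def _calibrate_link(z: np.ndarray, u: np.ndarray, gamma: float,
                    base_positivity: float, planted_r: float
                    ) -> tuple[float, float]:
    """Solve (intercept a, slope beta) of the logistic link
    p = expit(a + beta*z + gamma*u) so that the expected Pearson correlation
    between z and positivity equals ``planted_r`` while the mean positivity
    stays at ``base_positivity``.

    The Bernoulli/Gaussian mixed correlation has no usable closed form, so
    beta is found by bracketed root finding on the expected sample
    correlation; the intercept is re-centred alternately (both sub-problems
    are monotone).
    """
    a = float(logit(base_positivity))
    beta = 0.0
    BMAX = 50.0

    def solve_intercept(b: float, a0: float) -> float:
        # bracket wide enough that the linear terms cannot push every p to
        # the same side of base_positivity
        M = abs(b) * np.abs(z).max() + abs(gamma) * np.abs(u).max() + 40.0
        f = lambda aa: expit(aa + b * z + gamma * u).mean() - base_positivity
        return brentq(f, -M, M, xtol=1e-10)

    for _ in range(6):
        def r_of(b: float) -> float:
            aa = solve_intercept(b, a)
            return _point_biserial(z, expit(aa + b * z + gamma * u))

        r_hi = r_of(BMAX)
        r_lo = r_of(-BMAX)
        if not (r_lo - 1e-9 <= planted_r <= r_hi + 1e-9):
            raise UnachievableCorrelationError(planted_r, max(abs(r_lo), r_hi))
        if abs(planted_r) < 1e-12:
            beta_new = 0.0
        else:
            beta_new = brentq(lambda b: r_of(b) - planted_r, -BMAX, BMAX,
                              xtol=1e-8)
        a = solve_intercept(beta_new, a)
        if abs(beta_new - beta) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return a, beta


def generate_health(cfg: HealthGenConfig, env: EnvSeries) -> HealthTable:
    """Simulate the health-examination panel linked to ``env``.

    Record timestamps are uniform over the environmental span (leaving
    ``exposure_window_days`` of history).  Each indicator's positivity is
    Bernoulli with a logistic dose–response on the standardized trailing
    window-mean exposure, with the slope calibrated so the sample Pearson
    correlation approximates the planted value.  A shared standard-normal
    latent factor, scaled by ``label_dependence``, enters every indicator's
    logit (cross-label correlation) and every feature column; each feature
    additionally carries a mild loading on one label so classifiers have
    learnable structure.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.exposure_channel not in env.channels:
        raise ConfigError(f"env series lacks channel {cfg.exposure_channel!r}")
    dates = env.index
    if len(dates) <= cfg.exposure_window_days:
        raise ConfigError("env series shorter than the exposure window")
    eligible = dates[cfg.exposure_window_days - 1:]
    stamps = pd.DatetimeIndex(
        rng.choice(eligible.to_numpy(), size=cfg.n_records, replace=True)
    ).sort_values()
    exposure = _window_mean_exposure(env, cfg.exposure_channel, stamps,
                                     cfg.exposure_window_days)
    z = (exposure - exposure.mean()) / exposure.std()
    u = rng.standard_normal(cfg.n_records)
    gamma = cfg.label_dependence

    labels = {}
    for spec in cfg.indicators:
        a, beta = _calibrate_link(z, u, gamma, spec.base_positivity,
                                  spec.planted_r)
        p = expit(a + beta * z + gamma * u)
        labels[spec.name] = (rng.random(cfg.n_records) < p).astype(int)
    label_df = pd.DataFrame(labels)

    centered = label_df.to_numpy(float) - label_df.to_numpy(float).mean(axis=0)
    feats = np.empty((cfg.n_records, cfg.n_features))
    n_lab = label_df.shape[1]
    for j in range(cfg.n_features):
        eps = rng.standard_normal(cfg.n_records)
        feats[:, j] = (cfg.label_dependence * u
                       + cfg.feature_label_loading * centered[:, j % n_lab]
                       + eps)
    feat_df = pd.DataFrame(feats,
                           columns=[f"f{j + 1}" for j in range(cfg.n_features)])

    return HealthTable(
        features=feat_df,
        labels=label_df,
        timestamps=pd.Series(stamps, name="date"),
        exposure=pd.Series(exposure, name="exposure"),
    )
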