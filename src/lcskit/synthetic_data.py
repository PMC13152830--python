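"""Synthetic inputs for every pipeline stage.

The study this package replicates tracked 598 adolescents from low-income
families over four waves (468 completers), measuring family functioning
(5-item APGAR-type index, 3-point items) and externalizing problems (10 SDQ
conduct + hyperactivity items, 3-point).  No raw data are published; what is
published are the summary moments (means, SDs, correlations, n = 468) and
per-wave reliabilities.  This module generates data that embed exactly those
published quantities:

* :func:`table1_fixture` — the published 8-variable moment structure.
* :func:`generate_from_moments` — multivariate-normal composite scores,
  either drawn from the population implied by a moments object or affinely
  corrected so the *sample* moments match the targets to machine precision.
* :func:`simulate_lcs` — generative draws from the bivariate dual change
  score model itself (for parameter-recovery studies).
* :func:`generate_item_responses` — 3-point item-level responses whose
  discretized total-score mean, SD and Cronbach's alpha are calibrated to
  the published per-wave values.
* :func:`inject_missingness` — MCAR cell deletion or MAR dropout whose
  completer share is calibrated by root-finding (the study retained
  468/598 = 78.3%).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lcs_models import LcsParameters
from .sem_core import MomentsError, RawDataset, SampleMoments, SpecError

__all__ = [
    "FF_NAMES",
    "EP_NAMES",
    "table1_fixture",
    "recovery_parameters",
    "generate_from_moments",
    "simulate_lcs",
    "ItemConstructConfig",
    "apgar_config",
    "sdq_config",
    "generate_item_responses",
    "inject_missingness",
    "ENROLLED_N",
    "COMPLETER_N",
]

FF_NAMES = [f"FF_T{t}" for t in range(1, 5)]
EP_NAMES = [f"EP_T{t}" for t in range(1, 5)]

#: study enrolment and completer counts
ENROLLED_N = 598
COMPLETER_N = 468

_TABLE1_MEANS = [11.56, 11.26, 11.11, 11.22, 15.47, 15.55, 16.10, 15.78]
_TABLE1_SDS = [2.33, 2.20, 2.28, 2.27, 3.00, 2.98, 3.07, 3.11]
# lower triangle, row by row (FF_T2.. then EP_T1..), as printed
_TABLE1_LOWER = [
    [0.41],
    [0.29, 0.38],
    [0.20, 0.35, 0.41],
    [-0.38, -0.28, -0.22, -0.15],
    [-0.29, -0.28, -0.30, -0.17, 0.54],
    [-0.17, -0.17, -0.36, -0.18, 0.33, 0.41],
    [-0.19, -0.17, -0.25, -0.28, 0.36, 0.47, 0.37],
]


def table1_fixture() -> SampleMoments:
    """The published 8-variable moment structure (n = 468), exactly as printed."""
    p = 8
    R = np.eye(p)
    for i, row in enumerate(_TABLE1_LOWER, start=1):
        for j, r in enumerate(row):
            R[i, j] = R[j, i] = r
    return SampleMoments.from_sd_corr(FF_NAMES + EP_NAMES, _TABLE1_MEANS, _TABLE1_SDS,
                                      R, COMPLETER_N)


def recovery_parameters() -> LcsParameters:
    """The fixed generative condition for parameter-recovery studies.

    Chosen once to match the study's setting: intercept means and variances
    on the published score scales, family functioning drifting down and
    externalizing problems up across four waves, level-to-change couplings
    positive and change-to-change couplings negative (the published sign
    pattern), and dynamics strong enough that the model is well identified
    at the study's sample size.
    """
    is_cov = np.array([
        [4.0, 0.3, -1.2, 0.2],
        [0.3, 1.2, 0.2, -0.1],
        [-1.2, 0.2, 6.0, 0.4],
        [0.2, -0.1, 0.4, 1.5],
    ])
    return LcsParameters(
        n_waves=4,
        mu_ix=11.5, mu_iy=15.5, mu_xs=-3.825, mu_ys=3.625,
        is_covariance=is_cov,
        beta_x=-0.30, beta_y=-0.40,
        phi_x=0.30, phi_y=0.30,
        gamma_xy=0.45, gamma_yx=0.25,
        xi_xy=-0.37, xi_yx=-0.46,
        sigma2_ex=0.8, sigma2_ey=1.2,
    )


# ---------------------------------------------------------------------------
# moment-calibrated composite scores

def _psd_factor(Sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        ev, V = np.linalg.eigh(Sigma)
        if ev.min() < -1e-8:
            raise MomentsError("moments not positive semidefinite after repair")
        return V * np.sqrt(np.clip(ev, 0.0, None))


def generate_from_moments(moments: SampleMoments, n: int, seed: int,
                          mode: str = "population") -> RawDataset:
    """Draw composite scores from a multivariate normal with the given moments.

    mode="population": plain draws from N(mean, cov).
    mode="exact": additionally apply the affine correction that makes the
    sample mean and (n-1)-divisor sample covariance equal the targets to
    machine precision, whatever the seed.
    """
    if mode not in ("population", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    p = len(moments.variable_names)
    if mode == "exact" and n <= p:
        raise MomentsError("exact mode needs n > number of variables")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    L = _psd_factor(moments.covariance_matrix)
    if mode == "population":
        X = moments.mean_vector + Z @ L.T
    else:
        Zc = Z - Z.mean(axis=0)
        C = (Zc.T @ Zc) / (n - 1)
        W = np.linalg.cholesky(C)
        # whiten the realized sample, then recolor to the target moments
        X = moments.mean_vector + Zc @ np.linalg.inv(W).T @ L.T
    frame = pd.DataFrame(X, columns=moments.variable_names)
    return RawDataset(frame=frame, variable_names=list(moments.variable_names))


# ---------------------------------------------------------------------------
# generative LCS trajectories

def simulate_lcs(params: LcsParameters, n: int, seed: int,
                 x_names: list[str] | None = None,
                 y_names: list[str] | None = None) -> RawDataset:
    """Simulate observed wave scores from the bivariate dual change score model.

    Per participant: draw (i_x, s_x, i_y, s_y) from the 4x4 normal block,
    iterate the coupled change recursion, and add measurement error.
    """
    T = params.n_waves
    x_names = x_names or [f"FF_T{t}" for t in range(1, T + 1)]
    y_names = y_names or [f"EP_T{t}" for t in range(1, T + 1)]
    rng = np.random.default_rng(seed)
    mu = np.array([params.mu_ix, params.mu_xs, params.mu_iy, params.mu_ys])
    L = _psd_factor(params.is_covariance)
    isdraw = mu + rng.standard_normal((n, 4)) @ L.T
    ix, sx, iy, sy = isdraw.T

    x = np.empty((n, T))
    y = np.empty((n, T))
    x[:, 0], y[:, 0] = ix, iy
    dx_prev = np.zeros(n)
    dy_prev = np.zeros(n)
    for t in range(1, T):
        dx = sx + params.beta_x * x[:, t - 1] + params.gamma_xy * y[:, t - 1]
        dy = sy + params.beta_y * y[:, t - 1] + params.gamma_yx * x[:, t - 1]
        if t >= 2:
            dx = dx + params.xi_xy * dy_prev + params.phi_x * dx_prev
            dy = dy + params.xi_yx * dx_prev + params.phi_y * dy_prev
        x[:, t] = x[:, t - 1] + dx
        y[:, t] = y[:, t - 1] + dy
        dx_prev, dy_prev = dx, dy

    X = x + rng.standard_normal((n, T)) * math.sqrt(params.sigma2_ex)
    Y = y + rng.standard_normal((n, T)) * math.sqrt(params.sigma2_ey)
    frame = pd.DataFrame(np.hstack([X, Y]), columns=x_names + y_names)
    return RawDataset(frame=frame, variable_names=x_names + y_names)


# ---------------------------------------------------------------------------
# 3-point item responses with target reliability

@dataclass
class ItemConstructConfig:
    """Targets for one construct's item-level generator.

    ``target_alpha`` calibrates the latent inter-item correlation so the
    *discretized* 3-point items reach the requested Cronbach's alpha;
    ``target_rho`` instead fixes the latent correlation directly.  Total-score
    mean and SD targets (per wave) drive the two thresholds per wave through
    the documented moment-matching rule.
    """

    name: str
    n_items: int
    target_total_mean: list[float]
    target_total_sd: list[float]
    target_alpha: float | None = None
    target_rho: float | None = None
    n_categories: int = 3
    wave_factor_corr: float = 0.45  # cross-wave correlation of the construct factor

    def __post_init__(self) -> None:
        if self.n_categories != 3:
            raise SpecError("only 3-point items are supported")
        if self.n_items < 2:
            raise SpecError("need at least 2 items")
        if (self.target_alpha is None) == (self.target_rho is None):
            raise SpecError("give exactly one of target_alpha / target_rho")
        if len(self.target_total_mean) != len(self.target_total_sd):
            raise SpecError("per-wave mean and SD lists must have equal length")

    @property
    def n_waves(self) -> int:
        return len(self.target_total_mean)


def apgar_config() -> ItemConstructConfig:
    """Family-functioning (APGAR-type) construct: 5 items, published per-wave
    totals and a pooled alpha target of 0.78 (printed values 0.79/0.75/0.80/0.79)."""
    return ItemConstructConfig(
        name="ff", n_items=5,
        target_total_mean=[11.56, 11.26, 11.11, 11.22],
        target_total_sd=[2.33, 2.20, 2.28, 2.27],
        target_alpha=0.78,
    )


def sdq_config() -> ItemConstructConfig:
    """Externalizing problems (SDQ conduct + hyperactivity): 10 items, pooled
    alpha target 0.66 (printed values 0.63/0.66/0.66/0.68)."""
    return ItemConstructConfig(
        name="ep", n_items=10,
        target_total_mean=[15.47, 15.55, 16.10, 15.78],
        target_total_sd=[3.00, 2.98, 3.07, 3.11],
        target_alpha=0.66,
    )


def _thresholds_from_moments(item_mean: float, item_var: float) -> tuple[float, float]:
    """Two standard-normal thresholds giving a 3-category variable the
    requested mean and variance: with a = mean - 2 and s = var + a^2,
    p(1) = (s - a)/2 and p(3) = (s + a)/2."""
    a = item_mean - 2.0
    s = item_var + a * a
    p1 = (s - a) / 2.0
    p3 = (s + a) / 2.0
    if p1 < 0 or p3 < 0 or p1 + p3 > 1:
        lo, hi = abs(a) - a * a, 1.0 - a * a
        raise SpecError(
            f"item mean {item_mean:.3f} and variance {item_var:.3f} are infeasible "
            f"for 3 categories; feasible variance range is [{lo:.3f}, {hi:.3f}]")
    tau1 = stats.norm.ppf(np.clip(p1, 1e-12, 1 - 1e-12))
    tau2 = stats.norm.ppf(np.clip(1.0 - p3, 1e-12, 1 - 1e-12))
    return float(tau1), float(tau2)


def _discretize(z: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    return 1.0 + (z > tau1) + (z > tau2)


def _bvn_upper(a: float, b: float, rho: float) -> float:
    """P(Z1 > a, Z2 > b) for standard bivariate normal with correlation rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    # survival via inclusion-exclusion on the CDF
    return float(1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + mvn.cdf([a, b]))


def _discrete_corr(rho_lat: float, tau1: float, tau2: float) -> float:
    """Pearson correlation of two 3-category items discretized from latent
    standard normals with correlation rho_lat (same thresholds)."""
    if abs(rho_lat) < 1e-12:
        return 0.0
    taus = (tau1, tau2)
    p1 = stats.norm.cdf(tau1)
    p3 = stats.norm.sf(tau2)
    var = p1 + p3 - (p3 - p1) ** 2
    # d = 1 + 1{z>tau1} + 1{z>tau2}: covariance via the indicator decomposition
    cov = 0.0
    for a in taus:
        for b in taus:
            cov += _bvn_upper(a, b, rho_lat) - stats.norm.sf(a) * stats.norm.sf(b)
    return cov / var


def _calibrate_latent_rho(alpha: float, k: int, tau1: float, tau2: float) -> float:
    """Latent inter-item correlation whose discretized items hit the target alpha."""
    if not 0 < alpha < 1:
        raise SpecError("target alpha must lie in (0, 1)")
    r_target = alpha / (k - alpha * (k - 1))
    r_max = _discrete_corr(0.999, tau1, tau2)
    if r_target >= r_max:
        a_max = k * r_max / (1 + (k - 1) * r_max)
        raise SpecError(
            f"target alpha {alpha:.2f} infeasible for {k} 3-point items with these "
            f"thresholds; maximum attainable alpha is about {a_max:.2f}")
    return float(optimize.brentq(
        lambda r: _discrete_corr(r, tau1, tau2) - r_target, 1e-6, 0.999, xtol=1e-6))


def generate_item_responses(config: ItemConstructConfig, n: int, seed: int,
                            intercept_shift: dict[tuple[int, int], float] | None = None,
                            ) -> RawDataset:
    """Generate item-level 3-point responses for all waves of one construct.

    Columns are ``<name>_w<wave>_i<item>`` (waves and items 1-based).  Items
    within a wave share a single construct factor (exchangeable structure);
    the factor correlates ``wave_factor_corr`` across adjacent waves with
    geometric decay by lag.  ``intercept_shift[(wave, item)]`` shifts that
    item's latent mean (in latent SD units) before thresholding — used to
    build measurement-noninvariant data.
    """
    T = config.n_waves
    k = config.n_items
    rng = np.random.default_rng(seed)

    # per-wave item targets -> thresholds (mean/variance moment matching)
    waves = []
    for w in range(T):
        item_mean = config.target_total_mean[w] / k
        # total variance = k * v * (1 + (k - 1) * r_d): solve for the item variance
        if config.target_alpha is not None:
            r_for_var = config.target_alpha / (k - config.target_alpha * (k - 1))
        else:
            r_for_var = config.target_rho
        item_var = config.target_total_sd[w] ** 2 / (k * (1 + (k - 1) * r_for_var))
        tau1, tau2 = _thresholds_from_moments(item_mean, item_var)
        waves.append((item_mean, item_var, tau1, tau2))

    # latent inter-item correlation (calibrated against discretization loss
    # when an alpha target is given; thresholds of the first wave are used)
    if config.target_alpha is not None:
        rho_lat = _calibrate_latent_rho(config.target_alpha, k, waves[0][2], waves[0][3])
    else:
        rho_lat = config.target_rho
        if not 0 <= rho_lat <= 1:
            raise SpecError("target_rho must lie in [0, 1]")

    # construct factor across waves with geometric lag decay
    lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    Rf = config.wave_factor_corr ** lag
    Lf = _psd_factor(Rf)
    F = rng.standard_normal((n, T)) @ Lf.T

    lam = math.sqrt(rho_lat)
    uniq = math.sqrt(max(1.0 - rho_lat, 0.0))
    cols = {}
    for w in range(T):
        _, _, tau1, tau2 = waves[w]
        for j in range(k):
            z = lam * F[:, w] + uniq * rng.standard_normal(n)
            if intercept_shift:
                z = z + intercept_shift.get((w + 1, j + 1), 0.0)
            cols[f"{config.name}_w{w + 1}_i{j + 1}"] = _discretize(z, tau1, tau2)
    frame = pd.DataFrame(cols)
    if frame.nunique().min() == 1:
        raise SpecError("degenerate thresholds produced a constant item; "
                        "reliability is undefined")
    return RawDataset(frame=frame, variable_names=list(frame.columns))


# ---------------------------------------------------------------------------
# missingness / attrition

_WAVE_RE = re.compile(r"_(?:T|w)(\d+)")


def _wave_groups(names: list[str]) -> dict[int, list[str]]:
    groups: dict[int, list[str]] = {}
    for c in names:
        m = _WAVE_RE.search(c)
        if m:
            groups.setdefault(int(m.group(1)), []).append(c)
    return groups


def inject_missingness(data: RawDataset, mechanism: str, rate: float, seed: int,
                       hazard_slope: float = 0.6,
                       driver: str | None = None) -> RawDataset:
    """Blank values in a complete dataset.

    mechanism="MCAR": each modeled cell is blanked independently with
    probability ``rate``.

    mechanism="MAR_dropout": participants drop out at some wave >= 2 and all
    later waves are censored; the per-wave dropout hazard is logistic in the
    standardized wave-1 score of ``driver`` (default: the first wave-1
    column), with slope ``hazard_slope`` and an intercept found by
    root-finding so the expected completer share equals 1 - rate.  A boolean
    ``completer`` column records retention.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    frame = data.frame.copy()
    if mechanism == "MCAR":
        if rate > 0:
            X = frame[data.variable_names].to_numpy(dtype=float)
            mask = rng.random(X.shape) < rate
            X[mask] = np.nan
            frame[data.variable_names] = X
        frame["completer"] = ~frame[data.variable_names].isna().any(axis=1)
        return RawDataset(frame=frame, variable_names=list(data.variable_names),
                          covariate_names=list(data.covariate_names),
                          completer_col="completer")
    if mechanism != "MAR_dropout":
        raise ValueError(f"unknown mechanism {mechanism!r}")

    groups = _wave_groups(data.variable_names)
    if len(groups) < 2:
        raise SpecError("MAR dropout needs columns for at least 2 waves")
    wave_ids = sorted(groups)
    n_hazard_waves = len(wave_ids) - 1
    driver = driver or groups[wave_ids[0]][0]
    z = frame[driver].to_numpy(dtype=float)
    z = (z - np.nanmean(z)) / np.nanstd(z)
    target = 1.0 - rate

    def completer_share(a: float) -> float:
        h = 1.0 / (1.0 + np.exp(-(a + hazard_slope * z)))
        return float(np.mean((1.0 - h) ** n_hazard_waves))

    if rate == 0:
        frame["completer"] = True
        return RawDataset(frame=frame, variable_names=list(data.variable_names),
                          covariate_names=list(data.covariate_names),
                          completer_col="completer")
    a_hat = optimize.brentq(lambda a: completer_share(a) - target, -30.0, 30.0)
    h = 1.0 / (1.0 + np.exp(-(a_hat + hazard_slope * z)))
    n = len(frame)
    dropped = np.zeros(n, dtype=bool)
    completer = np.ones(n, dtype=bool)
    for w in wave_ids[1:]:
        newly = (~dropped) & (rng.random(n) < h)
        dropped |= newly
        completer &= ~newly
        frame.loc[dropped, groups[w]] = np.nan
    frame["completer"] = completer
    return RawDataset(frame=frame, variable_names=list(data.variable_names),
                      covariate_names=list(data.covariate_names),
                      completer_col="completer")
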