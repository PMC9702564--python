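"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-SNP effects (gamma_j, sigma_Xj) on the exposure and
(Gamma_j, sigma_Yj) on the outcome, the per-SNP Wald ratio is
beta_j = Gamma_j / gamma_j with first-order standard error sigma_Yj/|gamma_j|
(exposure-side noise ignored; the NO-Measurement-Error approximation).

* IVW combines the ratios with weights w_j = gamma_j^2 / sigma_Yj^2,
  equivalent to weighted least squares of Gamma on gamma through the origin.
  The default multiplicative random-effects model inflates the fixed-effect
  standard error by max(1, sqrt(Q/(n-1))) where Q is Cochran's heterogeneity
  statistic.
* MR-Egger fits Gamma_j = alpha + beta * gamma_j by weighted regression
  (weights 1/sigma_Yj^2) after orienting all gamma_j >= 0; a non-zero
  intercept alpha estimates directional horizontal pleiotropy and the slope
  remains a causal estimate under the InSIDE assumption.
* The weighted median is consistent when valid instruments carry at least
  half the weight; the weighted mode when the largest cluster of instruments
  is valid. Both take bootstrap standard errors from a seeded parametric
  resample of (gamma_j, Gamma_j).

All p-values are two-sided normal; confidence intervals are beta +/- z_975*se.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .harmonize import HarmonizedData, HarmonizedRecord

Z975 = float(stats.norm.ppf(0.975))  # 1.959964...

METHODS = ("wald", "ivw_fe", "ivw_re", "egger", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class EggerIntercept:
    value: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class CochranQ:
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal effect on the outcome scale per unit exposure."""

    method: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    intercept: Optional[EggerIntercept] = None
    cochran_q: Optional[CochranQ] = None


def _two_sided_p(z: float) -> float:
    return min(1.0, float(2.0 * stats.norm.sf(abs(z))))


def _make_estimate(method: str, beta: float, se: float, n_snp: int, **extra) -> MREstimate:
    return MREstimate(
        method=method,
        beta_hat=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        pvalue=_two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0),
        n_snp=n_snp,
        **extra,
    )


def _ratio_inputs(data: HarmonizedData):
    g, sx, G, sy = data.arrays()
    if np.any(g == 0):
        raise UndefinedRatioError("zero exposure effect among harmonized records")
    return g, sx, G, sy


def wald_ratio(rec: HarmonizedRecord) -> MREstimate:
    """Single-SNP ratio estimate Gamma/gamma with first-order standard error."""
    if rec.gamma == 0:
        raise UndefinedRatioError(f"{rec.variant_id}: gamma = 0")
    beta = rec.Gamma / rec.gamma
    se = rec.sigma_y / abs(rec.gamma)
    return _make_estimate("wald", beta, se, 1)


def ivw(data: HarmonizedData, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted combination of per-SNP Wald ratios.

    ``model='fixed'`` uses se = 1/sqrt(sum w); ``model='random'`` (default)
    applies the multiplicative random-effects inflation
    se_fixed * max(1, sqrt(Q/(n-1))). Cochran's Q with its chi-square p-value
    is attached whenever n >= 2.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    n = data.n_snp
    minimum = 1 if model == "fixed" else 2
    if n < minimum:
        raise InsufficientInstrumentsError(f"IVW ({model}) needs >= {minimum} SNPs, got {n}")
    g, _, G, sy = _ratio_inputs(data)
    w = g**2 / sy**2
    ratios = G / g
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    cq = None
    if n >= 2:
        df = n - 1
        cq = CochranQ(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))
    se = se_fixed
    if model == "random":
        se = se_fixed * max(1.0, math.sqrt(q / (n - 1)))
    method = "ivw_fe" if model == "fixed" else "ivw_re"
    return _make_estimate(method, beta, se, n, cochran_q=cq)


def egger(data: HarmonizedData) -> MREstimate:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Signs are oriented so all gamma_j >= 0 (flipping (gamma, Gamma) jointly
    leaves the ratio unchanged). Standard errors of slope and intercept are
    scaled by the multiplicative overdispersion factor
    max(1, sqrt(RSS_w/(n-2))).
    """
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {n}")
    g, _, G, sy = _ratio_inputs(data)
    s = np.where(g < 0, -1.0, 1.0)
    x, y = g * s, G * s
    w = 1.0 / sy**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swxx = float(np.sum(w * x * x))
    swy = float(np.sum(w * y))
    swxy = float(np.sum(w * x * y))
    det = sw * swxx - swx * swx
    if det <= 0 or np.ptp(x) == 0:
        raise DegenerateDesignError("no variance in oriented instrument strengths")
    slope = (sw * swxy - swx * swy) / det
    inter = (swxx * swy - swx * swxy) / det
    resid = y - inter - slope * x
    rss = float(np.sum(w * resid**2))
    scale2 = max(1.0, rss / (n - 2))
    se_slope = math.sqrt(scale2 * sw / det)
    se_inter = math.sqrt(scale2 * swxx / det)
    intercept = EggerIntercept(
        value=inter, se=se_inter, pvalue=_two_sided_p(inter / se_inter)
    )
    return _make_estimate("egger", slope, se_slope, n, intercept=intercept)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation at the midpoint ranks.

    With normalized weights w'_j sorted by ratio, the rank of ratio j is
    S_j = sum_{k<=j} w'_k - w'_j/2; the estimate interpolates between the
    ratios bracketing S = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    wn = np.asarray(weights, dtype=float)[order]
    wn = wn / wn.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0, grid_points: int = 512
) -> float:
    """Mode of the weight-smoothed density of the ratio estimates.

    Normal kernel with modified-Silverman bandwidth
    h = phi * 0.9 * min(sd, IQR/1.349) * n^(-1/5), argmax taken on an
    equally spaced grid spanning the ratios +/- 3h. Degenerate dispersion
    (all ratios identical) returns the common ratio.
    """
    r = np.asarray(ratios, dtype=float)
    wn = np.asarray(weights, dtype=float)
    wn = wn / wn.sum()
    if np.ptp(r) == 0:
        return float(r[0])
    n = len(r)
    sd = float(np.std(r, ddof=1))
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    candidates = [v for v in (sd, iqr / 1.349) if v > 0]
    disp = min(candidates)
    h = phi * 0.9 * disp * n ** (-0.2)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_points)
    z = (grid[:, None] - r[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ wn
    return float(grid[int(np.argmax(dens))])


def _bootstrap_se(
    point_fn: Callable[[np.ndarray, np.ndarray], float],
    g: np.ndarray,
    sx: np.ndarray,
    G: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: resample (gamma*, Gamma*) from their normal
    sampling distributions and re-evaluate the point estimator."""
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    tiny = np.finfo(float).tiny
    for i in range(n_boot):
        gb = rng.normal(g, sx)
        Gb = rng.normal(G, sy)
        gb = np.where(gb == 0, tiny, gb)
        est[i] = point_fn(Gb / gb, gb**2 / sy**2)
    return float(np.std(est, ddof=1))


def weighted_median(data: HarmonizedData, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error."""
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {n}")
    g, sx, G, sy = _ratio_inputs(data)
    w = g**2 / sy**2
    beta = weighted_median_point(G / g, w)
    se = _bootstrap_se(weighted_median_point, g, sx, G, sy, n_boot, seed)
    return _make_estimate("weighted_median", beta, se, n)


def weighted_mode(
    data: HarmonizedData,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_points: int = 512,
) -> MREstimate:
    """Weighted-mode estimator with parametric-bootstrap standard error."""
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs >= 3 SNPs, got {n}")
    g, sx, G, sy = _ratio_inputs(data)
    w = g**2 / sy**2

    def point(r: np.ndarray, wts: np.ndarray) -> float:
        return weighted_mode_point(r, wts, phi=phi, grid_points=grid_points)

    beta = point(G / g, w)
    se = _bootstrap_se(point, g, sx, G, sy, n_boot, seed)
    return _make_estimate("weighted_mode", beta, se, n)


def run_all(
    data: HarmonizedData,
    seed: int = 0,
    ivw_model: str = "random",
    n_boot: int = 1000,
    phi: float = 1.0,
) -> tuple[list[MREstimate], list[str]]:
    """Run every estimator whose SNP-count precondition is met.

    Returns ``(estimates, skipped)`` where ``skipped`` names the methods whose
    precondition failed (never raised as errors here). With a single SNP the
    Wald ratio and fixed-effect IVW (identical) are reported.
    """
    n = data.n_snp
    if n == 0:
        raise InsufficientInstrumentsError("no harmonized records")
    estimates: list[MREstimate] = []
    skipped: list[str] = []
    if n == 1:
        estimates.append(wald_ratio(data.records[0]))
        estimates.append(ivw(data, model="fixed"))
        skipped += ["egger", "weighted_median", "weighted_mode"]
        return estimates, skipped
    estimates.append(ivw(data, model=ivw_model))
    if n >= 3:
        estimates.append(egger(data))
        estimates.append(weighted_median(data, n_boot=n_boot, seed=seed))
        estimates.append(weighted_mode(data, phi=phi, n_boot=n_boot, seed=seed + 1))
    else:
        skipped += ["egger", "weighted_median", "weighted_mode"]
    return estimates, skipped
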