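"""Pleiotropy and robustness diagnostics.

* MR-PRESSO: a residual-sum-of-squares resampling framework. The global test
  compares the observed weighted RSS of leave-one-out IVW residuals against
  its distribution under a no-pleiotropy parametric simulation; the outlier
  test compares each SNP's weighted squared residual against its simulated
  distribution (Bonferroni-corrected within the instrument set); the
  distortion test asks whether removing the flagged outliers changes the
  causal estimate more than removing random SNP subsets of the same size.
* Leave-one-out: the IVW estimate recomputed with each SNP omitted in turn,
  flagging single-SNP dominance.
* Funnel data: per-SNP ratio estimates against their precision, with a simple
  weighted sign statistic for asymmetry (directional pleiotropy pulls ratios
  to one side of the combined estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw
from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .harmonize import HarmonizedData


def _loo_slopes(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for every SNP (vectorized)."""
    w = g**2 / sy**2
    num = np.sum(w * (G / g))
    den = np.sum(w)
    return (num - w * (G / g)) / (den - w)


@dataclass
class PressoResult:
    rss_observed: float
    global_p: float
    n_sim: int
    per_snp_p: list[tuple[str, float]]
    outliers: list[str]
    beta_raw: MREstimate
    beta_corrected: Optional[MREstimate]
    distortion_p: Optional[float]
    seed: int


def presso(
    data: HarmonizedData,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests (two-sample form).

    For each SNP j the leave-one-out IVW slope b_{-j} gives the residual
    r_j = Gamma_j - b_{-j} gamma_j and RSS_obs = sum_j r_j^2 / sigma_Yj^2.
    ``n_sim`` parametric datasets are drawn with gamma*_j ~ N(gamma_j,
    sigma_Xj) and Gamma*_j ~ N(b_{-j} gamma_j, sigma_Yj); the empirical
    exceedance rate of RSS* gives the global p-value with resolution
    1/(n_sim+1). Per-SNP outlier p-values use the simulated distribution of
    the weighted squared residuals, flagged at ``outlier_alpha/n_snp``.
    Fully reproducible under a fixed seed.
    """
    n = data.n_snp
    if n < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {n}")
    g, sx, G, sy = data.arrays()
    if np.any(g == 0):
        raise UndefinedRatioError("zero exposure effect among harmonized records")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    b_loo = _loo_slopes(g, G, sy)
    resid = G - b_loo * g
    t_obs = w * resid**2
    rss_obs = float(np.sum(t_obs))

    # parametric simulation under no horizontal pleiotropy
    gs = rng.normal(g, sx, size=(n_sim, n))
    Gs = rng.normal(b_loo * g, sy, size=(n_sim, n))
    gs = np.where(gs == 0, np.finfo(float).tiny, gs)
    ws = gs**2 / sy**2
    ratios = Gs / gs
    num = np.sum(ws * ratios, axis=1, keepdims=True)
    den = np.sum(ws, axis=1, keepdims=True)
    b_loo_star = (num - ws * ratios) / (den - ws)
    t_star = w * (Gs - b_loo_star * gs) ** 2
    rss_star = np.sum(t_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_p = (1 + np.sum(t_star >= t_obs, axis=0)) / (n_sim + 1)
    ids = data.variant_ids
    per_snp_p = list(zip(ids, per_p.astype(float)))
    threshold = outlier_alpha / n
    outliers = [vid for vid, p in per_snp_p if p < threshold]

    beta_raw = ivw(data)
    beta_corrected = None
    distortion_p = None
    k = len(outliers)
    if k and n - k >= 2:
        beta_corrected = ivw(data.subset([v for v in ids if v not in outliers]))
        d_obs = beta_raw.beta_hat - beta_corrected.beta_hat
        # null distribution of the shift under random outlier assignment
        w_iv = g**2 / sy**2
        contrib = w_iv * (G / g)
        tot_num, tot_den = float(np.sum(contrib)), float(np.sum(w_iv))
        idx = np.array([rng.choice(n, size=k, replace=False) for _ in range(n_distortion)])
        num_rm = np.sum(contrib[idx], axis=1)
        den_rm = np.sum(w_iv[idx], axis=1)
        d_null = beta_raw.beta_hat - (tot_num - num_rm) / (tot_den - den_rm)
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_distortion + 1)
        )

    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        per_snp_p=per_snp_p,
        outliers=outliers,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        distortion_p=distortion_p,
        seed=seed,
    )


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_variant_id: str
    estimate: MREstimate


@dataclass
class LeaveOneOutResult:
    rows: list[LeaveOneOutRow]
    full_estimate: MREstimate
    max_abs_deviation: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omitted_variant_id": [r.omitted_variant_id for r in self.rows],
                "beta_hat": [r.estimate.beta_hat for r in self.rows],
                "se": [r.estimate.se for r in self.rows],
                "pvalue": [r.estimate.pvalue for r in self.rows],
            }
        )


def leave_one_out(data: HarmonizedData, model: str = "random") -> LeaveOneOutResult:
    """IVW re-estimated with each SNP omitted in turn.

    The IVW model degrades to fixed-effect when only one SNP remains.
    """
    n = data.n_snp
    if n < 2:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 2 SNPs, got {n}")
    full = ivw(data, model=model if n >= 2 else "fixed")
    rows = []
    for rec in data.records:
        rest = data.without(rec.variant_id)
        est = ivw(rest, model=model if rest.n_snp >= 2 else "fixed")
        rows.append(LeaveOneOutRow(omitted_variant_id=rec.variant_id, estimate=est))
    max_dev = max(abs(r.estimate.beta_hat - full.beta_hat) for r in rows)
    return LeaveOneOutResult(rows=rows, full_estimate=full, max_abs_deviation=max_dev)


@dataclass
class FunnelResult:
    table: pd.DataFrame
    symmetry_statistic: float


def funnel_data(data: HarmonizedData, full_estimate: MREstimate) -> FunnelResult:
    """Per-SNP ratio vs precision table for funnel plotting.

    Precision is 1/se of the per-SNP Wald ratio, i.e. |gamma_j|/sigma_Yj.
    The symmetry statistic is the weighted mean of sign(ratio_j - beta_full)
    with IVW weights; values near 0 indicate a symmetric funnel.
    """
    g, _, G, sy = data.arrays()
    if np.any(g == 0):
        raise UndefinedRatioError("zero exposure effect among harmonized records")
    ratios = G / g
    precision = np.abs(g) / sy
    w = g**2 / sy**2
    signs = np.sign(ratios - full_estimate.beta_hat)
    symmetry = float(np.sum(w * signs) / np.sum(w))
    table = pd.DataFrame(
        {
            "variant_id": data.variant_ids,
            "ratio": ratios,
            "precision": precision,
        }
    )
    return FunnelResult(table=table, symmetry_statistic=symmetry)
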