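"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model is the standard two-sample MR setup with traits scaled
to unit variance, so the sampling standard error of a per-allele effect
estimated in N individuals at effect-allele frequency q is
sigma = 1/sqrt(2 q (1-q) N) — the same quantity that makes the
summary-statistic R-squared formula exact in expectation.

Per SNP j: a true exposure effect gamma_j (zero for null SNPs), a direct
(horizontally pleiotropic) outcome effect alpha_j, an optional shared
confounder loading lambda_j feeding both traits, and

    Gamma_j = beta * gamma_j + alpha_j + c_y * lambda_j,
    gamma_j -> gamma_j + c_x * lambda_j  (confounded SNPs only).

Observed effects add independent exposure- and outcome-sample noise (the
two-sample property). Each instrument comes with LD "satellite" tags (scaled
effects, declared r2) so clumping is exercised, plus correlated null blocks;
palindromic allele coding, random strand/allele presentation and outcome
missingness with proxies are injected at configurable rates. Case-control
outcomes are approximated by the same Gaussian model on the log-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .sumstats_io import ALL_FIELDS, LDTable, SummaryStatsTable

PLEIOTROPY_MODES = ("none", "balanced", "directional", "confounded")

_NONPAL_PAIRS = [
    ("A", "G"), ("A", "C"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def sampling_sd(eaf: np.ndarray | float, n: int) -> np.ndarray | float:
    """Standard error of a per-allele effect on a unit-variance trait."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def gamma_for_mean_f(f_target: float, n: int, rel_sd: float = 0.15) -> float:
    """Reference effect size |gamma| at eaf = 0.5 hitting a target mean F.

    Instrument effects are drawn at a reference frequency of 0.5 and scaled
    per SNP by the frequency-dependent sampling SD (rarer alleles get larger
    per-allele effects), so the expected instrument chi-square — and hence F —
    is frequency-invariant: E[F] ~ E[z^2] + 1 with z = gamma_ref * sqrt(N/2)
    drawn with relative spread ``rel_sd``.
    """
    e_gamma2 = (f_target - 1.0) / (0.5 * n)
    return math.sqrt(e_gamma2 / (1.0 + rel_sd**2))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic two-sample scenario."""

    n_instruments: int = 10
    n_null_snps: int = 200
    n_satellites: int = 2
    satellite_r: float = 0.8
    n_exposure: int = 251151
    n_outcome: int = 450000
    n_confounder: int = 806834
    causal_beta: float = math.log(0.80)
    gamma_mean: float = 0.0168
    gamma_sd: float = 0.0025
    eaf_low: float = 0.10
    eaf_high: float = 0.90
    pleiotropy: str = "none"
    mu_alpha: float = 0.0
    tau_alpha: float = 0.0
    prop_invalid: float = 0.0
    confounder_to_exposure: float = 0.0
    confounder_to_outcome: float = 0.0
    prop_confounded: float = 0.0
    lambda_mean: float = 0.015
    lambda_sd: float = 0.003
    palindrome_fraction: float = 0.0
    missing_in_outcome_fraction: float = 0.0
    proxy_fraction: float = 0.8
    proxy_r2: float = 0.9
    n_outliers: int = 0
    outlier_shift: float = 0.0
    null_block_size: int = 5
    null_block_r2: float = 0.5
    id_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy not in PLEIOTROPY_MODES:
            raise ConfigError(f"pleiotropy must be one of {PLEIOTROPY_MODES}")
        for name in ("prop_invalid", "prop_confounded", "palindrome_fraction",
                     "missing_in_outcome_fraction", "proxy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        for name in ("gamma_sd", "tau_alpha", "lambda_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.eaf_low < self.eaf_high < 1):
            raise ConfigError("require 0 < eaf_low < eaf_high < 1")
        if min(self.n_exposure, self.n_outcome) <= 2:
            raise ConfigError("sample sizes must exceed 2")


@dataclass
class SimTruth:
    """Ground truth of one scenario: causal effect and per-SNP parameters."""

    causal_beta: float
    snps: pd.DataFrame  # variant_id, role, gamma_true, alpha, lam, flags ...

    @property
    def instrument_ids(self) -> list[str]:
        return list(self.snps.loc[self.snps["role"] == "instrument", "variant_id"])

    @property
    def outlier_ids(self) -> list[str]:
        return list(self.snps.loc[self.snps["is_outlier"], "variant_id"])


@dataclass
class SimBundle:
    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    confounder: Optional[SummaryStatsTable]
    ld: LDTable
    truth: SimTruth
    config: SimConfig


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[dict] = []
    counter = cfg.id_offset

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"rs{counter:07d}"

    def alleles(palindromic: bool) -> tuple[str, str]:
        pool = _PAL_PAIRS if palindromic else _NONPAL_PAIRS
        return pool[rng.integers(len(pool))]

    n_inst = cfg.n_instruments
    invalid = np.zeros(n_inst, dtype=bool)
    k_inv = int(round(cfg.prop_invalid * n_inst))
    if cfg.pleiotropy in ("balanced", "directional") and k_inv:
        invalid[rng.choice(n_inst, size=k_inv, replace=False)] = True
    confounded = np.zeros(n_inst, dtype=bool)
    k_conf = int(round(cfg.prop_confounded * n_inst))
    if k_conf:
        confounded[rng.choice(n_inst, size=k_conf, replace=False)] = True
    outlier = np.zeros(n_inst, dtype=bool)
    if cfg.n_outliers:
        outlier[rng.choice(n_inst, size=cfg.n_outliers, replace=False)] = True
    missing = rng.random(n_inst) < cfg.missing_in_outcome_fraction

    ref_sd = float(sampling_sd(0.5, cfg.n_exposure))
    block = 0
    for i in range(n_inst):
        q = rng.uniform(cfg.eaf_low, cfg.eaf_high)
        # effect drawn at reference frequency 0.5, rescaled so the expected
        # instrument chi-square does not depend on allele frequency
        mag = abs(rng.normal(cfg.gamma_mean, cfg.gamma_sd))
        mag *= float(sampling_sd(q, cfg.n_exposure)) / ref_sd
        gamma = mag * rng.choice([-1.0, 1.0])
        alpha = 0.0
        if invalid[i]:
            alpha = rng.normal(cfg.mu_alpha, cfg.tau_alpha)
            if cfg.pleiotropy == "directional" and gamma < 0:
                # directional means consistent relative to the
                # exposure-increasing allele, not to an arbitrary strand
                alpha = -alpha
        lam = 0.0
        if confounded[i]:
            # loading anti-aligned with the exposure-increasing allele
            # (the BMI / reproductive-timing correlation is inverse), which
            # makes the confounding bias systematic rather than cancelling
            lam = -math.copysign(
                abs(rng.normal(cfg.lambda_mean, cfg.lambda_sd)), gamma
            )
            gamma += cfg.confounder_to_exposure * lam
        if outlier[i]:
            alpha += cfg.outlier_shift * float(sampling_sd(q, cfg.n_outcome))
        pal = rng.random() < cfg.palindrome_fraction
        ea, oa = alleles(pal)
        base = dict(
            chrom=str(1 + block % 22),
            block=block,
            is_invalid=bool(invalid[i]),
            is_confounded=bool(confounded[i]),
            is_outlier=bool(outlier[i]),
        )
        idx_id = new_id()
        rows.append(
            dict(
                variant_id=idx_id, role="instrument", pos=1_000_000 * (1 + block // 22),
                effect_allele=ea, other_allele=oa, eaf=q, gamma_true=gamma,
                alpha=alpha, lam=lam, is_palindromic=pal,
                missing_in_outcome=bool(missing[i]), proxy_of=None, **base,
            )
        )
        r = cfg.satellite_r
        for s in range(cfg.n_satellites):
            # tags in LD share the index variant's frequency (strong LD
            # implies similar allele frequencies) and carry r-scaled effects
            pal_s = rng.random() < cfg.palindrome_fraction
            ea_s, oa_s = alleles(pal_s)
            rows.append(
                dict(
                    variant_id=new_id(), role="satellite",
                    pos=1_000_000 * (1 + block // 22) + 10_000 * (s + 1),
                    effect_allele=ea_s, other_allele=oa_s, eaf=q,
                    gamma_true=r * gamma, alpha=r * alpha, lam=r * lam,
                    is_palindromic=pal_s, missing_in_outcome=False, proxy_of=None,
                    **base,
                )
            )
        if missing[i] and rng.random() < cfg.proxy_fraction:
            # proxy shares the index variant's allele coding and frequency so
            # it can be harmonized directly against the exposure record
            rp = math.sqrt(cfg.proxy_r2)
            rows.append(
                dict(
                    variant_id=new_id(), role="proxy",
                    pos=1_000_000 * (1 + block // 22) + 500,
                    effect_allele=ea, other_allele=oa, eaf=q,
                    gamma_true=rp * gamma, alpha=rp * alpha, lam=rp * lam,
                    is_palindromic=pal, missing_in_outcome=False, proxy_of=idx_id,
                    **base,
                )
            )
        block += 1

    n_blocks_null = math.ceil(cfg.n_null_snps / cfg.null_block_size) if cfg.n_null_snps else 0
    emitted = 0
    for nb in range(n_blocks_null):
        size = min(cfg.null_block_size, cfg.n_null_snps - emitted)
        for s in range(size):
            q = rng.uniform(cfg.eaf_low, cfg.eaf_high)
            pal = rng.random() < cfg.palindrome_fraction
            ea, oa = alleles(pal)
            rows.append(
                dict(
                    variant_id=new_id(), role="null", chrom=str(1 + block % 22),
                    pos=1_000_000 * (1 + block // 22) + 1_000 * s,
                    effect_allele=ea, other_allele=oa, eaf=q, gamma_true=0.0,
                    alpha=0.0, lam=0.0, block=block, is_invalid=False,
                    is_confounded=False, is_outlier=False, is_palindromic=pal,
                    missing_in_outcome=False, proxy_of=None,
                )
            )
        emitted += size
        block += 1

    df = pd.DataFrame(rows)
    df["sigma_x"] = sampling_sd(df["eaf"].to_numpy(), cfg.n_exposure)
    df["sigma_y"] = sampling_sd(df["eaf"].to_numpy(), cfg.n_outcome)
    return df


def _assoc_frame(
    ids, chrom, pos, ea, oa, eaf, beta_hat, sigma, n
) -> pd.DataFrame:
    z = beta_hat / sigma
    pvals = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_hat,
            "se": sigma,
            "pvalue": pvals,
            "n": n,
            "chrom": chrom,
            "pos": pos,
        }
    )[list(ALL_FIELDS)]


def _exposure_table(
    truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator, name: str
) -> SummaryStatsTable:
    t = truth[truth["role"] != "proxy"]
    sigma = t["sigma_x"].to_numpy()
    beta_hat = rng.normal(t["gamma_true"].to_numpy(), sigma)
    df = _assoc_frame(
        t["variant_id"], t["chrom"], t["pos"], t["effect_allele"], t["other_allele"],
        t["eaf"].to_numpy(), beta_hat, sigma, cfg.n_exposure,
    )
    return SummaryStatsTable(df, name, "exposure")


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _outcome_table(
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    name: str,
    causal_beta: Optional[float] = None,
) -> SummaryStatsTable:
    beta = cfg.causal_beta if causal_beta is None else causal_beta
    t = truth[~truth["missing_in_outcome"]].reset_index(drop=True)
    Gamma_true = (
        beta * t["gamma_true"].to_numpy()
        + t["alpha"].to_numpy()
        + cfg.confounder_to_outcome * t["lam"].to_numpy()
    )
    sigma = t["sigma_y"].to_numpy()
    Gamma_hat = rng.normal(Gamma_true, sigma)
    eaf = t["eaf"].to_numpy().copy()
    ea = t["effect_allele"].to_numpy(dtype=object).copy()
    oa = t["other_allele"].to_numpy(dtype=object).copy()
    pal = t["is_palindromic"].to_numpy()

    # random presentation: report some variants with the other allele as the
    # effect allele, and some non-palindromic variants on the opposite strand
    swap = rng.random(len(t)) < 0.5
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    Gamma_hat[swap] *= -1.0
    eaf[swap] = 1.0 - eaf[swap]
    flip_strand = (rng.random(len(t)) < 0.3) & ~pal
    ea[flip_strand] = [_COMP[a] for a in ea[flip_strand]]
    oa[flip_strand] = [_COMP[a] for a in oa[flip_strand]]

    df = _assoc_frame(
        t["variant_id"], t["chrom"], t["pos"], ea, oa, eaf, Gamma_hat, sigma, cfg.n_outcome
    )
    return SummaryStatsTable(df, name, "outcome")


def _confounder_table(
    truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator, name: str
) -> SummaryStatsTable:
    t = truth[truth["role"] != "proxy"]
    sigma = np.asarray(sampling_sd(t["eaf"].to_numpy(), cfg.n_confounder))
    beta_hat = rng.normal(t["lam"].to_numpy(), sigma)
    df = _assoc_frame(
        t["variant_id"], t["chrom"], t["pos"], t["effect_allele"], t["other_allele"],
        t["eaf"].to_numpy(), beta_hat, sigma, cfg.n_confounder,
    )
    return SummaryStatsTable(df, name, "confounder")


def _ld_table(truth: pd.DataFrame, cfg: SimConfig) -> LDTable:
    ld = LDTable()
    for _, grp in truth.groupby("block"):
        ids = list(grp["variant_id"])
        roles = list(grp["role"])
        proxies = {vid: po for vid, po in zip(grp["variant_id"], grp["proxy_of"]) if po}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if proxies.get(a) == b or proxies.get(b) == a:
                    ld.add(a, b, cfg.proxy_r2)
                elif roles[i] == "null":
                    ld.add(a, b, cfg.null_block_r2)
                else:
                    ld.add(a, b, cfg.satellite_r**2)
    return ld


def simulate_two_sample(
    cfg: SimConfig, exposure_name: str = "exposure", outcome_name: str = "outcome"
) -> SimBundle:
    """Generate one synthetic exposure/outcome pair with ground truth.

    Deterministic given ``cfg`` (including ``cfg.seed``). A confounder GWAS
    table is emitted whenever the scenario includes confounded instruments.
    """
    rng = np.random.default_rng(cfg.seed)
    truth_df = _draw_truth(cfg, rng)
    exposure = _exposure_table(truth_df, cfg, rng, exposure_name)
    outcome = _outcome_table(truth_df, cfg, rng, outcome_name)
    confounder = None
    if cfg.prop_confounded > 0:
        confounder = _confounder_table(truth_df, cfg, rng, "confounder")
    ld = _ld_table(truth_df, cfg)
    return SimBundle(
        exposure=exposure,
        outcome=outcome,
        confounder=confounder,
        ld=ld,
        truth=SimTruth(causal_beta=cfg.causal_beta, snps=truth_df),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Scenario presets: scale-matched to the reproductive-factor / osteoarthritis
# study design (instrument counts, instrument-strength magnitudes, effect
# sizes on the log-odds scale).
# ---------------------------------------------------------------------------

def _preset_afb_like(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(36.49, 251151)
    return SimConfig(
        n_instruments=10, n_null_snps=200, n_exposure=251151,
        causal_beta=math.log(0.80), gamma_mean=gm, gamma_sd=0.15 * gm, seed=seed,
    )


def _preset_aam_like(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(64.27, 329345)
    return SimConfig(
        n_instruments=349, n_null_snps=400, n_exposure=329345,
        causal_beta=math.log(0.91), gamma_mean=gm, gamma_sd=0.15 * gm,
        palindrome_fraction=0.08, missing_in_outcome_fraction=0.04,
        seed=seed,
    )


def _preset_anm_like(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(68.14, 69360)
    return SimConfig(
        n_instruments=54, n_null_snps=300, n_exposure=69360,
        causal_beta=0.0, gamma_mean=gm, gamma_sd=0.15 * gm,
        palindrome_fraction=0.06, missing_in_outcome_fraction=0.04,
        seed=seed,
    )


def _preset_balanced(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(64.0, 329345)
    return SimConfig(
        n_instruments=50, n_null_snps=100, n_exposure=329345,
        causal_beta=math.log(0.90), gamma_mean=gm, gamma_sd=0.15 * gm,
        pleiotropy="balanced", prop_invalid=1.0, mu_alpha=0.0, tau_alpha=0.004,
        seed=seed,
    )


def _preset_directional(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(36.49, 251151)
    return SimConfig(
        n_instruments=30, n_null_snps=100, n_exposure=251151,
        causal_beta=math.log(0.80), gamma_mean=gm, gamma_sd=0.15 * gm,
        pleiotropy="directional", prop_invalid=0.3, mu_alpha=0.012, tau_alpha=0.004,
        seed=seed,
    )


def _preset_confounded(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(64.0, 329345)
    return SimConfig(
        n_instruments=50, n_null_snps=100, n_exposure=329345,
        causal_beta=math.log(0.91), gamma_mean=gm, gamma_sd=0.15 * gm,
        pleiotropy="confounded", prop_confounded=0.2,
        confounder_to_exposure=-0.1, confounder_to_outcome=0.5,
        seed=seed,
    )


def _preset_outlier(seed: int) -> SimConfig:
    gm = gamma_for_mean_f(36.49, 251151)
    return SimConfig(
        n_instruments=20, n_null_snps=100, n_exposure=251151,
        causal_beta=math.log(0.80), gamma_mean=gm, gamma_sd=0.15 * gm,
        n_outliers=1, outlier_shift=10.0, seed=seed,
    )


_PRESETS = {
    "afb_like": _preset_afb_like,
    "aam_like": _preset_aam_like,
    "anm_like": _preset_anm_like,
    "balanced_pleiotropy": _preset_balanced,
    "directional_pleiotropy": _preset_directional,
    "confounded_bmi": _preset_confounded,
    "outlier_injection": _preset_outlier,
}


def scenario_presets(name: str, seed: int = 0) -> SimConfig:
    """A fully specified scenario configuration by name."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return builder(seed)


# ---------------------------------------------------------------------------
# Full-study emulation: three exposures sharing four outcome GWAS tables.
# ---------------------------------------------------------------------------

#: per-exposure true odds ratios for the four osteoarthritis outcome subtypes
STUDY_TRUE_OR = {
    "AAM": {"overall_oa": 0.91, "hip_oa": 1.01, "knee_oa": 0.86, "hip_knee_oa": 0.92},
    "ANM": {"overall_oa": 1.00, "hip_oa": 0.98, "knee_oa": 1.00, "hip_knee_oa": 1.00},
    "AFB": {"overall_oa": 0.80, "hip_oa": 0.76, "knee_oa": 0.81, "hip_knee_oa": 0.79},
}

_STUDY_PRESET = {"AAM": "aam_like", "ANM": "anm_like", "AFB": "afb_like"}
#: fraction of each exposure's instruments loading on the shared BMI-like
#: confounder (AAM 51/349, ANM 0/54, AFB 2/10 in scale)
_STUDY_PROP_CONFOUNDED = {"AAM": 0.146, "ANM": 0.0, "AFB": 0.2}


@dataclass
class StudyBundle:
    exposures: dict[str, SummaryStatsTable]
    outcomes: dict[str, SummaryStatsTable]
    confounder: SummaryStatsTable
    ld: LDTable
    truths: dict[str, SimTruth]


def simulate_study(seed: int = 0) -> StudyBundle:
    """Three synthetic exposures against four shared outcome GWAS tables.

    Each exposure has its own instrument set (disjoint variant ids); the four
    outcome tables each cover all exposures' SNPs, with subtype-specific true
    causal effects. A BMI-like confounder GWAS covering every SNP is emitted
    for the pruning sensitivity analysis.
    """
    exposures: dict[str, SummaryStatsTable] = {}
    truths: dict[str, SimTruth] = {}
    outcome_parts: dict[str, list[pd.DataFrame]] = {k: [] for k in
                                                    next(iter(STUDY_TRUE_OR.values()))}
    conf_parts: list[pd.DataFrame] = []
    ld = LDTable()
    for i, (exp_name, preset_name) in enumerate(_STUDY_PRESET.items()):
        cfg = scenario_presets(preset_name, seed=seed)
        cfg = replace(
            cfg,
            id_offset=100_000 * (i + 1),
            prop_confounded=_STUDY_PROP_CONFOUNDED[exp_name],
            confounder_to_exposure=-0.1,
            confounder_to_outcome=0.5,
        )
        rng = np.random.default_rng([seed, i])
        truth_df = _draw_truth(cfg, rng)
        exposures[exp_name] = _exposure_table(truth_df, cfg, rng, exp_name)
        truths[exp_name] = SimTruth(causal_beta=cfg.causal_beta, snps=truth_df)
        for k, (out_name, or_true) in enumerate(STUDY_TRUE_OR[exp_name].items()):
            out_rng = np.random.default_rng([seed, i, k])
            part = _outcome_table(
                truth_df, cfg, out_rng, out_name, causal_beta=math.log(or_true)
            )
            outcome_parts[out_name].append(part.df)
        conf_rng = np.random.default_rng([seed, i, 99])
        conf_parts.append(_confounder_table(truth_df, cfg, conf_rng, "BMI").df)
        part_ld = _ld_table(truth_df, cfg)
        for (a, b), r2 in part_ld._r2.items():
            ld.add(a, b, r2)

    outcomes = {
        name: SummaryStatsTable(pd.concat(parts, ignore_index=True), name, "outcome")
        for name, parts in outcome_parts.items()
    }
    confounder = SummaryStatsTable(
        pd.concat(conf_parts, ignore_index=True), "BMI", "confounder"
    )
    return StudyBundle(
        exposures=exposures, outcomes=outcomes, confounder=confounder, ld=ld,
        truths=truths,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated pair as TSV files (exposure, outcome, optional
    confounder, LD pairs and per-SNP truth) with canonical column names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, table in (
        ("exposure", bundle.exposure),
        ("outcome", bundle.outcome),
        ("confounder", bundle.confounder),
    ):
        if table is None:
            continue
        p = outdir / f"{label}.tsv"
        table.df.to_csv(p, sep="\t", index=False)
        paths[label] = p
    ld_rows = [(a, b, r2) for (a, b), r2 in bundle.ld._r2.items()]
    ld_df = pd.DataFrame(ld_rows, columns=["variant_id_a", "variant_id_b", "r2"])
    p = outdir / "ld.tsv"
    ld_df.to_csv(p, sep="\t", index=False)
    paths["ld"] = p
    p = outdir / "truth.tsv"
    bundle.truth.snps.to_csv(p, sep="\t", index=False)
    paths["truth"] = p
    return paths
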