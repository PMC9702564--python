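"""Pipeline orchestration and reporting.

Runs select -> clump -> strength filter -> harmonize -> estimate -> diagnose
for every exposure/outcome pair, converts log-odds effects to odds ratios,
flags nominal (alpha) and Bonferroni (alpha / n_exposures*n_outcomes)
significance, and assembles table- and forest-plot-ready outputs. When
confounder GWAS tables are configured the grid is repeated with
confounder-pruned instrument sets, reported as "<exposure> no <confounder>"
rows.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from .estimators import MREstimate, Z975, run_all
from .exceptions import ConfigError, DomainError, EmptyDataError
from .harmonize import EAF_AMBIGUITY, harmonize_set
from .instruments import (
    InstrumentSet,
    build_instruments,
    clump,
    filter_weak,
    prune_confounder,
    select_genome_wide,
)
from .sumstats_io import LDTable, SummaryStatsTable, read_ld_table, read_sumstats

log = logging.getLogger(__name__)


def bonferroni_threshold(n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_exposures * n_outcomes)."""
    if n_exposures < 1 or n_outcomes < 1:
        raise DomainError("exposure and outcome counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds causal estimate and its confidence bounds."""
    return (
        math.exp(est.beta_hat),
        math.exp(est.beta_hat - Z975 * est.se),
        math.exp(est.beta_hat + Z975 * est.se),
    )


@dataclass(frozen=True)
class ReportRow:
    exposure: str
    outcome: str
    method: str
    n_snp: int
    mean_f: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    significant_bonferroni: bool
    significant_nominal: bool


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs: sources, thresholds, seeds."""

    exposures: Mapping[str, SummaryStatsTable]
    outcomes: Mapping[str, SummaryStatsTable]
    ld: LDTable
    seed: int
    confounders: Mapping[str, SummaryStatsTable] = field(default_factory=dict)
    p_instrument: float = 5e-8
    r2_clump: float = 0.01
    r2_proxy: float = 0.8
    f_min: float = 10.0
    eaf_ambiguity: tuple[float, float] = EAF_AMBIGUITY
    window_bp: Optional[int] = None
    ivw_model: str = "random"
    n_boot: int = 1000
    phi: float = 1.0
    n_sim: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name, val, lo, hi in (
            ("p_instrument", self.p_instrument, 0.0, 1.0),
            ("r2_clump", self.r2_clump, 0.0, 1.0),
            ("r2_proxy", self.r2_proxy, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
        ):
            if not (lo < val < hi or val == hi):
                raise ConfigError(f"{name} = {val} outside ({lo}, {hi}]")
        if self.f_min < 0:
            raise ConfigError("f_min must be >= 0")


@dataclass
class PairDiagnostics:
    presso: Optional[diag.PressoResult] = None
    leave_one_out: Optional[diag.LeaveOneOutResult] = None
    funnel: Optional[diag.FunnelResult] = None
    dropped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PipelineResult:
    rows: list[ReportRow]
    diagnostics: dict[tuple[str, str], PairDiagnostics]
    instrument_sets: dict[str, InstrumentSet]
    errors: list[tuple[str, str, str]]  # (exposure, outcome, message)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def _pair_seed(seed: int, exposure: str, outcome: str) -> int:
    """Deterministic per-pair seed below 2**31."""
    h = zlib.crc32(f"{exposure}|{outcome}".encode())
    return int((seed * 2654435761 + h) % (2**31 - 1))


def _select_instruments(config: AnalysisConfig, name: str, table: SummaryStatsTable) -> InstrumentSet:
    candidates = select_genome_wide(table, config.p_instrument)
    clumped = clump(candidates, config.ld, config.r2_clump, config.window_bp)
    inst = filter_weak(build_instruments(clumped), config.f_min, exposure_name=name)
    log.info(
        "%s: %d genome-wide hits -> %d clumped -> %d strong (mean F %.2f)",
        name, len(candidates), len(clumped), inst.n_retained, inst.mean_f,
    )
    return inst


def _estimate_pair(
    config: AnalysisConfig,
    exp_label: str,
    inst: InstrumentSet,
    out_name: str,
    out_table: SummaryStatsTable,
    bonf: float,
) -> tuple[list[ReportRow], PairDiagnostics]:
    hd = harmonize_set(
        inst, out_table, config.ld,
        eaf_ambiguity=config.eaf_ambiguity, r2_proxy=config.r2_proxy,
    )
    f_by_id = {r.variant_id: r.f_stat for r in inst.retained}
    mean_f = float(np.mean([f_by_id[r.variant_id] for r in hd.records]))
    seed = _pair_seed(config.seed, exp_label, out_name)
    estimates, _ = run_all(
        hd, seed=seed, ivw_model=config.ivw_model, n_boot=config.n_boot, phi=config.phi
    )
    rows = []
    for est in estimates:
        or_, lo, hi = to_odds_ratio(est)
        rows.append(
            ReportRow(
                exposure=exp_label,
                outcome=out_name,
                method=est.method,
                n_snp=est.n_snp,
                mean_f=mean_f,
                odds_ratio=or_,
                ci_low=lo,
                ci_high=hi,
                pvalue=est.pvalue,
                significant_bonferroni=est.pvalue < bonf,
                significant_nominal=est.pvalue < config.alpha,
            )
        )
    pd_ = PairDiagnostics(dropped=list(hd.dropped))
    ivw_est = estimates[0]
    if hd.n_snp >= 4:
        pd_.presso = diag.presso(hd, n_sim=config.n_sim, seed=seed + 1)
    if hd.n_snp >= 2:
        pd_.leave_one_out = diag.leave_one_out(hd)
    pd_.funnel = diag.funnel_data(hd, ivw_est)
    return rows, pd_


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run the full exposure-by-outcome MR grid.

    Deterministic given config + seed. A stage failure for one pair (for
    example zero surviving harmonized records) is recorded in ``errors``
    while the remaining pairs still run.
    """
    bonf = bonferroni_threshold(len(config.exposures), len(config.outcomes), config.alpha)
    rows: list[ReportRow] = []
    diagnostics: dict[tuple[str, str], PairDiagnostics] = {}
    instrument_sets: dict[str, InstrumentSet] = {}
    errors: list[tuple[str, str, str]] = []

    # base instrument sets, then confounder-pruned variants appended
    labelled: list[tuple[str, InstrumentSet]] = []
    for exp_name, exp_table in config.exposures.items():
        inst = _select_instruments(config, exp_name, exp_table)
        instrument_sets[exp_name] = inst
        labelled.append((exp_name, inst))
    for exp_name, exp_table in config.exposures.items():
        for conf_name, conf_table in config.confounders.items():
            pruned = prune_confounder(
                instrument_sets[exp_name], conf_table, config.p_instrument
            )
            if pruned.n_retained < instrument_sets[exp_name].n_retained:
                label = f"{exp_name} no {conf_name}"
                instrument_sets[label] = pruned
                labelled.append((label, pruned))

    for exp_label, inst in labelled:
        for out_name, out_table in config.outcomes.items():
            try:
                pair_rows, pair_diag = _estimate_pair(
                    config, exp_label, inst, out_name, out_table, bonf
                )
            except EmptyDataError as exc:
                errors.append((exp_label, out_name, str(exc)))
                continue
            rows.extend(pair_rows)
            diagnostics[(exp_label, out_name)] = pair_diag
    return PipelineResult(
        rows=rows, diagnostics=diagnostics, instrument_sets=instrument_sets, errors=errors
    )


def forest_table(rows: list[ReportRow], method: Optional[str] = None) -> pd.DataFrame:
    """Plot-ready table grouped by exposure, preserving row order within groups."""
    if not rows:
        raise ConfigError("no rows to tabulate")
    df = pd.DataFrame([r.__dict__ for r in rows])
    if method is not None:
        df = df[df["method"] == method]
    df = df.sort_values(["exposure", "outcome", "method"], kind="stable")
    df["marker"] = np.where(
        df["significant_bonferroni"], "**", np.where(df["significant_nominal"], "*", "")
    )
    return df.reset_index(drop=True)


def plot_forest(rows: list[ReportRow], path: str | Path, method: str = "ivw_re") -> Path:
    """Render a simple forest plot (odds ratios with 95% CIs) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = forest_table(rows, method=method)
    labels = [f"{e} → {o}" for e, o in zip(df["exposure"], df["outcome"])]
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    ax.errorbar(
        df["odds_ratio"], y,
        xerr=[df["odds_ratio"] - df["ci_low"], df["ci_high"] - df["odds_ratio"]],
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="crimson", linestyle="--", linewidth=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Odds ratio per unit exposure (95% CI)")
    ax.set_title(f"MR estimates ({method})")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)
    return path


def load_config(path: str | Path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file.

    Expected layout::

        seed: 7
        ld: ld.tsv
        exposures:
          AFB: {path: afb.tsv, column_map: {variant_id: SNP, beta: b, ...}}
        outcomes:
          overall_oa: {path: oa.tsv, column_map: {...}}
        confounders:
          BMI: {path: bmi.tsv, column_map: {...}}
        thresholds: {p_instrument: 5.0e-8, r2_clump: 0.01, f_min: 10}
        estimation: {ivw_model: random, n_boot: 1000, phi: 1.0, n_sim: 1000}
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent

    def load_group(group: Mapping, trait_type: str) -> dict[str, SummaryStatsTable]:
        out = {}
        for name, entry in (group or {}).items():
            out[name] = read_sumstats(
                base / entry["path"], entry["column_map"], name, trait_type
            )
        return out

    ld = read_ld_table(base / doc["ld"]) if doc.get("ld") else LDTable()
    thresholds = doc.get("thresholds", {})
    estimation = doc.get("estimation", {})
    return AnalysisConfig(
        exposures=load_group(doc.get("exposures"), "exposure"),
        outcomes=load_group(doc.get("outcomes"), "outcome"),
        confounders=load_group(doc.get("confounders"), "confounder"),
        ld=ld,
        seed=int(doc["seed"]),
        **{k: thresholds[k] for k in
           ("p_instrument", "r2_clump", "r2_proxy", "f_min") if k in thresholds},
        **{k: estimation[k] for k in
           ("ivw_model", "n_boot", "phi", "n_sim") if k in estimation},
    )
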