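"""Instrument selection: significance screen, LD clumping, strength filtering,
proxy lookup and confounder pruning.

An instrumental variant must be robustly associated with the exposure
(genome-wide significance, p < 5e-8), quasi-independent of the other selected
variants (pairwise r2 <= 0.01 after greedy clumping on the smallest p-value),
and strong (F-statistic >= 10). The variance in the exposure explained by a
variant is computed from summary statistics as

    R2 = 2 b^2 q (1-q) / (2 b^2 q (1-q) + 2 se^2 N q (1-q))

which algebraically reduces to b^2 / (b^2 + se^2 N); the instrument F-statistic
is F = R2 (N - 2) / (1 - R2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import DomainError
from .sumstats_io import LDTable, SummaryStatsTable, VariantRecord

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.01
PROXY_R2 = 0.8
F_MIN = 10.0

EXCLUSION_REASONS = (
    "missing_in_outcome",
    "palindromic_ambiguous",
    "weak_instrument",
    "confounder_associated",
    "ld_pruned",
)


@dataclass(frozen=True)
class InstrumentRecord:
    """A candidate instrument with its exposure-side strength statistics."""

    variant: VariantRecord
    r2_explained: float
    f_stat: float
    is_proxy: bool = False
    proxy_of: Optional[str] = None
    excluded_reason: Optional[str] = None

    @property
    def variant_id(self) -> str:
        return self.variant.variant_id


@dataclass
class InstrumentSet:
    """Retained and excluded instruments for one exposure."""

    exposure_name: str
    retained: list[InstrumentRecord] = field(default_factory=list)
    excluded: list[InstrumentRecord] = field(default_factory=list)

    @property
    def mean_f(self) -> float:
        if not self.retained:
            return float("nan")
        return float(np.mean([r.f_stat for r in self.retained]))

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def __len__(self) -> int:
        return len(self.retained) + len(self.excluded)


def select_genome_wide(
    stats: SummaryStatsTable, p_threshold: float = GENOME_WIDE_P
) -> list[VariantRecord]:
    """Variants passing the genome-wide significance screen, ascending by p.

    Strict inequality (p < threshold); ties in p are broken by variant id so
    the ordering is reproducible.
    """
    hits = [rec for rec in stats if rec.pvalue < p_threshold]
    hits.sort(key=lambda r: (r.pvalue, r.variant_id))
    if not hits:
        log.info("%s: no variants pass p < %g", stats.trait_name, p_threshold)
    return hits


def clump(
    candidates: Sequence[VariantRecord],
    ld: LDTable,
    r2_threshold: float = CLUMP_R2,
    window_bp: Optional[int] = None,
) -> list[VariantRecord]:
    """Greedy LD clumping: keep the smallest-p variant of every correlated group.

    Repeatedly retain the remaining candidate with the smallest p-value and
    discard every remaining candidate with r2 > ``r2_threshold`` against it.
    If ``window_bp`` is given, candidates within that distance of a retained
    variant on the same chromosome are discarded as well (distance-based
    pre-screen; skipped for variants without positions). The result depends
    only on p-values, ids and LD, not on input order.
    """
    pool = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    retained: list[VariantRecord] = []
    while pool:
        lead = pool.pop(0)
        retained.append(lead)
        survivors = []
        for cand in pool:
            if ld.r2(lead.variant_id, cand.variant_id) > r2_threshold:
                continue
            if (
                window_bp is not None
                and lead.chrom is not None
                and cand.chrom == lead.chrom
                and lead.pos is not None
                and cand.pos is not None
                and abs(cand.pos - lead.pos) <= window_bp
            ):
                continue
            survivors.append(cand)
        pool = survivors
    return retained


def compute_strength(variant: VariantRecord) -> tuple[float, float]:
    """Variance explained (R2) and instrument F-statistic for one variant.

    Evaluates the full summary-statistic form of R2 (the 2q(1-q) factor
    appears in both numerator and denominator and cancels algebraically,
    making the result symmetric in eaf vs 1-eaf).
    """
    if variant.n <= 2:
        raise DomainError(f"{variant.variant_id}: sample size {variant.n} <= 2")
    b, se, q, n = variant.beta, variant.se, variant.eaf, variant.n
    num = 2.0 * b * b * q * (1.0 - q)
    den = num + 2.0 * se * se * n * q * (1.0 - q)
    r2 = num / den if den > 0 else 0.0
    f = r2 * (n - 2) / (1.0 - r2)
    return r2, f


def build_instruments(variants: Iterable[VariantRecord]) -> list[InstrumentRecord]:
    """Attach R2/F statistics to each candidate variant."""
    out = []
    for v in variants:
        r2, f = compute_strength(v)
        out.append(InstrumentRecord(variant=v, r2_explained=r2, f_stat=f))
    return out


def filter_weak(
    instruments: Sequence[InstrumentRecord],
    f_min: float = F_MIN,
    exposure_name: str = "",
) -> InstrumentSet:
    """Reject weak instruments (F below ``f_min``); F >= f_min is retained."""
    kept, rejected = [], []
    for inst in instruments:
        if inst.f_stat >= f_min:
            kept.append(inst)
        else:
            rejected.append(replace(inst, excluded_reason="weak_instrument"))
    return InstrumentSet(exposure_name=exposure_name, retained=kept, excluded=rejected)


def find_proxy(
    missing: VariantRecord,
    outcome: SummaryStatsTable,
    ld: LDTable,
    r2_min: float = PROXY_R2,
) -> Optional[VariantRecord]:
    """Best available proxy for an instrument absent from the outcome GWAS.

    Among outcome variants in strong LD (r2 > ``r2_min``) with the missing
    instrument, returns the one with the highest r2; ties are broken by the
    smaller outcome p-value, then lexicographic id. Returns None when no
    adequate proxy exists.
    """
    best: Optional[tuple[float, float, str, VariantRecord]] = None
    for vid, r2 in ld.partners(missing.variant_id, min_r2=r2_min):
        if vid not in outcome:
            continue
        rec = outcome.get(vid)
        key = (-r2, rec.pvalue, vid)
        if best is None or key < (best[0], best[1], best[2]):
            best = (-r2, rec.pvalue, vid, rec)
    return best[3] if best else None


def prune_confounder(
    instruments: InstrumentSet,
    confounder: SummaryStatsTable,
    p_threshold: float = GENOME_WIDE_P,
) -> InstrumentSet:
    """Remove instruments significantly associated with a confounder trait.

    A retained instrument whose association with the confounder reaches
    ``p < p_threshold`` is moved to the excluded list with reason
    ``confounder_associated``. Instruments absent from the confounder table
    are kept (no evidence of association). Exact-id lookup only.
    """
    kept, newly_excluded = [], []
    for inst in instruments.retained:
        vid = inst.variant_id
        if vid in confounder and confounder.get(vid).pvalue < p_threshold:
            newly_excluded.append(replace(inst, excluded_reason="confounder_associated"))
        else:
            kept.append(inst)
    if newly_excluded:
        log.info(
            "%s: pruned %d instrument(s) associated with %s",
            instruments.exposure_name,
            len(newly_excluded),
            confounder.trait_name,
        )
    return InstrumentSet(
        exposure_name=instruments.exposure_name,
        retained=kept,
        excluded=list(instruments.excluded) + newly_excluded,
    )
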