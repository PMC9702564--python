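"""Harmonization of exposure and outcome effects onto a common effect allele.

The exposure table's allele convention is the reference: the outcome record is
flipped (effect negated, frequency complemented) or strand-complemented to
match it. Palindromic variants (A/T or G/C) cannot be oriented from allele
letters alone; orientation falls back on effect-allele-frequency agreement and
the variant is dropped when either side's frequency is too close to 0.5 to be
informative (the configurable ambiguity window, default [0.42, 0.58]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import EmptyDataError
from .instruments import InstrumentSet, find_proxy
from .sumstats_io import LDTable, SummaryStatsTable, VariantRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
EAF_AMBIGUITY = (0.42, 0.58)

ACTIONS = ("none", "allele_flip", "strand_flip", "strand_flip_and_allele_flip")


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedRecord:
    """Aligned per-SNP effect pair: exposure (gamma, sigma_x), outcome (Gamma, sigma_y)."""

    variant_id: str
    gamma: float
    sigma_x: float
    Gamma: float
    sigma_y: float
    eaf_exposure: float
    eaf_outcome: float
    action_taken: str
    is_proxy: bool = False
    proxy_id: Optional[str] = None


@dataclass
class HarmonizedData:
    """Harmonized exposure/outcome effect pairs plus the drop ledger."""

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, sigma_x, Gamma, sigma_y) as float arrays in record order."""
        g = np.array([r.gamma for r in self.records], dtype=float)
        sx = np.array([r.sigma_x for r in self.records], dtype=float)
        G = np.array([r.Gamma for r in self.records], dtype=float)
        sy = np.array([r.sigma_y for r in self.records], dtype=float)
        return g, sx, G, sy

    def without(self, variant_id: str) -> "HarmonizedData":
        return HarmonizedData(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            records=[r for r in self.records if r.variant_id != variant_id],
        )

    def subset(self, variant_ids: Sequence[str]) -> "HarmonizedData":
        keep = set(variant_ids)
        return HarmonizedData(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            records=[r for r in self.records if r.variant_id in keep],
        )

    @classmethod
    def from_arrays(
        cls,
        gamma: Sequence[float],
        sigma_x: Sequence[float],
        Gamma: Sequence[float],
        sigma_y: Sequence[float],
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        variant_ids: Optional[Sequence[str]] = None,
    ) -> "HarmonizedData":
        """Convenience constructor for already-aligned effect arrays."""
        n = len(gamma)
        ids = list(variant_ids) if variant_ids is not None else [f"snp{i+1}" for i in range(n)]
        recs = [
            HarmonizedRecord(
                variant_id=ids[i],
                gamma=float(gamma[i]),
                sigma_x=float(sigma_x[i]),
                Gamma=float(Gamma[i]),
                sigma_y=float(sigma_y[i]),
                eaf_exposure=0.5,
                eaf_outcome=0.5,
                action_taken="none",
            )
            for i in range(n)
        ]
        return cls(exposure_name=exposure_name, outcome_name=outcome_name, records=recs)


def harmonize_pair(
    exp: VariantRecord,
    out: VariantRecord,
    eaf_ambiguity: tuple[float, float] = EAF_AMBIGUITY,
    is_proxy: bool = False,
    proxy_id: Optional[str] = None,
) -> tuple[Optional[HarmonizedRecord], Optional[str]]:
    """Align one outcome record to the exposure's effect allele.

    Returns ``(record, None)`` on success or ``(None, reason)`` when the pair
    must be dropped (``invalid_alleles``, ``allele_mismatch``,
    ``palindromic_ambiguous``).

    Cases: matching alleles are taken as-is; swapped alleles negate the
    outcome effect and complement its frequency; strand-complemented alleles
    are mapped through A<->T / C<->G first. For palindromic variants the two
    strand interpretations are indistinguishable from the letters, so the
    orientation with frequency agreement (both sides minor, or both major, for
    the same allele) is chosen; if either frequency falls inside the ambiguity
    window the variant is dropped.
    """
    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    if any(b not in COMPLEMENT for b in (e1, e2, o1, o2)):
        return None, "invalid_alleles"

    lo, hi = eaf_ambiguity

    def build(Gamma: float, eaf_out: float, action: str) -> HarmonizedRecord:
        return HarmonizedRecord(
            variant_id=exp.variant_id,
            gamma=exp.beta,
            sigma_x=exp.se,
            Gamma=Gamma,
            sigma_y=out.se,
            eaf_exposure=exp.eaf,
            eaf_outcome=eaf_out,
            action_taken=action,
            is_proxy=is_proxy,
            proxy_id=proxy_id,
        )

    if is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return None, "allele_mismatch"
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return None, "palindromic_ambiguous"
        # frequency of the exposure's effect allele on the outcome side,
        # reading the letters at face value
        eaf_for_e1 = out.eaf if o1 == e1 else 1.0 - out.eaf
        letters_swapped = o1 != e1
        if (exp.eaf < 0.5) == (eaf_for_e1 < 0.5):
            # face-value reading is frequency-consistent
            if letters_swapped:
                return build(-out.beta, eaf_for_e1, "allele_flip"), None
            return build(out.beta, eaf_for_e1, "none"), None
        # frequencies disagree: the outcome is reported on the opposite strand
        if letters_swapped:
            return build(out.beta, 1.0 - eaf_for_e1, "strand_flip"), None
        return build(-out.beta, 1.0 - eaf_for_e1, "strand_flip_and_allele_flip"), None

    if (o1, o2) == (e1, e2):
        return build(out.beta, out.eaf, "none"), None
    if (o1, o2) == (e2, e1):
        return build(-out.beta, 1.0 - out.eaf, "allele_flip"), None
    c1, c2 = COMPLEMENT[o1], COMPLEMENT[o2]
    if (c1, c2) == (e1, e2):
        return build(out.beta, out.eaf, "strand_flip"), None
    if (c1, c2) == (e2, e1):
        return build(-out.beta, 1.0 - out.eaf, "strand_flip_and_allele_flip"), None
    return None, "allele_mismatch"


def harmonize_set(
    instruments: InstrumentSet,
    outcome: SummaryStatsTable,
    ld: LDTable,
    eaf_ambiguity: tuple[float, float] = EAF_AMBIGUITY,
    r2_proxy: float = 0.8,
) -> HarmonizedData:
    """Harmonize every retained instrument against the outcome GWAS.

    Instruments absent from the outcome are substituted by their best proxy in
    strong LD (r2 > ``r2_proxy``) when one is available in the outcome table;
    the proxy contributes the outcome-side effect while the original
    instrument keeps the exposure-side effect (standard proxy practice; proxy
    allele coding is assumed shared with the index variant). Every input
    instrument ends up exactly once in ``records`` or ``dropped``.
    """
    data = HarmonizedData(
        exposure_name=instruments.exposure_name, outcome_name=outcome.trait_name
    )
    for inst in instruments.retained:
        vid = inst.variant_id
        if vid in outcome:
            rec, reason = harmonize_pair(inst.variant, outcome.get(vid), eaf_ambiguity)
        else:
            proxy = find_proxy(inst.variant, outcome, ld, r2_min=r2_proxy)
            if proxy is None:
                data.dropped.append((vid, "missing_in_outcome"))
                continue
            rec, reason = harmonize_pair(
                inst.variant,
                proxy,
                eaf_ambiguity,
                is_proxy=True,
                proxy_id=proxy.variant_id,
            )
        if rec is not None:
            data.records.append(rec)
        else:
            data.dropped.append((vid, reason or "unknown"))
    if not data.records:
        raise EmptyDataError(
            f"no harmonized records for {instruments.exposure_name} -> {outcome.trait_name}"
        )
    return data
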