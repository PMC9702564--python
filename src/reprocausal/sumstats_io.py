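"""Reading, validating and writing GWAS summary-statistic tables and LD lookups.

GWAS summary files in the wild carry arbitrary column names, so reading is
driven by an explicit ``column_map`` from canonical field names to source
columns. Rows that violate per-variant invariants (missing values, out-of-range
allele frequency or standard error, indel alleles) are dropped and counted
rather than failing the whole file; duplicated variant identifiers are a hard
error because every downstream join is keyed on them.
"""

from __future__ import annotations

import io
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical per-variant fields; chrom/pos are optional metadata
REQUIRED_FIELDS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
OPTIONAL_FIELDS = ("chrom", "pos")
ALL_FIELDS = REQUIRED_FIELDS + OPTIONAL_FIELDS

TRAIT_TYPES = ("exposure", "outcome", "confounder")


@dataclass(frozen=True)
class VariantRecord:
    """One per-variant GWAS association record.

    ``beta`` is the per-effect-allele effect on the trait (SD units for a
    quantitative trait, log-odds for a case-control trait), ``se`` its standard
    error, ``eaf`` the effect-allele frequency and ``n`` the analysed sample
    size.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: identical alleles")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.variant_id}: eaf {self.eaf} outside (0, 1)")
        if not (self.se > 0.0):
            raise ValidationError(f"{self.variant_id}: se must be positive")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.variant_id}: pvalue outside (0, 1]")


class SummaryStatsTable:
    """Validated GWAS summary statistics for a single trait (one sample).

    Wraps a :class:`pandas.DataFrame` with canonical columns and provides
    keyed access by ``variant_id``. Construction enforces uniqueness of
    variant identifiers; per-row invariants are enforced when rows are
    filtered in :func:`read_sumstats` / :meth:`from_dataframe`.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        trait_name: str,
        trait_type: str,
        drop_counts: Optional[Mapping[str, int]] = None,
    ) -> None:
        if trait_type not in TRAIT_TYPES:
            raise ConfigError(f"trait_type must be one of {TRAIT_TYPES}, got {trait_type!r}")
        missing = [c for c in REQUIRED_FIELDS if c not in df.columns]
        if missing:
            raise ConfigError(f"summary table missing canonical columns: {missing}")
        dup = df["variant_id"][df["variant_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"{trait_name}: duplicate variant_id values: {sorted(set(dup))[:10]}"
            )
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.drop_counts: dict[str, int] = dict(drop_counts or {})
        self._df = df.reset_index(drop=True)
        self._index = {vid: i for i, vid in enumerate(self._df["variant_id"])}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __iter__(self) -> Iterator[VariantRecord]:
        for vid in self._df["variant_id"]:
            yield self.get(vid)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def variant_ids(self) -> list[str]:
        return list(self._df["variant_id"])

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_counts.values())

    def get(self, variant_id: str) -> VariantRecord:
        row = self._df.iloc[self._index[variant_id]]
        chrom = row.get("chrom")
        pos = row.get("pos")
        return VariantRecord(
            variant_id=str(row["variant_id"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            n=int(row["n"]),
            chrom=None if pd.isna(chrom) else str(chrom),
            pos=None if pd.isna(pos) else int(pos),
        )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[VariantRecord], trait_name: str, trait_type: str
    ) -> "SummaryStatsTable":
        df = pd.DataFrame([r.__dict__ for r in records], columns=list(ALL_FIELDS))
        return cls(df, trait_name, trait_type)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, trait_name: str, trait_type: str
    ) -> "SummaryStatsTable":
        """Filter a raw canonical-column frame down to valid rows.

        Invalid rows are dropped and tallied in ``drop_counts`` by reason:
        ``missing``, ``indel_allele``, ``invalid_allele``, ``identical_alleles``,
        ``eaf_out_of_range``, ``nonpositive_se``, ``invalid_pvalue``,
        ``nonpositive_n``.
        """
        counts: dict[str, int] = defaultdict(int)
        work = df.copy()
        for col in OPTIONAL_FIELDS:
            if col not in work.columns:
                work[col] = pd.NA

        for col in ("eaf", "beta", "se", "pvalue", "n"):
            work[col] = pd.to_numeric(work[col], errors="coerce")
        for col in ("variant_id", "effect_allele", "other_allele"):
            work[col] = work[col].astype("string").str.strip()
        work["effect_allele"] = work["effect_allele"].str.upper()
        work["other_allele"] = work["other_allele"].str.upper()

        def drop(mask: pd.Series, reason: str) -> None:
            nonlocal work
            k = int(mask.sum())
            if k:
                counts[reason] += k
                work = work[~mask]

        drop(work[list(REQUIRED_FIELDS)].isna().any(axis=1), "missing")
        ea, oa = work["effect_allele"], work["other_allele"]
        drop((ea.str.len() > 1) | (oa.str.len() > 1), "indel_allele")
        ea, oa = work["effect_allele"], work["other_allele"]
        valid = ea.isin(list(VALID_BASES)) & oa.isin(list(VALID_BASES))
        drop(~valid, "invalid_allele")
        drop(work["effect_allele"] == work["other_allele"], "identical_alleles")
        drop(~((work["eaf"] > 0) & (work["eaf"] < 1)), "eaf_out_of_range")
        drop(~(work["se"] > 0), "nonpositive_se")
        drop(~((work["pvalue"] > 0) & (work["pvalue"] <= 1)), "invalid_pvalue")
        drop(~(work["n"] > 0), "nonpositive_n")

        work["n"] = work["n"].astype(int)
        if counts:
            log.info(
                "%s: dropped %d of %d rows (%s)",
                trait_name,
                sum(counts.values()),
                len(df),
                dict(counts),
            )
        return cls(work[list(ALL_FIELDS)], trait_name, trait_type, drop_counts=counts)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_name: str,
    trait_type: str,
) -> SummaryStatsTable:
    """Read a delimited GWAS summary-statistic file.

    ``column_map`` maps canonical field names (``variant_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``; optionally
    ``chrom``, ``pos``) to the column names used in the file. The delimiter is
    auto-detected from the header line (tab preferred over comma).
    """
    path = Path(path)
    unknown = [k for k in column_map if k not in ALL_FIELDS]
    if unknown:
        raise ConfigError(f"unknown canonical fields in column_map: {unknown}")
    missing_map = [k for k in REQUIRED_FIELDS if k not in column_map]
    if missing_map:
        raise ConfigError(f"column_map missing required fields: {missing_map}")

    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    absent = [src for src in column_map.values() if src not in raw.columns]
    if absent:
        raise ConfigError(f"{path}: mapped columns not found in file: {absent}")

    canonical = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})
    return SummaryStatsTable.from_dataframe(canonical, trait_name, trait_type)


class LDTable:
    """Symmetric pairwise r-squared lookup.

    Self-LD is implicitly 1; a pair absent from the table is treated as
    unlinked (r2 = 0). Conflicting duplicate entries are rejected.
    """

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = defaultdict(dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return  # self-LD is implicit
        key = self._key(a, b)
        old = self._r2.get(key)
        if old is not None and not math.isclose(old, r2, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(f"conflicting r2 entries for ({a},{b}): {old} vs {r2}")
        self._r2[key] = r2
        self._adj[a][b] = r2
        self._adj[b][a] = r2

    @classmethod
    def from_pairs(cls, entries: Iterable[tuple[str, str, float]]) -> "LDTable":
        tab = cls()
        for a, b, r2 in entries:
            tab.add(str(a), str(b), float(r2))
        return tab

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, a: str, min_r2: float = 0.0) -> list[tuple[str, float]]:
        """All variants with recorded r2 > ``min_r2`` against ``a``."""
        return [(b, r2) for b, r2 in self._adj.get(a, {}).items() if r2 > min_r2]

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_table(path: str | Path) -> LDTable:
    """Read a three-column (id_a, id_b, r2) pair list, with or without header."""
    path = Path(path)
    with open(path, "r") as fh:
        first = fh.readline().strip()
    if not first:
        return LDTable()
    sep = "\t" if "\t" in first else ","
    parts = first.split(sep)
    if len(parts) < 3:
        raise ValidationError(f"{path}: expected 3 columns, got {len(parts)}")
    try:
        float(parts[2])
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=sep, header=header)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "r2"]
    return LDTable.from_pairs(df.itertuples(index=False, name=None))


RESULT_COLUMNS = (
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "mean_F",
    "OR",
    "CI_low",
    "CI_high",
    "pvalue",
)


def _fmt(x: object) -> str:
    if isinstance(x, float):
        return "nan" if math.isnan(x) else f"{x:.6g}"
    return str(x)


def write_results(rows: Sequence[object], path: str | Path) -> None:
    """Write report rows as a TSV that round-trips losslessly at 6 significant digits.

    ``rows`` are any objects exposing the attributes ``exposure``, ``outcome``,
    ``method``, ``n_snp``, ``mean_f``, ``odds_ratio``, ``ci_low``, ``ci_high``,
    ``pvalue`` (duck-typed so the I/O layer does not depend on the report layer).
    """
    attr_of = {
        "mean_F": "mean_f",
        "OR": "odds_ratio",
        "CI_low": "ci_low",
        "CI_high": "ci_high",
    }
    buf = io.StringIO()
    buf.write("\t".join(RESULT_COLUMNS) + "\n")
    for row in rows:
        vals = [getattr(row, attr_of.get(col, col)) for col in RESULT_COLUMNS]
        buf.write("\t".join(_fmt(v) for v in vals) + "\n")
    Path(path).write_text(buf.getvalue())


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: results file missing columns {missing}")
    return df
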