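"""GWAS summary-statistics containers, validation, and text I/O.

The canonical on-disk format is a tab-separated table with one row per
variant and the header ``rsid  chrom  pos  effect_allele  other_allele
eaf  beta  se  pval  n``.  ``beta`` is the per-allele effect on the trait
(log-odds for binary traits, standard-deviation units for continuous
traits), ``se`` its standard error, ``eaf`` the effect-allele frequency.
A ``column_map`` argument lets :func:`read_sumstats` ingest tables with
other header dialects (IEU-OpenGWAS-style, GWAS-Catalog-style, ...)
without converting files on disk.

Validation drops rows that cannot be used downstream (non-positive
standard errors, p-values outside ``(0, 1]``, malformed alleles, ...) and
logs a count per reason; values of retained rows are never altered
beyond uppercasing alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")

#: Header aliases recognised without an explicit column_map (matched
#: case-insensitively).  Explicit column_map entries take precedence.
DEFAULT_ALIASES: Mapping[str, str] = {
    "rsid": "rsid",
    "snp": "rsid",
    "variant_id": "rsid",
    "markername": "rsid",
    "chrom": "chrom",
    "chr": "chrom",
    "chromosome": "chrom",
    "pos": "pos",
    "bp": "pos",
    "position": "pos",
    "base_pair_location": "pos",
    "effect_allele": "effect_allele",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "allele1": "effect_allele",
    "other_allele": "other_allele",
    "oa": "other_allele",
    "a2": "other_allele",
    "allele2": "other_allele",
    "non_effect_allele": "other_allele",
    "eaf": "eaf",
    "effect_allele_frequency": "eaf",
    "freq": "eaf",
    "af": "eaf",
    "maf": "eaf",
    "beta": "beta",
    "b": "beta",
    "effect": "beta",
    "se": "se",
    "standard_error": "se",
    "stderr": "se",
    "pval": "pval",
    "p": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "n": "n",
    "samplesize": "n",
    "sample_size": "n",
}

_BASES = frozenset("ACGT")


@dataclass
class VariantAssociation:
    """One variant's summary association for one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None


def _valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) >= 1 and set(a) <= _BASES


def compute_f_statistic(v: VariantAssociation) -> float:
    """Instrument-strength F-statistic, ``beta**2 / se**2``.

    Invariant to the sign of ``beta``; raises :class:`ValueError` if the
    standard error is not strictly positive.
    """
    if not v.se > 0:
        raise ValueError(f"se must be > 0, got {v.se!r}")
    return (v.beta / v.se) ** 2


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Return (valid rows, counts of dropped rows by reason)."""
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]

    df["rsid"] = df["rsid"].astype("string")
    df["chrom"] = df["chrom"].astype("string")
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype("string").str.upper()
    df["other_allele"] = df["other_allele"].astype("string").str.upper()

    dropped: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            dropped[reason] = dropped.get(reason, 0) + n
        return ~mask

    ea = df["effect_allele"]
    oa = df["other_allele"]
    ok = _drop(df["rsid"].isna() | (df["rsid"].str.len() == 0), "missing rsid")
    allele_ok = ea.map(_valid_allele, na_action="ignore").fillna(False).astype(
        bool
    ) & oa.map(_valid_allele, na_action="ignore").fillna(False).astype(bool)
    ok &= _drop(~allele_ok, "malformed alleles")
    ok &= _drop(allele_ok & (ea == oa), "identical alleles")
    ok &= _drop(~(df["beta"].notna() & np.isfinite(df["beta"].fillna(np.nan))), "missing beta")
    ok &= _drop(~(df["se"] > 0), "non-positive or missing se")
    ok &= _drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "p-value outside (0,1]")
    bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0)
    ok &= _drop(bad_eaf, "eaf outside [0,1]")
    bad_n = df["n"].notna() & ~(df["n"] > 0)
    ok &= _drop(bad_n, "non-positive n")

    df = df[ok]

    # Duplicate rsids: keep the row with the smallest p-value (stable).
    if df["rsid"].duplicated().any():
        order = np.argsort(df["pval"].to_numpy(), kind="stable")
        first = df.iloc[order].drop_duplicates("rsid", keep="first")
        n_dup = len(df) - len(first)
        dropped["duplicate rsid"] = dropped.get("duplicate rsid", 0) + n_dup
        df = first.sort_index()

    df["pos"] = df["pos"].astype("Int64")
    return df.reset_index(drop=True), dropped


class SummaryStats:
    """An ordered collection of variant associations for one trait.

    Thin wrapper around a validated :class:`pandas.DataFrame` with the
    canonical columns; ``trait_label`` and free-text ``provenance`` ride
    along for reporting.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        trait_label: str = "trait",
        provenance: str = "",
        validate: bool = True,
    ):
        if validate:
            df, dropped = _validate_frame(table)
            for reason, count in dropped.items():
                logger.warning(
                    "%s: dropped %d row(s): %s", trait_label, count, reason
                )
        else:
            df = table.reset_index(drop=True)
        self.df = df
        self.trait_label = trait_label
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SummaryStats({self.trait_label!r}, {len(self)} variants)"

    def subset(self, mask) -> "SummaryStats":
        """New SummaryStats with rows selected by a boolean mask (no re-validation)."""
        return SummaryStats(
            self.df[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            trait_label=self.trait_label,
            provenance=self.provenance,
            validate=False,
        )

    def variants(self) -> Iterator[VariantAssociation]:
        for row in self.df.itertuples(index=False):
            yield VariantAssociation(
                rsid=row.rsid,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
                pos=None if pd.isna(row.pos) else int(row.pos),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )

    @classmethod
    def from_variants(
        cls,
        variants,
        trait_label: str = "trait",
        provenance: str = "",
    ) -> "SummaryStats":
        rows = [
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "eaf": v.eaf,
                "beta": v.beta,
                "se": v.se,
                "pval": v.pval,
                "n": v.n,
            }
            for v in variants
        ]
        return cls(pd.DataFrame(rows, columns=CANONICAL_COLUMNS), trait_label, provenance)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
) -> SummaryStats:
    """Read a tab- or comma-separated summary-statistics table.

    ``column_map`` maps file headers to canonical field names; headers not
    covered by it are matched case-insensitively against common aliases.
    Raises :class:`ConfigurationError` when a required column cannot be
    resolved and :class:`EmptyInputError` when no valid row survives.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_detect_sep(path),
        na_values=["NA", ""],
        dtype={"chrom": str},
        float_precision="round_trip",
    )

    rename: dict[str, str] = {}
    explicit = dict(column_map or {})
    for col in df.columns:
        if col in explicit:
            rename[col] = explicit[col]
        elif col.lower() in DEFAULT_ALIASES:
            rename[col] = DEFAULT_ALIASES[col.lower()]
    df = df.rename(columns=rename)
    df = df.loc[:, ~df.columns.duplicated()]

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) {missing} not resolvable; "
            f"supply a column_map (headers found: {list(rename)})"
        )

    label = trait_label if trait_label is not None else path.stem
    stats = SummaryStats(df, trait_label=label, provenance=str(path))
    if len(stats) == 0:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    return stats


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write the canonical TSV (fixed header order, full float precision)."""
    if len(stats) == 0:
        raise EmptyInputError("refusing to write an empty summary-statistics table")
    stats.df.to_csv(path, sep="\t", index=False, na_rep="NA")
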