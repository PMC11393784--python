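"""Instrument selection and exposure/outcome harmonization.

Selection follows standard two-sample MR practice: genome-wide p-value
threshold (default 5e-8; 5e-6 is the conventional relaxed threshold for
reverse analyses), greedy LD clumping (r2 <= 0.001 within 10,000 kb by
default), and a weak-instrument filter on the F-statistic (F >= 10).

LD is supplied by the caller as an :class:`LDInfo` -- either a pairwise
r2 matrix or a declaration of pairwise independence -- rather than
queried from a reference panel.

Harmonization places exposure and outcome associations of shared
variants on a common effect-allele frame, flipping outcome effects where
orientations differ, re-complementing strand-swapped representations,
resolving palindromic (A/T, G/C) variants through allele frequencies
when both frequencies fall outside an ambiguity band, and dropping
variants that cannot be aligned.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ACTION_UNCHANGED = "unchanged"
ACTION_FLIPPED = "flipped"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_INCOMPATIBLE = "dropped_incompatible"


def complement(allele: str) -> str:
    """Base-wise complement of an allele string."""
    return allele.translate(_COMPLEMENT)


class LDInfo:
    """Pairwise linkage-disequilibrium information over a variant set.

    Either a symmetric r2 matrix (rsid x rsid DataFrame, unit diagonal)
    or a declaration that all variants are pairwise independent.
    """

    def __init__(self, matrix: pd.DataFrame | None = None):
        if matrix is not None:
            values = matrix.to_numpy(dtype=float)
            if matrix.shape[0] != matrix.shape[1] or list(matrix.index) != list(
                matrix.columns
            ):
                raise ConfigurationError("LD matrix must be square with matching labels")
            if not np.allclose(values, values.T, atol=1e-8):
                raise ConfigurationError("LD matrix must be symmetric")
            if not np.allclose(np.diag(values), 1.0, atol=1e-8):
                raise ConfigurationError("LD matrix diagonal must equal 1")
            if values.min() < -1e-8 or values.max() > 1 + 1e-8:
                raise ConfigurationError("LD r2 values must lie in [0, 1]")
        self.matrix = matrix

    @classmethod
    def independent(cls) -> "LDInfo":
        return cls(None)

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "LDInfo":
        return cls(matrix)

    @classmethod
    def read_tsv(cls, path) -> "LDInfo":
        with open(path) as fh:
            first = fh.readline().strip()
        if first == "independent":
            return cls.independent()
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        if self.is_independent:
            with open(path, "w") as fh:
                fh.write("independent\n")
        else:
            self.matrix.to_csv(path, sep="\t")

    @property
    def is_independent(self) -> bool:
        return self.matrix is None

    def submatrix(self, rsids: Sequence[str]) -> np.ndarray:
        """r2 matrix over ``rsids`` (zeros off-diagonal when independent)."""
        n = len(rsids)
        if self.is_independent:
            return np.eye(n)
        missing = [r for r in rsids if r not in self.matrix.index]
        if missing:
            raise ConfigurationError(f"LD matrix missing variants: {missing[:5]}")
        return self.matrix.loc[list(rsids), list(rsids)].to_numpy(dtype=float)


def select_by_pvalue(stats: SummaryStats, threshold: float) -> SummaryStats:
    """Variants with ``pval < threshold`` (strict), original order preserved."""
    if not threshold > 0:
        raise ConfigurationError(f"p-value threshold must be > 0, got {threshold}")
    mask = stats.df["pval"].to_numpy() < threshold
    if not mask.any():
        logger.warning(
            "%s: no variant passes p < %g", stats.trait_label, threshold
        )
    return stats.subset(mask)


def filter_weak_instruments(stats: SummaryStats, f_min: float = 10.0) -> SummaryStats:
    """Retain variants whose F-statistic (beta^2/se^2) is >= ``f_min``."""
    if f_min < 0:
        raise ConfigurationError("f_min must be >= 0")
    beta = stats.df["beta"].to_numpy(float)
    se = stats.df["se"].to_numpy(float)
    return stats.subset((beta / se) ** 2 >= f_min)


def ld_clump(
    stats: SummaryStats,
    ld: LDInfo | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly keep the remaining variant with the smallest p-value and
    discard all others on the same chromosome within ``window_kb``
    kilobases whose r2 with it exceeds ``r2_max``.  Output is sorted by
    chromosome and position.  Variants lacking a position are never
    considered within any window.
    """
    if ld is None:
        ld = LDInfo.independent()
    df = stats.df
    n = len(df)
    if n == 0:
        return stats
    r2 = ld.submatrix(df["rsid"].tolist())
    chrom = df["chrom"].astype(object).to_numpy()
    pos = df["pos"].to_numpy(dtype=float, na_value=np.nan)
    pval = df["pval"].to_numpy(float)

    active = np.ones(n, dtype=bool)
    kept = np.zeros(n, dtype=bool)
    window_bp = window_kb * 1000.0
    for i in np.argsort(pval, kind="stable"):
        if not active[i]:
            continue
        kept[i] = True
        active[i] = False
        if pd.isna(chrom[i]) or np.isnan(pos[i]):
            continue
        near = (
            active
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
            & (r2[i] > r2_max)
        )
        active[near] = False

    out = df[kept].sort_values(
        ["chrom", "pos"], kind="stable", na_position="last"
    )
    return SummaryStats(
        out.reset_index(drop=True),
        trait_label=stats.trait_label,
        provenance=stats.provenance,
        validate=False,
    )


def select_instruments(
    stats: SummaryStats,
    p_threshold: float = 5e-8,
    ld: LDInfo | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    f_min: float = 10.0,
) -> SummaryStats:
    """p-value threshold, then LD clumping, then weak-instrument filter."""
    out = select_by_pvalue(stats, p_threshold)
    out = ld_clump(out, ld=ld, r2_max=r2_max, window_kb=window_kb)
    return filter_weak_instruments(out, f_min=f_min)


class HarmonizedPairs:
    """Exposure/outcome associations for shared variants on a common
    effect-allele frame.

    Backed by plain numpy arrays for cheap estimator access; ``report``
    (when produced by :func:`harmonize`) records the action taken for
    every shared variant, including dropped ones.
    """

    def __init__(
        self,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        rsid=None,
        eaf_exp=None,
        eaf_out=None,
        effect_allele=None,
        other_allele=None,
        action=None,
        report: pd.DataFrame | None = None,
    ):
        self.beta_exp = np.asarray(beta_exp, dtype=float)
        self.se_exp = np.asarray(se_exp, dtype=float)
        self.beta_out = np.asarray(beta_out, dtype=float)
        self.se_out = np.asarray(se_out, dtype=float)
        n = len(self.beta_exp)
        for arr in (self.se_exp, self.beta_out, self.se_out):
            if len(arr) != n:
                raise ValueError("all coefficient arrays must share one length")
        if n and (not np.all(self.se_exp > 0) or not np.all(self.se_out > 0)):
            raise ValueError("standard errors must be strictly positive")
        self.rsid = (
            np.asarray(rsid, dtype=object)
            if rsid is not None
            else np.array([f"v{i}" for i in range(n)], dtype=object)
        )
        self.eaf_exp = None if eaf_exp is None else np.asarray(eaf_exp, dtype=float)
        self.eaf_out = None if eaf_out is None else np.asarray(eaf_out, dtype=float)
        self.effect_allele = (
            None if effect_allele is None else np.asarray(effect_allele, dtype=object)
        )
        self.other_allele = (
            None if other_allele is None else np.asarray(other_allele, dtype=object)
        )
        self.action = None if action is None else np.asarray(action, dtype=object)
        self.report = report

    def __len__(self) -> int:
        return len(self.beta_exp)

    def subset(self, mask) -> "HarmonizedPairs":
        mask = np.asarray(mask, dtype=bool)

        def _take(a):
            return None if a is None else a[mask]

        return HarmonizedPairs(
            self.beta_exp[mask],
            self.se_exp[mask],
            self.beta_out[mask],
            self.se_out[mask],
            rsid=self.rsid[mask],
            eaf_exp=_take(self.eaf_exp),
            eaf_out=_take(self.eaf_out),
            effect_allele=_take(self.effect_allele),
            other_allele=_take(self.other_allele),
            action=_take(self.action),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"rsid": self.rsid}
        if self.effect_allele is not None:
            data["effect_allele"] = self.effect_allele
            data["other_allele"] = self.other_allele
        data.update(
            beta_exp=self.beta_exp,
            se_exp=self.se_exp,
            beta_out=self.beta_out,
            se_out=self.se_out,
        )
        if self.eaf_exp is not None:
            data["eaf_exp"] = self.eaf_exp
        if self.eaf_out is not None:
            data["eaf_out"] = self.eaf_out
        if self.action is not None:
            data["action"] = self.action
        return pd.DataFrame(data)


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedPairs:
    """Align exposure and outcome onto the exposure's effect-allele frame.

    For each rsid shared between the two tables:

    * same allele pair, same orientation -> unchanged;
    * same pair, swapped orientation -> outcome beta negated and
      ``eaf_out`` replaced by ``1 - eaf_out``;
    * complementary-strand representation -> re-complemented, then the
      two rules above;
    * palindromic pair (A/T or G/C) -> orientation resolved by comparing
      allele frequencies when both lie outside ``palindrome_eaf_band``,
      otherwise dropped as ambiguous;
    * anything else -> dropped as incompatible.

    Raises :class:`EmptyInputError` when the rsid intersection is empty.
    """
    lo, hi = palindrome_eaf_band
    merged = pd.merge(
        exposure.df, outcome.df, on="rsid", suffixes=("_exp", "_out"), sort=False
    )
    if len(merged) == 0:
        raise EmptyInputError(
            f"no shared variants between {exposure.trait_label} and {outcome.trait_label}"
        )
    n_only_exp = len(exposure) - len(merged)
    if n_only_exp:
        logger.info(
            "%s vs %s: %d exposure variant(s) absent from outcome table",
            exposure.trait_label,
            outcome.trait_label,
            n_only_exp,
        )

    a1e = merged["effect_allele_exp"].to_numpy(dtype=object)
    a2e = merged["other_allele_exp"].to_numpy(dtype=object)
    a1o = merged["effect_allele_out"].to_numpy(dtype=object)
    a2o = merged["other_allele_out"].to_numpy(dtype=object)
    c1o = np.array([complement(a) for a in a1o], dtype=object)
    c2o = np.array([complement(a) for a in a2o], dtype=object)
    c2e = np.array([complement(a) for a in a2e], dtype=object)

    palindromic = a1e == c2e
    same = (a1o == a1e) & (a2o == a2e)
    swap = (a1o == a2e) & (a2o == a1e)
    comp_same = (c1o == a1e) & (c2o == a2e)
    comp_swap = (c1o == a2e) & (c2o == a1e)

    eaf_exp = merged["eaf_exp"].to_numpy(dtype=float, na_value=np.nan)
    eaf_out = merged["eaf_out"].to_numpy(dtype=float, na_value=np.nan)

    n = len(merged)
    flip = np.zeros(n, dtype=bool)
    action = np.full(n, ACTION_UNCHANGED, dtype=object)
    eaf_out_final = eaf_out.copy()

    # --- non-palindromic variants: alleles identify the orientation ----
    np_mask = ~palindromic
    compatible_np = same | swap | comp_same | comp_swap
    action[np_mask & ~compatible_np] = ACTION_DROPPED_INCOMPATIBLE
    flip_np = np_mask & compatible_np & ~same & (swap | (~comp_same & comp_swap))
    flip |= flip_np
    eaf_out_final[flip_np] = 1.0 - eaf_out[flip_np]

    # --- palindromic variants: frequencies identify the orientation ----
    p_mask = palindromic
    compatible_p = same | swap  # for palindromes the complement repeats these
    action[p_mask & ~compatible_p] = ACTION_DROPPED_INCOMPATIBLE
    cand = p_mask & compatible_p
    aligned_eaf = np.where(swap, 1.0 - eaf_out, eaf_out)
    in_band = lambda x: (x > lo) & (x < hi)  # noqa: E731
    ambiguous = cand & (
        np.isnan(eaf_exp)
        | np.isnan(aligned_eaf)
        | in_band(eaf_exp)
        | in_band(aligned_eaf)
    )
    action[ambiguous] = ACTION_DROPPED_PALINDROMIC
    resolved = cand & ~ambiguous
    mismatch = resolved & ((eaf_exp - 0.5) * (aligned_eaf - 0.5) < 0)
    flip_p = resolved & (swap ^ mismatch)
    flip |= flip_p
    eaf_out_final[resolved] = np.where(
        mismatch[resolved], 1.0 - aligned_eaf[resolved], aligned_eaf[resolved]
    )

    action[flip] = ACTION_FLIPPED

    kept = (action == ACTION_UNCHANGED) | (action == ACTION_FLIPPED)
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info(
            "%s vs %s: dropped %d shared variant(s) during harmonization",
            exposure.trait_label,
            outcome.trait_label,
            n_dropped,
        )

    beta_out = merged["beta_out"].to_numpy(float)
    beta_out = np.where(flip, -beta_out, beta_out)

    report = pd.DataFrame({"rsid": merged["rsid"], "action": action})
    return HarmonizedPairs(
        merged["beta_exp"].to_numpy(float)[kept],
        merged["se_exp"].to_numpy(float)[kept],
        beta_out[kept],
        merged["se_out"].to_numpy(float)[kept],
        rsid=merged["rsid"].to_numpy(dtype=object)[kept],
        eaf_exp=eaf_exp[kept],
        eaf_out=eaf_out_final[kept],
        effect_allele=a1e[kept],
        other_allele=a2e[kept],
        action=action[kept],
        report=report,
    )
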