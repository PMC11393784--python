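"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates three non-overlapping GWAS (exposure, mediator,
outcome) whose traits are linked by the chain

    exposure --kappa--> mediator --theta_M--> outcome
        \\_______________theta_dir_______________/

Each of the L exposure instruments j has a per-allele effect
gamma_j ~ Normal(0, gamma_sd**2) on the exposure, kappa * gamma_j on the
mediator, and (theta_dir + kappa * theta_M) * gamma_j + alpha_j on the
outcome, where alpha_j ~ Normal(pleio_mean, pleio_sd**2) is a direct
(horizontal-pleiotropy) path -- balanced when ``pleio_mean`` is 0,
directional otherwise.  A further L_med mediator-specific instruments
carry effects delta_j ~ Normal(0, delta_sd**2) on the mediator only,
propagating to the outcome as theta_M * delta_j; these emulate the
mediator GWAS's own hits and instrument the mediator -> outcome step.

Observed coefficients add finite-sample noise with the standard
GWAS-regression scaling se = 1 / sqrt(2 * n * maf * (1 - maf)); the
three samples are disjoint, so noise is independent across tables.
Effects are on the standardized (per-SD) scale; binary-outcome log-odds
are treated as approximately linear in the instrument effects (no
liability-threshold model).

The generative identity used by recovery tests:

    theta_total     = theta_dir + kappa * theta_M
    proportion_true = kappa * theta_M / theta_total
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .instruments import LDInfo
from .sumstats import CANONICAL_COLUMNS, SummaryStats

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


@dataclass
class ChainSimConfig:
    """Generative parameters for the exposure -> mediator -> outcome chain.

    Defaults describe a well-powered three-GWAS study in the
    strong-instrument regime: 100 exposure instruments and 100
    mediator-specific instruments with typical per-allele effects of
    0.15 SD (mean F near 10**3 at n = 100,000), where the ratio
    estimators' no-measurement-error assumption holds and their nominal
    intervals are approximately calibrated.  The causal chain is
    substantially mediated (kappa = 0.4, theta_M = 0.5, theta_dir = 0.1,
    hence theta_total = 0.3 and a true mediated proportion of 2/3), with
    no pleiotropy, common-variant allele frequencies, and a realistic
    share of palindromic variants.  Weak-instrument regimes can be
    studied by lowering ``gamma_sd``.
    """

    L: int = 100
    L_med: int = 100
    gamma_sd: float = 0.15
    delta_sd: float = 0.15
    kappa: float = 0.4
    theta_M: float = 0.5
    theta_dir: float = 0.1
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    med_pleio_sd: float = 0.0
    n_exp: int = 100_000
    n_med: int = 100_000
    n_out: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindrome_fraction: float = 0.15
    flip_fraction: float = 0.0
    missing_fraction: float = 0.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if self.L_med < 0:
            raise ConfigurationError("L_med must be >= 0")
        for name in ("gamma_sd", "delta_sd", "pleio_sd", "med_pleio_sd", "noise_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be a sub-interval of (0, 0.5]")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")
        for name in ("palindrome_fraction", "flip_fraction", "missing_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    @property
    def theta_total(self) -> float:
        return self.theta_dir + self.kappa * self.theta_M

    @property
    def proportion_true(self) -> float:
        """True mediated proportion kappa*theta_M / theta_total (NaN for
        a null chain, where no proportion is defined)."""
        if self.theta_total == 0:
            return float("nan")
        return self.kappa * self.theta_M / self.theta_total


def _gwas_se(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    # clip away the underflow-to-zero region so p stays inside (0, 1]
    return np.clip(2.0 * sps.norm.sf(np.abs(beta) / se), 1e-300, 1.0)


def simulate_chain(
    config: ChainSimConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, dict]:
    """Simulate the three summary-statistics tables plus a truth record.

    All three tables share the full variant set (exposure instruments
    followed by mediator-specific instruments) on a common allele frame;
    ``flip_fraction`` re-orients a random subset of outcome rows (to be
    undone by harmonization) and ``missing_fraction`` drops a random
    subset of rows per table (exercising the inner join).  The truth
    record carries the drawn effects and the per-trait instrument sets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.L + cfg.L_med

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n_total)
    gamma = rng.normal(0.0, cfg.gamma_sd, cfg.L) if cfg.gamma_sd > 0 else np.zeros(cfg.L)
    delta = (
        rng.normal(0.0, cfg.delta_sd, cfg.L_med)
        if cfg.delta_sd > 0
        else np.zeros(cfg.L_med)
    )
    alpha = rng.normal(cfg.pleio_mean, cfg.pleio_sd, cfg.L)
    eta = rng.normal(0.0, cfg.med_pleio_sd, cfg.L)

    true_exp = np.concatenate([gamma, np.zeros(cfg.L_med)])
    true_med = np.concatenate([cfg.kappa * gamma + eta, delta])
    true_out = np.concatenate(
        [
            cfg.theta_dir * gamma + cfg.theta_M * (cfg.kappa * gamma + eta) + alpha,
            cfg.theta_M * delta,
        ]
    )

    rsid = np.array([f"rs{i + 1}" for i in range(n_total)], dtype=object)
    chrom = np.full(n_total, "1", dtype=object)
    pos = (np.arange(n_total) + 1) * 1_000_000

    pal = rng.random(n_total) < cfg.palindrome_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), n_total)
    np_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), n_total)
    ea = np.where(
        pal,
        [_PALINDROMIC_PAIRS[i][0] for i in pal_idx],
        [_NONPALINDROMIC_PAIRS[i][0] for i in np_idx],
    ).astype(object)
    oa = np.where(
        pal,
        [_PALINDROMIC_PAIRS[i][1] for i in pal_idx],
        [_NONPALINDROMIC_PAIRS[i][1] for i in np_idx],
    ).astype(object)

    def _table(true_beta: np.ndarray, n: int, label: str) -> pd.DataFrame:
        se = _gwas_se(n, maf)
        beta = true_beta + cfg.noise_scale * se * rng.standard_normal(n_total)
        eaf = np.clip(
            maf + rng.standard_normal(n_total) * np.sqrt(maf * (1 - maf) / (2 * n)),
            1e-4,
            1 - 1e-4,
        )
        return pd.DataFrame(
            {
                "rsid": rsid,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": ea.copy(),
                "other_allele": oa.copy(),
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": _pvals(beta, se),
                "n": float(n),
            },
            columns=CANONICAL_COLUMNS,
        )

    exp_df = _table(true_exp, cfg.n_exp, "exposure")
    med_df = _table(true_med, cfg.n_med, "mediator")
    out_df = _table(true_out, cfg.n_out, "outcome")

    if cfg.flip_fraction > 0:
        flip = rng.random(n_total) < cfg.flip_fraction
        out_df.loc[flip, ["effect_allele", "other_allele"]] = out_df.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
        out_df.loc[flip, "beta"] = -out_df.loc[flip, "beta"]
        out_df.loc[flip, "eaf"] = 1.0 - out_df.loc[flip, "eaf"]

    tables = []
    for df, n, label in (
        (exp_df, cfg.n_exp, "exposure"),
        (med_df, cfg.n_med, "mediator"),
        (out_df, cfg.n_out, "outcome"),
    ):
        if cfg.missing_fraction > 0:
            keep = rng.random(len(df)) >= cfg.missing_fraction
            df = df[keep].reset_index(drop=True)
        tables.append(
            SummaryStats(df, trait_label=label, provenance="simulate_chain", validate=True)
        )

    truth = {
        "theta_total": cfg.theta_total,
        "proportion_true": cfg.proportion_true,
        "kappa": cfg.kappa,
        "theta_M": cfg.theta_M,
        "theta_dir": cfg.theta_dir,
        "gamma": gamma,
        "delta": delta,
        "alpha": alpha,
        "maf": maf,
        "exposure_instruments": list(rsid[: cfg.L]),
        "mediator_instruments": list(rsid[cfg.L :]),
    }
    return tables[0], tables[1], tables[2], truth


def simulate_ld_blocks(
    config: ChainSimConfig, block_size: int, within_r2: float
) -> LDInfo:
    """Block-diagonal LD over the simulated variant set.

    Consecutive variants (1 Mb apart in :func:`simulate_chain`) form
    blocks of ``block_size`` with pairwise r2 ``within_r2`` inside a
    block and 0 between blocks, so whole blocks fall inside the default
    10,000 kb clumping window for any block size up to 10.
    """
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    if not 0 <= within_r2 <= 1:
        raise ConfigurationError("within_r2 must lie in [0, 1]")
    n_total = config.L + config.L_med
    rsid = [f"rs{i + 1}" for i in range(n_total)]
    block = np.arange(n_total) // block_size
    mat = np.where(block[:, None] == block[None, :], within_r2, 0.0)
    np.fill_diagonal(mat, 1.0)
    return LDInfo(pd.DataFrame(mat, index=rsid, columns=rsid))
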