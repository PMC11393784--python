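"""Causal-effect estimators for two-sample MR on harmonized variant pairs.

All estimators are built on per-variant Wald ratios r_j = beta_out_j /
beta_exp_j with first-order standard errors se_rj = se_out_j /
|beta_exp_j| and inverse-variance weights w_j = 1 / se_rj**2 (a
second-order ratio SE incorporating the exposure-side uncertainty is
available behind a flag; in the F >= 10 regime the correction is
negligible).

* ``ivw``: weighted mean of ratios.  Fixed-effects SE is
  (sum w_j)**-1/2; the multiplicative random-effects SE scales it by
  sqrt(max(Q/(L-1), 1)); ``effects_model="auto"`` selects random effects
  exactly when the Cochran-Q p-value is below 0.05.
* ``egger``: weighted regression of outcome betas on exposure betas with
  an intercept (weights 1/se_out**2) after orienting every pair so the
  exposure beta is positive; the intercept estimates directional
  pleiotropy; inference uses a t reference with L-2 df.
* ``weighted_median``: weight-standardized 50th percentile of the ratio
  distribution; SE from a seeded parametric bootstrap.
* ``mode_estimate``: mode of a normal-kernel-smoothed ratio density
  (simple = unweighted, weighted = IVW weights); SE from a seeded
  parametric bootstrap.

p-values use a normal reference except MR-Egger (t, L-2 df); 95%
confidence intervals are beta_hat +/- 1.96 * se_hat (t quantile for
Egger).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import EmptyInputError, InsufficientInstrumentsError
from .instruments import HarmonizedPairs

logger = logging.getLogger(__name__)

Z95 = 1.96  # conventional 95% normal quantile used for reported intervals


@dataclass
class MREstimate:
    """A causal log-effect estimate (per SD of the exposure)."""

    method: str
    beta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)


def _ratio_arrays(
    pairs: HarmonizedPairs, second_order: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(kept mask applied) ratios, ratio SEs, weights, and the mask used."""
    keep = pairs.beta_exp != 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d pair(s) with zero exposure beta", n_dropped)
    bx = pairs.beta_exp[keep]
    by = pairs.beta_out[keep]
    sx = pairs.se_exp[keep]
    sy = pairs.se_out[keep]
    r = by / bx
    if second_order:
        se_r = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se_r = sy / np.abs(bx)
    w = 1.0 / se_r**2
    return r, se_r, w, keep


def wald_ratios(pairs: HarmonizedPairs, second_order: bool = False):
    """Per-variant Wald ratios as a tidy DataFrame (rsid, ratio, se, weight)."""
    import pandas as pd

    r, se_r, w, keep = _ratio_arrays(pairs, second_order)
    if len(r) == 0:
        raise EmptyInputError("no usable pairs (all exposure betas are zero)")
    return pd.DataFrame(
        {"rsid": pairs.rsid[keep], "ratio": r, "se_ratio": se_r, "weight": w}
    )


def _normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def ivw(
    pairs: HarmonizedPairs,
    effects_model: str = "auto",
    second_order: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``effects_model``: ``"fixed"``, ``"random"`` (multiplicative,
    variance floored at the fixed-effects variance), or ``"auto"``
    (random exactly when the Cochran-Q p-value is below 0.05).
    """
    if effects_model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    r, _, w, _ = _ratio_arrays(pairs, second_order)
    L = len(r)
    if L == 0:
        raise EmptyInputError("ivw requires at least one pair")
    sw = w.sum()
    beta = float((w * r).sum() / sw)
    se_fixed = float(np.sqrt(1.0 / sw))
    if L >= 2:
        q = float((w * (r - beta) ** 2).sum())
        q_pval = float(sps.chi2.sf(q, L - 1))
    else:
        q, q_pval = np.nan, np.nan
    use_random = effects_model == "random" or (
        effects_model == "auto" and L >= 2 and q_pval < 0.05
    )
    if use_random and L >= 2:
        scale = float(np.sqrt(max(q / (L - 1), 1.0)))
        model_used = "random"
    else:
        scale = 1.0
        model_used = "fixed"
    se = se_fixed * scale
    return MREstimate(
        method="ivw",
        beta_hat=beta,
        se_hat=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_normal_p(beta / se),
        n_snps=L,
        extras={"Q": q, "Q_pval": q_pval, "model_used": model_used},
    )


def egger(pairs: HarmonizedPairs, second_order: bool = False) -> MREstimate:
    """MR-Egger regression: pleiotropy-adjusted slope plus intercept test."""
    keep = pairs.beta_exp != 0
    bx = pairs.beta_exp[keep]
    by = pairs.beta_out[keep]
    sy = pairs.se_out[keep]
    L = len(bx)
    if L < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 pairs, got {L}")
    sign = np.sign(bx)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact fits trigger benign df warnings
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = (float(v) for v in fit.params)
    ise, sse = (float(v) for v in fit.bse)
    df = L - 2
    tq = float(sps.t.ppf(0.975, df))

    def _t_pval(est: float, se: float) -> float:
        if se == 0:
            return 1.0 if est == 0 else 0.0
        return float(2.0 * sps.t.sf(abs(est / se), df))

    return MREstimate(
        method="egger",
        beta_hat=slope,
        se_hat=sse,
        ci_low=slope - tq * sse,
        ci_high=slope + tq * sse,
        pval=_t_pval(slope, sse),
        n_snps=L,
        extras={
            "egger_intercept": intercept,
            "egger_intercept_se": ise,
            "egger_intercept_pval": _t_pval(intercept, ise),
            "df": df,
        },
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (weight-standardized percentile rule)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(0.5, p, v))


def _weighted_median_rows(rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of a (B, L) matrix with shared weights."""
    idx = np.argsort(rows, axis=1, kind="stable")
    v = np.take_along_axis(rows, idx, axis=1)
    w = weights[idx]
    cw = np.cumsum(w, axis=1)
    p = (cw - 0.5 * w) / cw[:, -1:]
    B, L = rows.shape
    j = (p < 0.5).sum(axis=1)
    out = np.empty(B)
    left = j == 0
    right = j == L
    out[left] = v[left, 0]
    out[right] = v[right, -1]
    mid = ~(left | right)
    rows_i = np.nonzero(mid)[0]
    jm = j[mid]
    p1, p2 = p[rows_i, jm - 1], p[rows_i, jm]
    v1, v2 = v[rows_i, jm - 1], v[rows_i, jm]
    out[mid] = v1 + (v2 - v1) * (0.5 - p1) / (p2 - p1)
    return out


def weighted_median(
    pairs: HarmonizedPairs,
    n_boot: int = 1000,
    seed: int = 0,
    second_order: bool = False,
) -> MREstimate:
    """Weighted-median estimator; consistent when valid instruments carry
    at least half of the total weight.  SE from a parametric bootstrap
    that resamples each ratio from Normal(r_j, se_rj)."""
    r, se_r, w, _ = _ratio_arrays(pairs, second_order)
    L = len(r)
    if L < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 pairs, got {L}"
        )
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    beta = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    sims = r[None, :] + se_r[None, :] * rng.standard_normal((n_boot, L))
    boot = _weighted_median_rows(sims, w)
    se = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    if se > 0:
        pval = _normal_p(beta / se)
    else:
        pval = 1.0 if beta == 0 else 0.0
    return MREstimate(
        method="weighted_median",
        beta_hat=beta,
        se_hat=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        n_snps=L,
    )


def _default_bandwidth(r: np.ndarray) -> float:
    """Modified-Silverman bandwidth from the MAD/SD of the ratios."""
    L = len(r)
    s = float(r.std(ddof=1)) if L > 1 else 0.0
    mad = float(1.4826 * np.median(np.abs(r - np.median(r))))
    scale = min(s, mad) if mad > 0 else s
    return 0.9 * scale * L ** (-1.0 / 5.0)


def _kde_mode(r: np.ndarray, w: np.ndarray, h: float, grid_size: int) -> float:
    if h <= 0 or np.ptp(r) == 0:
        # degenerate spread: the mode is the heaviest ratio value
        return float(r[np.argmax(w)])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def mode_estimate(
    pairs: HarmonizedPairs,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 512,
    second_order: bool = False,
) -> MREstimate:
    """Mode-based estimator (simple or weighted).

    The ratio density is smoothed with a normal kernel whose bandwidth is
    ``bandwidth_factor`` times a MAD-based default, and maximized on a
    ``grid_size``-point grid spanning the ratios +/- 3 bandwidths.  The
    weighted variant weights each ratio's kernel by its IVW weight.
    """
    r, se_r, w, _ = _ratio_arrays(pairs, second_order)
    L = len(r)
    if L < 3:
        raise InsufficientInstrumentsError(
            f"mode estimator requires >= 3 pairs, got {L}"
        )
    kw = w / w.sum() if weighted else np.full(L, 1.0 / L)
    h = bandwidth_factor * _default_bandwidth(r)
    beta = _kde_mode(r, kw, h, grid_size)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rb = r + se_r * rng.standard_normal(L)
        boot[b] = _kde_mode(rb, kw, bandwidth_factor * _default_bandwidth(rb), grid_size)
    se = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    if se > 0:
        pval = _normal_p(beta / se)
    else:
        pval = 1.0 if beta == 0 else 0.0
    return MREstimate(
        method="weighted_mode" if weighted else "simple_mode",
        beta_hat=beta,
        se_hat=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        n_snps=L,
        extras={"bandwidth": h},
    )


def beta_to_or(estimate: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-effect estimate to an odds ratio with 95% CI.

    Returned at full precision; reporting layers round to 3 decimals.
    """
    return (
        float(np.exp(estimate.beta_hat)),
        float(np.exp(estimate.ci_low)),
        float(np.exp(estimate.ci_high)),
    )


def estimate_all(
    pairs: HarmonizedPairs,
    effects_model: str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """The five-estimator suite (IVW primary; Egger, weighted median,
    simple and weighted mode as supplementary).  Robust estimators are
    skipped (absent from the result) below their minimum instrument
    counts."""
    out: dict[str, MREstimate] = {}
    out["ivw"] = ivw(pairs, effects_model=effects_model)
    if len(pairs) >= 3:
        out["egger"] = egger(pairs)
        out["weighted_median"] = weighted_median(
            pairs, n_boot=n_boot, seed=(seed + 1) % 2**31
        )
        out["simple_mode"] = mode_estimate(
            pairs, weighted=False, n_boot=n_boot, seed=(seed + 2) % 2**31
        )
        out["weighted_mode"] = mode_estimate(
            pairs, weighted=True, n_boot=n_boot, seed=(seed + 3) % 2**31
        )
    return out
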