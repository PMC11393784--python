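"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q over the Wald ratios (chi-square reference with L-1 df under
homogeneity), the MR-Egger intercept test for directional pleiotropy,
leave-one-out influence analysis, and an MR-PRESSO-style residual
sum-of-squares test with per-variant outlier detection and a distortion
test.

Every Monte-Carlo operation takes an explicit integer seed; all random
draws come from a single ``numpy.random.default_rng(seed)`` stream
consumed in a fixed order, so results are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MREstimate, _ratio_arrays, ivw
from .instruments import HarmonizedPairs


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results.

    ``outlier_pvals`` are raw per-variant empirical p-values (a value of
    0 means the observed residual exceeded every simulated one);
    outliers are declared at ``outlier_alpha`` with a Bonferroni
    correction over L, and only when the global test itself is
    significant.  ``distortion_pval`` is NaN when no outlier is
    detected.
    """

    global_rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray
    outlier_indices: np.ndarray
    outlier_rsids: list
    distortion_pval: float
    estimate_before: MREstimate
    estimate_after: MREstimate
    n_sim: int


def cochran_q(pairs: HarmonizedPairs) -> HeterogeneityResult:
    """Cochran's Q over Wald ratios around the fixed-effects IVW mean."""
    r, _, w, _ = _ratio_arrays(pairs)
    L = len(r)
    if L < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q requires >= 2 pairs, got {L}")
    beta = (w * r).sum() / w.sum()
    q = float((w * (r - beta) ** 2).sum())
    return HeterogeneityResult(Q=q, df=L - 1, pval=float(sps.chi2.sf(q, L - 1)))


def egger_intercept_test(pairs: HarmonizedPairs) -> tuple[float, float, float]:
    """(intercept, SE, t-test p-value) from the MR-Egger regression."""
    from .estimators import egger

    ex = egger(pairs).extras
    return ex["egger_intercept"], ex["egger_intercept_se"], ex["egger_intercept_pval"]


def leave_one_out(pairs: HarmonizedPairs, effects_model: str = "auto") -> pd.DataFrame:
    """IVW estimate after excluding each variant in turn.

    Returns L+1 rows: one per exclusion plus the all-variant estimate
    (``excluded_rsid`` empty).  A row is flagged when excluding that
    variant changes the sign of the estimate or moves it outside the
    full-set confidence interval.
    """
    L = len(pairs)
    if L < 3:
        raise InsufficientInstrumentsError(f"leave-one-out requires >= 3 pairs, got {L}")
    full = ivw(pairs, effects_model=effects_model)
    rows = []
    for i in range(L):
        mask = np.ones(L, dtype=bool)
        mask[i] = False
        est = ivw(pairs.subset(mask), effects_model=effects_model)
        flagged = bool(
            np.sign(est.beta_hat) != np.sign(full.beta_hat)
            or est.beta_hat < full.ci_low
            or est.beta_hat > full.ci_high
        )
        rows.append(
            {
                "excluded_rsid": pairs.rsid[i],
                "beta": est.beta_hat,
                "se": est.se_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "flagged": flagged,
            }
        )
    rows.append(
        {
            "excluded_rsid": "",
            "beta": full.beta_hat,
            "se": full.se_hat,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
            "pval": full.pval,
            "flagged": False,
        }
    )
    return pd.DataFrame(rows)


def _loo_betas(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW means, vectorized."""
    s0 = w.sum()
    s1 = (w * r).sum()
    return (s1 - w * r) / (s0 - w)


def mr_presso(
    pairs: HarmonizedPairs,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier search, distortion test.

    The observed global statistic is the weighted residual sum of squares
    RSS = sum_j w_j (r_j - beta_IVW^(-j))**2 with leave-one-out IVW
    predictions.  Its null distribution comes from ``n_sim`` parametric
    simulations drawing beta_exp ~ Normal(beta_exp_j, se_exp_j) and
    beta_out ~ Normal(beta_exp_j * beta_IVW^(-j), se_out_j); the global
    p-value is (1 + #{RSS_sim >= RSS_obs}) / (1 + n_sim).  Per-variant
    outlier p-values compare each observed residual against its own
    simulated distribution; variants are declared outliers at
    ``outlier_alpha`` Bonferroni-corrected over L whenever the global
    test is significant at ``outlier_alpha``.  The distortion test
    compares the before/after-removal estimates against a permutation
    distribution built by removing random same-size subsets of inliers.
    """
    L = len(pairs)
    if L < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 pairs, got {L}")
    if n_sim < 100:
        raise ConfigurationError("MR-PRESSO requires n_sim >= 100")

    r, _, w, keep = _ratio_arrays(pairs)
    bx = pairs.beta_exp[keep]
    sx = pairs.se_exp[keep]
    sy = pairs.se_out[keep]
    rsid = pairs.rsid[keep]
    L = len(r)

    beta_loo = _loo_betas(r, w)
    res_obs = w * (r - beta_loo) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    x_sim = bx[None, :] + sx[None, :] * rng.standard_normal((n_sim, L))
    y_sim = (bx * beta_loo)[None, :] + sy[None, :] * rng.standard_normal((n_sim, L))
    r_sim = y_sim / x_sim
    w_sim = (x_sim / sy[None, :]) ** 2
    s0 = w_sim.sum(axis=1, keepdims=True)
    s1 = (w_sim * r_sim).sum(axis=1, keepdims=True)
    bloo_sim = (s1 - w_sim * r_sim) / (s0 - w_sim)
    res_sim = w_sim * (r_sim - bloo_sim) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_pval = float((1 + (rss_sim >= rss_obs).sum()) / (1 + n_sim))
    outlier_pvals = (res_sim >= res_obs[None, :]).mean(axis=0)

    estimate_before = ivw(pairs, effects_model="auto")
    if global_pval < outlier_alpha:
        outlier_mask = outlier_pvals < outlier_alpha / L
    else:
        outlier_mask = np.zeros(L, dtype=bool)
    outlier_indices = np.nonzero(outlier_mask)[0]

    if len(outlier_indices) and len(outlier_indices) < L - 1:
        keep_mask = ~outlier_mask
        estimate_after = ivw(pairs.subset(keep_mask), effects_model="auto")
        d_obs = (estimate_after.beta_hat - estimate_before.beta_hat) / abs(
            estimate_before.beta_hat
        )
        inliers = np.nonzero(keep_mask)[0]
        n_out = len(outlier_indices)
        s0_all = w.sum()
        s1_all = (w * r).sum()
        d_sim = np.empty(n_sim)
        for k in range(n_sim):
            drop = rng.choice(inliers, size=n_out, replace=False)
            beta_k = (s1_all - (w[drop] * r[drop]).sum()) / (s0_all - w[drop].sum())
            d_sim[k] = (beta_k - estimate_before.beta_hat) / abs(
                estimate_before.beta_hat
            )
        distortion_pval = float((np.abs(d_sim) >= abs(d_obs)).mean())
    else:
        estimate_after = estimate_before
        distortion_pval = float("nan")

    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outlier_indices=outlier_indices,
        outlier_rsids=list(rsid[outlier_indices]),
        distortion_pval=distortion_pval,
        estimate_before=estimate_before,
        estimate_after=estimate_after,
        n_sim=n_sim,
    )
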