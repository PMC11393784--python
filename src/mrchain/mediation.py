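"""Two-step MR mediation: product of coefficients with delta-method CIs.

Three univariable MR estimates are combined: beta0 (total effect,
exposure -> outcome), beta1 (exposure -> mediator), and beta2
(mediator -> outcome).  The indirect effect through the mediator is
beta1 * beta2, its first-order delta-method standard error

    se_indirect = sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)

(the cross term se1**2 * se2**2 can be added behind a flag; the
cross-covariance is zero in the non-overlapping two-sample setting),
and the mediated proportion is 100 * beta1 * beta2 / beta0 with its CI
obtained by dividing the indirect-effect CI bounds by beta0.

beta2 comes from UNIVARIABLE MR of the mediator on the outcome; no
multivariable adjustment for the exposure is applied, which every
result carries as a limitation note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .config import AnalysisConfig
from .errors import UndefinedProportionError
from .estimators import Z95, ivw
from .instruments import LDInfo, harmonize, select_instruments
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

LIMITATION_NOTE = "beta2 from univariable MR; not adjusted for the exposure"


def round_half_away(x: float, decimals: int) -> float:
    """Round with ties going away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def indirect_effect(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    second_order: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Indirect effect beta1*beta2 with delta-method SE and 95% CI.

    Symmetric in its two (beta, se) argument pairs.
    """
    if not (se1 > 0 and se2 > 0):
        raise ValueError("se1 and se2 must be > 0")
    ind = beta1 * beta2
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if second_order:
        var += se1**2 * se2**2
    se = float(np.sqrt(var))
    return float(ind), se, (ind - Z95 * se, ind + Z95 * se)


def mediated_proportion(
    beta0: float,
    indirect: float,
    indirect_ci: tuple[float, float],
) -> tuple[float, tuple[float, float], bool]:
    """Mediated proportion (percent) with CI from dividing the
    indirect-effect CI bounds by beta0 (bounds returned ascending).

    Returns (proportion_pct, (ci_low_pct, ci_high_pct), inconsistent)
    where ``inconsistent`` flags proportions outside [0, 100] (reported,
    not an error).  Raises :class:`UndefinedProportionError` when
    ``beta0`` is zero.
    """
    if beta0 == 0:
        raise UndefinedProportionError("total effect beta0 is zero")
    pct = 100.0 * indirect / beta0
    bounds = sorted(100.0 * b / beta0 for b in indirect_ci)
    inconsistent = not (0.0 <= pct <= 100.0)
    return pct, (bounds[0], bounds[1]), inconsistent


@dataclass
class MediationResult:
    """beta0/beta1/beta2 with the composed indirect effect and proportion."""

    exposure: str
    mediator: str
    outcome: str
    beta0: float
    se0: float
    beta1: float = float("nan")
    se1: float = float("nan")
    beta2: float = float("nan")
    se2: float = float("nan")
    ci0: tuple[float, float] = (float("nan"), float("nan"))
    ci1: tuple[float, float] = (float("nan"), float("nan"))
    ci2: tuple[float, float] = (float("nan"), float("nan"))
    indirect: float = float("nan")
    se_indirect: float = float("nan")
    indirect_ci: tuple[float, float] = (float("nan"), float("nan"))
    proportion_pct: float = float("nan")
    proportion_ci_pct: tuple[float, float] = (float("nan"), float("nan"))
    inconsistent: bool = False
    screened_out: bool = False
    screen_pval: float = float("nan")
    note: str = LIMITATION_NOTE
    extras: dict = field(default_factory=dict)


def result_from_betas(
    beta0: float,
    se0: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
    second_order: bool = False,
) -> MediationResult:
    """Compose a MediationResult directly from the three coefficients."""
    ind, se_ind, ind_ci = indirect_effect(beta1, se1, beta2, se2, second_order)
    pct, pct_ci, inconsistent = mediated_proportion(beta0, ind, ind_ci)
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        beta0=beta0,
        se0=se0,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        ci0=(beta0 - Z95 * se0, beta0 + Z95 * se0),
        ci1=(beta1 - Z95 * se1, beta1 + Z95 * se1),
        ci2=(beta2 - Z95 * se2, beta2 + Z95 * se2),
        indirect=ind,
        se_indirect=se_ind,
        indirect_ci=ind_ci,
        proportion_pct=pct,
        proportion_ci_pct=pct_ci,
        inconsistent=inconsistent,
    )


def two_step_mediation(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    config: AnalysisConfig | None = None,
    ld: LDInfo | None = None,
) -> MediationResult:
    """Run the full two-step mediation pipeline on three GWAS tables.

    beta0, beta1, beta2 each come from instrument selection,
    harmonization, and IVW (with the configured effects model).  The
    mediator's instrument set excludes variants already selected as
    exposure instruments, so the two steps use disjoint panels.  A
    mediator whose IVW effect on the outcome is not significant at
    ``config.screen_alpha`` is screened out: the result carries beta2
    and the screening p-value but no indirect effect.
    """
    config = config or AnalysisConfig()

    def _estimate(ex_stats: SummaryStats, out_stats: SummaryStats, exclude=None):
        sel = select_instruments(
            ex_stats,
            p_threshold=config.threshold_for(ex_stats.trait_label),
            ld=ld,
            r2_max=config.clump_r2,
            window_kb=config.clump_kb,
            f_min=config.f_min,
        )
        if exclude is not None:
            sel = sel.subset(~sel.df["rsid"].isin(exclude).to_numpy())
        pairs = harmonize(sel, out_stats, config.palindrome_band)
        est = ivw(pairs, effects_model=config.effects_model)
        return est, sel

    est0, exp_sel = _estimate(exposure, outcome)
    est1, _ = _estimate(exposure, mediator)
    exposure_rsids = set(exp_sel.df["rsid"])
    est2, _ = _estimate(mediator, outcome, exclude=exposure_rsids)

    base = dict(
        exposure=exposure.trait_label,
        mediator=mediator.trait_label,
        outcome=outcome.trait_label,
        beta0=est0.beta_hat,
        se0=est0.se_hat,
        beta1=est1.beta_hat,
        se1=est1.se_hat,
        beta2=est2.beta_hat,
        se2=est2.se_hat,
    )
    if est2.pval >= config.screen_alpha:
        logger.info(
            "%s screened out as mediator for %s (mediator->outcome p=%.3g)",
            mediator.trait_label,
            exposure.trait_label,
            est2.pval,
        )
        return MediationResult(
            **base,
            ci0=(est0.ci_low, est0.ci_high),
            ci1=(est1.ci_low, est1.ci_high),
            ci2=(est2.ci_low, est2.ci_high),
            screened_out=True,
            screen_pval=est2.pval,
            extras={"n_snps": (est0.n_snps, est1.n_snps, est2.n_snps)},
        )
    result = result_from_betas(**base)
    result.ci0 = (est0.ci_low, est0.ci_high)
    result.ci1 = (est1.ci_low, est1.ci_high)
    result.ci2 = (est2.ci_low, est2.ci_high)
    result.screen_pval = est2.pval
    result.extras = {
        "n_snps": (est0.n_snps, est1.n_snps, est2.n_snps),
        "ivw_models": (
            est0.extras.get("model_used"),
            est1.extras.get("model_used"),
            est2.extras.get("model_used"),
        ),
    }
    return result


def _fmt(x: float, decimals: int) -> str:
    return f"{round_half_away(x, decimals):.{decimals}f}"


def report_mediation(result: MediationResult) -> dict:
    """Display-layer row for a mediation result.

    Reporting convention: the indirect effect and its CI are rounded to
    3 decimals FIRST and the displayed proportion (2 decimals) is then
    computed from those rounded values and the 3-decimal total effect --
    the convention used by printed mediation tables.  Full-precision
    values are emitted alongside under ``*_full`` keys.
    """
    if result.screened_out:
        return {
            "exposure": result.exposure,
            "mediator": result.mediator,
            "outcome": result.outcome,
            "screened_out": True,
            "screen_pval": result.screen_pval,
            "beta2_display": f"{_fmt(result.beta2, 3)}({_fmt(result.ci2[0], 3)},{_fmt(result.ci2[1], 3)})",
        }
    b0_r = round_half_away(result.beta0, 3)
    ind_r = round_half_away(result.indirect, 3)
    ci_r = (
        round_half_away(result.indirect_ci[0], 3),
        round_half_away(result.indirect_ci[1], 3),
    )
    prop_r = round_half_away(100.0 * ind_r / b0_r, 2)
    prop_ci = sorted(round_half_away(100.0 * b / b0_r, 2) for b in ci_r)

    def _beta_disp(b, ci):
        return f"{_fmt(b, 3)}({_fmt(ci[0], 3)},{_fmt(ci[1], 3)})"

    return {
        "exposure": result.exposure,
        "mediator": result.mediator,
        "outcome": result.outcome,
        "beta0_display": _beta_disp(result.beta0, result.ci0),
        "beta1_display": _beta_disp(result.beta1, result.ci1),
        "beta2_display": _beta_disp(result.beta2, result.ci2),
        "indirect_display": f"{ind_r:.3f}({ci_r[0]:.3f},{ci_r[1]:.3f})",
        "proportion_display": f"{prop_r:.2f}({prop_ci[0]:.2f},{prop_ci[1]:.2f})",
        "indirect_rounded": ind_r,
        "indirect_ci_rounded": ci_r,
        "proportion_pct_rounded": prop_r,
        "proportion_ci_pct_rounded": tuple(prop_ci),
        "indirect_full": result.indirect,
        "se_indirect_full": result.se_indirect,
        "indirect_ci_full": result.indirect_ci,
        "proportion_pct_full": result.proportion_pct,
        "proportion_ci_pct_full": result.proportion_ci_pct,
        "inconsistent": result.inconsistent,
        "screened_out": False,
        "note": result.note,
    }
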