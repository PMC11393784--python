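"""End-to-end orchestration: single-direction MR, bidirectional MR,
mediator screening, and the two-step mediation suite.

A direction is called "supported" when the primary IVW estimate is
significant at ``config.alpha`` (optionally Bonferroni-corrected over
the number of exposures tested) and its sign agrees with the weighted
median -- the robust estimator whose consistency condition is weakest.
Every report records which IVW branch (fixed or random effects) the
heterogeneity rule selected.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import EmptyInputError, InsufficientInstrumentsError
from .estimators import beta_to_or, estimate_all
from .instruments import LDInfo, harmonize, select_instruments
from .mediation import report_mediation, two_step_mediation
from .sensitivity import cochran_q, egger_intercept_test, leave_one_out, mr_presso
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

#: column order of the tidy estimates table
ESTIMATE_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "or",
    "or_low",
    "or_high",
    "ivw_model",
]


def single_mr(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: AnalysisConfig | None = None,
    ld: LDInfo | None = None,
    p_threshold: float | None = None,
    run_presso: bool = True,
) -> dict:
    """One exposure -> outcome analysis: selection, harmonization, the
    five estimators, and the sensitivity battery (as instrument counts
    permit)."""
    config = config or AnalysisConfig()
    threshold = (
        p_threshold
        if p_threshold is not None
        else config.threshold_for(exposure.trait_label)
    )
    selected = select_instruments(
        exposure,
        p_threshold=threshold,
        ld=ld,
        r2_max=config.clump_r2,
        window_kb=config.clump_kb,
        f_min=config.f_min,
    )
    pairs = harmonize(selected, outcome, config.palindrome_band)
    seed = config.derive_seed(f"{exposure.trait_label}->{outcome.trait_label}")
    estimates = estimate_all(
        pairs,
        effects_model=config.effects_model,
        n_boot=config.n_boot,
        seed=seed,
    )
    report: dict = {
        "exposure": exposure.trait_label,
        "outcome": outcome.trait_label,
        "p_threshold": threshold,
        "n_snps": len(pairs),
        "pairs": pairs,
        "estimates": estimates,
    }
    L = len(pairs)
    report["heterogeneity"] = cochran_q(pairs) if L >= 2 else None
    report["egger_intercept"] = egger_intercept_test(pairs) if L >= 3 else None
    report["leave_one_out"] = leave_one_out(pairs) if L >= 3 else None
    if run_presso and L >= 4:
        report["presso"] = mr_presso(
            pairs,
            n_sim=config.n_sim,
            outlier_alpha=config.presso_alpha,
            seed=(seed + 11) % 2**31,
        )
    else:
        report["presso"] = None
    return report


def direction_supported(report: dict, alpha: float = 0.05) -> bool:
    """IVW significant at alpha with sign agreement against the weighted
    median (when the latter is available)."""
    est = report["estimates"]
    iv = est["ivw"]
    if not iv.pval < alpha:
        return False
    wm = est.get("weighted_median")
    if wm is not None and np.sign(wm.beta_hat) != np.sign(iv.beta_hat):
        return False
    return True


def run_bidirectional(
    config: AnalysisConfig,
    trait_a: SummaryStats,
    trait_b: SummaryStats,
    ld: LDInfo | None = None,
) -> dict:
    """A -> B (forward threshold) and B -> A (reverse threshold).

    A direction whose instrument selection or harmonization yields no
    usable variants (common when one trait is a weakly powered disease
    GWAS) is reported as unsupported with the failure recorded, rather
    than aborting the other direction.
    """

    def _direction(exposure, outcome, threshold):
        try:
            report = single_mr(exposure, outcome, config, ld=ld, p_threshold=threshold)
        except (EmptyInputError, InsufficientInstrumentsError) as exc:
            logger.warning(
                "%s -> %s not estimable: %s",
                exposure.trait_label,
                outcome.trait_label,
                exc,
            )
            return {
                "exposure": exposure.trait_label,
                "outcome": outcome.trait_label,
                "p_threshold": threshold,
                "n_snps": 0,
                "pairs": None,
                "estimates": {},
                "heterogeneity": None,
                "egger_intercept": None,
                "leave_one_out": None,
                "presso": None,
                "error": str(exc),
                "supported": False,
            }
        report["supported"] = direction_supported(report, config.alpha)
        return report

    forward = _direction(
        trait_a, trait_b, config.threshold_for(trait_a.trait_label)
    )
    reverse = _direction(
        trait_b, trait_a, config.threshold_for(trait_b.trait_label, reverse=True)
    )
    return {"forward": forward, "reverse": reverse}


def estimates_table(report: dict) -> pd.DataFrame:
    """Tidy one-row-per-method table (with odds-ratio columns) for a
    single-direction report."""
    rows = []
    for name, est in report["estimates"].items():
        or_, or_lo, or_hi = beta_to_or(est)
        rows.append(
            {
                "exposure": report["exposure"],
                "outcome": report["outcome"],
                "method": name,
                "n_snps": est.n_snps,
                "beta": est.beta_hat,
                "se": est.se_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "or": or_,
                "or_low": or_lo,
                "or_high": or_hi,
                "ivw_model": est.extras.get("model_used", ""),
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def diagnostics_table(report: dict) -> pd.DataFrame:
    """One-row diagnostics summary (Q, Egger intercept, MR-PRESSO)."""
    het = report["heterogeneity"]
    eg = report["egger_intercept"]
    presso = report["presso"]
    row = {
        "exposure": report["exposure"],
        "outcome": report["outcome"],
        "n_snps": report["n_snps"],
        "Q": het.Q if het else np.nan,
        "Q_df": het.df if het else np.nan,
        "Q_pval": het.pval if het else np.nan,
        "egger_intercept": eg[0] if eg else np.nan,
        "egger_intercept_se": eg[1] if eg else np.nan,
        "egger_intercept_pval": eg[2] if eg else np.nan,
        "presso_global_pval": presso.global_pval if presso else np.nan,
        "presso_distortion_pval": presso.distortion_pval if presso else np.nan,
        "presso_outliers": ";".join(map(str, presso.outlier_rsids)) if presso else "",
    }
    return pd.DataFrame([row])


def write_direction_report(report: dict, outdir, prefix: str) -> None:
    """Write estimates/diagnostics/leave-one-out/harmonization TSVs with
    a fixed float format so identical runs are byte-identical."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    estimates_table(report).to_csv(
        outdir / f"{prefix}_estimates.tsv", sep="\t", index=False, float_format=fmt
    )
    diagnostics_table(report).to_csv(
        outdir / f"{prefix}_diagnostics.tsv", sep="\t", index=False, float_format=fmt
    )
    if report["leave_one_out"] is not None:
        report["leave_one_out"].to_csv(
            outdir / f"{prefix}_leave_one_out.tsv",
            sep="\t",
            index=False,
            float_format=fmt,
        )
    pairs = report["pairs"]
    if pairs is not None and pairs.report is not None:
        pairs.report.to_csv(
            outdir / f"{prefix}_harmonization.tsv", sep="\t", index=False
        )


def run_mediation_suite(
    config: AnalysisConfig,
    exposures: Sequence[SummaryStats],
    mediators: Sequence[SummaryStats],
    outcome: SummaryStats,
    ld: LDInfo | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """For every exposure with a supported total effect, evaluate each
    mediator (screening on the mediator -> outcome IVW p-value) and emit
    display-convention mediation rows plus a screening log."""
    alpha = config.alpha / max(len(exposures), 1) if config.bonferroni else config.alpha
    rows: list[dict] = []
    screen_log: list[dict] = []
    for exposure in exposures:
        try:
            total = single_mr(exposure, outcome, config, ld=ld, run_presso=False)
        except InsufficientInstrumentsError as exc:
            screen_log.append(
                {"exposure": exposure.trait_label, "event": f"skipped: {exc}"}
            )
            continue
        if not direction_supported(total, alpha):
            screen_log.append(
                {
                    "exposure": exposure.trait_label,
                    "event": "no supported total effect on outcome",
                    "ivw_pval": total["estimates"]["ivw"].pval,
                }
            )
            continue
        for mediator in mediators:
            result = two_step_mediation(exposure, mediator, outcome, config, ld=ld)
            if result.screened_out:
                screen_log.append(
                    {
                        "exposure": exposure.trait_label,
                        "mediator": mediator.trait_label,
                        "event": "mediator screened out (mediator->outcome not significant)",
                        "screen_pval": result.screen_pval,
                    }
                )
                continue
            rows.append(report_mediation(result))
    columns = [
        "exposure",
        "mediator",
        "outcome",
        "beta0_display",
        "beta1_display",
        "beta2_display",
        "indirect_display",
        "proportion_display",
        "indirect_full",
        "se_indirect_full",
        "proportion_pct_full",
        "inconsistent",
        "note",
    ]
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame[[c for c in columns if c in frame.columns]]
    return frame, screen_log
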