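"""Multivariable MR and two-step MR mediation.

Multivariable MR regresses the outcome effects jointly on the effect matrix
of several exposures (weighted, no intercept), giving each exposure's direct
effect conditional on the others. Two-step mediation combines the
exposure→mediator effect (β1) with the mediator→outcome effect adjusted for
the exposure (β2): indirect = β1·β2, and the proportion mediated is
indirect/total on the log-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DegenerateInstrumentError
from .estimators import InstrumentSet, MrEstimate, estimate_auto, primary_estimate
from .sumstats import HarmonizedPair, SumstatsTable, harmonize


@dataclass
class MvmrInput:
    """Harmonized instrument effects for several exposures and one outcome."""

    variants: list[str]
    exposure_betas: np.ndarray  # (n_variants, n_exposures)
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    exposure_ids: list[str]

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_betas = np.asarray(self.outcome_betas, float)
        self.outcome_ses = np.asarray(self.outcome_ses, float)
        k, p = self.exposure_betas.shape
        if len(self.variants) != k or len(self.exposure_ids) != p:
            raise ValueError("inconsistent MVMR dimensions")
        if self.exposure_ses.shape != (k, p):
            raise ValueError("exposure_ses shape mismatch")
        if self.outcome_betas.shape != (k,) or self.outcome_ses.shape != (k,):
            raise ValueError("outcome vector shape mismatch")
        if k <= p:
            raise ValueError("MVMR needs more variants than exposures")


def mvmr_ivw(mvmr_input: MvmrInput) -> list[MrEstimate]:
    """Multivariable IVW: WLS of outcome betas on the exposure-beta matrix.

    No intercept; weights 1/outcome_se². SEs use the weighted-regression
    covariance with the residual scale floored at 1 (multiplicative
    overdispersion), and two-sided normal p-values.
    """
    X = mvmr_input.exposure_betas
    y = mvmr_input.outcome_betas
    w = 1.0 / mvmr_input.outcome_ses**2
    k, p = X.shape

    if np.linalg.matrix_rank(X) < p:
        # Name the offenders via near-zero pivots of the QR decomposition.
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [mvmr_input.exposure_ids[i] for i in np.nonzero(diag <= tol)[0]]
        raise CollinearityError(
            f"rank-deficient exposure matrix; offending exposure(s): {bad or mvmr_input.exposure_ids}"
        )

    fit = sm.WLS(y, X, weights=w).fit()
    scale = max(float(fit.scale), 1.0)
    ses = np.sqrt(np.diag(fit.normalized_cov_params) * scale)

    out = []
    for j, exp_id in enumerate(mvmr_input.exposure_ids):
        beta = float(fit.params[j])
        se = float(ses[j])
        pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
        est = MrEstimate("mvmr_ivw", beta, se, pval, k)
        est.exposure_id = exp_id  # type: ignore[attr-defined]
        out.append(est)
    return out


@dataclass
class MediationResult:
    """Two-step MR decomposition of a total effect through one mediator."""

    total_effect: float
    beta1: float
    beta2: float
    indirect: float
    direct: float
    proportion: float
    inconsistent: bool
    beta1_se: Optional[float] = None
    beta2_se: Optional[float] = None
    total_se: Optional[float] = None

    @property
    def proportion_pct(self) -> float:
        return self.proportion * 100.0


def drop_overlapping_instruments(
    mediator_set: InstrumentSet, exposure_set: InstrumentSet
) -> InstrumentSet:
    """Remove mediator instruments shared with the exposure's instrument set."""
    overlap = set(mediator_set.variant_ids) & set(exposure_set.variant_ids)
    if not overlap:
        return mediator_set
    return mediator_set.drop(sorted(overlap))


def build_mvmr_input(
    exposure_tables: "dict[str, SumstatsTable]",
    outcome: SumstatsTable,
    variant_ids: Sequence[str],
) -> MvmrInput:
    """Assemble an MVMR input by harmonizing each exposure with the outcome.

    Only variants kept after harmonization against every exposure are used.
    """
    ids = list(exposure_tables)
    per_exp: dict[str, dict[str, HarmonizedPair]] = {}
    for exp_id, table in exposure_tables.items():
        pairs = harmonize(table.subset(list(variant_ids)), outcome)
        per_exp[exp_id] = {p.variant_id: p for p in pairs if p.kept}
    usable = [v for v in variant_ids if all(v in per_exp[e] for e in ids)]
    xb = np.array([[per_exp[e][v].beta_exp for e in ids] for v in usable])
    xs = np.array([[per_exp[e][v].se_exp for e in ids] for v in usable])
    first = per_exp[ids[0]]
    yb = np.array([first[v].beta_out for v in usable])
    ys = np.array([first[v].se_out for v in usable])
    return MvmrInput(list(usable), xb, xs, yb, ys, ids)


def two_step_mediation(
    exp_to_med: InstrumentSet,
    exp_to_out: InstrumentSet,
    mvmr_input: MvmrInput,
    mediator_id: Optional[str] = None,
    adjusted: bool = True,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MediationResult:
    """Two-step MR: β1 from exposure→mediator, β2 from MVMR, products reported.

    ``mediator_id`` defaults to the outcome of the first step. With
    ``adjusted=True`` (default) β2 is the mediator's coefficient adjusted for
    the exposure in the multivariable model; ``adjusted=False`` refits the
    multivariable model with the mediator column alone. The proportion
    mediated is indirect/total; when the indirect and total effects disagree
    in sign the result is flagged inconsistent.
    """
    if mediator_id is None:
        mediator_id = exp_to_med.outcome_id

    beta1_est = primary_estimate(estimate_auto(exp_to_med, n_boot=n_boot, seed=seed))
    total_est = primary_estimate(estimate_auto(exp_to_out, n_boot=n_boot, seed=seed))

    if adjusted:
        estimates = mvmr_ivw(mvmr_input)
    else:
        j = mvmr_input.exposure_ids.index(mediator_id)
        solo = MvmrInput(
            mvmr_input.variants,
            mvmr_input.exposure_betas[:, [j]],
            mvmr_input.exposure_ses[:, [j]],
            mvmr_input.outcome_betas,
            mvmr_input.outcome_ses,
            [mediator_id],
        )
        estimates = mvmr_ivw(solo)
    try:
        beta2_est = next(e for e in estimates if e.exposure_id == mediator_id)
    except StopIteration:
        raise ValueError(f"mediator {mediator_id!r} not among MVMR exposures")

    total = total_est.beta
    if total == 0:
        raise DegenerateInstrumentError("total effect is zero; proportion undefined")
    indirect = beta1_est.beta * beta2_est.beta
    return MediationResult(
        total_effect=total,
        beta1=beta1_est.beta,
        beta2=beta2_est.beta,
        indirect=indirect,
        direct=total - indirect,
        proportion=indirect / total,
        inconsistent=(indirect != 0 and math.copysign(1, indirect) != math.copysign(1, total)),
        beta1_se=beta1_est.se,
        beta2_se=beta2_est.se,
        total_se=total_est.se,
    )


def mediation_from_effects(indirect: float, total: float) -> float:
    """Proportion mediated (as a fraction) from printed effect sizes."""
    if total == 0:
        raise DegenerateInstrumentError("total effect is zero; proportion undefined")
    return indirect / total


__all__ = [
    "MvmrInput",
    "MediationResult",
    "mvmr_ivw",
    "two_step_mediation",
    "build_mvmr_input",
    "drop_overlapping_instruments",
    "mediation_from_effects",
]
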