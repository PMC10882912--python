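"""Two-sample MR estimators and heterogeneity/pleiotropy diagnostics.

All causal effects are on the exposure→outcome scale implied by the inputs
(log-odds per SD of exposure for binary outcomes). The 95% CI multiplier is
fixed at 1.959964 for bit-reproducibility; Egger inference uses a t
distribution with n_snp − 2 degrees of freedom, everything else the normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateInstrumentError,
    EmptyInputError,
    InsufficientInstrumentsError,
)
from .instruments import InstrumentMetrics
from .sumstats import HarmonizedPair

Z95 = 1.959964

METHODS = ("wald", "ivw_fixed", "ivw_random", "egger", "weighted_median")


@dataclass
class InstrumentSet:
    """Harmonized, kept instrument pairs for one exposure–outcome analysis."""

    pairs: list[HarmonizedPair]
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    metrics: Optional[list[InstrumentMetrics]] = None

    def __post_init__(self) -> None:
        self.pairs = [p for p in self.pairs if p.kept]
        if not self.pairs:
            raise EmptyInputError("instrument set has no kept pairs")
        ids = [p.variant_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant_ids in instrument set")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([p.beta_exp for p in self.pairs])
        sx = np.array([p.se_exp for p in self.pairs])
        by = np.array([p.beta_out for p in self.pairs])
        sy = np.array([p.se_out for p in self.pairs])
        return bx, sx, by, sy

    def drop(self, variant_ids: Sequence[str]) -> "InstrumentSet":
        drop = set(variant_ids)
        return InstrumentSet(
            [p for p in self.pairs if p.variant_id not in drop],
            self.exposure_id,
            self.outcome_id,
        )


@dataclass
class MrEstimate:
    """A causal-effect estimate from one method with its diagnostics."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q_stat: Optional[float] = None
    q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pvalue: Optional[float] = None
    primary: bool = False

    def __post_init__(self) -> None:
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        """exp(beta) — meaningful for binary outcomes only."""
        return math.exp(self.beta)


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return 2.0 * stats.norm.sf(abs(beta / se))


def wald_ratio(pair: HarmonizedPair) -> MrEstimate:
    """Single-instrument causal estimate beta_out/beta_exp.

    The first-order (delta-method) standard error se_out/|beta_exp| is used,
    ignoring uncertainty in the exposure effect.
    """
    if pair.beta_exp == 0:
        raise DegenerateInstrumentError(f"{pair.variant_id}: beta_exp is zero")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MrEstimate("wald", beta, se, _norm_p(beta, se), 1)


def ivw(instrument_set: InstrumentSet, mode: str = "random") -> MrEstimate:
    """Inverse-variance-weighted estimate (weighted regression through the origin).

    ``random`` (default) applies a multiplicative random-effects scale
    sqrt(Q/(k−1)) floored at 1, so it coincides with the fixed-effect
    estimate under homogeneity. Cochran's Q and its chi-square p-value
    (k − 1 df) are attached in both modes.
    """
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be 'fixed' or 'random'")
    k = len(instrument_set)
    if k < 2:
        raise InsufficientInstrumentsError(
            "IVW needs >= 2 instruments; use wald_ratio for a single SNP"
        )
    bx, _, by, sy = instrument_set.arrays()
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = math.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    se = se_fixed
    if mode == "random":
        se = se_fixed * max(1.0, math.sqrt(q / (k - 1)))
    return MrEstimate(
        f"ivw_{mode}", beta, se, _norm_p(beta, se), k, q_stat=q, q_pvalue=q_p
    )


def egger(instrument_set: InstrumentSet) -> MrEstimate:
    """MR-Egger: weighted regression with a free intercept.

    Instruments are oriented so every exposure beta is non-negative (both
    betas flipped together when negative). The slope is the causal estimate;
    the intercept and its t-test (n_snp − 2 df) form the directional
    pleiotropy test. The residual scale is floored at 1 (multiplicative
    random effects), as for IVW.
    """
    k = len(instrument_set)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx, _, by, sy = instrument_set.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise CollinearityError("all exposure betas identical after orientation")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    fit = sm.WLS(by, X, weights=w).fit()
    scale = max(float(fit.scale), 1.0)
    se_all = np.sqrt(np.diag(fit.normalized_cov_params) * scale)
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    se_slope, se_int = float(se_all[1]), float(se_all[0])
    df = k - 2
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df) if se_slope > 0 else 0.0
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df) if se_int > 0 else (
        1.0 if intercept == 0 else 0.0
    )
    est = MrEstimate("egger", slope, se_slope, p_slope, k)
    est.egger_intercept = intercept
    est.egger_intercept_se = se_int
    est.egger_intercept_pvalue = p_int
    return est


def _weighted_median_sorted(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight at 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    below = int(np.max(np.nonzero(cum < 0.5)[0]))
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + (r[below + 1] - r[below]) * frac)


def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians (vectorized bootstrap helper)."""
    order = np.argsort(R, axis=1, kind="stable")
    r = np.take_along_axis(R, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    # index of last entry with cum < 0.5 in each row
    below = np.clip((cum < 0.5).sum(axis=1) - 1, 0, R.shape[1] - 2)
    rows = np.arange(R.shape[0])
    c0 = cum[rows, below]
    c1 = cum[rows, below + 1]
    r0 = r[rows, below]
    r1 = r[rows, below + 1]
    frac = np.where(c1 > c0, (0.5 - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
    out = r0 + (r1 - r0) * frac
    out = np.where(cum[:, 0] >= 0.5, r[:, 0], out)
    return out


def weighted_median(
    instrument_set: InstrumentSet,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Per-SNP ratios beta_out/beta_exp are weighted by (beta_exp/se_out)² —
    the inverse first-order variance of the ratio — and the estimate is the
    ratio at cumulative weight 0.5. The SE is the standard deviation of the
    estimate over ``n_boot`` parametric resamples of both betas.
    """
    k = len(instrument_set)
    if k < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    bx, sx, by, sy = instrument_set.arrays()
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure beta in instrument set")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median_sorted(ratios, weights)

    rng = np.random.default_rng(seed)
    BX = bx + sx * rng.standard_normal((n_boot, k))
    BY = by + sy * rng.standard_normal((n_boot, k))
    BX = np.where(BX == 0, np.finfo(float).tiny, BX)
    boots = _weighted_median_rows(BY / BX, (BX / sy[None, :]) ** 2)
    se = float(np.std(boots, ddof=1))
    return MrEstimate("weighted_median", beta, se, _norm_p(beta, se), k)


def estimate_auto(
    instrument_set: InstrumentSet,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> list[MrEstimate]:
    """Method dispatch on instrument count.

    1 SNP → Wald ratio only; 2 SNPs → IVW only; ≥ 3 SNPs → IVW (random and
    fixed), MR-Egger and the weighted median, with heterogeneity and
    pleiotropy diagnostics attached. The primary estimate (Wald or
    random-effects IVW) carries ``primary=True``.
    """
    k = len(instrument_set)
    if k == 1:
        est = wald_ratio(instrument_set.pairs[0])
        est.primary = True
        return [est]
    if k == 2:
        est = ivw(instrument_set, mode="random")
        est.primary = True
        return [est]
    primary = ivw(instrument_set, mode="random")
    primary.primary = True
    return [
        primary,
        ivw(instrument_set, mode="fixed"),
        egger(instrument_set),
        weighted_median(instrument_set, n_boot=n_boot, seed=seed),
    ]


def primary_estimate(estimates: Sequence[MrEstimate]) -> MrEstimate:
    for est in estimates:
        if est.primary:
            return est
    raise ValueError("no primary estimate present")


__all__ = [
    "InstrumentSet",
    "MrEstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "estimate_auto",
    "primary_estimate",
    "Z95",
    "METHODS",
]
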