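"""Bayesian colocalization of two association regions under a single-causal-
variant assumption, yielding posterior probabilities PPH0–PPH4.

The five hypotheses for a region shared by two traits: H0 no association with
either trait; H1/H2 association with one trait only; H3 both traits
associated through distinct causal variants; H4 both traits share one causal
variant. Evidence per SNP is the Wakefield approximate Bayes factor computed
from the marginal beta and SE; all aggregation is done in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .errors import EmptyOverlapError
from .sumstats import SnpAssociation, SumstatsTable

logger = logging.getLogger(__name__)

#: Effect-scale prior SD by trait type: 0.15 SD for quantitative traits,
#: 0.2 on the log-odds scale for binary traits.
DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}

#: Conventional evidence threshold for a shared causal variant.
PPH4_THRESHOLD = 0.80

HYPOTHESES = ("pph0", "pph1", "pph2", "pph3", "pph4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causality.

    p1/p2: causal for trait 1/2 only; p12: causal for both. Field-standard
    defaults p1 = p2 = 1e-4, p12 = 1e-5.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")


@dataclass
class ColocResult:
    """Posterior probabilities over the five hypotheses for one region pair."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    priors: ColocPriors
    per_snp_h4: "dict[str, float]"

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])

    @property
    def modal_hypothesis(self) -> str:
        return HYPOTHESES[int(np.argmax(self.posteriors))]

    @property
    def h4_pass(self) -> bool:
        return self.pph4 >= PPH4_THRESHOLD

    def as_percent(self) -> "dict[str, float]":
        """Posteriors as percentages rounded to 3 decimals (report format)."""
        return {h: round(float(p) * 100.0, 3) for h, p in zip(HYPOTHESES, self.posteriors)}


def _log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    z2 = (beta / se) ** 2
    shrink = prior_sd**2 / (prior_sd**2 + se**2)
    # log(1 - shrink) = log(se^2 / (prior_sd^2 + se^2)), stable for shrink near 1
    log_one_minus = 2.0 * np.log(se) - np.log(prior_sd**2 + se**2)
    return 0.5 * (log_one_minus + shrink * z2)


def snp_log_abf(assoc: SnpAssociation, prior_sd: float) -> float:
    """Log approximate Bayes factor for one SNP's association evidence.

    With z = beta/se and shrink = prior_sd²/(prior_sd² + se²):
    log ABF = 0.5·(log(1 − shrink) + shrink·z²), computed stably when the
    shrinkage factor is near 1.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    return float(_log_abf(np.asarray(assoc.beta), np.asarray(assoc.se), prior_sd))


def logdiffexp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a ≥ b, -inf when the difference underflows."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def colocalize(
    region1: SumstatsTable,
    region2: SumstatsTable,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: Optional[float] = None,
    prior_sd2: Optional[float] = None,
) -> ColocResult:
    """Colocalize two regions using the variants they share.

    Hypothesis weights (log scale, unnormalized) with S1 = LSE(l1),
    S2 = LSE(l2), S12 = LSE(l1 + l2):

    * H0 = 0
    * H1 = log p1 + S1
    * H2 = log p2 + S2
    * H3 = log p1 + log p2 + logdiffexp(S1 + S2, S12)
    * H4 = log p12 + S12

    With a single shared SNP no distinct-variant configuration exists and the
    H3 weight is −inf. ``per_snp_h4`` is the posterior that each shared SNP
    is the common causal variant, conditional on H4.
    """
    if prior_sd1 is None:
        prior_sd1 = DEFAULT_PRIOR_SD[region1.trait_type]
    if prior_sd2 is None:
        prior_sd2 = DEFAULT_PRIOR_SD[region2.trait_type]

    shared = sorted(v for v in region1.records if v in region2.records)
    if not shared:
        raise EmptyOverlapError(
            f"no shared variants between {region1.trait_id!r} and {region2.trait_id!r}"
        )

    b1 = np.array([region1[v].beta for v in shared])
    s1 = np.array([region1[v].se for v in shared])
    b2 = np.array([region2[v].beta for v in shared])
    s2 = np.array([region2[v].se for v in shared])

    l1 = _log_abf(b1, s1, prior_sd1)
    l2 = _log_abf(b2, s2, prior_sd2)

    S1 = float(logsumexp(l1))
    S2 = float(logsumexp(l2))
    S12 = float(logsumexp(l1 + l2))

    if len(shared) == 1:
        cross = -math.inf
    else:
        cross = logdiffexp(S1 + S2, S12)
        if not math.isfinite(cross):
            logger.warning(
                "H3 cross term underflowed (S1+S2 <= S12); H3 weight set to -inf"
            )

    weights = np.array(
        [
            0.0,
            math.log(priors.p1) + S1,
            math.log(priors.p2) + S2,
            math.log(priors.p1) + math.log(priors.p2) + cross,
            math.log(priors.p12) + S12,
        ]
    )
    post = np.exp(weights - logsumexp(weights))
    post = post / post.sum()

    h4_w = np.exp(l1 + l2 - logsumexp(l1 + l2))
    per_snp = {v: float(p) for v, p in zip(shared, h4_w)}

    return ColocResult(
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        n_snps=len(shared),
        priors=priors,
        per_snp_h4=per_snp,
    )


__all__ = [
    "ColocPriors",
    "ColocResult",
    "snp_log_abf",
    "colocalize",
    "logdiffexp",
    "DEFAULT_PRIOR_SD",
    "PPH4_THRESHOLD",
    "HYPOTHESES",
]
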