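"""MR-PRESSO: Monte-Carlo global pleiotropy test and per-SNP outlier test.

The observed statistic is the weighted residual sum of squares of each
instrument around the leave-one-out IVW fit; the null distribution is built
by resampling both betas around their leave-one-out expectations. The
distortion stage of the original procedure is not included — one pass of
outlier removal produces the cleaned set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientInstrumentsError
from .estimators import InstrumentSet


@dataclass
class PressoResult:
    """Global test and per-SNP outlier decisions."""

    global_rss: float
    global_pvalue: float
    outlier_pvalues: "dict[str, float]"
    outliers: list[str]
    n_sim: int
    seed: Optional[int]
    cleaned: Optional[InstrumentSet]


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each instrument, vectorized.

    Works on 1-D arrays or on (n_sim, k) matrices with shared weights.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def presso(
    instrument_set: InstrumentSet,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Run the global and outlier tests; flagged outliers are removed once.

    Monte-Carlo p-values use the add-one convention, so the global p-value
    is bounded below by 1/(n_sim + 1). Per-SNP p-values are Bonferroni
    corrected over the instrument count before comparison with
    ``outlier_alpha``.
    """
    k = len(instrument_set)
    if k < 4:
        raise InsufficientInstrumentsError(
            "MR-PRESSO needs >= 4 instruments (leave-one-out must keep >= 3)"
        )
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")

    bx, sx, by, sy = instrument_set.arrays()
    w = 1.0 / sy**2

    beta_loo = _loo_ivw(bx, by, w)
    rss_i = w * (by - beta_loo * bx) ** 2
    global_rss = float(rss_i.sum())

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, k))
    by_sim = beta_loo * bx + sy * rng.standard_normal((n_sim, k))
    beta_loo_sim = _loo_ivw(bx_sim, by_sim, w)
    rss_sim = w * (by_sim - beta_loo_sim * bx_sim) ** 2

    global_sim = rss_sim.sum(axis=1)
    global_p = float((1 + np.sum(global_sim >= global_rss)) / (n_sim + 1))

    per_snp_raw = (1 + np.sum(rss_sim >= rss_i, axis=0)) / (n_sim + 1)
    per_snp_adj = np.minimum(1.0, per_snp_raw * k)

    ids = instrument_set.variant_ids
    outlier_p = {vid: float(p) for vid, p in zip(ids, per_snp_adj)}
    outliers = [vid for vid, p in outlier_p.items() if p < outlier_alpha]

    cleaned: Optional[InstrumentSet] = None
    if outliers and len(outliers) < k:
        cleaned = instrument_set.drop(outliers)
    elif not outliers:
        cleaned = instrument_set

    return PressoResult(
        global_rss=global_rss,
        global_pvalue=global_p,
        outlier_pvalues=outlier_p,
        outliers=outliers,
        n_sim=n_sim,
        seed=seed,
        cleaned=cleaned,
    )


__all__ = ["PressoResult", "presso"]
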