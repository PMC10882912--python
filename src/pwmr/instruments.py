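"""cis-pQTL instrument selection: cis-window filtering, LD clumping, strength.

The cis window is defined around the gene's transcription start site (TSS),
inclusive at both boundaries. Clumping is the standard greedy index-SNP
procedure on marginal p-values; LD is supplied as an explicit correlation
matrix so the package needs no reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSampleSizeError, MissingLdError
from .sumstats import SnpAssociation, SumstatsTable

#: Conventional weak-instrument floor for the F statistic.
WEAK_F_THRESHOLD = 10.0


@dataclass
class LdMatrix:
    """Square symmetric matrix of pairwise allelic correlations r."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix dimension does not match variant_ids")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.abs(self.r).max(initial=0.0) > 1.0 + 1e-8:
            raise ValueError("LD correlations must lie in [-1, 1]")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != m:
            raise ValueError("duplicate variant_ids in LD matrix")

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise MissingLdError(f"variant {variant_id!r} absent from LD matrix")

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)

    def submatrix(self, variant_ids: Sequence[str]) -> "LdMatrix":
        idx = [self.index(v) for v in variant_ids]
        return LdMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    def to_file(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_file(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds governing instrument selection.

    window_kb is the clumping window measured from the index SNP;
    cis_window_kb is the distance from the TSS defining the cis region.
    """

    p_threshold: float
    r2_threshold: float
    window_kb: float
    cis_window_kb: float = 500.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.window_kb <= 0 or self.cis_window_kb <= 0:
            raise ValueError("selection thresholds must be positive")
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must be in (0, 1)")


#: Discovery-stage preset: relaxed significance for cis regions.
DISCOVERY = SelectionCriteria(
    p_threshold=1e-5, r2_threshold=0.01, window_kb=1000.0, cis_window_kb=500.0
)
#: Replication-stage preset: genome-wide significance, near-independence.
REPLICATION = SelectionCriteria(
    p_threshold=5e-8, r2_threshold=0.001, window_kb=10000.0, cis_window_kb=500.0
)

PRESETS = {"discovery": DISCOVERY, "replication": REPLICATION}


@dataclass(frozen=True)
class InstrumentMetrics:
    """Per-instrument variance explained and strength."""

    variant_id: str
    r2: float
    f_stat: float
    n: int
    k: int

    @property
    def weak(self) -> bool:
        return self.f_stat < WEAK_F_THRESHOLD


def cis_filter(
    table: SumstatsTable,
    gene_chrom: str,
    gene_tss: int,
    cis_window_kb: float = 500.0,
) -> SumstatsTable:
    """Restrict a table to variants within ±cis_window_kb of the gene TSS.

    Boundary positions are inclusive; variants on other chromosomes are
    removed. An empty result is allowed.
    """
    if gene_tss < 1:
        raise ValueError("gene_tss must be >= 1")
    window_bp = cis_window_kb * 1000.0
    keep = [
        rec.variant_id
        for rec in table
        if rec.chrom == str(gene_chrom) and abs(rec.pos - gene_tss) <= window_bp
    ]
    return table.subset(keep)


def clump(
    table: SumstatsTable,
    ld: LdMatrix,
    criteria: SelectionCriteria,
) -> list[str]:
    """Greedy LD clumping of significant variants; returns index-SNP ids.

    Candidates are the variants with p below ``criteria.p_threshold``; the
    unclaimed candidate with the smallest p (ties broken by ascending
    variant_id) is emitted, and every unclaimed candidate within
    ``window_kb`` of it whose squared correlation exceeds ``r2_threshold``
    is discarded. Selection order is returned, and is invariant to the
    input row order.
    """
    candidates = [rec for rec in table if rec.pvalue < criteria.p_threshold]
    for rec in candidates:
        ld.index(rec.variant_id)  # raises MissingLdError with the culprit named

    window_bp = criteria.window_kb * 1000.0
    order = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    claimed: set[str] = set()
    selected: list[str] = []
    for rec in order:
        if rec.variant_id in claimed:
            continue
        selected.append(rec.variant_id)
        claimed.add(rec.variant_id)
        for other in order:
            if other.variant_id in claimed:
                continue
            if (
                abs(other.pos - rec.pos) <= window_bp
                and ld.r2(rec.variant_id, other.variant_id) > criteria.r2_threshold
            ):
                claimed.add(other.variant_id)
    return selected


def variance_explained(
    rec: SnpAssociation, method: str = "z", trait_sd: float = 1.0
) -> float:
    """Proportion of exposure variance explained by one SNP.

    ``"z"`` (default) uses the squared t/z statistic, R² = z²/(z² + n − 2),
    which needs no allele frequency. ``"eaf"`` uses 2·eaf·(1−eaf)·β² on a
    standardized trait and requires the frequency to be present.
    """
    if method == "z":
        z2 = rec.z**2
        return z2 / (z2 + rec.n - 2)
    if method == "eaf":
        if rec.eaf is None:
            raise ValueError(f"{rec.variant_id}: eaf required for eaf-based R²")
        return 2.0 * rec.eaf * (1.0 - rec.eaf) * (rec.beta / trait_sd) ** 2
    raise ValueError(f"unknown R² method {method!r}")


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F = R²·(N − k − 1) / ((1 − R²)·k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise InvalidSampleSizeError(f"sample size {n} too small for k={k}")
    return r2 * (n - k - 1) / ((1.0 - r2) * k)


def instrument_strength(
    records: Iterable[SnpAssociation],
    k: int,
    r2_method: str = "z",
) -> list[InstrumentMetrics]:
    """Per-SNP R² and F for a selected instrument set of size ``k``."""
    metrics = []
    for rec in records:
        r2 = variance_explained(rec, method=r2_method)
        metrics.append(
            InstrumentMetrics(
                variant_id=rec.variant_id,
                r2=r2,
                f_stat=f_statistic(r2, rec.n, k),
                n=rec.n,
                k=k,
            )
        )
    return metrics


def set_strength(metrics: Sequence[InstrumentMetrics]) -> float:
    """Whole-set F using the mean per-SNP R² and k = |set|."""
    k = len(metrics)
    if k == 0:
        raise ValueError("empty metrics")
    mean_r2 = float(np.mean([m.r2 for m in metrics]))
    n = min(m.n for m in metrics)
    return f_statistic(mean_r2, n, k)


__all__ = [
    "LdMatrix",
    "SelectionCriteria",
    "InstrumentMetrics",
    "DISCOVERY",
    "REPLICATION",
    "PRESETS",
    "cis_filter",
    "clump",
    "instrument_strength",
    "variance_explained",
    "f_statistic",
    "set_strength",
    "WEAK_F_THRESHOLD",
]
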