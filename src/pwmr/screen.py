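"""Proteome-wide screen orchestration.

Per protein: cis-window filtering → LD clumping → harmonization with the
outcome → MR estimation with diagnostics. Bonferroni correction uses the
number of proteins actually tested against the outcome as the denominator
(proteins with no instrument or no outcome overlap are excluded and logged,
and do not inflate the correction). Colocalization runs for the
Bonferroni-significant hits unless ``coloc_all`` is set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .coloc import ColocPriors, PPH4_THRESHOLD, colocalize
from .errors import EmptyInputError, EmptyOverlapError
from .estimators import InstrumentSet, MrEstimate, estimate_auto, primary_estimate
from .instruments import (
    DISCOVERY,
    LdMatrix,
    SelectionCriteria,
    cis_filter,
    clump,
    instrument_strength,
)
from .sumstats import SumstatsTable, format_p, harmonize, write_results_table

logger = logging.getLogger(__name__)

SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class GeneInfo:
    """Gene annotation needed to define a protein's cis region."""

    protein_id: str
    chrom: str
    tss: int


@dataclass
class ScreenRow:
    """One tested protein–outcome pair in the screen results table."""

    protein_id: str
    outcome_id: str
    gene_chrom: str
    gene_pos: int
    n_snp: int
    method_primary: str
    beta: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue_raw: float
    pvalue_bonferroni: Optional[float] = None
    pph4: Optional[float] = None
    coloc_skip_reason: Optional[str] = None
    flags: set = field(default_factory=set)


def bonferroni(pvalues: Iterable[float], n_tests: int) -> list[float]:
    """Bonferroni correction: min(1, p·n_tests) for each p-value."""
    pvalues = list(pvalues)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if n_tests < len(pvalues):
        raise ValueError("n_tests must be at least the number of p-values")
    return [min(1.0, p * n_tests) for p in pvalues]


@dataclass
class ScreenResult:
    rows: list[ScreenRow]
    excluded: list[tuple]
    n_tests: int


def run_screen(
    exposures: Mapping[str, SumstatsTable],
    genes: Mapping[str, GeneInfo],
    outcome: SumstatsTable,
    ld_provider: Callable[[str], LdMatrix],
    criteria: SelectionCriteria = DISCOVERY,
    coloc_priors: ColocPriors = ColocPriors(),
    coloc_all: bool = False,
    seed: int = 0,
    n_boot: int = 200,
) -> ScreenResult:
    """Run the per-protein MR screen against one outcome.

    Returns rows sorted by raw p-value plus an exclusion log of
    (protein_id, reason) for proteins that could not be tested. Results are
    deterministic for a fixed seed: per-protein child seeds are derived from
    ``seed`` in sorted protein order.
    """
    if len(outcome) == 0:
        raise EmptyInputError("outcome table is empty")

    pids = sorted(exposures)
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(pids), 1))

    rows: list[ScreenRow] = []
    excluded: list[tuple] = []
    cis_tables: dict[str, SumstatsTable] = {}

    for idx, pid in enumerate(pids):
        gene = genes[pid]
        cis = cis_filter(exposures[pid], gene.chrom, gene.tss, criteria.cis_window_kb)
        if len(cis) == 0:
            excluded.append((pid, "no variants in cis window"))
            continue
        cis_tables[pid] = cis
        selected = clump(cis, ld_provider(pid), criteria)
        if not selected:
            excluded.append((pid, "no significant instruments after clumping"))
            continue
        try:
            pairs = harmonize(cis.subset(selected), outcome)
        except EmptyOverlapError:
            excluded.append((pid, "no SNPs in outcome"))
            continue
        kept = [p for p in pairs if p.kept]
        if not kept:
            excluded.append((pid, "no instruments kept after harmonization"))
            continue

        iset = InstrumentSet(kept, pid, outcome.trait_id)
        metrics = instrument_strength(
            [cis[v] for v in iset.variant_ids], k=1
        )
        estimates = estimate_auto(iset, n_boot=n_boot, seed=int(child_seeds[idx]))
        prim = primary_estimate(estimates)
        flags = set()
        if any(m.weak for m in metrics):
            flags.add("weak_instrument")
        rows.append(
            ScreenRow(
                protein_id=pid,
                outcome_id=outcome.trait_id,
                gene_chrom=gene.chrom,
                gene_pos=gene.tss,
                n_snp=prim.n_snp,
                method_primary=prim.method,
                beta=prim.beta,
                or_=math.exp(prim.beta),
                ci_low=math.exp(prim.ci_low),
                ci_high=math.exp(prim.ci_high),
                pvalue_raw=prim.pvalue,
                flags=flags,
            )
        )

    n_tests = len(rows)
    if n_tests:
        corrected = bonferroni([r.pvalue_raw for r in rows], n_tests)
        for row, p_adj in zip(rows, corrected):
            row.pvalue_bonferroni = p_adj
            if p_adj < SIGNIFICANCE_ALPHA:
                row.flags.add("significant")

    for row in rows:
        if not (coloc_all or "significant" in row.flags):
            row.coloc_skip_reason = "not Bonferroni-significant"
            continue
        try:
            res = colocalize(cis_tables[row.protein_id], outcome, coloc_priors)
        except EmptyOverlapError:
            row.coloc_skip_reason = "no shared variants in cis region"
            continue
        row.pph4 = res.pph4
        if res.pph4 >= PPH4_THRESHOLD:
            row.flags.add("coloc_pass")

    rows.sort(key=lambda r: (r.pvalue_raw, r.protein_id))
    logger.info(
        "screen: %d proteins tested, %d excluded, %d significant",
        n_tests,
        len(excluded),
        sum("significant" in r.flags for r in rows),
    )
    return ScreenResult(rows=rows, excluded=excluded, n_tests=n_tests)


def replicate_compare(discovery: ScreenRow, replication: MrEstimate) -> bool:
    """Replication flag: same effect direction and replication p < 0.05."""
    replicated = (
        math.copysign(1.0, discovery.beta) == math.copysign(1.0, replication.beta)
        and replication.pvalue < SIGNIFICANCE_ALPHA
    )
    if replicated:
        discovery.flags.add("replicated")
    return replicated


def write_screen_table(rows: Sequence[ScreenRow], path) -> None:
    """Write the screen results in the report layout (ORs, corrected p, PPH4 %)."""
    out = []
    for r in rows:
        out.append(
            {
                "protein_id": r.protein_id,
                "outcome_id": r.outcome_id,
                "n_snp": r.n_snp,
                "method": r.method_primary,
                "or": r.or_,
                "ci_low_or": r.ci_low,
                "ci_high_or": r.ci_high,
                "pvalue": r.pvalue_raw,
                "bf_pvalue": r.pvalue_bonferroni,
                "pph4_pct": "NA" if r.pph4 is None else f"{r.pph4 * 100.0:.3f}",
                "flags": ",".join(sorted(r.flags)) or "none",
            }
        )
    write_results_table(
        out,
        path,
        or_columns=("or", "ci_low_or", "ci_high_or"),
        p_columns=("pvalue", "bf_pvalue"),
    )


def manhattan_report(
    rows: Sequence[ScreenRow],
    out_path,
    n_tests: Optional[int] = None,
) -> None:
    """Manhattan-style plot: −log10 raw p by gene start position.

    A horizontal line marks the Bonferroni threshold (corrected p = 0.05);
    significant points are labelled, with positive effects in red and
    negative in blue. Both the requested file and a companion in the other
    format (vector/raster) are written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if n_tests is None:
        n_tests = max(len(rows), 1)
    threshold = -math.log10(SIGNIFICANCE_ALPHA / n_tests)

    fig, ax = plt.subplots(figsize=(8, 4))
    if rows:
        x = [r.gene_pos for r in rows]
        y = [-math.log10(max(r.pvalue_raw, 1e-300)) for r in rows]
        ax.scatter(x, y, s=12, color="grey", zorder=2)
        sig = sorted(
            (r for r in rows if "significant" in r.flags), key=lambda r: r.gene_pos
        )
        offset = 0.0
        for r in sig:
            color = "red" if r.beta > 0 else "blue"
            yy = -math.log10(max(r.pvalue_raw, 1e-300))
            ax.scatter([r.gene_pos], [yy], s=24, color=color, zorder=3)
            ax.annotate(
                r.protein_id,
                (r.gene_pos, yy),
                textcoords="offset points",
                xytext=(4, 4 + offset),
                fontsize=8,
                color=color,
            )
            offset = (offset + 8.0) % 24.0  # deterministic collision offsets
    ax.axhline(threshold, color="blue", linestyle="--", linewidth=1, zorder=1)
    ax.set_xlabel("gene start position (bp)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()

    out_path = str(out_path)
    fig.savefig(out_path, dpi=150)
    stem, _, ext = out_path.rpartition(".")
    companion = f"{stem}.svg" if ext.lower() == "png" else f"{stem}.png"
    fig.savefig(companion, dpi=150)
    plt.close(fig)


__all__ = [
    "GeneInfo",
    "ScreenRow",
    "ScreenResult",
    "bonferroni",
    "run_screen",
    "replicate_compare",
    "write_screen_table",
    "manhattan_report",
    "SIGNIFICANCE_ALPHA",
]
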