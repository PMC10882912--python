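"""Shared test fixtures and independent oracles.

The oracles deliberately recompute results by a different route than the
implementation (normal equations, exhaustive enumeration, cumulative-weight
scans) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations

import numpy as np

from pwmr.estimators import InstrumentSet
from pwmr.instruments import LdMatrix
from pwmr.screen import GeneInfo
from pwmr.simulate import SyntheticScenario, simulate_pair
from pwmr.sumstats import HarmonizedPair, SnpAssociation, SumstatsTable


def make_snp(
    vid="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.05,
    p=0.01,
    n=10_000,
) -> SnpAssociation:
    return SnpAssociation(vid, chrom, pos, ea, oa, eaf, beta, se, p, n)


def make_pair(vid, bx, sx, by, sy, action="kept") -> HarmonizedPair:
    return HarmonizedPair(vid, bx, sx, by, sy, 0.3, 0.3, action)


def make_set(bx, sx, by, sy) -> InstrumentSet:
    pairs = [
        make_pair(f"rs{i}", float(a), float(b), float(c), float(d))
        for i, (a, b, c, d) in enumerate(zip(bx, sx, by, sy))
    ]
    return InstrumentSet(pairs, "exposure", "outcome")


def random_set(rng, k=None) -> InstrumentSet:
    """A random small instrument set for oracle-equivalence checks."""
    if k is None:
        k = int(rng.integers(3, 11))
    bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1.0, 1.0], k)
    sx = rng.uniform(0.01, 0.1, k)
    by = rng.normal(0.3 * bx, 0.05)
    sy = rng.uniform(0.02, 0.2, k)
    return make_set(bx, sx, by, sy)


# -- oracles ------------------------------------------------------------------


def wls_oracle(X, y, w):
    """Weighted least squares by the normal equations; returns (coef, se_unit,
    sigma2) where se_unit is sqrt(diag((X'WX)^-1)) without residual scaling."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
    se_unit = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    return coef, se_unit, sigma2


def weighted_median_oracle(ratios, weights) -> float:
    """Scan of the sorted cumulative-weight function for the 0.5 crossing."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    for i in range(len(r) - 1):
        if cum[i] < 0.5 <= cum[i + 1]:
            return float(r[i] + (r[i + 1] - r[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i]))
    return float(r[-1])


def coloc_oracle(b1, s1, b2, s2, p1, p2, p12, sd1, sd2):
    """Posterior over H0..H4 by explicit enumeration of causal-configuration
    pairs in linear space (feasible for a handful of SNPs)."""

    def bf(beta, se, sd):
        z2 = (beta / se) ** 2
        shrink = sd**2 / (sd**2 + se**2)
        return math.sqrt(1.0 - shrink) * math.exp(0.5 * shrink * z2)

    bf1 = [bf(b, s, sd1) for b, s in zip(b1, s1)]
    bf2 = [bf(b, s, sd2) for b, s in zip(b2, s2)]
    m = len(bf1)
    h0 = 1.0
    h1 = p1 * sum(bf1)
    h2 = p2 * sum(bf2)
    h3 = p1 * p2 * sum(bf1[i] * bf2[j] for i in range(m) for j in range(m) if i != j)
    h4 = p12 * sum(bf1[i] * bf2[i] for i in range(m))
    total = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / total


def clump_oracle(records, ld: LdMatrix, criteria) -> list[str]:
    """Lexicographically-first maximal valid subset in (p, id) candidate order."""
    cands = sorted(
        (r for r in records if r.pvalue < criteria.p_threshold),
        key=lambda r: (r.pvalue, r.variant_id),
    )
    window = criteria.window_kb * 1000.0

    def compatible(a, b):
        return (
            abs(a.pos - b.pos) > window
            or ld.r2(a.variant_id, b.variant_id) <= criteria.r2_threshold
        )

    def valid(subset):
        return all(compatible(a, b) for a, b in combinations(subset, 2))

    n = len(cands)
    best = None
    for size in range(n, 0, -1):
        for idx in combinations(range(n), size):
            subset = [cands[i] for i in idx]
            if not valid(subset):
                continue
            # maximal: no outside candidate can be added
            if any(
                all(compatible(cands[j], s) for s in subset)
                for j in range(n)
                if j not in idx
            ):
                continue
            if best is None or idx < best:
                best = idx
        # maximal subsets can have different sizes; keep scanning all sizes
    return [cands[i].variant_id for i in best] if best else []


def run_mediation_pipeline(spec, seed, n=50_000):
    """Full two-step mediation on a simulated chain: instrument selection,
    harmonization, univariable MR for β1/total, MVMR for β2."""
    from pwmr.instruments import REPLICATION, cis_filter, clump
    from pwmr.mediation import (
        build_mvmr_input,
        drop_overlapping_instruments,
        two_step_mediation,
    )
    from pwmr.simulate import simulate_mediation_chain
    from pwmr.sumstats import harmonize as _harmonize

    # Ten strong causal variants per block (0.3 SD effects, spaced so the
    # strict clumping preset keeps them all): the many-strong-instrument
    # regime of real protein/lipid mediators, where sampling error on the
    # proportion is small relative to the 5-point recovery tolerance.
    scn = SyntheticScenario(
        n_snps=60,
        ld_rho=0.5,
        n_exp=n,
        n_out=n,
        causal_idx=tuple(range(2, 60, 6)),
        gamma=(0.3,) * 10,
        mediator_spec=spec,
        seed=seed,
    )
    e, m, o, ld, truth = simulate_mediation_chain(scn)
    sel_e = clump(cis_filter(e, "1", truth.exposure_tss, 500), ld, REPLICATION)
    sel_m = clump(cis_filter(m, "2", truth.mediator_tss, 500), ld, REPLICATION)
    exp_to_med = InstrumentSet(
        [p for p in _harmonize(e.subset(sel_e), m) if p.kept], "exposure", "mediator"
    )
    exp_to_out = InstrumentSet(
        [p for p in _harmonize(e.subset(sel_e), o) if p.kept], "exposure", "outcome"
    )
    mediator_set = InstrumentSet(
        [p for p in _harmonize(m.subset(sel_m), o) if p.kept], "mediator", "outcome"
    )
    mediator_set = drop_overlapping_instruments(mediator_set, exp_to_out)
    mvmr_input = build_mvmr_input(
        {"exposure": e, "mediator": m}, o, sel_e + mediator_set.variant_ids
    )
    res = two_step_mediation(
        exp_to_med, exp_to_out, mvmr_input, mediator_id="mediator", seed=0
    )
    return res, truth


# -- synthetic screen battery -------------------------------------------------


def _rekey(table: SumstatsTable, pid: str) -> SumstatsTable:
    recs = [
        dataclasses.replace(r, variant_id=f"{pid}:{r.variant_id}", chrom=pid)
        for r in table
    ]
    return SumstatsTable.from_records(pid, table.trait_type, recs,
                                      table.sample_size_default)


def make_screen_inputs(
    n_proteins: int,
    planted: int | None = None,
    theta: float = 0.5,
    seed: int = 0,
    n_snps: int = 15,
    n_out: int = 50_000,
    drop_outcome_for: int | None = None,
):
    """Build a multi-protein screen: each protein its own region/LD block.

    ``planted`` marks the single protein with a causal effect ``theta``;
    ``drop_outcome_for`` removes a protein's variants from the outcome table
    to exercise the exclusion rule.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_proteins)
    exposures, genes, lds = {}, {}, {}
    outcome_records = []
    for i in range(n_proteins):
        pid = f"P{i:03d}"
        scn = SyntheticScenario(
            n_snps=n_snps,
            ld_rho=0.3,
            n_exp=7_213,
            n_out=n_out,
            causal_idx=(2, 7, 12),
            gamma=(0.15, 0.12, 0.10),
            theta=theta if i == planted else 0.0,
            seed=int(seeds[i]),
        )
        e, o, ld, truth = simulate_pair(scn)
        exposures[pid] = _rekey(e, pid)
        genes[pid] = GeneInfo(pid, pid, truth.tss)
        lds[pid] = LdMatrix([f"{pid}:{v}" for v in ld.variant_ids], ld.r)
        if i != drop_outcome_for:
            o2 = _rekey(o, pid)
            outcome_records.extend(o2.records.values())
    outcome = SumstatsTable.from_records("HF", "binary", outcome_records, n_out)
    return exposures, genes, lds, outcome
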