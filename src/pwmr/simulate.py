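"""Synthetic GWAS summary statistics with the structure the pipeline assumes.

Marginal SNP effects are induced through an AR(1) LD correlation matrix R by
sparse causal effects: the true marginal exposure effects are b_exp = R·γ and
the outcome effects b_out = θ·b_exp + R·δ, with δ optional per-SNP direct
(pleiotropic) effects. Observed betas are drawn from a multivariate normal
with mean b and covariance R/n — the standardized-effect approximation, in
which every SE is 1/√n. Exposure and outcome draws are independent,
reflecting the two-sample design with non-overlapping cohorts.

Default sample sizes mirror the study conditions the pipeline targets: 7,213
individuals for the protein (pQTL) panel and 346,631 for the binary outcome.

Colocalization scenarios (``coloc_mode``) replace the θ-path by explicit
region structure: h0 neither trait associated, h1/h2 one trait only, h3 both
traits with distinct causal variants, h4 a shared causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import block_diag, cholesky, toeplitz

from .instruments import LdMatrix
from .sumstats import SnpAssociation, SumstatsTable

COLOC_MODES = ("h0", "h1", "h2", "h3", "h4")

# Non-palindromic effect/other allele pairs (strand always resolvable).
_ALLELE_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)

_REGION_START = 1_000_000
_SPACING = 1_000  # bp between adjacent simulated SNPs


@dataclass(frozen=True)
class SyntheticScenario:
    """Generating parameters for one exposure/outcome region pair.

    gamma are causal SNP→exposure effects in SD units; theta is the causal
    exposure→outcome effect (log-odds per SD for a binary outcome);
    pleiotropy_mean/sd parameterize per-SNP direct effects on the outcome
    (a non-zero mean gives directional pleiotropy that the Egger intercept
    should detect). mediator_spec is a (beta1, beta2, direct) triple for
    exposure→mediator→outcome chains.
    """

    n_snps: int = 200
    ld_rho: float = 0.8
    n_exp: int = 7_213
    n_out: int = 346_631
    causal_idx: Optional[tuple] = None  # default: the region's middle SNP
    gamma: Optional[tuple] = None  # default: 0.15 SD per causal SNP
    theta: float = 0.3
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    coloc_mode: Optional[str] = None
    out_causal_idx: Optional[tuple] = None
    gamma_out: Optional[tuple] = None
    mediator_spec: Optional[tuple] = None
    n_med: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_exp <= 2 or self.n_out <= 2:
            raise ValueError("sample sizes must exceed 2")
        if self.causal_idx is None:
            object.__setattr__(self, "causal_idx", (self.n_snps // 2,))
        if self.gamma is None:
            object.__setattr__(self, "gamma", (0.15,) * len(self.causal_idx))
        if any(i < 0 or i >= self.n_snps for i in self.causal_idx):
            raise ValueError("causal_idx out of range")
        if len(self.gamma) != len(self.causal_idx):
            raise ValueError("gamma and causal_idx must have equal length")
        if self.coloc_mode is not None and self.coloc_mode not in COLOC_MODES:
            raise ValueError(f"coloc_mode must be one of {COLOC_MODES}")


@dataclass
class SimulationTruth:
    """Every generating quantity of one simulated region pair."""

    scenario: SyntheticScenario
    b_exp: np.ndarray
    b_out: np.ndarray
    causal_ids: list[str]
    out_causal_ids: list[str]
    chrom: str
    tss: int


@dataclass
class ChainTruth:
    """Generating quantities of an exposure→mediator→outcome chain."""

    scenario: SyntheticScenario
    beta1: float
    beta2: float
    direct: float
    total: float
    proportion: float
    exposure_tss: int
    mediator_tss: int


def make_ld(n_snps: int, ld_rho: float, prefix: str = "snp") -> LdMatrix:
    """AR(1) LD matrix: r_ij = ld_rho^|i−j| (symmetric positive definite)."""
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    r = toeplitz(ld_rho ** np.arange(n_snps))
    ids = [f"{prefix}{i:04d}" for i in range(n_snps)]
    return LdMatrix(ids, r)


def _draw_table(
    trait_id: str,
    trait_type: str,
    b_true: np.ndarray,
    chol_lower: np.ndarray,
    n: int,
    rng: np.random.Generator,
    ids: Sequence[str],
    chroms: Sequence[str],
    positions: Sequence[int],
    eaf: np.ndarray,
    alleles: Sequence[tuple],
) -> SumstatsTable:
    m = len(ids)
    beta = b_true + chol_lower @ rng.standard_normal(m) / np.sqrt(n)
    se = np.full(m, 1.0 / np.sqrt(n))
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    records = [
        SnpAssociation(
            variant_id=ids[i],
            chrom=chroms[i],
            pos=positions[i],
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(p[i]),
            n=n,
        )
        for i in range(m)
    ]
    return SumstatsTable.from_records(trait_id, trait_type, records, n)


def _region_layout(rng: np.random.Generator, m: int, chrom: str, start: int):
    positions = [start + i * _SPACING for i in range(m)]
    eaf = rng.uniform(0.05, 0.95, m)
    alleles = [_ALLELE_PAIRS[j] for j in rng.integers(0, len(_ALLELE_PAIRS), m)]
    return positions, eaf, alleles


def _sparse(m: int, idx: Sequence[int], values: Sequence[float]) -> np.ndarray:
    v = np.zeros(m)
    for i, g in zip(idx, values):
        v[i] += g
    return v


def simulate_pair(
    scn: SyntheticScenario,
) -> tuple[SumstatsTable, SumstatsTable, LdMatrix, SimulationTruth]:
    """Simulate one exposure region and the matching outcome region."""
    rng = np.random.default_rng(scn.seed)
    m = scn.n_snps
    ld = make_ld(m, scn.ld_rho)
    R = ld.r
    L = cholesky(R, lower=True)

    gamma_out = scn.gamma_out if scn.gamma_out is not None else scn.gamma
    if scn.out_causal_idx is not None:
        out_idx = scn.out_causal_idx
    elif scn.coloc_mode == "h3":
        out_idx = tuple((i + m // 2) % m for i in scn.causal_idx)
    else:
        out_idx = scn.causal_idx

    exp_causal = _sparse(m, scn.causal_idx, scn.gamma)
    b_exp = R @ exp_causal
    if scn.coloc_mode is None:
        b_out = scn.theta * b_exp
        if scn.pleiotropy_sd > 0 or scn.pleiotropy_mean != 0:
            delta = rng.normal(scn.pleiotropy_mean, scn.pleiotropy_sd, m)
            b_out = b_out + R @ delta
    elif scn.coloc_mode in ("h0", "h1"):
        if scn.coloc_mode == "h0":
            b_exp = np.zeros(m)
        b_out = np.zeros(m)
    else:  # h2, h3, h4: outcome has its own causal configuration
        if scn.coloc_mode == "h2":
            b_exp = np.zeros(m)
        b_out = R @ _sparse(m, out_idx, gamma_out)

    chrom = "1"
    positions, eaf, alleles = _region_layout(rng, m, chrom, _REGION_START)
    tss = positions[m // 2]
    chroms = [chrom] * m

    exposure = _draw_table(
        "exposure", "quantitative", b_exp, L, scn.n_exp, rng,
        ld.variant_ids, chroms, positions, eaf, alleles,
    )
    outcome = _draw_table(
        "outcome", "binary", b_out, L, scn.n_out, rng,
        ld.variant_ids, chroms, positions, eaf, alleles,
    )
    truth = SimulationTruth(
        scenario=scn,
        b_exp=b_exp,
        b_out=b_out,
        causal_ids=[ld.variant_ids[i] for i in scn.causal_idx],
        out_causal_ids=[ld.variant_ids[i] for i in out_idx],
        chrom=chrom,
        tss=tss,
    )
    return exposure, outcome, ld, truth


def simulate_mediation_chain(
    scn: SyntheticScenario,
) -> tuple[SumstatsTable, SumstatsTable, SumstatsTable, LdMatrix, ChainTruth]:
    """Simulate an exposure→mediator→outcome chain over two LD blocks.

    The first block carries the exposure's cis instruments (marginal effects
    b_e = R·γ); the second carries instruments acting on the mediator
    directly (same γ pattern). Marginal effects are b_e / β1·b_e /
    (direct + β1·β2)·b_e on the exposure block and 0 / b_m / β2·b_m on the
    mediator block, so multivariable MR on the union identifies (direct, β2).
    """
    if scn.mediator_spec is None:
        raise ValueError("mediator_spec (beta1, beta2, direct) is required")
    beta1, beta2, direct = scn.mediator_spec
    total = direct + beta1 * beta2

    rng = np.random.default_rng(scn.seed)
    m = scn.n_snps
    block = make_ld(m, scn.ld_rho)
    R = block.r
    L = cholesky(R, lower=True)

    b_e = R @ _sparse(m, scn.causal_idx, scn.gamma)
    b_m = R @ _sparse(m, scn.causal_idx, scn.gamma)

    ids = [f"exp{i:04d}" for i in range(m)] + [f"med{i:04d}" for i in range(m)]
    ld = LdMatrix(ids, block_diag(R, R))
    chroms = ["1"] * m + ["2"] * m
    pos1, eaf1, all1 = _region_layout(rng, m, "1", _REGION_START)
    pos2, eaf2, all2 = _region_layout(rng, m, "2", 2 * _REGION_START)
    positions = pos1 + pos2
    eaf = np.concatenate([eaf1, eaf2])
    alleles = list(all1) + list(all2)
    L2 = block_diag(L, L)

    mean_exp = np.concatenate([b_e, np.zeros(m)])
    mean_med = np.concatenate([beta1 * b_e, b_m])
    mean_out = np.concatenate([total * b_e, beta2 * b_m])

    n_med = scn.n_med if scn.n_med is not None else scn.n_out
    exposure = _draw_table(
        "exposure", "quantitative", mean_exp, L2, scn.n_exp, rng,
        ids, chroms, positions, eaf, alleles,
    )
    mediator = _draw_table(
        "mediator", "quantitative", mean_med, L2, n_med, rng,
        ids, chroms, positions, eaf, alleles,
    )
    outcome = _draw_table(
        "outcome", "binary", mean_out, L2, scn.n_out, rng,
        ids, chroms, positions, eaf, alleles,
    )
    truth = ChainTruth(
        scenario=scn,
        beta1=beta1,
        beta2=beta2,
        direct=direct,
        total=total,
        proportion=(beta1 * beta2 / total) if total != 0 else float("nan"),
        exposure_tss=pos1[m // 2],
        mediator_tss=pos2[m // 2],
    )
    return exposure, mediator, outcome, ld, truth


__all__ = [
    "SyntheticScenario",
    "SimulationTruth",
    "ChainTruth",
    "make_ld",
    "simulate_pair",
    "simulate_mediation_chain",
    "COLOC_MODES",
]
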