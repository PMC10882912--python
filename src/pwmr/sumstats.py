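"""GWAS summary-statistics containers, readers/writers, and allele harmonization.

Conventions used throughout the package:

* Positions are 1-based and windows are inclusive at both ends.
* Effect sizes for binary traits are log-odds per effect-allele copy; odds
  ratios appear only in formatted output. Quantitative traits are in SD units.
* Alleles are single upper-case nucleotides; indels and multi-allelic records
  are rejected at parse time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    ConfigError,
    DuplicateVariantError,
    EmptyInputError,
    EmptyOverlapError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Standard field names understood by :func:`read_sumstats`.
STANDARD_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

TRAIT_TYPES = ("quantitative", "binary")


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if not self.se > 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be positive")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta not finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue outside (0, 1]")
        if self.n < 1:
            raise ValueError(f"{self.variant_id}: n must be positive")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SumstatsTable:
    """Ordered collection of :class:`SnpAssociation`, unique by variant_id."""

    trait_id: str
    trait_type: str
    records: "dict[str, SnpAssociation]" = field(default_factory=dict)
    sample_size_default: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}")

    @classmethod
    def from_records(
        cls,
        trait_id: str,
        trait_type: str,
        records: Iterable[SnpAssociation],
        sample_size_default: int = 0,
    ) -> "SumstatsTable":
        table = cls(trait_id, trait_type, {}, sample_size_default)
        for rec in records:
            if rec.variant_id in table.records:
                raise DuplicateVariantError(
                    f"duplicate variant_id {rec.variant_id!r} in {trait_id!r}"
                )
            table.records[rec.variant_id] = rec
        return table

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records.values())

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> SnpAssociation:
        return self.records[variant_id]

    def subset(self, variant_ids: Sequence[str]) -> "SumstatsTable":
        """New table restricted to ``variant_ids`` (kept in the given order)."""
        return SumstatsTable.from_records(
            self.trait_id,
            self.trait_type,
            (self.records[v] for v in variant_ids if v in self.records),
            self.sample_size_default,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {f: getattr(rec, f) for f in STANDARD_FIELDS}
                for rec in self.records.values()
            ],
            columns=list(STANDARD_FIELDS),
        )


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_type: str = "quantitative",
    trait_id: Optional[str] = None,
    sample_size_default: int = 0,
    sep: Optional[str] = None,
) -> SumstatsTable:
    """Read a tab- or comma-delimited summary-statistics file.

    ``column_map`` maps standard field names (see :data:`STANDARD_FIELDS`) to
    the column names in the file; unmapped fields default to their standard
    names. ``eaf`` and ``n`` columns are optional — missing ``n`` falls back
    to ``sample_size_default``. Rows violating record invariants are skipped
    and counted; gzip input is handled transparently.
    """
    column_map = dict(column_map or {})
    names = {f: column_map.get(f, f) for f in STANDARD_FIELDS}
    df = pd.read_csv(path, sep=sep, engine="python")

    mandatory = [f for f in STANDARD_FIELDS if f not in ("eaf", "n")]
    missing = [names[f] for f in mandatory if names[f] not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s) {missing}")

    has_eaf = names["eaf"] in df.columns
    has_n = names["n"] in df.columns

    records: list[SnpAssociation] = []
    seen: set[str] = set()
    n_skipped = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        vid = str(row_d[names["variant_id"]])
        if vid in seen:
            raise DuplicateVariantError(f"{path}: duplicate variant_id {vid!r}")
        seen.add(vid)
        try:
            eaf = float(row_d[names["eaf"]]) if has_eaf else None
            if eaf is not None and math.isnan(eaf):
                eaf = None
            n = int(row_d[names["n"]]) if has_n else int(sample_size_default)
            rec = SnpAssociation(
                variant_id=vid,
                chrom=str(row_d[names["chrom"]]),
                pos=int(row_d[names["pos"]]),
                effect_allele=str(row_d[names["effect_allele"]]).upper(),
                other_allele=str(row_d[names["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(row_d[names["beta"]]),
                se=float(row_d[names["se"]]),
                pvalue=float(row_d[names["pvalue"]]),
                n=n,
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.info("skipping row %s: %s", vid, exc)
            continue
        records.append(rec)

    if not records:
        raise EmptyInputError(f"{path}: no valid rows")
    table = SumstatsTable.from_records(
        trait_id or str(path), trait_type, records, sample_size_default
    )
    table.n_skipped = n_skipped
    if n_skipped:
        logger.info("%s: skipped %d invalid row(s)", path, n_skipped)
    return table


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write a table in the standard tab-delimited layout readable by
    :func:`read_sumstats`."""
    table.to_dataframe().to_csv(path, sep="\t", index=False)


# -- harmonization -----------------------------------------------------------

ACTIONS = ("kept", "sign_flipped", "dropped_palindromic", "dropped_mismatch")


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one variant after allele alignment."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action: str

    @property
    def kept(self) -> bool:
        return self.action in ("kept", "sign_flipped")


def _informative(eaf: float, limit: float) -> bool:
    return min(eaf, 1.0 - eaf) < limit


def harmonize(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    palindromic_eaf_limit: float = 0.42,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    For every variant present in both tables: same allele orientation keeps the
    record; swapped effect/other alleles flips the outcome beta's sign (and
    eaf_out becomes 1 − eaf_out); strand-complemented alleles are resolved the
    same way. Palindromic variants (A/T, C/G) are kept only when both allele
    frequencies are informative (min(eaf, 1−eaf) < ``palindromic_eaf_limit``)
    and fall on the same side of 0.5 after orientation alignment; a missing
    frequency on either side drops the variant. Anything else is a mismatch.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInputError("harmonize requires two non-empty tables")
    if not (0.0 < palindromic_eaf_limit < 0.5):
        raise ValueError("palindromic_eaf_limit must be in (0, 0.5)")

    shared = [v for v in exposure.records if v in outcome.records]
    if not shared:
        raise EmptyOverlapError(
            f"no overlapping variants between {exposure.trait_id!r} "
            f"and {outcome.trait_id!r}"
        )

    pairs: list[HarmonizedPair] = []
    for vid in shared:
        e = exposure[vid]
        o = outcome[vid]
        pairs.append(_harmonize_one(e, o, palindromic_eaf_limit))

    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.action] = counts.get(p.action, 0) + 1
    logger.info(
        "harmonized %s vs %s: %s",
        exposure.trait_id,
        outcome.trait_id,
        counts,
    )
    return pairs


def _harmonize_one(
    e: SnpAssociation, o: SnpAssociation, limit: float
) -> HarmonizedPair:
    def make(action: str, beta_out: float, eaf_out: Optional[float]) -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=e.variant_id,
            beta_exp=e.beta,
            se_exp=e.se,
            beta_out=beta_out,
            se_out=o.se,
            eaf_exp=e.eaf,
            eaf_out=eaf_out,
            action=action,
        )

    e_pair = (e.effect_allele, e.other_allele)
    o_pair = (o.effect_allele, o.other_allele)
    oc_pair = (COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele])

    if e.is_palindromic:
        # For A/T and C/G pairs strand-complementing maps the pair onto
        # itself, so only the frequencies can resolve orientation.
        if set(o_pair) != set(e_pair):
            return make("dropped_mismatch", o.beta, o.eaf)
        if o_pair == e_pair:
            flipped = False
            beta_out, eaf_out = o.beta, o.eaf
        else:
            flipped = True
            beta_out = -o.beta
            eaf_out = None if o.eaf is None else 1.0 - o.eaf
        if e.eaf is None or eaf_out is None:
            return make("dropped_palindromic", o.beta, o.eaf)
        same_side = (e.eaf - 0.5) * (eaf_out - 0.5) > 0
        if same_side and _informative(e.eaf, limit) and _informative(eaf_out, limit):
            return make("sign_flipped" if flipped else "kept", beta_out, eaf_out)
        return make("dropped_palindromic", o.beta, o.eaf)

    for cand in (o_pair, oc_pair):
        if cand == e_pair:
            return make("kept", o.beta, o.eaf)
        if cand == (e.other_allele, e.effect_allele):
            eaf_out = None if o.eaf is None else 1.0 - o.eaf
            return make("sign_flipped", -o.beta, eaf_out)
    return make("dropped_mismatch", o.beta, o.eaf)


# -- output formatting -------------------------------------------------------


def format_or(value: float) -> str:
    """Odds ratios and their CI bounds are printed to 3 decimals."""
    return f"{value:.3f}"


def format_p(value: float) -> str:
    """P-values are printed in scientific notation with 3 significant digits."""
    return f"{value:.2E}"


def _looks_like_p(name: str) -> bool:
    low = name.lower()
    return "pvalue" in low or low == "p" or low.endswith("_p") or low.startswith("p_")


def _looks_like_or(name: str) -> bool:
    low = name.lower()
    return low in ("or", "or_") or "odds" in low or low.startswith("or_") or low.endswith("_or")


def write_results_table(
    rows: Sequence[Mapping],
    path,
    or_columns: Optional[Sequence[str]] = None,
    p_columns: Optional[Sequence[str]] = None,
) -> None:
    """Write result records to a tab-delimited file with one header line.

    Column roles default to name heuristics: odds-ratio-like columns are
    printed to 3 decimals, p-value-like columns in scientific notation with 3
    significant digits. With zero rows a header-only file is produced, which
    requires explicit ``or_columns``/``p_columns`` (or none) since there is no
    schema to sniff — the header is then taken from those plus nothing else.
    """
    rows = [dict(r) for r in rows]
    if rows:
        columns = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != columns:
                raise ValueError("rows do not share a schema")
    else:
        columns = list(or_columns or []) + list(p_columns or [])

    or_cols = set(or_columns) if or_columns is not None else {
        c for c in columns if _looks_like_or(c)
    }
    p_cols = set(p_columns) if p_columns is not None else {
        c for c in columns if _looks_like_p(c)
    }

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            out = []
            for c in columns:
                v = r[c]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    out.append("NA")
                elif c in or_cols:
                    out.append(format_or(float(v)))
                elif c in p_cols:
                    out.append(format_p(float(v)))
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


__all__ = [
    "SnpAssociation",
    "SumstatsTable",
    "HarmonizedPair",
    "read_sumstats",
    "harmonize",
    "write_results_table",
    "format_or",
    "format_p",
    "STANDARD_FIELDS",
    "COMPLEMENT",
    "VALID_ALLELES",
]
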