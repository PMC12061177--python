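"""Instrumental-variable selection for two-sample Mendelian randomization.

The filter chain mirrors standard MR practice: genome-wide-significance
threshold on the exposure association, greedy LD clumping to near-independent
index SNPs, a weak-instrument filter based on the single-SNP variance
explained

    R² = 2·EAF·(1−EAF)·β²,    F = R²·(N−2)/(1−R²),

removal of SNPs strongly associated with the outcome, removal of SNPs on a
user-supplied confounder exclusion list, and Steiger directionality
filtering (a SNP explaining more variance in the outcome than in the
exposure is likely acting in the reverse direction and is dropped).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .harmonize import Exclusion, HarmonizedPair, HarmonizedSet
from .sumstats_io import SNPRecord, SummaryStats

__all__ = [
    "InstrumentCriteria",
    "LDInfo",
    "InstrumentStrength",
    "filter_by_exposure_p",
    "ld_clump",
    "instrument_strength",
    "apply_filters",
    "steiger_filter",
    "steiger_direction",
    "MissingEafError",
]


class MissingEafError(ValueError):
    """Raised when instrument strength is requested for a record without EAF."""


@dataclass(frozen=True)
class InstrumentCriteria:
    """Thresholds governing instrument selection.

    Defaults correspond to the forward (exposure -> outcome) analysis; the
    reverse direction conventionally relaxes ``p_exposure_max`` to 5e-6 when
    few SNPs reach genome-wide significance.
    """

    p_exposure_max: float = 5e-8
    clump_r2_max: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    p_outcome_min: float = 5e-5
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self):
        for name in ("p_exposure_max", "clump_r2_max", "clump_window_kb",
                     "f_min", "p_outcome_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.clump_r2_max < 1:
            raise ValueError("clump_r2_max must be < 1")
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass(frozen=True, slots=True)
class InstrumentStrength:
    snp_id: str
    r2: float
    f_stat: float


class LDInfo:
    """Pairwise LD (r²) plus per-SNP genomic positions.

    Built from a square r² matrix or a long-format (snp_a, snp_b, r2) table,
    together with a (snp_id, chrom, bp) position table.  Unrecorded pairs are
    treated as unlinked (r² = 0); self-r² is 1.
    """

    def __init__(self, positions: Mapping[str, tuple[str, int]],
                 r2: Mapping[tuple[str, str], float] | None = None):
        self._pos = {s: (str(c), int(bp)) for s, (c, bp) in positions.items()}
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), v in (r2 or {}).items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"r2({a},{b}) = {v} outside [0, 1]")
            self._r2[(a, b) if a <= b else (b, a)] = float(v)

    def has_position(self, snp_id: str) -> bool:
        return snp_id in self._pos

    def position(self, snp_id: str) -> tuple[str, int]:
        return self._pos[snp_id]

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get((a, b) if a <= b else (b, a), 0.0)

    @classmethod
    def from_tables(cls, positions: pd.DataFrame,
                    pairs: pd.DataFrame | None = None,
                    matrix: pd.DataFrame | None = None) -> "LDInfo":
        """Build from dataframes: ``positions`` with columns (snp_id, chrom, bp);
        either ``pairs`` (snp_a, snp_b, r2) or a square ``matrix`` indexed and
        labelled by snp_id."""
        pos = {str(r.snp_id): (str(r.chrom), int(r.bp))
               for r in positions.itertuples(index=False)}
        r2: dict[tuple[str, str], float] = {}
        if pairs is not None:
            for r in pairs.itertuples(index=False):
                r2[(str(r.snp_a), str(r.snp_b))] = float(r.r2)
        if matrix is not None:
            ids = [str(s) for s in matrix.index]
            vals = matrix.to_numpy(dtype=float)
            if vals.shape[0] != vals.shape[1]:
                raise ValueError("LD matrix must be square")
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    if i < j:
                        r2[(a, b)] = vals[i, j]
        return cls(pos, r2)


def filter_by_exposure_p(ss: SummaryStats, p_max: float) -> SummaryStats:
    """Keep SNPs with exposure p-value strictly below ``p_max`` (order kept)."""
    kept = [r.snp_id for r in ss if r.pval < p_max]
    return ss.subset(kept)


def ld_clump(ss: SummaryStats, ld: LDInfo, r2_max: float = 0.001,
             window_kb: float = 10_000.0) -> SummaryStats:
    """Greedy LD clumping to independent index SNPs.

    Repeatedly takes the remaining SNP with the smallest exposure p-value
    (ties broken by snp_id) as an index SNP and removes every other SNP on
    the same chromosome within ``window_kb`` whose r² with it is >= ``r2_max``.
    """
    missing = [r.snp_id for r in ss if not ld.has_position(r.snp_id)]
    if missing:
        raise KeyError(f"SNPs missing from LD position table: {missing}")

    order = sorted(ss, key=lambda r: (r.pval, r.snp_id))
    kept: list[str] = []
    remaining = list(order)
    window_bp = window_kb * 1000.0
    while remaining:
        index = remaining.pop(0)
        kept.append(index.snp_id)
        ic, ibp = ld.position(index.snp_id)
        survivors = []
        for r in remaining:
            c, bp = ld.position(r.snp_id)
            in_window = (c == ic) and (abs(bp - ibp) <= window_bp)
            if in_window and ld.r2(index.snp_id, r.snp_id) >= r2_max:
                continue
            survivors.append(r)
        remaining = survivors
    # restore the input ordering among kept ids
    kept_set = set(kept)
    return ss.subset([r.snp_id for r in ss if r.snp_id in kept_set])


def _r2_single_snp(eaf: float, beta: float) -> float:
    """Variance in a standardized trait explained by one SNP: 2·EAF·(1−EAF)·β²."""
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def instrument_strength(rec: SNPRecord) -> InstrumentStrength:
    """Per-SNP R² and F-statistic from EAF, β and N.

    F = R²·(N−2)/(1−R²) with R² = 2·EAF·(1−EAF)·β².  Requires EAF; a record
    without EAF has undefined strength (raises :class:`MissingEafError`, and
    filter chains exclude the SNP with reason ``no_eaf``).
    """
    if rec.eaf is None:
        raise MissingEafError(f"{rec.snp_id}: EAF required for R²/F computation")
    if rec.n < 3:
        raise ValueError(f"{rec.snp_id}: n must be >= 3 for the F-statistic")
    r2 = _r2_single_snp(rec.eaf, rec.beta)
    f = r2 * (rec.n - 2) / (1.0 - r2)
    return InstrumentStrength(rec.snp_id, r2, f)


def _pair_exposure_record(p: HarmonizedPair) -> SNPRecord:
    # exposure-side view of a harmonized pair; alleles are placeholders since
    # strength depends only on (eaf, beta, n)
    return SNPRecord(p.snp_id, "A", "G", p.beta_exp, p.se_exp, p.eaf_exp,
                     p.pval_exp, p.n_exp)


def apply_filters(hset: HarmonizedSet, criteria: InstrumentCriteria) -> HarmonizedSet:
    """Weak-instrument, outcome-association and confounder filters.

    Excludes pairs with exposure-side F below ``criteria.f_min``
    (``weak_instrument``; ``no_eaf`` when EAF is absent so F is undefined),
    outcome p-value below ``criteria.p_outcome_min`` (``outcome_associated``),
    and ids on the confounder exclusion list (``confounder``).  Idempotent.
    """
    pairs: list[HarmonizedPair] = []
    log = list(hset.exclusion_log)
    for p in hset.pairs:
        if p.eaf_exp is None:
            log.append(Exclusion(p.snp_id, "filter", "no_eaf"))
            continue
        strength = instrument_strength(_pair_exposure_record(p))
        if strength.f_stat < criteria.f_min:
            log.append(Exclusion(p.snp_id, "filter", "weak_instrument"))
            continue
        if p.pval_out < criteria.p_outcome_min:
            log.append(Exclusion(p.snp_id, "filter", "outcome_associated"))
            continue
        if p.snp_id in criteria.exclusion_list:
            log.append(Exclusion(p.snp_id, "filter", "confounder"))
            continue
        pairs.append(p)
    return HarmonizedSet(pairs, log)


def _steiger_z(r_exp: float, r_out: float, n_exp: int, n_out: int) -> tuple[float, float]:
    """One-sided Fisher-z comparison of two independent correlations.

    z = (atanh(r_exp) − atanh(r_out)) / sqrt(1/(n_exp−3) + 1/(n_out−3));
    returns (z, one-sided p for the alternative r_exp > r_out).
    """
    z = (math.atanh(r_exp) - math.atanh(r_out)) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    return z, float(stats.norm.sf(z))


def steiger_direction(hset: HarmonizedSet) -> dict:
    """Pooled-set Steiger directionality test.

    Pools per-SNP variance explained on each side (r = sqrt(Σ R²)) and tests
    whether the instruments explain significantly more variance in the
    exposure than in the outcome.  SNPs lacking EAF on either side are
    omitted from the pooled sums.
    """
    r2_exp_sum = 0.0
    r2_out_sum = 0.0
    used = 0
    n_exp = n_out = 0
    for p in hset.pairs:
        if p.eaf_exp is None or p.eaf_out is None:
            continue
        r2_exp_sum += _r2_single_snp(p.eaf_exp, p.beta_exp)
        r2_out_sum += _r2_single_snp(p.eaf_out, p.beta_out)
        used += 1
        n_exp, n_out = p.n_exp, p.n_out
    if used == 0:
        return {"r2_exp": math.nan, "r2_out": math.nan, "z": math.nan,
                "pval": math.nan, "direction_true": None, "n_snp_used": 0}
    r_exp = math.sqrt(min(r2_exp_sum, 1.0 - 1e-12))
    r_out = math.sqrt(min(r2_out_sum, 1.0 - 1e-12))
    z, p = _steiger_z(r_exp, r_out, n_exp, n_out)
    return {"r2_exp": r2_exp_sum, "r2_out": r2_out_sum, "z": z, "pval": p,
            "direction_true": bool(r2_exp_sum > r2_out_sum and p < 0.05),
            "n_snp_used": used}


def steiger_filter(hset: HarmonizedSet, alpha: float = 0.05) -> HarmonizedSet:
    """Per-SNP Steiger directionality filter.

    A SNP is kept only when its exposure-side R² exceeds its outcome-side R²
    AND the one-sided Fisher-z test of the corresponding correlations
    (|r| = sqrt(R²), sample sizes n_exp/n_out) is significant at ``alpha``;
    otherwise it is excluded with reason ``steiger_false``.  SNPs lacking EAF
    on either side pass with a warning (direction untestable).
    """
    pairs: list[HarmonizedPair] = []
    log = list(hset.exclusion_log)
    warned = False
    for p in hset.pairs:
        if p.eaf_exp is None or p.eaf_out is None:
            if not warned:
                warnings.warn("Steiger filter: SNPs without EAF on both sides "
                              "pass unfiltered", stacklevel=2)
                warned = True
            pairs.append(p)
            continue
        r2_exp = _r2_single_snp(p.eaf_exp, p.beta_exp)
        r2_out = _r2_single_snp(p.eaf_out, p.beta_out)
        _, pval = _steiger_z(math.sqrt(min(r2_exp, 1 - 1e-12)),
                             math.sqrt(min(r2_out, 1 - 1e-12)),
                             p.n_exp, p.n_out)
        if r2_exp > r2_out and pval < alpha:
            pairs.append(p)
        else:
            log.append(Exclusion(p.snp_id, "steiger", "steiger_false"))
    return HarmonizedSet(pairs, log)
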