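"""Harmonize exposure and outcome summary statistics onto a common effect allele.

Two GWAS report the same SNP relative to arbitrary allele orderings and,
possibly, opposite DNA strands.  Before any ratio of outcome to exposure
effects is meaningful, both studies must refer to the same effect allele:
swapped alleles flip the sign of the outcome effect (and complement the
allele frequency), strand differences are resolved by complementing, and
palindromic SNPs (A/T, C/G) — whose strand cannot be resolved from the
alleles — are removed outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .exceptions import EmptyInstrumentError
from .sumstats_io import SNPRecord, SummaryStats, write_table

__all__ = [
    "HarmonizedPair",
    "HarmonizedSet",
    "Exclusion",
    "classify_palindrome",
    "harmonize_pair",
    "harmonize_set",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Exclusion(NamedTuple):
    snp_id: str
    stage: str
    reason: str


@dataclass(frozen=True, slots=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    eaf_exp: float | None
    pval_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    eaf_out: float | None
    pval_out: float
    n_out: int
    flipped: bool = False

    def __post_init__(self):
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


@dataclass
class HarmonizedSet:
    """Harmonized exposure/outcome pairs plus a complete exclusion log.

    Every SNP handed to :func:`harmonize_set` appears exactly once: either in
    ``pairs`` or in ``exclusion_log``.
    """

    pairs: list[HarmonizedPair]
    exclusion_log: list[Exclusion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def array(self, name: str) -> np.ndarray:
        """Column of pair attribute ``name`` as a float array (NaN for missing)."""
        vals = [getattr(p, name) for p in self.pairs]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        keep = set(snp_ids)
        return HarmonizedSet([p for p in self.pairs if p.snp_id in keep],
                             list(self.exclusion_log))

    def drop(self, snp_ids: Iterable[str], stage: str, reason: str) -> "HarmonizedSet":
        """Remove SNPs, appending one exclusion-log entry per removed SNP."""
        gone = set(snp_ids)
        log = list(self.exclusion_log)
        log.extend(Exclusion(p.snp_id, stage, reason) for p in self.pairs
                   if p.snp_id in gone)
        return HarmonizedSet([p for p in self.pairs if p.snp_id not in gone], log)

    def write_exclusion_log(self, path) -> None:
        write_table([e._asdict() for e in self.exclusion_log], path)


def classify_palindrome(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is its own reverse complement (A/T or C/G)."""
    return COMPLEMENT[effect_allele] == other_allele


def harmonize_pair(exp: SNPRecord, out: SNPRecord) -> HarmonizedPair | Exclusion:
    """Align one outcome record to the exposure's effect allele.

    Returns a :class:`HarmonizedPair`, or an :class:`Exclusion` when the SNP
    is palindromic or the allele sets cannot be reconciled.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id!r} vs {out.snp_id!r}")
    if classify_palindrome(exp.effect_allele, exp.other_allele):
        return Exclusion(exp.snp_id, "harmonize", "palindromic")

    o_ea, o_oa = out.effect_allele, out.other_allele
    if {o_ea, o_oa} != {exp.effect_allele, exp.other_allele}:
        # try the opposite strand
        o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        if {o_ea, o_oa} != {exp.effect_allele, exp.other_allele}:
            return Exclusion(exp.snp_id, "harmonize", "allele_mismatch")

    if o_ea == exp.effect_allele:
        flipped = False
        beta_out, eaf_out = out.beta, out.eaf
    else:  # alleles swapped relative to exposure: invert the outcome effect
        flipped = True
        beta_out = -out.beta
        eaf_out = None if out.eaf is None else 1.0 - out.eaf

    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
        pval_exp=exp.pval, n_exp=exp.n,
        beta_out=beta_out, se_out=out.se, eaf_out=eaf_out,
        pval_out=out.pval, n_out=out.n,
        flipped=flipped,
    )


def harmonize_set(exposure: SummaryStats, outcome: SummaryStats,
                  snp_ids: Sequence[str] | None = None,
                  require_nonempty: bool = True) -> HarmonizedSet:
    """Harmonize the instrument SNPs of ``exposure`` against ``outcome``.

    ``snp_ids`` (default: every exposure SNP) must be a subset of the exposure
    ids.  SNPs absent from the outcome are logged ``missing_in_outcome``; the
    rest pass through :func:`harmonize_pair`.  Raises
    :class:`EmptyInstrumentError` (carrying the log) if nothing survives and
    ``require_nonempty``.
    """
    ids = list(snp_ids) if snp_ids is not None else list(exposure.records)
    missing = [s for s in ids if s not in exposure]
    if missing:
        raise ValueError(f"instrument ids absent from exposure: {missing}")

    pairs: list[HarmonizedPair] = []
    log: list[Exclusion] = []
    for snp_id in ids:
        if snp_id not in outcome:
            log.append(Exclusion(snp_id, "harmonize", "missing_in_outcome"))
            continue
        res = harmonize_pair(exposure[snp_id], outcome[snp_id])
        if isinstance(res, Exclusion):
            log.append(res)
        else:
            pairs.append(res)
    hset = HarmonizedSet(pairs, log)
    if require_nonempty and not pairs:
        raise EmptyInstrumentError("no instruments survived harmonization",
                                   exclusion_log=log)
    return hset
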