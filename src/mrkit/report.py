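"""Result assembly: odds-ratio conversion and per-direction BH-FDR tables.

Causal effects are estimated on the log-odds scale; reports convert them to
odds ratios with normal-theory 95% intervals, OR = exp(β),
CI = exp(β ± 1.96·se).  Within each analysis direction the IVW p-values
across outcomes form one multiple-testing family and are adjusted by the
Benjamini–Hochberg step-up procedure; an association is called significant
when both the raw and the adjusted p fall below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import Z95, MREstimate
from .sensitivity import SensitivityReport

__all__ = [
    "PairResult",
    "bh_adjust",
    "effect_to_or",
    "assemble_report",
]


@dataclass
class PairResult:
    """Everything reported for one exposure/outcome pair in one direction."""

    exposure_label: str
    outcome_label: str
    direction: str  # "forward" or "reverse"
    estimates: dict[str, MREstimate]
    sensitivity: SensitivityReport | None
    n_snp_final: int
    estimable: bool = True
    note: str = ""
    first_pass: dict = field(default_factory=dict)  # pre-outlier-removal results
    raw_p_ivw: float | None = None
    fdr_p_ivw: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.direction, self.outcome_label if self.direction == "forward"
                else self.exposure_label)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    For sorted p_(i), adj_(i) = min_{k >= i} min(1, p_(k)·m/k).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Convert a log-odds effect and SE to (OR, ci_low, ci_high)."""
    if not se > 0:
        raise ValueError("se must be > 0")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


def _forest_rows(res: PairResult) -> list[dict]:
    rows = []
    other = res.exposure_label if res.direction == "forward" else res.outcome_label
    target = res.outcome_label if res.direction == "forward" else res.exposure_label
    for method, est in res.estimates.items():
        or_, lo, hi = effect_to_or(est.beta, est.se)
        rows.append({
            "direction": res.direction,
            "exposure": res.exposure_label,
            "outcome": res.outcome_label,
            "method": method,
            "n_snp": est.n_snp,
            "beta": est.beta,
            "se": est.se,
            "or": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "pval": est.pval,
            "fdr_pval": res.fdr_p_ivw if method.startswith("ivw") else None,
            "significant": (bool(est.pval < 0.05 and res.fdr_p_ivw is not None
                                 and res.fdr_p_ivw < 0.05)
                            if method.startswith("ivw") else None),
        })
    _ = (other, target)
    return rows


def _sensitivity_row(res: PairResult) -> dict:
    s = res.sensitivity
    return {
        "direction": res.direction,
        "exposure": res.exposure_label,
        "outcome": res.outcome_label,
        "p_q_egger": s.q_egger.pval if s and s.q_egger else None,
        "p_q_ivw": s.q_ivw.pval if s else None,
        "p_egger_intercept": s.egger_intercept.pval if s and s.egger_intercept else None,
        "p_presso_global": s.presso.global_p if s and s.presso else None,
    }


def assemble_report(results: Sequence[PairResult],
                    expected_per_direction: int | None = None,
                    ivw_method: str = "ivw_mre") -> dict[str, pd.DataFrame]:
    """Assemble forest-style and sensitivity tables with per-direction FDR.

    The FDR family is the set of outcomes within one direction.  When
    ``expected_per_direction`` is given and a direction has fewer estimable
    results, the adjustment still runs over those present, with a warning.
    Duplicate (direction, counterpart) entries raise.
    """
    seen = set()
    for r in results:
        if r.key in seen:
            raise ValueError(f"duplicate result for {r.key}")
        seen.add(r.key)

    for direction in ("forward", "reverse"):
        group = [r for r in results
                 if r.direction == direction and r.estimable
                 and ivw_method in r.estimates]
        if not group:
            continue
        if expected_per_direction is not None and len(group) != expected_per_direction:
            warnings.warn(f"{direction}: FDR family has {len(group)} results, "
                          f"expected {expected_per_direction}", stacklevel=2)
        raw = [r.estimates[ivw_method].pval for r in group]
        adj = bh_adjust(raw)
        for r, p_raw, p_adj in zip(group, raw, adj):
            r.raw_p_ivw = float(p_raw)
            r.fdr_p_ivw = float(p_adj)

    forest_rows: list[dict] = []
    sens_rows: list[dict] = []
    for r in results:
        if not r.estimable:
            forest_rows.append({
                "direction": r.direction, "exposure": r.exposure_label,
                "outcome": r.outcome_label, "method": None, "n_snp": r.n_snp_final,
                "beta": None, "se": None, "or": None, "or_ci_low": None,
                "or_ci_high": None, "pval": None, "fdr_pval": None,
                "significant": None})
            continue
        forest_rows.extend(_forest_rows(r))
        sens_rows.append(_sensitivity_row(r))

    forest = pd.DataFrame(forest_rows)
    sens = pd.DataFrame(sens_rows)
    out = {}
    for direction in ("forward", "reverse"):
        if len(forest):
            out[f"{direction}_forest"] = forest[forest.direction == direction].reset_index(drop=True)
        else:
            out[f"{direction}_forest"] = forest.copy()
        if len(sens):
            out[f"{direction}_sensitivity"] = sens[sens.direction == direction].reset_index(drop=True)
        else:
            out[f"{direction}_sensitivity"] = sens.copy()
    return out
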