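"""Heterogeneity and pleiotropy diagnostics for a harmonized instrument set.

Implements the standard MR sensitivity battery: Cochran's Q under the IVW
model and Rücker's Q' about the Egger fit, the Egger intercept test,
MR-PRESSO (global residual-sum-of-squares test, per-SNP outlier test and
distortion test, all by seeded parametric simulation), Radial MR per-SNP Q
contributions, and leave-one-out IVW.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .estimators import ivw, mr_egger, ratio_estimates
from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedSet

__all__ = [
    "QResult",
    "PressoResult",
    "RadialResult",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "radial_mr",
    "leave_one_out",
    "sensitivity_report",
]


class QResult(NamedTuple):
    q: float
    df: int
    pval: float


class InterceptResult(NamedTuple):
    value: float
    se: float
    pval: float


@dataclass(frozen=True)
class PressoResult:
    global_p: float
    outlier_ids: tuple[str, ...]
    distortion_p: float | None  # None when no outliers were flagged
    n_sim: int
    raw_outlier_p: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RadialResult:
    snp_ids: tuple[str, ...]
    q_contributions: np.ndarray
    pvals: np.ndarray
    outlier_ids: tuple[str, ...]
    beta_radial: float
    weights: str


@dataclass(frozen=True)
class SensitivityReport:
    """All diagnostics for one exposure/outcome pair."""

    q_ivw: QResult
    q_egger: QResult | None
    egger_intercept: InterceptResult | None
    presso: PressoResult | None
    radial: RadialResult
    loo: list[dict] | None


def cochran_q(hset: HarmonizedSet, model: str = "ivw") -> QResult:
    """Cochran's Q heterogeneity statistic.

    ``model='ivw'``: Q = Σ w_j (β̂_j − β̂_IVW-fixed)² over the Wald ratios,
    w_j = 1/se_j², df = L−1.  ``model='egger'``: Rücker's Q', the weighted
    residual sum of squares about the Egger fit, df = L−2.  p from χ².
    """
    L = len(hset)
    if model == "ivw":
        if L < 2:
            raise InsufficientInstrumentsError("Q(IVW) requires >= 2 instruments")
        b, s = ratio_estimates(hset)
        w = 1.0 / s**2
        beta = float(np.sum(w * b) / np.sum(w))
        q = float(np.sum(w * (b - beta) ** 2))
        df = L - 1
    elif model == "egger":
        if L < 3:
            raise InsufficientInstrumentsError("Q'(Egger) requires >= 3 instruments")
        est = mr_egger(hset)
        q = est.extra["rss_w"]
        df = L - 2
    else:
        raise ValueError(f"unknown model {model!r}")
    return QResult(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(hset: HarmonizedSet) -> InterceptResult:
    """Egger intercept (directional-pleiotropy) test: the intercept row of
    the MR-Egger fit with its SE and two-sided p."""
    est = mr_egger(hset)
    return InterceptResult(est.extra["intercept"], est.extra["intercept_se"],
                           est.extra["intercept_pval"])


def _loo_slopes(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW-fixed slopes of βo on βe (through the origin),
    vectorized over leading axes: θ̂_{−j} for each j."""
    s_xx = np.sum(be**2 * w, axis=-1, keepdims=True)
    s_xy = np.sum(be * bo * w, axis=-1, keepdims=True)
    return (s_xy - be * bo * w) / (s_xx - be**2 * w)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              sig: float = 0.05) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the leave-one-out weighted RSS,
    RSS_obs = Σ_j w_j (βo_j − θ̂_{−j} βe_j)² with w_j = 1/σo_j².  Null data
    are simulated as βe*_j ~ N(βe_j, σe_j) and βo*_j ~ N(θ̂_{−j}·βe_j, σo_j),
    the statistic recomputed each time, and

        global_p = (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).

    The per-SNP outlier p compares each observed squared residual with its
    simulated distribution (Bonferroni-corrected by L; outliers where the
    corrected p < ``sig``).  The distortion p compares the shift in the IVW
    estimate after removing the flagged outliers against the shifts from
    removing equally many random SNPs (two-sided empirical p).  All
    randomness derives from ``seed``.
    """
    L = len(hset)
    if L < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 instruments")
    be = hset.array("beta_exp")
    se = hset.array("se_exp")
    bo = hset.array("beta_out")
    so = hset.array("se_out")
    w = 1.0 / so**2
    snp_ids = hset.snp_ids

    theta_loo = _loo_slopes(be, bo, w)
    res_obs = w * (bo - theta_loo * be) ** 2
    rss_obs = float(np.sum(res_obs))

    rng = np.random.default_rng(seed)
    be_star = rng.normal(be, se, size=(n_sim, L))
    bo_star = rng.normal(theta_loo * be, so, size=(n_sim, L))
    theta_star = _loo_slopes(be_star, bo_star, w)
    res_star = w * (bo_star - theta_star * be_star) ** 2
    rss_star = np.sum(res_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    p_j = (1 + np.sum(res_star >= res_obs, axis=0)) / (n_sim + 1)
    p_corr = np.minimum(1.0, p_j * L)
    outliers = tuple(snp_ids[j] for j in range(L) if p_corr[j] < sig)

    distortion_p: float | None = None
    if outliers:
        out_idx = [snp_ids.index(s) for s in outliers]
        keep = np.ones(L, dtype=bool)
        keep[out_idx] = False
        theta_all = float(np.sum(be * bo * w) / np.sum(be**2 * w))
        theta_removed = float(np.sum((be * bo * w)[keep]) / np.sum((be**2 * w)[keep]))
        d_obs = abs(theta_removed - theta_all)
        k = len(out_idx)
        count = 0
        for _ in range(n_sim):
            idx = rng.choice(L, size=k, replace=False)
            m = np.ones(L, dtype=bool)
            m[idx] = False
            t = float(np.sum((be * bo * w)[m]) / np.sum((be**2 * w)[m]))
            if abs(t - theta_all) >= d_obs:
                count += 1
        distortion_p = float((1 + count) / (n_sim + 1))

    return PressoResult(global_p, outliers, distortion_p, n_sim,
                        raw_outlier_p={s: float(p) for s, p in zip(snp_ids, p_corr)})


def radial_mr(hset: HarmonizedSet, alpha: float = 0.05,
              weights: str = "first") -> RadialResult:
    """Radial MR per-SNP Q contributions and outlier flags.

    With first-order weights w_j = βe_j²/σo_j² the radial-IVW slope equals
    the fixed-effect IVW estimate and the contributions q_j = w_j (β̂_j − β̂)²
    sum exactly to Cochran's Q.  ``weights='second'`` uses modified
    second-order weights w_j = 1/(σo_j²/βe_j² + βo_j²σe_j²/βe_j⁴).
    p_j from χ²(1); outliers where p_j < ``alpha``.
    """
    L = len(hset)
    if L < 2:
        raise InsufficientInstrumentsError("Radial MR requires >= 2 instruments")
    be = hset.array("beta_exp")
    se = hset.array("se_exp")
    bo = hset.array("beta_out")
    so = hset.array("se_out")
    b = bo / be
    if weights == "first":
        w = be**2 / so**2
    elif weights == "second":
        w = 1.0 / (so**2 / be**2 + bo**2 * se**2 / be**4)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    beta = float(np.sum(w * b) / np.sum(w))
    q_j = w * (b - beta) ** 2
    p_j = stats.chi2.sf(q_j, 1)
    snp_ids = tuple(hset.snp_ids)
    outliers = tuple(s for s, p in zip(snp_ids, p_j) if p < alpha)
    return RadialResult(snp_ids, q_j, p_j, outliers, beta, weights)


def leave_one_out(hset: HarmonizedSet, mode: str = "mre") -> list[dict]:
    """IVW estimate recomputed with each SNP left out in turn.

    A SNP is flagged influential when its omission flips the sign of the
    estimate or moves the p-value across 0.05 relative to the full-set fit.
    """
    L = len(hset)
    if L < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = ivw(hset, mode=mode)
    rows = []
    for p in hset.pairs:
        sub = HarmonizedSet([q for q in hset.pairs if q.snp_id != p.snp_id])
        est = ivw(sub, mode=mode)
        influential = (np.sign(est.beta) != np.sign(full.beta) and full.beta != 0) or \
                      ((est.pval < 0.05) != (full.pval < 0.05))
        rows.append({"left_out": p.snp_id, "beta": est.beta, "se": est.se,
                     "pval": est.pval, "influential": bool(influential)})
    return rows


def sensitivity_report(hset: HarmonizedSet, seed: int | None = None,
                       n_sim: int = 1000, presso_sig: float = 0.05,
                       radial_alpha: float = 0.05,
                       ivw_mode: str = "mre") -> SensitivityReport:
    """Run the full diagnostic battery, omitting tests whose instrument-count
    preconditions are not met (reported as None)."""
    L = len(hset)
    q_ivw = cochran_q(hset, "ivw")
    q_egger = cochran_q(hset, "egger") if L >= 3 else None
    intercept = egger_intercept_test(hset) if L >= 3 else None
    presso = mr_presso(hset, n_sim=n_sim, seed=seed, sig=presso_sig) if L >= 4 else None
    radial = radial_mr(hset, alpha=radial_alpha)
    loo = leave_one_out(hset, mode=ivw_mode) if L >= 3 else None
    return SensitivityReport(q_ivw, q_egger, intercept, presso, radial, loo)
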