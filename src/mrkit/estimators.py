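"""Causal-effect estimators for two-sample summary-data MR.

Given L harmonized SNPs with exposure effects βe_j (se σe_j) and outcome
effects βo_j (se σo_j), the per-SNP Wald ratio is β̂_j = βo_j/βe_j with
first-order delta-method standard error σo_j/|βe_j|.  The estimators differ
in how they pool the ratios and which invalid-instrument patterns they
tolerate:

* **IVW** — inverse-variance-weighted mean of the ratios; the multiplicative
  random-effects variant inflates the fixed-effect SE by
  max(1, sqrt(Q/(L−1))) with Q Cochran's heterogeneity statistic.
* **MR-Egger** — weighted regression of βo on βe with a free intercept; the
  slope is the causal effect under the InSIDE assumption and the intercept
  measures directional pleiotropy.
* **Weighted median** — the 50th weighted percentile of the ratios;
  consistent when valid instruments carry at least half the weight.
  SE by seeded parametric bootstrap.
* **cML-MA** — constrained maximum likelihood allowing K SNPs to carry free
  direct effects, model-averaged over K with BIC weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import EstimationError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair, HarmonizedSet

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cml_ma",
    "ratio_estimates",
]

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal effect on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 5e-324
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)))


def ratio_estimates(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order delta-method SEs."""
    be = hset.array("beta_exp")
    bo = hset.array("beta_out")
    so = hset.array("se_out")
    if np.any(be == 0):
        bad = [p.snp_id for p in hset.pairs if p.beta_exp == 0]
        raise EstimationError(f"zero exposure effect for {bad}: Wald ratio undefined")
    return bo / be, so / np.abs(be)


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate: βo/βe with SE σo/|βe|."""
    if pair.beta_exp == 0:
        raise EstimationError(f"{pair.snp_id}: zero exposure effect")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MREstimate("wald", beta, se, _normal_p(beta, se), 1,
                      extra={"snp_id": pair.snp_id})


def _ivw_core(b: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW mean, its SE and Cochran's Q for ratio estimates."""
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    return beta, se_fixed, q


def ivw(hset: HarmonizedSet, mode: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode='fe'`` gives the fixed-effect SE (Σw)^(−1/2); ``mode='mre'``
    (default) multiplies it by max(1, sqrt(Q/(L−1))) — the multiplicative
    random-effects model.  With a single instrument the estimate reduces to
    the Wald ratio (flagged in ``extra``).
    """
    if mode not in ("fe", "mre"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    L = len(hset)
    if L < 1:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if L == 1:
        est = wald_ratio(hset.pairs[0])
        return MREstimate("ivw_fe" if mode == "fe" else "ivw_mre",
                          est.beta, est.se, est.pval, 1,
                          extra={"fallback": "wald", **est.extra})
    b, s = ratio_estimates(hset)
    beta, se_fixed, q = _ivw_core(b, s)
    if mode == "fe":
        se = se_fixed
    else:
        se = se_fixed * max(1.0, math.sqrt(q / (L - 1)))
    return MREstimate("ivw_fe" if mode == "fe" else "ivw_mre",
                      beta, se, _normal_p(beta, se), L,
                      extra={"q": q, "q_df": L - 1, "se_fixed": se_fixed})


def _oriented(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(βe, σe, βo, σo) with pairs flipped so every βe >= 0 (Egger convention)."""
    be = hset.array("beta_exp")
    se = hset.array("se_exp")
    bo = hset.array("beta_out")
    so = hset.array("se_out")
    sign = np.where(be < 0, -1.0, 1.0)
    return be * sign, se, bo * sign, so


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: WLS of βo on βe with intercept, weights 1/σo².

    Pairs are first oriented so all βe >= 0.  Slope SE and intercept SE are
    inflated by max(1, sqrt(RSS_w/(L−2))); the p-values use t(L−2).  The
    intercept, its SE and p (the directional-pleiotropy test) are stored in
    ``extra``.
    """
    L = len(hset)
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    be, _, bo, so = _oriented(hset)
    w = 1.0 / so**2
    sw = np.sum(w)
    xbar = np.sum(w * be) / sw
    ybar = np.sum(w * bo) / sw
    sxx = np.sum(w * (be - xbar) ** 2)
    if sxx <= 0:
        raise EstimationError("degenerate design: all exposure effects equal")
    slope = float(np.sum(w * (be - xbar) * (bo - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = bo - intercept - slope * be
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, math.sqrt(rss_w / (L - 2)))
    se_slope = math.sqrt(1.0 / sxx) * phi
    se_int = math.sqrt(1.0 / sw + xbar**2 / sxx) * phi
    df = L - 2
    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(slope) / se_slope, df)))
    p_int = float(min(1.0, 2.0 * stats.t.sf(abs(intercept) / se_int, df)))
    return MREstimate("egger", slope, se_slope, p_slope, L,
                      extra={"intercept": intercept, "intercept_se": se_int,
                             "intercept_pval": p_int, "rss_w": rss_w,
                             "scale": phi, "df": df})


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation (Bowden convention).

    Sort the estimates; with normalized weights w_(j), the cumulative
    mid-weight is s_j = cumsum(w)_(j) − w_(j)/2; interpolate between the two
    order statistics whose s straddles 1/2.
    """
    order = np.argsort(b, kind="stable")
    bs = b[order]
    ws = w[order] / np.sum(w)
    s = np.cumsum(ws) - ws / 2.0
    if s[0] >= 0.5:
        return float(bs[0])
    if s[-1] <= 0.5:
        return float(bs[-1])
    k = int(np.searchsorted(s, 0.5, side="left"))  # s[k-1] < 0.5 <= s[k]
    return float(bs[k - 1] + (bs[k] - bs[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Weights are inverse-variance weights of the Wald ratios.  The SE is the
    standard deviation of the weighted median over ``n_boot`` resamples
    β̂*_j ~ Normal(β̂_j, se_j), drawn from ``seed``.
    """
    L = len(hset)
    if L < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    b, s = ratio_estimates(hset)
    w = 1.0 / s**2
    beta = _weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, s, size=(n_boot, L))
    # vectorized weighted median across bootstrap rows
    order = np.argsort(draws, axis=1, kind="stable")
    bs = np.take_along_axis(draws, order, axis=1)
    ws = (w / np.sum(w))[order]
    smid = np.cumsum(ws, axis=1) - ws / 2.0
    boots = np.empty(n_boot)
    for i in range(n_boot):
        si, bi = smid[i], bs[i]
        if si[0] >= 0.5:
            boots[i] = bi[0]
        elif si[-1] <= 0.5:
            boots[i] = bi[-1]
        else:
            k = int(np.searchsorted(si, 0.5, side="left"))
            boots[i] = bi[k - 1] + (bi[k] - bi[k - 1]) * (0.5 - si[k - 1]) / (si[k] - si[k - 1])
    se = float(np.std(boots, ddof=1))
    return MREstimate("wmedian", beta, se, _normal_p(beta, se), L,
                      extra={"n_boot": n_boot})


# ---------------------------------------------------------------------------
# cML-MA
# ---------------------------------------------------------------------------

def _cml_profile_dev(theta: float, be, se, bo, so, mask) -> float:
    """Profile deviance over the valid set (r_j profiled to 0, b_j profiled out):
    Σ_{j valid} (βo_j − θ·βe_j)² / (σo_j² + θ²·σe_j²)."""
    num = (bo[mask] - theta * be[mask]) ** 2
    den = so[mask] ** 2 + theta**2 * se[mask] ** 2
    return float(np.sum(num / den))


def _cml_fit_one_k(be, se, bo, so, K: int, max_iter: int, tol: float):
    """Constrained-ML fit with exactly K invalid instruments.

    Alternates (i) ranking SNPs by squared standardized residuals at the
    current θ and declaring the top K invalid (their direct effects r_j are
    profiled out exactly, contributing zero deviance), with (ii) minimizing
    the exact profile deviance over θ on the valid set.  Returns
    (theta, dev, support_indices, converged).
    """
    L = be.size
    w0 = 1.0 / so**2
    theta = float(np.sum(be * bo * w0) / np.sum(be**2 * w0))  # IVW-fixed start
    support: tuple[int, ...] = ()
    converged = False
    for _ in range(max_iter):
        t = (bo - theta * be) ** 2 / (so**2 + theta**2 * se**2)
        if K > 0:
            new_support = tuple(sorted(np.argsort(-t, kind="stable")[:K].tolist()))
        else:
            new_support = ()
        mask = np.ones(L, dtype=bool)
        if new_support:
            mask[list(new_support)] = False
        res = optimize.minimize_scalar(
            _cml_profile_dev, bracket=(theta - 0.5, theta + 0.5),
            args=(be, se, bo, so, mask))
        theta_new = float(res.x)
        if new_support == support and abs(theta_new - theta) < tol:
            theta = theta_new
            converged = True
            break
        support, theta = new_support, theta_new
    mask = np.ones(L, dtype=bool)
    if support:
        mask[list(support)] = False
    dev = _cml_profile_dev(theta, be, se, bo, so, mask)
    return theta, dev, support, converged


def _cml_se(theta: float, be, se, bo, so, mask) -> float:
    """SE from the numerical curvature of the profile deviance at θ̂.

    The deviance is twice the negative profile log-likelihood, so
    Var(θ̂) ≈ 2 / dev''(θ̂).
    """
    h = 1e-4 * max(1.0, abs(theta))
    d0 = _cml_profile_dev(theta, be, se, bo, so, mask)
    dp = _cml_profile_dev(theta + h, be, se, bo, so, mask)
    dm = _cml_profile_dev(theta - h, be, se, bo, so, mask)
    curv = (dp - 2.0 * d0 + dm) / h**2
    if curv <= 0:
        return math.inf
    return math.sqrt(2.0 / curv)


def cml_ma(hset: HarmonizedSet, k_grid: Sequence[int] | None = None,
           max_iter: int = 100, tol: float = 1e-8,
           seed: int | None = None) -> MREstimate:
    """Constrained-maximum-likelihood model-averaging estimate (BIC-only).

    For each candidate number K of invalid instruments the constrained ML
    problem — minimize Σ_j [(βo_j − θ·b_j − r_j)²/σo_j² + (βe_j − b_j)²/σe_j²]
    with at most K nonzero r_j — is solved by alternating support selection
    and exact profile minimization in θ.  BIC(K) = dev(θ̂_K) + K·log(L);
    estimates are averaged with weights ∝ exp(−BIC/2), and the averaged
    variance adds between-model dispersion to the within-model variances.

    ``seed`` is accepted for interface stability; the BIC-only procedure is
    deterministic and does not consume it.
    """
    L = len(hset)
    if L < 3:
        raise InsufficientInstrumentsError("cML-MA requires >= 3 instruments")
    if k_grid is None:
        k_grid = range(0, L - 1)  # 0 .. L-2
    k_grid = sorted(set(int(k) for k in k_grid))
    if any(k < 0 or k > L - 2 for k in k_grid):
        raise ValueError(f"k_grid must be within 0..{L - 2}")

    be = hset.array("beta_exp")
    sexp = hset.array("se_exp")
    bo = hset.array("beta_out")
    so = hset.array("se_out")

    fits = {}
    for K in k_grid:
        theta, dev, support, conv = _cml_fit_one_k(be, sexp, bo, so, K, max_iter, tol)
        if not conv:
            warnings.warn(f"cML: K={K} did not converge; dropped", stacklevel=2)
            continue
        mask = np.ones(L, dtype=bool)
        if support:
            mask[list(support)] = False
        se_k = _cml_se(theta, be, sexp, bo, so, mask)
        if not math.isfinite(se_k):
            warnings.warn(f"cML: K={K} has degenerate curvature; dropped",
                          stacklevel=2)
            continue
        bic = dev + K * math.log(L)
        fits[K] = (theta, se_k, bic, support)
    if not fits:
        raise EstimationError("cML-MA: no K in the grid converged")

    bics = np.array([fits[K][2] for K in fits])
    wts = np.exp(-(bics - bics.min()) / 2.0)
    wts = wts / wts.sum()
    thetas = np.array([fits[K][0] for K in fits])
    ses = np.array([fits[K][1] for K in fits])
    beta = float(np.sum(wts * thetas))
    var = float(np.sum(wts * (ses**2 + (thetas - beta) ** 2)))
    se = math.sqrt(var)

    k_list = list(fits)
    k_best = k_list[int(np.argmin(bics))]
    snp_ids = hset.snp_ids
    invalid_ids = [snp_ids[i] for i in fits[k_best][3]]
    return MREstimate("cml_ma", beta, se, _normal_p(beta, se), L,
                      extra={"bic_weights": {int(K): float(w) for K, w in zip(k_list, wts)},
                             "k_best": int(k_best),
                             "invalid_ids": invalid_ids})
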