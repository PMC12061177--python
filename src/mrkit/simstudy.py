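"""Monte-Carlo evaluation harnesses for the estimators and diagnostics.

These drive the synthetic generator through the harmonization layer and the
estimators exactly as the pipeline does, and summarize recovery of the known
ground truth: bias and CI coverage under a true effect, type-I error under
the null, robustness of the weighted median under contamination, Egger
intercept recovery of planted directional pleiotropy, and planted-outlier
detection rates for MR-PRESSO and Radial MR.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import replace

import numpy as np

from .estimators import cml_ma, ivw, mr_egger, weighted_median
from .harmonize import HarmonizedSet, harmonize_set
from .sensitivity import mr_presso, radial_mr
from .synthgwas import SimConfig, simulate_pair

__all__ = ["calibrate_estimators", "contamination_study",
           "outlier_detection_study", "simulate_harmonized"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def simulate_harmonized(cfg: SimConfig) -> tuple[HarmonizedSet, object]:
    """One simulated pair pushed through harmonization; returns (hset, truth)."""
    exposure, outcome, truth = simulate_pair(cfg)
    hset = harmonize_set(exposure, outcome)
    return hset, truth


def _fit(method: str, hset: HarmonizedSet, seed: int):
    if method == "ivw":
        return ivw(hset)
    if method == "egger":
        return mr_egger(hset)
    if method == "wmedian":
        return weighted_median(hset, seed=seed)
    if method == "cml":
        return cml_ma(hset, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def calibrate_estimators(theta: float, n_rep: int, seed: int,
                         methods: tuple[str, ...] = ("ivw", "egger", "wmedian", "cml"),
                         base_cfg: SimConfig | None = None) -> dict[str, dict]:
    """Bias, 95%-CI coverage and rejection rate at nominal 0.05 per estimator.

    Each replicate draws a fresh pair from the generator's default strong-
    instrument, no-pleiotropy conditions (overridable via ``base_cfg``) with
    the requested true effect, harmonizes it, and fits every estimator.
    Under ``theta = 0`` the rejection rate is the empirical type-I error.
    """
    base = base_cfg or SimConfig()
    seeds = _child_seeds(seed, n_rep)
    acc = {m: {"est": [], "cover": 0, "reject": 0} for m in methods}
    for s in seeds:
        cfg = replace(base, theta=theta, seed=int(s))
        hset, _ = simulate_harmonized(cfg)
        for m in methods:
            est = _fit(m, hset, int(s))
            acc[m]["est"].append(est.beta)
            acc[m]["cover"] += int(est.ci_low <= theta <= est.ci_high)
            acc[m]["reject"] += int(est.pval < 0.05)
    out = {}
    for m in methods:
        e = np.array(acc[m]["est"])
        out[m] = {
            "mean_bias": float(np.mean(e) - theta),
            "sd": float(np.std(e, ddof=1)),
            "mc_se": float(np.std(e, ddof=1) / math.sqrt(n_rep)),
            "coverage": acc[m]["cover"] / n_rep,
            "rejection_rate": acc[m]["reject"] / n_rep,
            "n_rep": n_rep,
        }
    return out


def contamination_study(n_rep: int, seed: int, theta: float = 0.1,
                        prop_invalid: float = 0.3,
                        pleiotropy_mean: float = 0.03,
                        pleiotropy_sd: float = 0.01,
                        base_cfg: SimConfig | None = None) -> dict:
    """Directional-pleiotropy contamination: WM robustness and Egger recovery.

    A fraction of instruments carries direct effects ~ N(mean, sd).  Reports
    the mean bias of IVW and the weighted median, and the mean Egger
    intercept next to the mean planted per-SNP direct effect (averaged over
    all L SNPs, which is what the intercept targets under InSIDE).
    """
    base = base_cfg or SimConfig()
    base = replace(base, theta=theta, pleiotropy_mode="directional",
                   prop_invalid=prop_invalid, pleiotropy_mean=pleiotropy_mean,
                   pleiotropy_sd=pleiotropy_sd)
    seeds = _child_seeds(seed, n_rep)
    est_ivw, est_wm, intercepts, planted = [], [], [], []
    for s in seeds:
        cfg = replace(base, seed=int(s))
        hset, truth = simulate_harmonized(cfg)
        est_ivw.append(ivw(hset).beta)
        est_wm.append(weighted_median(hset, seed=int(s)).beta)
        intercepts.append(mr_egger(hset).extra["intercept"])
        planted.append(float(np.mean(truth.direct_effect)))
    return {
        "bias_ivw": float(np.mean(est_ivw) - theta),
        "bias_wm": float(np.mean(est_wm) - theta),
        "mean_egger_intercept": float(np.mean(intercepts)),
        "mean_planted_pleiotropy": float(np.mean(planted)),
        "n_rep": n_rep,
    }


def outlier_detection_study(n_runs: int, seed: int, n_snp: int = 20,
                            displace_se: float = 10.0,
                            presso_nsim: int = 1000,
                            base_cfg: SimConfig | None = None) -> dict:
    """Planted gross-outlier detection rates for MR-PRESSO and Radial MR.

    Each run simulates a clean pair, displaces one SNP's outcome effect by
    ``displace_se`` outcome standard errors, and checks whether that SNP is
    flagged by each method.
    """
    base = base_cfg or SimConfig()
    base = replace(base, n_snp=n_snp, theta=0.1)
    seeds = _child_seeds(seed, n_runs)
    hit_presso = hit_radial = 0
    for s in seeds:
        cfg = replace(base, seed=int(s))
        hset, _ = simulate_harmonized(cfg)
        rng = np.random.default_rng(int(s) + 1)
        j = int(rng.integers(len(hset)))
        target = hset.pairs[j]
        contaminated = dataclasses.replace(
            target, beta_out=target.beta_out + displace_se * target.se_out)
        pairs = list(hset.pairs)
        pairs[j] = contaminated
        hset = HarmonizedSet(pairs)
        presso = mr_presso(hset, n_sim=presso_nsim, seed=int(s))
        radial = radial_mr(hset)
        hit_presso += int(target.snp_id in presso.outlier_ids)
        hit_radial += int(target.snp_id in radial.outlier_ids)
    return {"presso_rate": hit_presso / n_runs,
            "radial_rate": hit_radial / n_runs,
            "n_runs": n_runs}
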