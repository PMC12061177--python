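"""Synthetic paired GWAS summary statistics with known causal ground truth.

The generator draws L independent instruments under the structural model

    βo_j = θ·βe_j + r_j ,

where θ is the causal effect of exposure on outcome on the log-odds scale,
βe_j the true per-allele instrument effect and r_j a per-SNP direct
(pleiotropic) effect on the outcome.  Observed effects add Gaussian noise
with the standard single-SNP standard-error approximation for a
standardized trait, se_j ≈ 1/sqrt(2·EAF_j·(1−EAF_j)·N).  True instrument
effects are drawn half-normal — the effect allele is taken to be the
exposure-increasing allele — so that directional pleiotropy has a
well-defined orientation.

Pleiotropy regimes:

* ``none`` — every r_j = 0;
* ``balanced`` — invalid SNPs draw r_j ~ N(0, sd);
* ``directional`` — invalid SNPs draw r_j ~ N(mean, sd);
* ``inside_violating`` — invalid r_j correlated with instrument strength,
  r_j = mean·(βe_j/beta_exp_sd) + N(0, sd), breaking the InSIDE assumption.

Presets carry the case+control sample sizes of the motivating studies
(a schizophrenia GWAS and five dementia GWAS) so the noise regime matches
realistic study shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import SNPRecord, SummaryStats

__all__ = ["SimConfig", "SimTruth", "simulate_pair", "preset", "preset_pair",
           "PRESET_N"]

#: total GWAS sample sizes (cases + controls) of the motivating studies
PRESET_N = {
    "schizophrenia": 53_386 + 77_258,   # 130,644
    "acd": 18_216 + 330_460,            # all-cause dementia, 348,676
    "ad": 85_934 + 401_577,             # Alzheimer's disease, 487,511
    "vad": 3_116 + 433_066,             # vascular dementia, 436,182
    "ftd": 515 + 2_509,                 # frontotemporal dementia, 3,024
    "dlb": 2_591 + 4_027,               # dementia with Lewy bodies, 6,618
}

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic exposure/outcome GWAS pair.

    Defaults emulate the forward analysis of the motivating design: a large
    psychiatric exposure GWAS (N=130,644) against the largest dementia
    outcome GWAS (N=348,676), 50 strong independent instruments
    (half-normal effects, sd 0.05, per-SNP F floor 30) and no pleiotropy.
    """

    n_snp: int = 50
    n_exp: int = PRESET_N["schizophrenia"]
    n_out: int = PRESET_N["acd"]
    theta: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.0
    prop_invalid: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    beta_exp_sd: float = 0.05
    f_floor: float | None = 30.0
    palindromic_frac: float = 0.0
    strand_flip_frac: float = 0.0
    swapped_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ValueError("prop_invalid must lie in [0, 1]")
        if self.n_exp < 100 or self.n_out < 100:
            raise ValueError("sample sizes must be >= 100")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must be a subinterval of (0, 1)")
        if self.beta_exp_sd == 0 and self.f_floor is not None:
            raise ValueError("beta_exp_sd=0 cannot satisfy an F floor")
        for frac in (self.palindromic_frac, self.strand_flip_frac, self.swapped_frac):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("allele fractions must lie in [0, 1]")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated pair, for recovery tests."""

    theta_true: float
    snp_ids: tuple[str, ...]
    beta_exp_true: np.ndarray
    direct_effect: np.ndarray
    valid: np.ndarray  # boolean; False where a direct effect was planted

    @property
    def prop_invalid(self) -> float:
        return float(np.mean(~self.valid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": list(self.snp_ids),
                             "beta_exp_true": self.beta_exp_true,
                             "direct_effect": self.direct_effect,
                             "valid": self.valid})


def _approx_se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 5e-324, 1.0)


def simulate_pair(cfg: SimConfig) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Generate one exposure/outcome summary-statistic pair plus ground truth.

    Deterministic given ``cfg`` (all randomness from ``cfg.seed``).  The
    first round(prop_invalid·n_snp) SNPs of a seeded permutation carry
    direct effects so the invalid fraction is exact.  Configured fractions
    of SNPs are made palindromic or represented on the opposite strand / with
    swapped alleles in the outcome file, to exercise harmonization.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snp
    snp_ids = tuple(f"rs{j + 1:06d}" for j in range(L))

    eaf = rng.uniform(cfg.eaf_range[0], cfg.eaf_range[1], size=L)
    se_exp = _approx_se(eaf, cfg.n_exp)
    se_out = _approx_se(eaf, cfg.n_out)

    # half-normal true effects; resample per SNP until the per-SNP F-statistic
    # (true effect, exposure N) clears the requested floor
    beta_true = np.abs(rng.normal(0.0, cfg.beta_exp_sd, size=L))
    if cfg.f_floor is not None:
        for j in range(L):
            for _ in range(10_000):
                r2 = 2.0 * eaf[j] * (1.0 - eaf[j]) * beta_true[j] ** 2
                f = r2 * (cfg.n_exp - 2) / (1.0 - r2)
                if f >= cfg.f_floor:
                    break
                beta_true[j] = abs(rng.normal(0.0, cfg.beta_exp_sd))
            else:
                raise ValueError("could not satisfy F floor; raise beta_exp_sd "
                                 "or lower f_floor")

    n_invalid = round(cfg.prop_invalid * L)
    invalid_idx = rng.permutation(L)[:n_invalid]
    valid = np.ones(L, dtype=bool)
    valid[invalid_idx] = False
    r = np.zeros(L)
    if n_invalid and cfg.pleiotropy_mode != "none":
        if cfg.pleiotropy_mode == "balanced":
            r[invalid_idx] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        elif cfg.pleiotropy_mode == "directional":
            r[invalid_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd,
                                        size=n_invalid)
        else:  # inside_violating: direct effect tracks instrument strength
            r[invalid_idx] = (cfg.pleiotropy_mean
                              * beta_true[invalid_idx] / cfg.beta_exp_sd
                              + rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid))

    beta_exp_obs = beta_true + rng.normal(0.0, se_exp)
    beta_out_true = cfg.theta * beta_true + r
    beta_out_obs = beta_out_true + rng.normal(0.0, se_out)

    # allele assignment: configured fractions palindromic / strand-flipped /
    # swapped in the outcome representation
    n_pal = round(cfg.palindromic_frac * L)
    n_strand = round(cfg.strand_flip_frac * L)
    n_swap = round(cfg.swapped_frac * L)
    perm = rng.permutation(L)
    pal_set = set(perm[:n_pal].tolist())
    rest = perm[n_pal:]
    strand_set = set(rest[:n_strand].tolist())
    swap_set = set(rng.permutation(L)[:n_swap].tolist())

    exp_records, out_records = [], []
    for j in range(L):
        if j in pal_set:
            ea, oa = _PALINDROMIC[int(rng.integers(len(_PALINDROMIC)))]
        else:
            ea, oa = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
        exp_records.append(SNPRecord(
            snp_ids[j], ea, oa, float(beta_exp_obs[j]), float(se_exp[j]),
            float(eaf[j]), float(_pvals(beta_exp_obs[[j]], se_exp[[j]])[0]),
            cfg.n_exp))
        o_ea, o_oa = ea, oa
        o_beta, o_eaf = float(beta_out_obs[j]), float(eaf[j])
        if j in strand_set and j not in pal_set:
            o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
        if j in swap_set:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        out_records.append(SNPRecord(
            snp_ids[j], o_ea, o_oa, o_beta, float(se_out[j]), o_eaf,
            float(_pvals(beta_out_obs[[j]], se_out[[j]])[0]), cfg.n_out))

    exposure = SummaryStats.from_records("exposure", exp_records,
                                         provenance=f"synthetic seed={cfg.seed}")
    outcome = SummaryStats.from_records("outcome", out_records,
                                        provenance=f"synthetic seed={cfg.seed}")
    truth = SimTruth(cfg.theta, snp_ids, beta_true, r, valid)
    return exposure, outcome, truth


def preset(name: str, **overrides) -> SimConfig:
    """A SimConfig whose exposure sample size matches the named study.

    ``name`` is one of schizophrenia, acd, ad, vad, ftd, dlb; remaining
    fields take their defaults unless overridden by keyword.
    """
    key = name.lower()
    if key not in PRESET_N:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESET_N)}")
    kwargs = {"n_exp": PRESET_N[key]}
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def preset_pair(exposure: str, outcome: str, **overrides) -> SimConfig:
    """A SimConfig with exposure and outcome sample sizes from two presets."""
    e, o = exposure.lower(), outcome.lower()
    for k in (e, o):
        if k not in PRESET_N:
            raise KeyError(f"unknown preset {k!r}; choose from {sorted(PRESET_N)}")
    kwargs = {"n_exp": PRESET_N[e], "n_out": PRESET_N[o]}
    kwargs.update(overrides)
    return SimConfig(**kwargs)
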