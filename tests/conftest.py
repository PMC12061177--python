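import numpy as np
import pytest

from mrkit.harmonize import HarmonizedPair, HarmonizedSet
from mrkit.sumstats_io import SNPRecord, SummaryStats


def make_hset(beta_exp, se_exp, beta_out, se_out, eaf=None, n_exp=100_000,
              n_out=100_000, pval_exp=None, pval_out=None):
    """Build a HarmonizedSet directly from effect arrays (test helper)."""
    L = len(beta_exp)
    eaf = eaf if eaf is not None else [0.3] * L
    pairs = []
    for j in range(L):
        pairs.append(HarmonizedPair(
            snp_id=f"rs{j + 1:03d}",
            beta_exp=float(beta_exp[j]), se_exp=float(se_exp[j]),
            eaf_exp=None if eaf[j] is None else float(eaf[j]),
            pval_exp=float(pval_exp[j]) if pval_exp is not None else 1e-10,
            n_exp=int(n_exp),
            beta_out=float(beta_out[j]), se_out=float(se_out[j]),
            eaf_out=None if eaf[j] is None else float(eaf[j]),
            pval_out=float(pval_out[j]) if pval_out is not None else 0.5,
            n_out=int(n_out)))
    return HarmonizedSet(pairs)


def make_sumstats(label, rows):
    """rows: iterable of (snp_id, ea, oa, beta, se, eaf, pval, n)."""
    return SummaryStats.from_records(
        label, [SNPRecord(*r) for r in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def hset_small():
    """Three concordant instruments with mild heterogeneity."""
    return make_hset(beta_exp=[0.10, 0.08, 0.12], se_exp=[0.01, 0.01, 0.01],
                     beta_out=[0.05, 0.03, 0.06], se_out=[0.02, 0.01, 0.015])
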