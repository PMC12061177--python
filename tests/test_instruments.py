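import math

import pytest
from hypothesis import given, settings, strategies as st

from mrkit.instruments import (InstrumentCriteria, LDInfo, MissingEafError,
                               apply_filters, filter_by_exposure_p,
                               instrument_strength, ld_clump, steiger_filter)
from mrkit.sumstats_io import SNPRecord

from conftest import make_hset, make_sumstats


def rec(snp_id, pval=1e-9, beta=0.1, eaf=0.3, n=50_000, se=0.01):
    return SNPRecord(snp_id, "A", "G", beta, se, eaf, pval, n)


class TestExposurePFilter:
    def test_strict_threshold(self):
        ss = make_sumstats("e", [
            ("rs1", "A", "G", 0.1, 0.01, 0.3, 1e-9, 1000),
            ("rs2", "A", "G", 0.1, 0.01, 0.3, 4e-8, 1000),
            ("rs3", "A", "G", 0.1, 0.01, 0.3, 6e-8, 1000)])
        kept = filter_by_exposure_p(ss, 5e-8)
        assert list(kept.records) == ["rs1", "rs2"]
        assert len(filter_by_exposure_p(ss, 5e-6)) == 3

    def test_empty_input(self):
        ss = make_sumstats("e", [("rs1", "A", "G", 0.1, 0.01, 0.3, 1e-9, 1000)])
        assert len(filter_by_exposure_p(ss.subset([]), 5e-8)) == 0


def _ld(positions, pairs=None):
    return LDInfo({s: (c, bp) for s, c, bp in positions},
                  {tuple(k): v for k, v in (pairs or {}).items()})


class TestLDClump:
    def test_linked_neighbour_removed(self):
        ss = make_sumstats("e", [
            ("rs1", "A", "G", 0.1, 0.01, 0.3, 1e-10, 1000),
            ("rs2", "A", "G", 0.1, 0.01, 0.3, 1e-9, 1000)])
        ld = _ld([("rs1", "1", 100_000), ("rs2", "1", 105_000)],
                 {("rs1", "rs2"): 0.5})
        kept = ld_clump(ss, ld, r2_max=0.001, window_kb=10_000)
        assert list(kept.records) == ["rs1"]

    def test_window_does_not_span_chromosomes(self):
        ss = make_sumstats("e", [
            ("rs1", "A", "G", 0.1, 0.01, 0.3, 1e-10, 1000),
            ("rs2", "A", "G", 0.1, 0.01, 0.3, 1e-9, 1000)])
        ld = _ld([("rs1", "1", 100_000), ("rs2", "2", 100_000)],
                 {("rs1", "rs2"): 0.9})
        assert len(ld_clump(ss, ld, 0.001, 10_000)) == 2

    def test_missing_position_is_hard_error(self):
        ss = make_sumstats("e", [("rs1", "A", "G", 0.1, 0.01, 0.3, 1e-10, 1000)])
        with pytest.raises(KeyError, match="rs1"):
            ld_clump(ss, _ld([]), 0.001, 10_000)

    def test_matches_brute_force_oracle(self, rng):
        """Greedy clumping agrees with an independent re-derivation on random
        instances (<= 12 SNPs): iterate the definition - best remaining p-value
        is an index SNP; any SNP in its window with r2 >= threshold is not."""
        for trial in range(200):
            L = int(rng.integers(2, 13))
            ids = [f"rs{j}" for j in range(L)]
            pvals = rng.uniform(1e-12, 1e-6, L)
            chrom = rng.choice(["1", "2"], L)
            bp = rng.integers(1, 30_000_000, L)
            pos = {ids[j]: (chrom[j], int(bp[j])) for j in range(L)}
            r2 = {}
            for a in range(L):
                for b in range(a + 1, L):
                    if rng.random() < 0.5:
                        r2[(ids[a], ids[b])] = float(rng.random())
            ld = LDInfo(pos, r2)
            ss = make_sumstats("e", [
                (ids[j], "A", "G", 0.1, 0.01, 0.3, float(pvals[j]), 1000)
                for j in range(L)])
            got = set(ld_clump(ss, ld, 0.1, 5_000).records)

            # oracle: direct transcription of the priority rule
            order = sorted(ids, key=lambda s: (float(pvals[ids.index(s)]), s))
            removed, index_snps = set(), []
            for s in order:
                if s in removed:
                    continue
                index_snps.append(s)
                sc, sbp = pos[s]
                for t in order:
                    if t == s or t in removed:
                        continue
                    tc, tbp = pos[t]
                    if sc == tc and abs(tbp - sbp) <= 5_000_000 and ld.r2(s, t) >= 0.1:
                        removed.add(t)
            assert got == set(index_snps), f"trial {trial}"


class TestInstrumentStrength:
    def test_printed_formula_midrange(self):
        s = instrument_strength(rec("rs1", beta=0.1, eaf=0.5, n=10_002))
        assert s.r2 == pytest.approx(0.005)
        assert s.f_stat == pytest.approx(0.005 * 10_000 / 0.995, rel=1e-12)
        assert s.f_stat == pytest.approx(50.251, abs=5e-4)

    def test_printed_formula_large_n(self):
        s = instrument_strength(rec("rs1", beta=0.05, eaf=0.3, n=130_644))
        assert s.r2 == pytest.approx(2 * 0.3 * 0.7 * 0.0025)
        assert s.f_stat == pytest.approx(0.00105 * 130_642 / 0.99895, rel=1e-12)
        assert s.f_stat == pytest.approx(137.3, abs=0.05)

    def test_zero_effect(self):
        s = instrument_strength(rec("rs1", beta=0.0))
        assert s.r2 == 0.0 and s.f_stat == 0.0

    def test_missing_eaf_undefined(self):
        with pytest.raises(MissingEafError):
            instrument_strength(rec("rs1", eaf=None))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 0.5), st.floats(0.001, 0.2), st.floats(0.001, 0.2),
           st.integers(1000, 10**6), st.integers(1000, 10**6))
    def test_monotone_in_effect_and_n(self, eaf, b1, b2, n1, n2):
        lo_b, hi_b = sorted((b1, b2))
        lo_n, hi_n = sorted((n1, n2))
        f_small = instrument_strength(rec("rs1", beta=lo_b, eaf=eaf, n=lo_n)).f_stat
        f_bigger_beta = instrument_strength(rec("rs1", beta=hi_b, eaf=eaf, n=lo_n)).f_stat
        f_bigger_n = instrument_strength(rec("rs1", beta=lo_b, eaf=eaf, n=hi_n)).f_stat
        assert f_bigger_beta >= f_small
        assert f_bigger_n >= f_small


class TestApplyFilters:
    def _criteria(self, **kw):
        return InstrumentCriteria(**kw)

    def test_weak_instrument_excluded(self):
        # F just under 10: solve r2 so that r2*(n-2)/(1-r2) ~ 9.9
        hs = make_hset([0.004], [0.001], [0.0], [0.01], eaf=[0.5], n_exp=1_000_000)
        f = instrument_strength(rec("x", beta=0.004, eaf=0.5, n=1_000_000)).f_stat
        assert f < 10
        out = apply_filters(hs, self._criteria())
        assert len(out) == 0
        assert out.exclusion_log[0].reason == "weak_instrument"

    def test_outcome_associated_excluded(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.01], pval_out=[1e-6])
        out = apply_filters(hs, self._criteria())
        assert out.exclusion_log[0].reason == "outcome_associated"

    def test_confounder_excluded(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.01])
        out = apply_filters(hs, self._criteria(exclusion_list={"rs001"}))
        assert out.exclusion_log[0].reason == "confounder"

    def test_no_eaf_excluded(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.01], eaf=[None])
        out = apply_filters(hs, self._criteria())
        assert out.exclusion_log[0].reason == "no_eaf"

    def test_idempotent(self):
        hs = make_hset([0.1, 0.004, 0.2], [0.01] * 3, [0.05, 0.0, 0.1],
                       [0.01] * 3, pval_out=[0.5, 0.5, 1e-7])
        once = apply_filters(hs, self._criteria())
        twice = apply_filters(once, self._criteria())
        assert once.pairs == twice.pairs
        assert once.exclusion_log == twice.exclusion_log


class TestSteigerFilter:
    def test_clear_true_direction_kept(self):
        # r2_exp ~ 0.01 >> r2_out ~ 1e-4
        hs = make_hset([math.sqrt(0.01 / 0.42)], [0.01],
                       [math.sqrt(1e-4 / 0.42)], [0.01],
                       eaf=[0.3], n_exp=50_000, n_out=50_000)
        assert len(steiger_filter(hs)) == 1

    def test_clear_false_direction_excluded(self):
        hs = make_hset([math.sqrt(1e-4 / 0.42)], [0.01],
                       [math.sqrt(0.01 / 0.42)], [0.01],
                       eaf=[0.3], n_exp=50_000, n_out=50_000)
        out = steiger_filter(hs)
        assert len(out) == 0
        assert out.exclusion_log[0].reason == "steiger_false"

    def test_equal_r2_not_significantly_true_excluded(self):
        """r2_exp == r2_out gives Fisher z = 0, one-sided p = 0.5: excluded."""
        b = math.sqrt(0.001 / 0.42)
        hs = make_hset([b], [0.01], [b], [0.01], eaf=[0.3],
                       n_exp=50_000, n_out=50_000)
        out = steiger_filter(hs)
        assert len(out) == 0

    def test_missing_eaf_passes_with_warning(self):
        hs = make_hset([0.1], [0.01], [0.01], [0.01], eaf=[None])
        with pytest.warns(UserWarning):
            assert len(steiger_filter(hs)) == 1

    def test_retains_strong_valid_instruments(self):
        """Instruments acting only through the exposure survive Steiger
        filtering >= 95% of the time (theta = 0.1, 200 simulated SNPs)."""
        from mrkit.simstudy import simulate_harmonized
        from mrkit.synthgwas import SimConfig
        hs, _ = simulate_harmonized(SimConfig(n_snp=200, theta=0.1, seed=123))
        kept = steiger_filter(hs)
        assert len(kept) / len(hs) >= 0.95
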