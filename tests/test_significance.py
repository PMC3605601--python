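"""Rational thresholds, integer-only decisions, overflow bounds, and the
oblivious Benjamini-Hochberg procedure vs independent oracles."""

import random
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from ppgwas.assoc import RationalStat
from ppgwas.errors import ConfigurationError
from ppgwas.mpc import Engine, RingConfig
from ppgwas.significance import (
    batcher_network,
    bh_ring_width_check,
    bonferroni,
    chi2_critical_rational,
    decide,
    decide_all,
    ring_width_check,
    secure_bh,
)


def _engine(seed=0, k=128):
    return Engine(RingConfig(k), seed=seed)


def _stat(eng, m, n, test_id="chi2"):
    return RationalStat(m=eng.share(m), n=eng.share(n), test_id=test_id)


class TestRationalThreshold:
    def test_alpha_005_q_1000(self):
        th = chi2_critical_rational(0.05, 1000)
        assert (th.p, th.q) == (3841, 1000)

    def test_alpha_05_q_1000(self):
        th = chi2_critical_rational(0.5, 1000)
        assert (th.p, th.q) == (454, 1000)

    def test_bracketing_invariant(self):
        for alpha in (0.5, 0.05, 0.01, 1e-5):
            for q in (10**3, 10**6):
                th = chi2_critical_rational(alpha, q)
                t = float(chi2_dist.isf(alpha, df=1))
                assert th.p / th.q <= t < (th.p + 1) / th.q

    def test_monotone_in_alpha(self):
        assert chi2_critical_rational(0.01, 1000).p > chi2_critical_rational(0.05, 1000).p

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            chi2_critical_rational(0.0)
        with pytest.raises(ConfigurationError):
            chi2_critical_rational(0.05, q_precision=10)


class TestBonferroni:
    def test_single_test_equals_uncorrected(self):
        assert bonferroni(0.05, 1, 1000).p == chi2_critical_rational(0.05, 1000).p

    def test_genome_wide_level(self):
        """alpha/262264 ~ 1.9065e-7 maps to the chi-square(1) critical value."""
        th = bonferroni(0.05, 262_264, 10**6)
        t = float(chi2_dist.isf(0.05 / 262_264, df=1))
        assert th.p == int(t * 10**6)
        assert abs(th.alpha - 1.9065e-7) / 1.9065e-7 < 1e-3

    def test_corrected_threshold_strictly_larger(self):
        assert bonferroni(0.05, 100, 1000).p > chi2_critical_rational(0.05, 1000).p


class TestRingWidthCheck:
    def test_paper_scale_cohort_fits_k128(self):
        ok, _ = ring_width_check(128, 1080, 10**6)
        assert ok

    def test_k32_violates(self):
        ok, min_k = ring_width_check(32, 1080, 10**6)
        assert not ok
        assert min_k > 32

    def test_min_k_is_minimal_and_monotone(self):
        prev = 0
        for n in (100, 500, 1080, 5000):
            ok_at_min, min_k = ring_width_check(64, n, 10**6)
            _, min_k2 = ring_width_check(min_k, n, 10**6)
            assert min_k2 == min_k
            assert ring_width_check(min_k, n, 10**6)[0]
            assert not ring_width_check(min_k - 1, n, 10**6)[0]
            assert min_k >= prev
            prev = min_k

    def test_bh_bound_is_stricter(self):
        assert bh_ring_width_check(128, 1080)[1] > ring_width_check(128, 1080)[1]
        assert bh_ring_width_check(128, 1080)[0]


class TestDecide:
    def test_clear_exceedance(self):
        eng = _engine()
        th = chi2_critical_rational(0.05, 1000)
        d, u = decide(eng, _stat(eng, 10, 1), th)
        assert (d, u) == (1, 0)

    def test_zero_statistic_never_significant(self):
        eng = _engine()
        th = chi2_critical_rational(0.05, 1000)
        assert decide(eng, _stat(eng, 0, 7), th) == (0, 0)

    def test_boundary_tie_counts_significant(self):
        eng = _engine()
        th = chi2_critical_rational(0.05, 1000)  # p/q = 3841/1000
        d, _ = decide(eng, _stat(eng, 3841, 1000), th)
        assert d == 1

    def test_undefined_statistic_flagged_not_significant(self):
        eng = _engine()
        th = chi2_critical_rational(0.05, 1000)
        d, u = decide(eng, _stat(eng, 0, 0), th)
        assert (d, u) == (0, 1)

    def test_matches_exact_rational_comparison_on_random_fractions(self):
        eng = _engine(1)
        rng = random.Random(1)
        th = chi2_critical_rational(0.05, 10**6)
        for _ in range(100):
            m = rng.randrange(0, 10**7)
            n = rng.randrange(1, 10**6)
            d, _ = decide(eng, _stat(eng, m, n), th)
            assert d == int(Fraction(m, n) >= Fraction(th.p, th.q))

    def test_decisions_are_audited(self):
        eng = _engine()
        th = chi2_critical_rational(0.05, 1000)
        decide(eng, _stat(eng, 5, 1), th, label="rs42")
        kinds = {(a.kind, a.label) for a in eng.audit}
        assert ("decision", "rs42") in kinds
        assert ("undefined_flag", "rs42") in kinds


class TestThresholdFidelity:
    """Integer decisions disagree with the floating-point rule only inside
    the rounding band [p/q, t(alpha)), whose width shrinks as 1/q."""

    def _disagreements(self, q, n_draws=4000, seed=0):
        rng = random.Random(seed)
        t_exact = float(chi2_dist.isf(0.05, df=1))
        th = chi2_critical_rational(0.05, q)
        band = 0
        disagree = 0
        for _ in range(n_draws):
            # fractions concentrated around the critical region
            n = rng.randrange(10**3, 10**4)
            m = int(n * rng.uniform(3.5, 4.2))
            rational = m * th.q >= th.p * n
            floating = (m / n) >= t_exact
            if rational != floating:
                disagree += 1
                assert Fraction(th.p, th.q) <= Fraction(m, n) < Fraction(t_exact)
        return disagree

    def test_band_membership_and_shrinkage(self):
        d_coarse = self._disagreements(q=10**3)
        d_fine = self._disagreements(q=10**6)
        assert d_coarse > 0  # coarse threshold visibly disagrees near t(alpha)
        assert d_fine <= d_coarse / 50  # ~1/q scaling leaves essentially none


class TestBatcherNetwork:
    @pytest.mark.parametrize("n", [2, 4, 8, 16, 64])
    def test_sorts_every_random_input(self, n):
        rng = random.Random(n)
        net = batcher_network(n)
        for _ in range(20):
            data = [rng.randrange(100) for _ in range(n)]
            for i, j in net:
                if data[i] < data[j]:  # descending compare-exchange
                    data[i], data[j] = data[j], data[i]
            assert data == sorted(data, reverse=True)

    def test_comparator_count_depends_only_on_length(self):
        assert len(batcher_network(16)) == len(batcher_network(16))
        with pytest.raises(ConfigurationError):
            batcher_network(12)


def _bh_oracle(values, alpha):
    """Independent oracle: statsmodels BH on the chi-square(1) p-values."""
    pvals = chi2_dist.sf(np.asarray(values, dtype=float), df=1)
    return multipletests(pvals, alpha=alpha, method="fdr_bh")[0].astype(int).tolist()


class TestSecureBH:
    def _run(self, eng, fractions, alpha=0.05, q=10**6):
        stats = [_stat(eng, m, n) for m, n in fractions]
        ids = [f"s{i}" for i in range(len(fractions))]
        return secure_bh(eng, stats, alpha, ids, q_precision=q)

    def test_all_zero_statistics_reject_nothing(self):
        eng = _engine(2)
        dv = self._run(eng, [(0, 1)] * 8)
        assert dv.decisions == [0] * 8
        assert dv.rejection_count == 0

    def test_one_huge_statistic_among_nulls(self):
        eng = _engine(3)
        rng = random.Random(3)
        fractions = [(rng.randrange(0, 200), 1000) for _ in range(31)]
        fractions.insert(17, (500_000, 1000))  # statistic 500
        dv = self._run(eng, fractions)
        assert dv.decisions[17] == 1
        vals = [m / n for m, n in fractions]
        assert dv.decisions == _bh_oracle(vals, 0.05)

    def test_random_instances_match_statsmodels_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(3):
            eng = _engine(40 + trial)
            values = rng.chisquare(1, size=45)
            values[rng.integers(0, 45, size=4)] += 20  # some real signal
            fractions = [(int(v * 10**6), 10**6) for v in values]
            dv = self._run(eng, fractions)
            oracle = _bh_oracle([m / n for m, n in fractions], 0.05)
            assert dv.decisions == oracle
            assert dv.rejection_count == sum(oracle)

    def test_undefined_statistics_sink_and_flag(self):
        eng = _engine(5)
        fractions = [(40_000, 1000), (0, 0), (90_000, 1000), (0, 0)]
        dv = self._run(eng, fractions)
        assert dv.undefined == [0, 1, 0, 1]
        assert dv.decisions[1] == 0 and dv.decisions[3] == 0
        assert dv.decisions[0] == 1 and dv.decisions[2] == 1

    def test_comparison_schedule_depends_only_on_length(self):
        counts = []
        for seed, scale in ((6, 1), (7, 37)):
            eng = _engine(seed)
            fractions = [((i * scale) % 97 * 1000, 1000) for i in range(20)]
            self._run(eng, fractions)
            counts.append(eng.bus.snapshot()["messages"])
        assert counts[0] == counts[1]

    def test_only_decision_kinds_opened(self):
        eng = _engine(8)
        self._run(eng, [(10_000, 1000)] * 5)
        kinds = {a.kind for a in eng.audit}
        assert kinds <= {"decision", "undefined_flag", "rejection_count"}


class TestDecideAll:
    def test_vector_decisions_and_metadata(self):
        eng = _engine(9)
        th = chi2_critical_rational(0.05, 10**6)
        stats = [_stat(eng, m, n) for m, n in ((10_000_000, 1000), (0, 1), (0, 0))]
        dv = decide_all(eng, stats, th, ["a", "b", "c"])
        assert dv.decisions == [1, 0, 0]
        assert dv.undefined == [0, 0, 1]
        assert dv.rejection_count == 1
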