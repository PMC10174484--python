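"""Unit and property tests for the per-replicate generative chain."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from metabarsim.core import (
    CommunityProfile,
    ProtocolParams,
    ReadDepthRule,
    amplify_first_pcr,
    amplify_index_pcr,
    compute_read_proportions,
    draw_reads,
    draw_template_counts,
    simulate_replicate,
    subsample_cleanup,
)
from metabarsim.errors import DegenerateReplicateError, InvalidParameterError

from chain_oracle import TINY, bin_outcomes, sample_oracle_chain


def _community(lam, eff):
    n = len(lam)
    return CommunityProfile([f"sp{i}" for i in range(n)],
                            np.asarray(lam, float), np.asarray(eff, float))


class TestTemplateSampling:
    def test_zero_concentration_is_degenerate_at_zero(self, rng):
        com = _community([0.0, 5.0], [0.7, 0.7])
        draws = np.array([draw_template_counts(com, 1.0, rng) for _ in range(200)])
        assert np.all(draws[:, 0] == 0)
        assert draws[:, 1].max() > 0

    def test_zero_mass_matches_poisson(self, rng):
        com = _community([1.0], [0.7])
        n = 10_000
        w = np.array([draw_template_counts(com, 1.0, rng)[0] for _ in range(n)])
        p = np.exp(-1.0)
        assert abs((w == 0).mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_mean_at_high_concentration(self, rng):
        com = _community([10_000.0], [0.7])
        w = np.array([draw_template_counts(com, 1.0, rng)[0] for _ in range(10_000)])
        se = np.sqrt(10_000 / 10_000)
        assert abs(w.mean() - 10_000) < 3 * se

    def test_invalid_volume_raises(self, rng):
        com = _community([1.0], [0.7])
        with pytest.raises(InvalidParameterError):
            draw_template_counts(com, -1.0, rng)
        with pytest.raises(InvalidParameterError):
            _community([-1.0], [0.7])


class TestFirstPcr:
    def test_zero_template_stays_zero(self, rng):
        x1 = amplify_first_pcr(np.zeros(3), np.array([0.5, 0.7, 1.0]), 35, rng)
        assert np.all(x1 == 0)

    def test_perfect_doubling_mean(self, rng):
        # a = 1 doubles each cycle: W=10, 3 cycles -> mean 80
        draws = np.array([
            amplify_first_pcr(np.array([10.0]), np.array([1.0]), 3, rng)[0]
            for _ in range(100_000)
        ])
        se = np.sqrt(80 / 100_000)
        assert abs(draws.mean() - 80) < 3 * se

    def test_growth_factor_matches_exact_arithmetic(self, rng):
        # oracle: (1 + 7/10)^35 evaluated in exact rational arithmetic
        exact = float(Fraction(17, 10) ** 35)
        draws = np.array([
            amplify_first_pcr(np.array([1.0]), np.array([0.7]), 35, rng)[0]
            for _ in range(10_000)
        ])
        se = np.sqrt(exact / 10_000)  # Gaussian regime: var == mean
        assert abs(draws.mean() - exact) < 4 * se
        assert exact == pytest.approx(1.16335e8, rel=1e-4)

    def test_out_of_range_efficiency_raises(self, rng):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(InvalidParameterError):
                amplify_first_pcr(np.array([1.0]), np.array([bad]), 35, rng)


class TestCleanupAndIndexing:
    def test_cleanup_trivia(self, rng):
        assert subsample_cleanup(np.zeros(2), 0.5, rng).tolist() == [0, 0]
        x1 = np.array([17.0, 3.0])
        assert np.array_equal(subsample_cleanup(x1, 1.0, rng), x1)
        with pytest.raises(InvalidParameterError):
            subsample_cleanup(x1, 0.0, rng)

    def test_cleanup_binomial_moments(self, rng):
        draws = np.array([
            subsample_cleanup(np.array([100.0]), 0.2, rng)[0]
            for _ in range(100_000)
        ])
        assert abs(draws.mean() - 20) < 3 * np.sqrt(16 / 100_000)
        assert draws.var() == pytest.approx(16, rel=0.05)
        assert np.all(draws <= 100)

    def test_indexing_growth_matches_exact_arithmetic(self, rng):
        exact = float(Fraction(19, 10) ** 10)  # 1.9^10
        assert exact == pytest.approx(613.1066, abs=1e-3)
        draws = np.array([
            amplify_index_pcr(np.array([1.0]), 10, 0.9, rng)[0]
            for _ in range(100_000)
        ])
        assert abs(draws.mean() - exact) < 3 * np.sqrt(exact / 100_000)

    def test_indexing_is_species_neutral(self, rng):
        x3 = np.array([
            amplify_index_pcr(np.array([50.0, 50.0]), 10, 0.9, rng)
            for _ in range(20_000)
        ])
        m = x3.mean(axis=0)
        se = np.sqrt(x3.var(axis=0).max() / 20_000)
        assert abs(m[0] - m[1]) < 4 * se


class TestProportionsAndReads:
    @pytest.mark.parametrize("x3, expected", [
        ([100, 300], [0.25, 0.75]),
        ([7], [1.0]),
        ([2e16, 6e16], [0.25, 0.75]),  # log-space path at extreme counts
    ])
    def test_proportions(self, x3, expected):
        p = compute_read_proportions(np.array(x3, dtype=float))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateReplicateError):
            compute_read_proportions(np.zeros(2))

    def test_reads_trivia(self, rng):
        assert draw_reads(np.array([0.5, 0.5]), 0, rng).sum() == 0
        y = draw_reads(np.array([1.0, 0.0]), 100, rng)
        assert y.tolist() == [100, 0]
        for _ in range(50):
            y = draw_reads(np.array([0.2, 0.3, 0.5]), 1_000, rng)
            assert y.sum() == 1_000
        with pytest.raises(InvalidParameterError):
            draw_reads(np.array([0.5, 0.4]), 10, rng)


class TestSimulateReplicate:
    protocol = ProtocolParams(depth_rule=ReadDepthRule(1_000, 2_000))

    def test_single_species_takes_all_reads(self):
        com = _community([10_000.0], [0.7])
        res = simulate_replicate(com, self.protocol, 7)
        assert res.W[0] > 0
        assert res.Y[0] == res.n_reads

    def test_zero_concentration_species_never_read(self):
        com = _community([0.0, 100.0], [0.7, 0.7])
        for seed in range(20):
            res = simulate_replicate(com, self.protocol, seed)
            assert res.Y[0] == 0

    def test_determinism_given_seed(self):
        com = _community([5.0, 50.0], [0.4, 0.9])
        a = simulate_replicate(com, self.protocol, 42)
        b = simulate_replicate(com, self.protocol, 42)
        for field in ("W", "X1", "X2", "X3", "p", "Y"):
            assert np.array_equal(getattr(a, field), getattr(b, field))
        assert a.n_reads == b.n_reads

    def test_zero_propagation_and_conservation(self):
        com = _community([0.8, 0.8, 50.0], [0.3, 0.9, 0.7])
        for seed in range(200):
            res = simulate_replicate(com, self.protocol, seed)
            zero = res.W == 0
            assert np.all(res.Y[zero] == 0)
            assert np.all(res.X1[zero] == 0)
            if not res.degenerate:
                assert res.Y.sum() == res.n_reads
                assert res.p.sum() == pytest.approx(1.0, abs=1e-9)
            else:
                assert res.Y.sum() == 0

    @pytest.mark.parametrize("lam_v", [0.5, 1.0, 5.0, 10.0])
    def test_template_zero_rate_is_analytic(self, lam_v, rng):
        com = _community([lam_v], [0.7])
        n = 20_000
        w0 = np.mean([
            draw_template_counts(com, 1.0, rng)[0] == 0 for _ in range(n)
        ])
        p = np.exp(-lam_v)
        assert abs(w0 - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-4

    def test_nondetection_monotone_in_lambda_and_efficiency(self):
        # p(Y=0) for the focal species should fall as lambda or a rises
        def p_y0(lam0, a0, seed, n=3_000):
            com = _community([lam0, 50.0], [a0, 0.7])
            prot = ProtocolParams(depth_rule=ReadDepthRule(500, 500))
            rng = np.random.default_rng(seed)
            return np.mean([
                simulate_replicate(com, prot, rng).Y[0] == 0 for _ in range(n)
            ])

        lo, hi = p_y0(1.0, 0.7, 1), p_y0(5.0, 0.7, 2)
        assert hi < lo - 0.05
        lo_a, hi_a = p_y0(5.0, 0.35, 3), p_y0(5.0, 0.7, 4)
        assert hi_a < lo_a - 0.05


class TestChainAgainstIndependentOracle:
    def test_tiny_instance_distribution_matches(self):
        """10^5 simulator draws vs a scipy-sampled re-implementation of the
        same chain; two-sample chi-square on binned (W, Y) outcomes."""
        n = 100_000
        cfg = TINY
        com = _community(cfg["lam"], cfg["a"])
        prot = ProtocolParams(
            volume_uL=cfg["volume"], n_pcr1=cfg["n_pcr1"], n_pcr2=cfg["n_pcr2"],
            cleanup_fraction=cfg["pi"], index_efficiency=cfg["index_eff"],
            depth_rule=ReadDepthRule(cfg["n_reads"], cfg["n_reads"]),
        )
        rng = np.random.default_rng(2024)
        W0 = np.empty(n, dtype=int)
        Y0 = np.empty(n, dtype=int)
        for k in range(n):
            res = simulate_replicate(com, prot, rng)
            W0[k], Y0[k] = res.W[0], res.Y[0]
        sim_counts = bin_outcomes(W0, Y0)

        ow, oy = sample_oracle_chain(n, seed=99)
        oracle_counts = bin_outcomes(ow, oy)

        table = np.vstack([sim_counts, oracle_counts])
        keep = table.sum(axis=0) >= 10  # merge-away near-empty cells
        table = np.hstack([table[:, keep],
                           table[:, ~keep].sum(axis=1, keepdims=True)])
        _, pvalue, _, _ = stats.chi2_contingency(table)
        assert pvalue > 0.01
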