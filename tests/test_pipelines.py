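"""Fisher combination, BH adjustment and the two gene-wise pipelines."""

import numpy as np
import pytest
from scipy import special

from wassdd import bh_adjust, fisher_combine, variant_a, variant_b
from wassdd.distance import default_grid


class TestFisherCombine:
    def test_two_null_pvalues_combine_to_one(self):
        assert fisher_combine(1.0, 1.0) == 1.0

    def test_closed_form_chi2_four_df(self):
        # chi2_4 survival at x is exp(-x/2) * (1 + x/2)
        x = -4.0 * np.log(0.05)
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine(0.05, 0.05) == pytest.approx(expected, abs=1e-12)
        assert fisher_combine(0.05, 0.05) == pytest.approx(0.01748, abs=1e-4)

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.01, 1.0, 25)
        for p2 in (0.03, 0.4, 1.0):
            vals = [fisher_combine(p1, p2) for p1 in grid]
            assert np.all(np.diff(vals) >= 0)

    def test_rejects_out_of_range(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                fisher_combine(bad, 0.5)


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_equal_and_singleton_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(bh_adjust([0.7]), [0.7])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_order_preserving(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _zero_inflated(rng, n, zero_frac, loc):
    """Nonnegative sample with an exact zero count (so tests that place the
    signal in one stage are not blurred by sampling noise in the other)."""
    vals = np.abs(rng.normal(loc, 1.0, n)) + 0.1
    vals[rng.permutation(n)[:round(n * zero_frac)]] = 0.0
    return vals


class TestVariantA:
    def test_no_signal_gene(self, rng):
        a = _zero_inflated(rng, 200, 0.3, 3.0)
        b = _zero_inflated(rng, 200, 0.3, 3.0)
        cdr = np.full(200, 0.5)
        res = variant_a(a, b, cdr, cdr, n_sub=200, seed=0)
        assert res.p_zero > 0.05
        assert res.p_nonzero > 0.05
        assert res.p_comb > 0.01

    def test_signal_isolated_in_zero_stage(self, rng):
        a = _zero_inflated(rng, 200, 0.5, 3.0)
        b = _zero_inflated(rng, 200, 0.1, 3.0)
        cdr = np.full(200, 0.5)
        res = variant_a(a, b, cdr, cdr, n_sub=500, seed=1)
        assert res.p_zero < 1e-4
        assert res.p_nonzero > 0.05

    def test_signal_isolated_in_nonzero_stage(self, rng):
        a = _zero_inflated(rng, 200, 0.3, 2.0)
        b = _zero_inflated(rng, 200, 0.3, 5.0)
        cdr = np.full(200, 0.5)
        res = variant_a(a, b, cdr, cdr, n_sub=500, seed=2)
        assert res.p_nonzero < 1 / 501
        assert res.p_zero > 0.05
        assert res.p_comb < 1e-3

    def test_too_few_nonzero_falls_back_to_zero_stage(self):
        a = np.array([0.0] * 50 + [1.0])
        b = np.array([0.0] * 30 + [2.0, 3.0, 1.0] * 7)
        cdr = lambda n: np.full(n, 0.5)
        res = variant_a(a, b, cdr(a.size), cdr(b.size), n_sub=100, seed=0)
        assert "too_few_nonzero" in res.flags
        assert res.p_nonzero is None
        assert res.decomposition is None
        assert res.p_comb == res.p_zero

    def test_deterministic_given_seed(self, rng):
        a = _zero_inflated(rng, 80, 0.4, 2.0)
        b = _zero_inflated(rng, 90, 0.2, 2.5)
        cdr_a, cdr_b = rng.random(80), rng.random(90)
        r1 = variant_a(a, b, cdr_a, cdr_b, n_sub=150, seed=5)
        r2 = variant_a(a, b, cdr_a, cdr_b, n_sub=150, seed=5)
        assert (r1.p_zero, r1.p_nonzero, r1.p_comb) == \
               (r2.p_zero, r2.p_nonzero, r2.p_comb)


class TestVariantB:
    def test_distance_set_combinatorics(self, rng):
        sa = [rng.gamma(3, 1, 40) + 0.1 for _ in range(4)]
        sb = [rng.gamma(3, 1, 40) + 0.1 for _ in range(4)]
        res = variant_b(sa, sb, paired=True, grid=default_grid(200))
        assert res.d_bc.size == 16  # 4 * 4 cross pairs
        assert res.d_wc.size == 12  # 2 * C(4, 2) within pairs

    def test_requires_replicates(self, rng):
        with pytest.raises(ValueError, match="replicates"):
            variant_b([rng.random(10)], [rng.random(10), rng.random(10)])

    def test_complete_separation_hits_exact_wilcoxon_minimum(self, rng):
        sa = [rng.gamma(3, 1, 50) + 0.1 for _ in range(4)]
        sb = [rng.gamma(3, 1, 50) + 100.0 for _ in range(4)]
        res = variant_b(sa, sb, paired=True)
        # all 16 between-condition distances exceed all 12 within-condition
        # ones: one-sided exact rank-sum minimum 1 / C(28, 16)
        assert res.p_nonzero == pytest.approx(1 / special.comb(28, 16), rel=1e-9)
        assert res.mean_frac_location > 0.9
        assert res.mean_frac_location + res.mean_frac_size + \
            res.mean_frac_shape == pytest.approx(1.0)

    def test_zero_stage_uses_cmh_on_replicate_strata(self, rng):
        sa = [_zero_inflated(rng, 100, 0.5, 3.0) for _ in range(3)]
        sb = [_zero_inflated(rng, 100, 0.1, 3.0) for _ in range(3)]
        res = variant_b(sa, sb, paired=True)
        assert res.p_zero < 1e-6

    def test_unequal_replicate_counts_skip_zero_stage(self, rng):
        sa = [rng.gamma(2, 1, 30) + 0.1 for _ in range(3)]
        sb = [rng.gamma(2, 1, 30) + 0.1 for _ in range(2)]
        res = variant_b(sa, sb, paired=False)
        assert res.p_zero is None
        assert "zero_test_skipped" in res.flags
        assert res.p_comb == res.p_nonzero
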