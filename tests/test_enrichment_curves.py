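"""Q-Q points, fold-enrichment curves, rank tests and Storey π1."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stratenrich import enrichment_curves as ec
from stratenrich.synthetic_data import simulate_pvalue_mixture


class TestQqPoints:
    def test_single_point_midpoint_rank(self):
        exp, obs = ec.qq_points([0.5])
        assert exp[0] == pytest.approx(-np.log10(0.5))
        assert obs[0] == pytest.approx(-np.log10(0.5))

    def test_uniform_sample_hugs_diagonal(self):
        rng = np.random.default_rng(21)
        exp, obs = ec.qq_points(rng.uniform(size=10_000))
        assert np.median(np.abs(obs - exp)) < 0.01
        assert np.max(np.abs(obs - exp)[100:]) < 0.15  # away from the extreme tail

    def test_constant_small_p_deflects_left(self):
        exp, obs = ec.qq_points(np.full(1000, 1e-8))
        assert np.allclose(obs, 8.0)
        assert exp.max() < 4.4 and np.all(obs >= exp)

    def test_expected_depends_only_on_n(self):
        rng = np.random.default_rng(0)
        e1, _ = ec.qq_points(rng.uniform(size=500))
        e2, _ = ec.qq_points(rng.beta(0.3, 1.0, size=500))
        np.testing.assert_allclose(e1, e2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ec.qq_points([])


class TestFoldEnrichment:
    def test_self_comparison_is_unity(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=2000)
        curve = ec.fold_enrichment(p, p, min_denominator=10)
        np.testing.assert_allclose(curve.ratio, 1.0)
        assert curve.ratio[0] == 1.0  # threshold 0 with complete sets

    def test_hand_counted_truncation(self):
        s = [0.001, 0.5, 0.5, 0.5]
        base = [0.01, 0.5, 0.5, 0.5]
        curve = ec.fold_enrichment(s, base, bin_width=0.1, min_denominator=1)
        # baseline runs out beyond -log10(0.01) = 2, so t = 2.5 is truncated away
        assert curve.thresholds.max() <= 2.0 + 1e-9
        i = int(np.argmin(np.abs(curve.thresholds - 1.0)))
        assert curve.ratio[i] == pytest.approx(1.0)  # (1/4) / (1/4)
        assert curve.n_denominator[-1] >= 1

    def test_enriched_set_monotone_rising(self):
        rng = np.random.default_rng(31)
        base = rng.uniform(size=20_000)
        s = simulate_pvalue_mixture(5_000, pi1=0.10, seed=31)
        curve = ec.fold_enrichment(s, base, min_denominator=50)
        assert curve.ratio[-1] > curve.ratio[0]
        assert np.all(np.diff(curve.ratio) >= -1e-9)

    def test_empty_baseline_errors(self):
        with pytest.raises(ValueError):
            ec.fold_enrichment([0.5], [])


def _mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    combined = np.concatenate([a, b])
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in itertools.combinations(range(len(combined)), na):
        ga = combined[list(idx)]
        gb = np.delete(combined, list(idx))
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestMannWhitney:
    def test_disjoint_triples(self):
        u, p = ec.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.10, abs=1e-9)  # 2/20 assignments

    def test_identical_samples_symmetric(self):
        a = np.arange(1.0, 30.0)
        _, p = ec.mann_whitney(a, a, method="asymptotic")
        assert p >= 0.99

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 60), min_size=2, max_size=5),
        st.lists(st.integers(61, 120), min_size=2, max_size=5),
    )
    def test_exact_branch_matches_enumeration(self, a, b):
        # shift to break ties between groups while keeping arbitrary patterns
        a = np.array(sorted(set(a)), dtype=float)
        b = np.array(sorted(set(b)), dtype=float) + 0.5
        if len(a) != len(b):
            n = min(len(a), len(b))
            a, b = a[:n], b[:n]
        u, p = ec.mann_whitney(a, b)
        assert p == pytest.approx(_mw_exact_oracle(a, b), abs=1e-9)

    def test_type_one_error_calibration(self):
        """Independent null chi-squared samples reject at about the nominal rate."""
        rng = np.random.default_rng(77)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.chisquare(1, size=1000)
            b = rng.chisquare(1, size=1000)
            _, p = ec.mann_whitney(a, b)
            rej += p < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ec.mann_whitney([], [1.0])


class TestPi1:
    def test_all_tiny_p_gives_one(self):
        est = ec.estimate_pi1(np.full(1000, 1e-8))
        assert est.pi1 == pytest.approx(1.0)
        np.testing.assert_allclose(est.pi0_grid, 0.0)

    def test_uniform_near_zero(self):
        p = np.random.default_rng(5).uniform(size=100_000)
        p[p == 0] = 1e-300
        assert ec.estimate_pi1(p).pi1 <= 0.02

    def test_mixture_recovery_at_paper_scale(self):
        est = ec.estimate_pi1(simulate_pvalue_mixture(50_000, pi1=0.21, seed=8))
        assert 0.16 <= est.pi1 <= 0.26

    def test_monotone_under_injection(self):
        """Adding more small p-values never decreases π1 on the same seed."""
        rng = np.random.default_rng(9)
        base = rng.uniform(size=20_000)
        base[base == 0] = 1e-300
        last = -1.0
        for n_inject in (0, 500, 2000, 5000):
            p = base.copy()
            p[:n_inject] = 1e-8
            est = ec.estimate_pi1(p)
            assert est.pi1 >= last - 1e-9
            last = est.pi1

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            ec.estimate_pi1(np.full(50, 0.5))

    def test_fixed_lambda_method(self):
        p = np.random.default_rng(1).uniform(size=50_000)
        p[p == 0] = 1e-300
        est = ec.estimate_pi1(p, method="fixed", fixed_lambda=0.5)
        assert est.pi1 == pytest.approx(0.0, abs=0.03)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ec.estimate_pi1([])
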