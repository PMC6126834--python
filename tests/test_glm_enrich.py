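"""Chi-squared linear models, design construction and meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from stratenrich import glm_enrich as gl
from stratenrich.assoc_stats import p_from_chisq
from stratenrich.io_formats import AnnotationSet


def _variants(n, total_ld=None):
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "maf": 0.2,
            "is_genic": True,
            "tss_distance": 100.0,
            "total_ld": np.ones(n) if total_ld is None else total_ld,
        }
    )


def _stats(ids, z2):
    z2 = np.asarray(z2, dtype=float)
    return pd.DataFrame({"variant_id": ids, "trait": "t", "p": p_from_chisq(z2), "z2": z2})


def _aset(label, ids):
    return AnnotationSet(label, frozenset(ids), "test")


class TestDesignSpec:
    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gl.DesignSpec(terms=("a", "a"))

    def test_interaction_must_reference_main_terms(self):
        with pytest.raises(ValueError, match="undeclared"):
            gl.DesignSpec(terms=("a",), interactions=(("a", "b"),))

    def test_unknown_scope(self):
        with pytest.raises(ValueError, match="scope"):
            gl.DesignSpec(terms=("a",), scope="everything")


class TestBuildDesign:
    def test_indicator_column_sums(self):
        v = _variants(4)
        stats = _stats(v["variant_id"], [1, 2, 3, 4])
        sets = {"eqtl:a": _aset("eqtl:a", {"v0", "v2"}), "control:a": _aset("control:a", {"v1"})}
        spec = gl.DesignSpec(terms=("eqtl:a", "control:a"))
        X, y = gl.build_design(v, stats, set(v["variant_id"]), spec, sets)
        assert X["eqtl:a"].sum() == 2
        assert len(y) == 4

    def test_scope_restriction_row_count(self):
        v = _variants(1000)
        stats = _stats(v["variant_id"], np.ones(1000))
        eqtl = {f"v{i}" for i in range(100)}
        ctrl = {f"v{i}" for i in range(100, 200)}
        sets = {"eqtl:a": _aset("eqtl:a", eqtl), "control:a": _aset("control:a", ctrl)}
        spec = gl.DesignSpec(terms=("eqtl:a",), scope="eqtl_controls")
        X, y = gl.build_design(v, stats, set(v["variant_id"]), spec, sets)
        assert X.shape[0] == 200

    def test_interaction_is_elementwise_product(self):
        v = _variants(50, total_ld=np.linspace(1, 5, 50))
        stats = _stats(v["variant_id"], np.ones(50))
        sets = {"eqtl:a": _aset("eqtl:a", {f"v{i}" for i in range(0, 50, 3)})}
        spec = gl.DesignSpec(
            terms=("eqtl:a", "total_ld"), interactions=(("eqtl:a", "total_ld"),)
        )
        X, _ = gl.build_design(v, stats, set(v["variant_id"]), spec, sets)
        np.testing.assert_allclose(
            X["eqtl:a:total_ld"], X["eqtl:a"].to_numpy() * X["total_ld"].to_numpy()
        )

    def test_constant_column_names_term(self):
        v = _variants(10)
        stats = _stats(v["variant_id"], np.ones(10))
        sets = {"eqtl:a": _aset("eqtl:a", set())}
        spec = gl.DesignSpec(terms=("eqtl:a",))
        with pytest.raises(ValueError, match="eqtl:a"):
            gl.build_design(v, stats, set(v["variant_id"]), spec, sets)


class TestFitChisqGlm:
    def test_constant_response(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.integers(0, 2, size=50).astype(float)})
        fit = gl.fit_chisq_glm(X, np.full(50, 3.3))
        assert fit.loc[fit.term == "const", "beta"].iloc[0] == pytest.approx(3.3)
        assert fit.loc[fit.term == "x", "beta"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_single_indicator_equals_group_mean_difference(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=500).astype(float)
        y = rng.chisquare(1, size=500) + 0.4 * x
        fit = gl.fit_chisq_glm(pd.DataFrame({"g": x}), y)
        closed_form = y[x == 1].mean() - y[x == 0].mean()
        assert fit.loc[fit.term == "g", "beta"].iloc[0] == pytest.approx(closed_form, rel=1e-10)

    def test_matches_closed_form_ols_oracle(self):
        """β and SE agree with the normal-equation solution computed by hand."""
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"a": rng.integers(0, 2, 300).astype(float), "ld": rng.uniform(1, 6, 300)}
        )
        y = 1.0 + 0.3 * X["a"].to_numpy() + 0.1 * X["ld"].to_numpy() + rng.normal(0, 1.4, 300)
        fit = gl.fit_chisq_glm(X, y)
        M = np.column_stack([np.ones(300), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        resid = y - M @ beta
        sigma2 = resid @ resid / (300 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(M.T @ M)))
        np.testing.assert_allclose(fit["beta"], beta, rtol=1e-9)
        np.testing.assert_allclose(fit["se"], se, rtol=1e-9)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.integers(0, 2, 200).astype(float), "b": rng.uniform(size=200)})
        y = rng.chisquare(1, size=200)
        fit = gl.fit_chisq_glm(X, y)
        M = np.column_stack([np.ones(200), X.to_numpy()])
        resid = y - M @ fit["beta"].to_numpy()
        np.testing.assert_allclose(M.T @ resid, 0.0, atol=1e-8)

    def test_parameter_recovery_simulation(self):
        """E[χ²] = 1 + 0.2·x_eqtl + 0.05·(totLD − 1) recovered within 3 SE."""
        rng = np.random.default_rng(4)
        n = 100_000
        x = (rng.random(n) < 0.05).astype(float)
        tld = 1.0 + rng.exponential(2.0, size=n)
        sigma2 = 1.0 + 0.2 * x + 0.05 * (tld - 1.0)
        y = sigma2 * rng.chisquare(1, size=n)
        fit = gl.fit_chisq_glm(pd.DataFrame({"eqtl": x, "ld": tld - 1.0}), y)
        for term, truth in [("eqtl", 0.2), ("ld", 0.05), ("const", 1.0)]:
            row = fit.loc[fit.term == term].iloc[0]
            assert abs(row["beta"] - truth) <= 3 * row["se"], (term, row["beta"], row["se"])

    def test_rank_deficiency_errors(self):
        X = pd.DataFrame({"a": [1.0, 0, 1, 0, 1, 0], "b": [1.0, 0, 1, 0, 1, 0], "c": [0.1, 0.4, 0.5, 0.2, 0.9, 0.3]})
        with pytest.raises(ValueError, match="collinear"):
            gl.fit_chisq_glm(X, np.arange(6.0))


class TestMetaAnalyze:
    def _fit(self, beta, se, term="eqtl"):
        return pd.DataFrame({"term": [term], "beta": [beta], "se": [se], "p": [0.5], "n": [100]})

    def test_identical_replicates(self):
        meta = gl.meta_analyze([self._fit(0.18, 0.04)] * 10)
        row = meta.term("eqtl")
        assert row["beta_bar"] == pytest.approx(0.18)
        assert row["beta_iv"] == pytest.approx(0.18)
        assert row["ci_low"] <= row["beta_bar"] <= row["ci_high"]

    def test_mean_of_two(self):
        meta = gl.meta_analyze([self._fit(0.1, 0.05), self._fit(0.2, 0.05)])
        assert meta.term("eqtl")["beta_bar"] == pytest.approx(0.15)

    def test_inverse_variance_weighting(self):
        meta = gl.meta_analyze([self._fit(0.0, 0.01), self._fit(1.0, 1.0)])
        row = meta.term("eqtl")
        assert row["beta_bar"] == pytest.approx(0.5)
        # the precise estimate (beta 0, SE 0.01) dominates the pooled value
        assert row["beta_iv"] == pytest.approx(1.0 / (1e4 + 1), rel=1e-6)

    def test_missing_term_errors(self):
        with pytest.raises(ValueError, match="term mismatch"):
            gl.meta_analyze([self._fit(0.1, 0.05, term="a"), self._fit(0.1, 0.05, term="b")])


class TestInteractionScan:
    def test_empty_partner_list_reduces_to_base_fit(self, tiny_world, tiny_stats):
        variants, ld_pairs, sets = tiny_world
        from stratenrich.ld_ops import random_prune

        reps = random_prune(variants, ld_pairs, n_sets=3, seed=1)
        sets = dict(sets)
        base = gl.DesignSpec(terms=("eqtl:adipose", "total_ld"))
        plain = gl.fit_on_replicates(variants, tiny_stats, reps, base, sets)
        scanned = gl.interaction_scan(
            variants, tiny_stats, reps, base, sets, eqtl_term="eqtl:adipose", partner_terms=()
        )
        pd.testing.assert_frame_equal(plain.table, scanned.table)
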