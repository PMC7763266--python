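"""MML87 message-length criterion: structure code, decomposition, lambda search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmlgranger import (CandidateSet, LambdaSearch, MMLScore, fit_mle,
                        get_family, hmml, mml_code, structure_code)
from mmlgranger.mml import _lambda_profile
from mmlgranger.panel import DesignMatrix, subset_design


def make_design(X, y, d=1):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1] // d
    cmap = [(j, l) for j in range(p) for l in range(1, d + 1)]
    return DesignMatrix(X, cmap, np.asarray(y, dtype=float), d, p, 0)


class TestStructureCode:
    def test_known_value(self):
        # log C(5, 2) + log 6 = log 10 + log 6
        assert structure_code(5, 2) == pytest.approx(np.log(10) + np.log(6),
                                                     abs=1e-12)

    def test_empty_set(self):
        assert structure_code(7, 0) == pytest.approx(np.log(8.0), abs=1e-12)

    def test_full_set(self):
        assert structure_code(4, 4) == pytest.approx(np.log(5.0), abs=1e-12)

    def test_product_form(self):
        assert structure_code(5, 2, product_form=True) == pytest.approx(
            np.log(10) + np.log(6), abs=1e-12)  # 5*2 = C(5,2) = 10 here
        assert structure_code(3, 2, product_form=True) == pytest.approx(
            np.log(6) + np.log(4), abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            structure_code(3, 4)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(p=st.integers(1, 12), k=st.integers(0, 12))
    def test_binomial_symmetry(self, p, k):
        if k > p:
            return
        # log C(p,k) part is symmetric under k -> p-k
        a = structure_code(p, k) - np.log(p + 1.0)
        b = structure_code(p, p - k) - np.log(p + 1.0)
        assert a == pytest.approx(b, abs=1e-10)


class TestDecomposition:
    def hand_total(self, X, y, beta, phi, lam, p, k, m):
        """Independently coded gaussian message length (identity W)."""
        resid = y - X @ beta
        L = -0.5 * m * np.log(2 * np.pi * phi) - float(resid @ resid) / (2 * phi)
        sign, logdet = np.linalg.slogdet(X.T @ X + lam * np.eye(X.shape[1]))
        fisher = 0.5 * logdet
        prior = (k / 2) * np.log(2 * np.pi * lam) + lam / (2 * phi) * float(beta @ beta)
        const = (0.5 * np.log(m) - (k + 1) / 2 * np.log(2 * np.pi)
                 + 0.5 * np.log((k + 1) * np.pi))
        struct = (np.log(math.factorial(p)
                         // (math.factorial(k) * math.factorial(p - k)))
                  + np.log(p + 1.0))
        return L, fisher, prior, const, struct

    def test_three_point_toy_ten_digits(self):
        # 3 observations, 2 series, d = 1, both series selected (k = 2)
        X = np.array([[1.0, 0.5], [2.0, -1.0], [0.5, 1.5]])
        y = np.array([1.2, 1.8, -0.4])
        dm = make_design(X, y, d=1)
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        lam = 1.0
        score = mml_code(dm, fit, fam, lam)
        L, fisher, prior, const, struct = self.hand_total(
            X, y, fit.beta, fit.dispersion, lam, p=2, k=2, m=3)
        assert score.neg_log_lik == pytest.approx(-L, rel=1e-10)
        assert score.fisher_logdet == pytest.approx(fisher, rel=1e-10)
        assert score.prior_terms == pytest.approx(prior, rel=1e-10)
        assert score.constant_terms == pytest.approx(const, rel=1e-10)
        assert score.structure_code == pytest.approx(struct, rel=1e-10)
        assert score.total == pytest.approx(
            -L + fisher + prior + const + struct, rel=1e-10)

    def test_spectral_identity(self, rng):
        # gaussian W = I: 0.5 logdet(X'X + lam I) = 0.5 sum log(s_j^2 + lam)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        dm = make_design(X, y, d=2)
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        s = np.linalg.svd(X, compute_uv=False)
        for lam in (0.1, 1.0, 31.6, 1000.0):
            score = mml_code(dm, fit, fam, lam)
            expect = 0.5 * float(np.sum(np.log(s ** 2 + lam)))
            assert score.fisher_logdet == pytest.approx(expect, abs=1e-10)

    def test_empty_model_formula(self, rng):
        y = rng.normal(size=30)
        dm = DesignMatrix(np.empty((30, 0)), [], y, 1, 3, 0)
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        score = mml_code(dm, fit, fam, 0.1, k=0)
        assert score.fisher_logdet == 0.0 and score.prior_terms == 0.0
        expect_const = 0.5 * np.log(30) - 0.5 * np.log(2 * np.pi) + 0.5 * np.log(np.pi)
        assert score.constant_terms == pytest.approx(expect_const, abs=1e-12)
        assert score.structure_code == pytest.approx(np.log(4.0), abs=1e-12)

    def test_total_is_sum_of_parts(self):
        s = MMLScore(1.0, 2.0, 3.0, 4.0, 5.0, 0.1)
        assert s.total == 15.0

    def test_invalid_lambda(self, rng):
        dm = make_design(rng.normal(size=(10, 2)), rng.normal(size=10))
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        with pytest.raises(ValueError):
            mml_code(dm, fit, fam, 0.0)

    def test_count_coefficients_switch(self, rng):
        X = rng.normal(size=(30, 4))
        dm = make_design(X, rng.normal(size=30), d=2)  # p=2, k=2, dk=4
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        lam = 1.0
        a = mml_code(dm, fit, fam, lam)
        b = mml_code(dm, fit, fam, lam, count_coefficients=True)
        # prior term grows by (dk - k)/2 * log(2 pi lam)
        diff = b.prior_terms - a.prior_terms
        assert diff == pytest.approx((4 - 2) / 2 * np.log(2 * np.pi * lam),
                                     abs=1e-10)


class TestLambdaSearch:
    def test_box_validation(self):
        with pytest.raises(ValueError):
            LambdaSearch(10.0, 1.0)
        with pytest.raises(ValueError):
            LambdaSearch(-1.0, 10.0)

    def test_profile_matches_mml_code(self, rng):
        """Eigenvalue-based profile equals the direct slogdet assembly."""
        X = rng.normal(size=(40, 4))
        dm = make_design(X, rng.normal(size=40), d=2)
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        total = _lambda_profile(dm, fit, fam, robust=False,
                                count_coefficients=False)
        for lam in (0.1, 3.0, 700.0):
            assert total(lam) == pytest.approx(
                mml_code(dm, fit, fam, lam).total, abs=1e-8)

    def test_minimum_not_above_endpoints(self, planted_panel):
        from mmlgranger import LagConfig, build_full_design
        full = build_full_design(planted_panel, LagConfig(2), target=2)
        fam = get_family("gaussian")
        cand = CandidateSet((1, 0, 0), 2)
        search = LambdaSearch()
        best = hmml(full, cand, fam, search)
        dm = subset_design(full, cand)
        fit = fit_mle(dm, fam)
        total = _lambda_profile(dm, fit, fam, False, False)
        assert best <= total(search.lo) + 1e-9
        assert best <= total(search.hi) + 1e-9

    def test_fisher_monotone_and_prior_linear_in_lambda(self, rng):
        X = rng.normal(size=(50, 4))
        dm = make_design(X, rng.normal(size=50), d=2)
        fam = get_family("gaussian")
        fit = fit_mle(dm, fam)
        lams = np.geomspace(0.1, 1000, 9)
        fisher = [mml_code(dm, fit, fam, l).fisher_logdet for l in lams]
        assert np.all(np.diff(fisher) >= 0)
        # beta-penalty part of the prior term is linear in lambda
        bb = float(fit.beta @ fit.beta) / (2 * fit.dispersion)
        np.testing.assert_allclose(
            [mml_code(dm, fit, fam, l).prior_terms
             - (2 / 2.0) * np.log(2 * np.pi * l) for l in lams],
            [bb * l for l in lams], rtol=1e-10)

    def test_infeasible_candidate_scores_inf(self, rng):
        # gamma target with a regressor sign that forces eta <= 0 somewhere
        from mmlgranger import LagConfig, TimeSeriesPanel, build_full_design
        x1 = rng.normal(size=60)                     # signed regressor
        x2 = rng.gamma(2.0, 1.0, size=60)
        panel = TimeSeriesPanel(np.vstack([x1, x2]), ["gaussian", "gamma"])
        full = build_full_design(panel, LagConfig(1), target=1)
        fam = get_family("gamma")
        score = hmml(full, CandidateSet((1, 0), 1), fam, LambdaSearch(),
                     dispersion=0.5)
        # either rejected as infeasible or fit with positive predictor; in
        # both cases the score is well-defined and the empty set is finite
        empty = hmml(full, CandidateSet((0, 0), 1), fam, LambdaSearch(),
                     dispersion=0.5)
        assert np.isfinite(empty)
        assert score >= empty or np.isfinite(score)

    def test_return_detail(self, planted_panel):
        from mmlgranger import LagConfig, build_full_design
        full = build_full_design(planted_panel, LagConfig(2), target=2)
        fam = get_family("gaussian")
        total, detail, fit = hmml(full, CandidateSet((1, 0, 0), 2), fam,
                                  LambdaSearch(), return_detail=True)
        assert detail.total == pytest.approx(total, abs=1e-6)
        assert LambdaSearch().lo <= detail.lam <= LambdaSearch().hi
        rec = detail.to_record()
        assert set(rec) == {"neg_log_lik", "fisher_logdet", "prior_terms",
                            "constant_terms", "structure_code", "lambda",
                            "total"}
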