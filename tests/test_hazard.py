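"""Unit tests for the Cox stage: partial likelihoods, metrics, fitting."""

import numpy as np
import pytest
from autograd import grad
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as lifelines_cindex
from scipy.optimize import minimize_scalar

import pandas as pd
from cellhazard.data import SurvivalTable
from cellhazard.hazard import (
    CellHazardCox,
    _partial_loglik_core,
    _tie_structure,
    breslow_baseline,
    breslow_loglik,
    brier_scores,
    concordance_index,
    efron_loglik,
    integrated_brier_score,
    partial_loglik,
    predict_survival,
    resample_cindex_ci,
)


def random_survival(rng, n=30, tie_prob=0.5):
    if rng.random() < tie_prob:
        t = rng.integers(1, 10, n).astype(float)
    else:
        t = rng.exponential(1.0, n) + 1e-3
    e = (rng.random(n) < 0.7).astype(int)
    if e.sum() == 0:
        e[rng.integers(n)] = 1
    return SurvivalTable(t, e)


class TestPartialLikelihoods:
    def test_two_sample_hand_value(self):
        surv = SurvivalTable([1.0, 2.0], [1, 1])
        eta = np.array([np.log(2.0), 0.0])
        expected = (np.log(2) - np.log(3)) + 0.0
        assert breslow_loglik(eta, surv) == pytest.approx(expected, abs=1e-12)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            surv = random_survival(rng, tie_prob=0.0)
            eta = rng.normal(0, 1, len(surv))
            assert efron_loglik(eta, surv) == pytest.approx(
                breslow_loglik(eta, surv), abs=1e-12
            )

    def test_no_events_is_an_error(self):
        surv = SurvivalTable([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            breslow_loglik(np.zeros(2), surv)
        with pytest.raises(ValueError):
            breslow_loglik(np.array([np.inf, 0.0]), SurvivalTable([1, 2], [1, 1]))

    def test_auto_tie_dispatch(self):
        tied = SurvivalTable([1.0, 1.0, 2.0], [1, 1, 1])
        eta = np.array([0.3, -0.2, 0.1])
        assert partial_loglik(eta, tied) == pytest.approx(efron_loglik(eta, tied))
        untied = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        assert partial_loglik(eta, untied) == pytest.approx(
            breslow_loglik(eta, untied)
        )

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        surv = random_survival(rng, n=40)
        eta = rng.normal(0, 1, 40)
        perm = rng.permutation(40)
        surv_p = SurvivalTable(surv.time[perm], surv.event[perm])
        for fn in (breslow_loglik, efron_loglik):
            assert fn(eta, surv) == pytest.approx(fn(eta[perm], surv_p), abs=1e-10)

    def test_autodiff_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        surv = random_survival(rng, n=25)
        eta = rng.normal(0, 1, 25)
        ev, R, Q, frac = _tie_structure(surv)
        for args in [(None, None), (Q, frac)]:
            g = grad(lambda e: _partial_loglik_core(e, ev, R, *args))(eta)
            h = 1e-5
            for i in range(0, 25, 5):
                d = np.zeros(25)
                d[i] = h
                fd = (
                    _partial_loglik_core(eta + d, ev, R, *args)
                    - _partial_loglik_core(eta - d, ev, R, *args)
                ) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_single_covariate_recovers_oracle_cox_coefficient(self):
        """Maximising our partial likelihood over one scalar coefficient
        reproduces a lifelines Cox fit on n=300."""
        rng = np.random.default_rng(7)
        n = 300
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(n, dtype=int)
        surv = SurvivalTable(t, e)
        res = minimize_scalar(
            lambda b: -breslow_loglik(b * x, surv), bounds=(-5, 5), method="bounded"
        )
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": t, "e": e}), "t", "e"
        )
        assert res.x == pytest.approx(cph.params_["x"], abs=0.05)


class TestConcordance:
    def test_perfect_and_null(self):
        surv = SurvivalTable([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.array([3.0, 2.0, 1.0]), surv) == 1.0
        assert concordance_index(np.zeros(3), surv) == 0.5

    def test_null_distribution_centered_at_half(self):
        """Random risk scores against random times: mean c over 1000 reps
        within 0.5 +/- 0.02."""
        rng = np.random.default_rng(0)
        surv = random_survival(rng, n=200, tie_prob=0.0)
        cs = [
            concordance_index(rng.normal(size=200), surv) for _ in range(1000)
        ]
        assert abs(np.mean(cs) - 0.5) < 0.02

    def test_matches_lifelines(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            surv = random_survival(rng, n=50)
            eta = rng.normal(0, 1, 50)
            assert concordance_index(eta, surv) == pytest.approx(
                lifelines_cindex(surv.time, -eta, surv.event), abs=1e-12
            )

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, a, b):
        rng = np.random.default_rng(11)
        surv = random_survival(rng, n=40)
        eta = rng.normal(0, 1, 40)
        c0 = concordance_index(eta, surv)
        assert concordance_index(a * eta + b, surv) == pytest.approx(c0)
        assert concordance_index(np.exp(eta), surv) == pytest.approx(c0)

    def test_no_comparable_pairs_error(self):
        surv = SurvivalTable([1.0, 1.0], [1, 1])  # tied event pair excluded
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), surv)


class TestBrier:
    def test_constant_half_prediction_no_censoring(self):
        """S = 0.5 everywhere, no censoring: Brier(t) = 0.25, IBS = 0.25."""
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, 200) + 1e-3
        surv = SurvivalTable(t, np.ones(200, dtype=int))
        grid = np.linspace(t.min(), np.quantile(t, 0.8), 50)
        # eta = 0 and a baseline whose survival is exactly 0.5 on the grid
        baseline = (np.array([0.0]), np.array([np.log(2.0)]))
        bs = brier_scores(np.zeros(200), surv, baseline, grid)
        np.testing.assert_allclose(bs, 0.25, atol=1e-12)
        assert integrated_brier_score(
            np.zeros(200), surv, baseline, grid
        ) == pytest.approx(0.25, abs=1e-12)

    def test_sharp_oracle_predictions_drive_ibs_to_zero(self):
        """Predictions matching outcomes ever more sharply push IBS toward 0."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        surv = SurvivalTable(t, np.ones(5, dtype=int))
        grid = np.linspace(1.0, 4.5, 40)
        prev = np.inf
        for scale in (0.0, 1.0, 4.0):
            # eta spreads out: each sample's hazard concentrates near its time
            eta = scale * (np.mean(t) - t)
            ibs = integrated_brier_score(
                eta, surv, breslow_baseline(eta, surv), grid
            )
            assert ibs < prev
            prev = ibs
        assert prev < 0.05

    def test_matches_scikit_survival(self):
        """Oracle equivalence on 20 random datasets within 1e-6."""
        from sksurv.metrics import integrated_brier_score as sk_ibs

        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 60
            t = rng.exponential(1.0, n).round(2) + 0.01
            e = (rng.random(n) < 0.7).astype(int)
            if e.sum() < 2:
                continue
            eta = rng.normal(0, 1, n)
            surv = SurvivalTable(t, e)
            base = breslow_baseline(eta, surv)
            grid = np.linspace(t[e == 1].min() + 1e-6, np.quantile(t, 0.7), 40)
            S = predict_survival(eta, base, grid)
            y = np.array(
                [(bool(ei), ti) for ei, ti in zip(e, t)],
                dtype=[("event", bool), ("time", float)],
            )
            assert integrated_brier_score(eta, surv, base, grid) == pytest.approx(
                sk_ibs(y, y, S, grid), abs=1e-6
            )

    def test_zero_censoring_weight_is_an_error(self):
        # the censoring KM hits 0 at t=2, where an event also needs a weight
        t = np.array([1.0, 2.0, 2.0])
        surv = SurvivalTable(t, [1, 1, 0])
        baseline = breslow_baseline(np.zeros(3), surv)
        with pytest.raises(ValueError, match="censoring"):
            brier_scores(np.zeros(3), surv, baseline, np.array([2.1]))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 50
        t = rng.exponential(1.0, n) + 1e-3
        e = (rng.random(n) < 0.8).astype(int)
        eta = rng.normal(0, 1, n)
        surv = SurvivalTable(t, e)
        grid = np.linspace(t[e == 1].min(), np.quantile(t, 0.7), 30)
        base = breslow_baseline(eta, surv)
        ibs1 = integrated_brier_score(eta, surv, base, grid)
        perm = rng.permutation(n)
        surv_p = SurvivalTable(t[perm], e[perm])
        base_p = breslow_baseline(eta[perm], surv_p)
        ibs2 = integrated_brier_score(eta[perm], surv_p, base_p, grid)
        assert ibs1 == pytest.approx(ibs2, abs=1e-12)


class TestFitting:
    def test_shift_invariance_of_partial_likelihood(self, fitted_cox, study_data):
        """Fractions sum to 1 per sample, so adding a constant to every
        per-cell beta shifts eta by that constant and leaves the Cox partial
        likelihood unchanged."""
        surv = study_data["survival"]
        eta = fitted_cox.eta_
        for fn in (breslow_loglik, efron_loglik):
            assert fn(eta + 3.7, surv) == pytest.approx(fn(eta, surv), abs=1e-8)

    def test_fractions_frozen_during_fit(self, fitted_deconv, fitted_cox):
        # the Cox stage consumed the fraction matrix without touching it
        np.testing.assert_allclose(fitted_deconv.fractions_.sum(axis=0), 1.0,
                                   atol=1e-6)
        assert fitted_cox.beta_.shape[0] == fitted_deconv.fractions_.shape[0]

    def test_eta_linear_in_beta(self, fitted_deconv):
        M = fitted_deconv.fractions_
        rng = np.random.default_rng(0)
        beta = rng.normal(size=M.shape[0])
        np.testing.assert_allclose(M.T @ (2.0 * beta), 2.0 * (M.T @ beta),
                                   rtol=1e-12)

    def test_zero_event_training_split_error(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(10, 3))
        M = np.full((10, 20), 0.1)
        surv = SurvivalTable(rng.exponential(1, 20) + 0.01,
                             np.zeros(20, dtype=int))
        with pytest.raises(ValueError):
            CellHazardCox().fit(Z, M, surv)

    def test_fit_determinism(self, fitted_vae, fitted_deconv, study_data):
        a = CellHazardCox(max_epochs=40, random_state=5).fit(
            fitted_vae.latent_mean_, fitted_deconv.fractions_, study_data["survival"]
        )
        b = CellHazardCox(max_epochs=40, random_state=5).fit(
            fitted_vae.latent_mean_, fitted_deconv.fractions_, study_data["survival"]
        )
        assert a.cindex_test_ == b.cindex_test_
        np.testing.assert_array_equal(a.beta_, b.beta_)

    def test_resample_ci_bounds_ordered(self, fitted_vae, fitted_deconv,
                                        study_data):
        lo, hi, cs = resample_cindex_ci(
            fitted_vae.latent_mean_,
            fitted_deconv.fractions_,
            study_data["survival"],
            n_iter=3,
            seed=1,
            max_epochs=40,
        )
        assert lo <= hi
        assert len(cs) == 3
        with pytest.raises(ValueError):
            resample_cindex_ci(
                fitted_vae.latent_mean_, fitted_deconv.fractions_,
                study_data["survival"], n_iter=1,
            )
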