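"""Pooled-ML estimation: likelihood, information criteria, CV%, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import pdcascade as pc
from pdcascade.estimate import DEFAULT_FIXED, _Problem

REF = pc.baicalein_reference_params()
FREE = [n for n in pc.PARAM_NAMES if n not in DEFAULT_FIXED]


def brute_force_nll(params, error_model, dataset):
    """Straight-line per-record Gaussian NLL, independent of the package path."""
    total = 0.0
    for _, row in dataset.iterrows():
        states = pc.predict_states(params, row["baicalein_uM"], [row["time_h"]])
        pred = float(states[row["analyte"]][0])
        sd = float(error_model.sigma_for(np.array([pred]))[0])
        total += 0.5 * math.log(2 * math.pi * sd**2)
        total += 0.5 * ((row["value"] - pred) / sd) ** 2
    return total


class TestNegLogLikelihood:
    def test_zero_residual_additive_closed_form(self, design):
        em = pc.ErrorModel(kind="additive", sigma_add=2.0)
        ds = pc.predict_design(REF, design)
        nll = pc.neg_log_likelihood(REF, em, ds, design)
        n = len(ds)
        assert nll == pytest.approx(0.5 * n * math.log(2 * math.pi * 4.0), rel=1e-12)

    def test_single_record_formula(self, design):
        em = pc.ErrorModel(kind="additive", sigma_add=1.0)
        ds = pc.predict_design(REF, design).iloc[:1].copy()
        pred = ds["value"].iloc[0]
        ds["value"] = pred + 2.0
        nll = pc.neg_log_likelihood(REF, em, ds, design)
        assert nll == pytest.approx(0.5 * math.log(2 * math.pi) + 2.0, rel=1e-12)

    def test_matches_brute_force(self, design, prop_error, noisy_dataset):
        sub = noisy_dataset.sample(40, random_state=0)
        want = brute_force_nll(REF, prop_error, sub)
        got = pc.neg_log_likelihood(REF, prop_error, sub, design)
        assert got == pytest.approx(want, rel=1e-9)

    def test_invalid_params_give_inf(self, design, prop_error, noisy_dataset):
        bad = REF.replace(alpha=0.3)  # f(40 μM) > 1
        assert pc.neg_log_likelihood(bad, prop_error, noisy_dataset, design) == np.inf


class TestInformationCriteria:
    def test_trivial(self):
        assert pc.information_criteria(0.0, 1, 1) == (2.0, 0.0)

    @given(
        m2ll=st.floats(-1e4, 1e4),
        p=st.integers(1, 50),
        n=st.integers(1, 10_000),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_identities(self, m2ll, p, n):
        aic, bic = pc.information_criteria(m2ll, p, n)
        assert aic == pytest.approx(m2ll + 2 * p)
        assert bic == pytest.approx(m2ll + p * math.log(n))

    def test_published_pair(self):
        # -2LL 2818.03 with 24 free parameters reproduces AIC 2866.03
        aic, _ = pc.information_criteria(2818.03, 24, 300)
        assert aic == pytest.approx(2866.03)


class TestFit:
    def test_fixed_point_on_noise_free_data(self, design):
        em = pc.ErrorModel(kind="proportional", sigma_prop=0.0)
        ds = pc.generate_dataset(REF, design, em, seed=1)
        fr = pc.fit(ds, design, init=REF, n_starts=1, seed=0)
        for n in FREE:
            assert getattr(fr.estimates, n) == pytest.approx(
                getattr(REF, n), rel=1e-4
            )

    def test_fixed_parameter_honored(self, noisy_dataset, design):
        fr = pc.fit(
            noisy_dataset,
            design,
            init=REF,
            fixed=DEFAULT_FIXED | {"alpha"},
            n_starts=1,
            seed=0,
        )
        assert fr.estimates.alpha == REF.alpha
        assert "alpha" not in fr.free_names

    def test_nll_improves_on_init(self, noisy_fit, noisy_dataset, design):
        prob = _Problem(noisy_dataset, design)
        m2ll_init, _ = prob.profiled_minus2ll(REF, 1.0)
        assert noisy_fit.minus2ll <= m2ll_init + 1e-9

    def test_profile_sanity(self, noisy_fit, noisy_dataset, design):
        # perturbing any single free parameter ±20% cannot beat the optimum
        prob = _Problem(noisy_dataset, design)
        best, _ = prob.profiled_minus2ll(noisy_fit.estimates, 1.0)
        for name in noisy_fit.free_names:
            for factor in (0.8, 1.2):
                perturbed = noisy_fit.estimates.replace(
                    **{name: getattr(noisy_fit.estimates, name) * factor}
                )
                m2ll, _ = prob.profiled_minus2ll(perturbed, 1.0)
                assert m2ll >= best - 1e-6, f"{name} x{factor} beat the optimum"

    def test_ic_identities_on_fit(self, noisy_fit):
        aic, bic = pc.information_criteria(
            noisy_fit.minus2ll, noisy_fit.p, noisy_fit.n_obs
        )
        assert noisy_fit.aic == aic
        assert noisy_fit.bic == bic
        assert noisy_fit.p == len(noisy_fit.free_names) + len(noisy_fit.sigmas)

    def test_result_roundtrip(self, noisy_fit):
        restored = pc.FitResult.from_dict(noisy_fit.to_dict())
        assert restored.estimates == noisy_fit.estimates
        assert restored.minus2ll == noisy_fit.minus2ll


class TestParameterCV:
    def test_fixed_excluded_and_magnitudes(self, noisy_fit, noisy_dataset, design):
        cv = pc.parameter_cv(noisy_fit, noisy_dataset, design, method="hessian")
        assert set(cv) == set(FREE)
        assert all(0 < v < 100 for v in cv.values())

    def test_shrinks_with_replicates(self, design, prop_error):
        big = pc.StudyDesign(
            arms=design.arms,
            times=design.times,
            replicates={k: 4 * v for k, v in design.replicates.items()},
        )
        cvs = {}
        for label, d in [("small", design), ("big", big)]:
            ds = pc.generate_dataset(REF, d, prop_error, seed=31)
            fr = pc.fit(ds, d, init=REF, n_starts=1, seed=0)
            cvs[label] = pc.parameter_cv(fr, ds, d, method="hessian")
        # 4x the data should shrink SEs roughly 2x; allow Monte-Carlo slack
        ratios = [cvs["big"][n] / cvs["small"][n] for n in FREE]
        assert np.median(ratios) == pytest.approx(0.5, abs=0.2)

    def test_bootstrap_agrees_with_hessian(self, noisy_fit, noisy_dataset, design):
        hess = pc.parameter_cv(noisy_fit, noisy_dataset, design, method="hessian")
        boot = pc.parameter_cv(
            noisy_fit, noisy_dataset, design, method="bootstrap", n_boot=40, seed=2
        )
        for n in FREE:
            assert boot[n] == pytest.approx(hess[n], rel=1.0), n  # within 2x


class TestRecover:
    def test_noise_free_recovery_is_exact(self, design):
        em = pc.ErrorModel(kind="proportional", sigma_prop=0.0)
        rs = pc.recover(
            REF, design, em, n_sim=1, seed=50, n_starts=1, compute_coverage=False
        )
        for n in FREE:
            assert rs.medians[n] == pytest.approx(getattr(REF, n), rel=1e-4)

    def test_rmse_improves_with_replicates(self, design, prop_error):
        doubled = pc.StudyDesign(
            arms=design.arms,
            times=design.times,
            replicates={k: 2 * v for k, v in design.replicates.items()},
        )
        r1 = pc.recover(
            REF, design, prop_error, n_sim=8, seed=500, n_starts=2,
            compute_coverage=False,
        )
        r2 = pc.recover(
            REF, doubled, prop_error, n_sim=8, seed=500, n_starts=2,
            compute_coverage=False,
        )
        log_ratios = [math.log(r2.rmse[n] / r1.rmse[n]) for n in FREE]
        assert np.mean(log_ratios) < 0.0

    def test_summary_frame(self, design):
        em = pc.ErrorModel(kind="proportional", sigma_prop=0.0)
        rs = pc.recover(
            REF, design, em, n_sim=1, seed=50, n_starts=1, compute_coverage=False
        )
        frame = rs.to_frame()
        assert list(frame["parameter"]) == FREE
        assert rs.n_converged == 1


class TestCascadeRegressor:
    def test_sklearn_contract(self):
        est = pc.CascadeRegressor(n_starts=3, seed=1)
        cloned = clone(est)
        assert cloned.get_params()["n_starts"] == 3
        cloned.set_params(seed=9)
        assert cloned.seed == 9

    def test_fit_predict(self, noisy_dataset):
        est = pc.CascadeRegressor(n_starts=2, seed=0).fit(noisy_dataset)
        assert est.params_.alpha == pytest.approx(REF.alpha, rel=0.5)
        pred = est.predict(noisy_dataset)
        assert pred.shape == (len(noisy_dataset),)
        assert np.all(pred > 0)
        assert est.result_.converged

    def test_predict_before_fit_raises(self, noisy_dataset):
        with pytest.raises(RuntimeError, match="not fitted"):
            pc.CascadeRegressor().predict(noisy_dataset)
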