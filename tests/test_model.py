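"""Cascade model core: drug effect, closed forms, solver, invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import pdcascade as pc
from conftest import random_valid_params

REF = pc.baicalein_reference_params()
GRID = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])


class TestDrugEffect:
    @pytest.mark.parametrize(
        "alpha, conc, expected",
        [
            (0.0832, math.e, 0.0832),  # one e-fold of concentration
            (0.0832, 1.0, 0.0),
            (0.0, 40.0, 0.0),
            (0.0832, 40.0, 0.0832 * math.log(40.0)),
            (0.1, 0.5, 0.0),  # sub-1 μM clamp: no predicted stimulation
            (0.1, 0.0, 0.0),
        ],
    )
    def test_values(self, alpha, conc, expected):
        assert pc.drug_effect(alpha, conc) == pytest.approx(expected, abs=1e-15)

    def test_total_shutdown_rejected(self):
        with pytest.raises(ValueError, match="negative production"):
            pc.drug_effect(0.5, 40.0)

    @pytest.mark.parametrize("alpha, conc", [(-0.1, 10.0), (0.1, -1.0)])
    def test_preconditions(self, alpha, conc):
        with pytest.raises(ValueError):
            pc.drug_effect(alpha, conc)


class TestTnfClosedForm:
    def test_initial_condition(self):
        assert pc.tnf_closed_form(REF, 20.0, 0.0) == pytest.approx(REF.tnf0)

    def test_zero_elimination_limit(self):
        p = REF.replace(k_out_tnf=0.0)
        assert pc.tnf_closed_form(p, 0.0, 2.0) == pytest.approx(
            p.tnf0 + 2.0 * p.k_in_tnf
        )

    def test_pinned_reference_value(self):
        # independent hand evaluation of S/k + (tnf0 - S/k) e^{-k t} at the
        # reference constants, control arm, t = 1 h
        assert pc.tnf_closed_form(REF, 0.0, 1.0) == pytest.approx(
            3750.2154579143826, rel=1e-12
        )


class TestDelayedInput:
    @pytest.fixture(scope="class")
    def traj(self):
        return pc.simulate_cascade(REF, 0.0, np.linspace(0.0, 12.0, 241))

    def test_pre_stimulus_history(self, traj):
        assert pc.delayed_input(traj, 1.0, 1.38, REF.tnf0) == REF.tnf0

    def test_boundary_uses_history(self, traj):
        assert pc.delayed_input(traj, 1.38, 1.38, REF.tnf0) == REF.tnf0

    def test_interpolated_matches_closed_form(self, traj):
        got = pc.delayed_input(traj, 4.0, 1.41, REF.tnf0)
        want = float(pc.tnf_closed_form(REF, 0.0, 4.0 - 1.41))
        assert got == pytest.approx(want, rel=1e-6)

    def test_extrapolation_forbidden(self, traj):
        with pytest.raises(ValueError, match="extrapolation"):
            pc.delayed_input(traj, 14.0, 1.0, REF.tnf0)


class TestSimulateCascade:
    def test_no_production_baselines_persist(self):
        p = REF.replace(
            k_in_tnf=0.0, k_in_il6=0.0, k_in_inos=0.0, k_in_no=0.0, il6_0=0.0
        )
        traj = pc.simulate_cascade(p, 0.0, GRID)
        for name, series in traj.states().items():
            baseline = {"TNF": p.tnf0, "IL6": 0.0, "iNOS": p.inos0, "NO": p.no0}[name]
            # TNF decays from tnf0; the zero-input IL-6 stays at 0; the
            # non-eliminated iNOS/NO stay at baseline
            if name in ("iNOS", "NO", "IL6"):
                assert series == pytest.approx(np.full_like(GRID, baseline), abs=1e-9)

    def test_tnf_matches_closed_form(self):
        traj = pc.simulate_cascade(REF, 40.0, GRID)
        want = pc.tnf_closed_form(REF, 40.0, GRID)
        np.testing.assert_allclose(traj.tnf, want, rtol=1e-10)

    def test_inos_matches_quadrature(self):
        traj = pc.simulate_cascade(REF, 10.0, GRID, rtol=1e-10, atol=1e-10)
        for i, t in enumerate(GRID[1:], start=1):
            integral, _ = quad(
                lambda s: float(pc.model.tnf_delayed(REF, 10.0, s, REF.tau2)),
                0.0,
                t,
                limit=200,
            )
            want = REF.inos0 + REF.k_in_inos * integral
            assert traj.inos[i] == pytest.approx(want, rel=1e-6)

    def test_dose_monotonicity(self):
        lo = pc.simulate_cascade(REF, 10.0, GRID)
        hi = pc.simulate_cascade(REF, 40.0, GRID)
        for name in pc.ANALYTES:
            assert np.all(hi.states()[name][1:] <= lo.states()[name][1:] + 1e-12)

    def test_accumulation_without_elimination(self):
        traj = pc.simulate_cascade(REF, 20.0, GRID)
        assert np.all(np.diff(traj.inos) >= -1e-12)
        assert np.all(np.diff(traj.no) >= -1e-12)

    def test_control_equals_zero_alpha(self):
        a = pc.simulate_cascade(REF, 0.0, GRID)
        b = pc.simulate_cascade(REF.replace(alpha=0.0), 0.0, GRID)
        for name in pc.ANALYTES:
            np.testing.assert_array_equal(a.states()[name], b.states()[name])

    def test_grid_refinement_converges(self):
        coarse_grid = np.linspace(0.0, 12.0, 25)
        fine_grid = np.linspace(0.0, 12.0, 49)
        coarse = pc.simulate_cascade(REF, 40.0, coarse_grid)
        fine = pc.simulate_cascade(REF, 40.0, fine_grid)
        for name in pc.ANALYTES:
            c, f = coarse.states()[name][1:], fine.states()[name][2::2]
            np.testing.assert_allclose(c, f, rtol=1e-6)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            pc.simulate_cascade(REF, 0.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            pc.simulate_cascade(REF, 0.0, [0.0, 2.0, 2.0])


class TestFastPath:
    def test_matches_ode_solver(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_valid_params(rng)
            conc = float(rng.choice([0.0, 10.0, 20.0, 40.0]))
            fast = pc.predict_states(p, conc, GRID[1:])
            traj = pc.simulate_cascade(p, conc, GRID, rtol=1e-10, atol=1e-10)
            for j, name in enumerate(pc.ANALYTES):
                np.testing.assert_allclose(
                    fast[name], traj.states()[name][1:], rtol=1e-6,
                    err_msg=f"{name} mismatch",
                )

    def test_requires_zero_elimination(self):
        with pytest.raises(ValueError, match="semi-analytic"):
            pc.predict_states(REF.replace(k_out_no=0.01), 0.0, [1.0])


class TestInosRelativeRatio:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((2.0, 1.0, 2.0, 1.0), 1.0),
            ((2.0, 1.0, 1.0, 1.0), 2.0),
            ((3.0, 1.5, 0.8, 1.6), 4.0),
        ],
    )
    def test_values(self, args, expected):
        assert pc.inos_relative_ratio(*args) == pytest.approx(expected)

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            pc.inos_relative_ratio(1.0, 0.0, 1.0, 1.0)


class TestPDParameters:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            pc.PDParameters(**{**REF.model_dump(), "k_out_tnf": -0.1})
        with pytest.raises(ValueError):
            pc.PDParameters(**{**REF.model_dump(), "delta": 0.0})

    def test_check_arms(self):
        REF.check_arms([0.0, 10.0, 20.0, 40.0])
        with pytest.raises(ValueError, match="shutdown"):
            REF.replace(alpha=0.3).check_arms([40.0])
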