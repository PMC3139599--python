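"""Constraint resolution, residual assembly and least-squares fitting."""

import numpy as np
import pytest

import kinfit as kf
from kinfit.fitting import (
    ConstraintSet,
    Experiment,
    FitProblem,
    Parameter,
    ParameterSet,
    residuals,
    resolve_constraints,
    standard_errors,
)
from kinfit.io import ProgressCurve
from kinfit.odegen import generate_odes
from kinfit.scheme import parse_scheme
from kinfit.simulate import Observable


class TestConstraints:
    def test_identity_tie(self):
        ties = ConstraintSet([("k13", "k3", 1.0)])
        assert resolve_constraints(ties, {"k3": 7.0}) == {"k3": 7.0, "k13": 7.0}

    def test_proportional_tie(self):
        ties = ConstraintSet([("k10", "k4", 2.0)])
        out = resolve_constraints(ties, {"k4": 0.5})
        assert out["k10"] == 1.0

    def test_chain_composes(self):
        ties = ConstraintSet([("b", "a", 2.0), ("c", "b", 3.0)])
        assert resolve_constraints(ties, {"a": 1.0})["c"] == 6.0

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            ConstraintSet([("a", "b", 1.0), ("b", "a", 1.0)])

    def test_missing_master_rejected(self):
        ties = ConstraintSet([("b", "a", 2.0)])
        with pytest.raises(KeyError, match="'a'"):
            resolve_constraints(ties, {"c": 1.0})

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet([("b", "a", 0.0)])

    def test_parameter_invariants(self):
        with pytest.raises(ValueError, match="outside"):
            Parameter("k", value=5.0, lower=0.0, upper=1.0)
        with pytest.raises(ValueError, match="tied to itself"):
            Parameter("k", tie=("k", 1.0))
        p = Parameter("k", value=1e30, fixed=True)  # fixed ignores bounds
        assert p.fixed


def _binding_problem(k0=2.0, E0=2.0, I0=1.0, data=None, n=25,
                     free_y0=False, noise_seed=None):
    """Small E + I -> EI problem with optionally perturbable pieces."""
    ode = generate_odes(parse_scheme("E + I -> EI ; k0"))
    t = np.linspace(0, 4, n)
    signal = kf.closed_form_bimolecular(E0, I0, k0, t)
    if noise_seed is not None:
        signal = signal + np.random.default_rng(noise_seed).normal(0, 0.01, n)
    curve = ProgressCurve("c.dat", t, data if data is not None else signal)
    params = ParameterSet([Parameter("k0", value=k0)])
    y0: dict = {"EI": 0.0}
    if free_y0:
        params.add(Parameter("curve0:E", value=E0))
        params.add(Parameter("curve0:I", value=I0))
        y0.update({"E": "curve0:E", "I": "curve0:I"})
    else:
        y0.update({"E": E0, "I": I0})
    exp = Experiment(curve=curve, y0=y0, observable=Observable({"E": 1.0}))
    return FitProblem(odesys=ode, experiments=[exp], parameters=params)


class TestResiduals:
    def test_noiseless_truth_gives_zero(self):
        prob = _binding_problem()
        r = residuals(prob, prob.initial_free_vector())
        assert np.max(np.abs(r)) <= 1e-7

    def test_zero_data_gives_negative_model(self):
        prob = _binding_problem(data=np.zeros(25))
        r = residuals(prob, [2.0])
        model = prob.model_signal(prob.experiments[0],
                                  prob.full_values([2.0]))
        assert np.allclose(r, -model)

    def test_ssq_minimized_at_truth(self):
        """Brute-force scan over k0 brackets the minimum at the
        generating value."""
        prob = _binding_problem()
        grid = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0])
        ssq = [float(residuals(prob, [g]) @ residuals(prob, [g]))
               for g in grid]
        assert grid[int(np.argmin(ssq))] == 2.0
        assert ssq[3] < ssq[4] < ssq[5] < ssq[6]

    def test_integration_failure_becomes_penalty(self, monkeypatch):
        prob = _binding_problem()
        monkeypatch.setattr(
            "kinfit.fitting.integrate",
            lambda *a, **k: (_ for _ in ()).throw(
                kf.IntegrationError("boom", 0.0)),
        )
        with pytest.warns(RuntimeWarning, match="penalty"):
            r = residuals(prob, [2.0])
        assert np.all(r == kf.fitting.PENALTY)


class TestFit:
    def test_recovers_k0_from_perturbed_start(self):
        prob = _binding_problem()
        prob.parameters["k0"].value = 20.0
        res = kf.fit(prob)
        assert res.converged
        assert res.estimates["k0"] == pytest.approx(2.0, rel=1e-6)

    def test_joint_recovery_with_free_initials(self):
        prob = _binding_problem(free_y0=True)
        # keep E0 > I0 so the start stays in the excess-enzyme regime
        for name, f in [("k0", 10.0), ("curve0:E", 5.0), ("curve0:I", 0.2)]:
            prob.parameters[name].value *= f
        res = kf.fit(prob, ftol=1e-14)
        for name, truth in [("k0", 2.0), ("curve0:E", 2.0), ("curve0:I", 1.0)]:
            assert res.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_all_fixed_is_first_approximation(self):
        prob = _binding_problem()
        prob.parameters["k0"].fixed = True
        res = kf.fit(prob)
        assert res.converged and res.iterations == 0
        assert "first approximation" in res.message
        assert res.estimates["k0"] == 2.0
        assert res.standard_errors["k0"] == 0.0

    def test_trace_is_strictly_improving(self):
        prob = _binding_problem(noise_seed=0)
        prob.parameters["k0"].value = 30.0
        res = kf.fit(prob)
        ssqs = [s for s, _ in res.trace]
        assert all(b < a for a, b in zip(ssqs, ssqs[1:]))
        assert res.ssq <= ssqs[0]

    def test_deterministic(self):
        r1 = kf.fit(_binding_problem(noise_seed=3))
        r2 = kf.fit(_binding_problem(noise_seed=3))
        assert r1.estimates == r2.estimates
        assert r1.ssq == r2.ssq

    def test_tie_exact_in_result(self):
        ode = generate_odes(parse_scheme("A -> B ; k1\nA -> B ; k2"))
        t = np.linspace(0, 3, 20)
        data = 1.0 - np.exp(-1.5 * t)
        params = ParameterSet([
            Parameter("k1", value=0.3),
            Parameter("k2", tie=("k1", 2.0)),
        ])
        exp = Experiment(ProgressCurve("b.dat", t, data),
                         {"A": 1.0, "B": 0.0}, Observable({"B": 1.0}))
        prob = FitProblem(ode, [exp], params)
        res = kf.fit(prob)
        assert res.estimates["k2"] == 2.0 * res.estimates["k1"]  # exact
        assert res.estimates["k1"] == pytest.approx(0.5, rel=1e-6)
        assert res.standard_errors["k2"] == 2.0 * res.standard_errors["k1"]

    def test_needs_more_data_than_parameters(self):
        prob = _binding_problem(n=2, free_y0=True)
        with pytest.raises(ValueError, match="more data rows"):
            kf.fit(prob)

    def test_sensitivity_jacobian_matches_fd_route(self):
        prob = _binding_problem(noise_seed=4, free_y0=True)
        for name, f in [("k0", 3.0), ("curve0:E", 0.5), ("curve0:I", 2.0)]:
            prob.parameters[name].value *= f
        r_fd = kf.fit(prob, ftol=1e-13)
        r_sens = kf.fit(prob, ftol=1e-13, jac="sensitivity")
        for name in r_fd.free_names:
            assert r_sens.estimates[name] == pytest.approx(
                r_fd.estimates[name], rel=1e-4)
            assert r_sens.standard_errors[name] == pytest.approx(
                r_fd.standard_errors[name], rel=1e-2)


class TestStandardErrors:
    def test_zero_residuals_give_zero_se(self):
        J = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        se = standard_errors(J, np.zeros(3), ["a", "b"])
        assert se == {"a": 0.0, "b": 0.0}

    def test_collinear_parameters_flagged(self):
        J = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.warns(RuntimeWarning, match="not identifiable"):
            se = standard_errors(J, np.full(5, 0.1), ["a", "b"])
        assert all(np.isnan(v) for v in se.values())

    def test_exponential_decay_matches_analytic_linearization(self):
        """SE of a one-parameter exponential-decay rate fit agrees with
        the closed-form weighted-linearization value within 20%."""
        ode = generate_odes(parse_scheme("A -> B ; k"))
        k_true, sigma = 1.2, 0.01
        t = np.linspace(0, 4, 60)
        rng = np.random.default_rng(8)
        data = np.exp(-k_true * t) + rng.normal(0, sigma, len(t))
        exp = Experiment(ProgressCurve("a.dat", t, data),
                         {"A": 1.0, "B": 0.0}, Observable({"A": 1.0}))
        prob = FitProblem(ode, [exp],
                          ParameterSet([Parameter("k", value=1.0)]))
        res = kf.fit(prob)
        k_hat = res.estimates["k"]
        # linearization: d model/dk = -t e^{-kt}; SE = sigma/||J||
        J = -t * np.exp(-k_hat * t)
        se_analytic = sigma / np.linalg.norm(J)
        assert res.standard_errors["k"] == pytest.approx(se_analytic, rel=0.2)
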