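"""Integration, observables and the closed-form oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import kinfit as kf
from kinfit.odegen import generate_odes
from kinfit.scheme import parse_scheme


@pytest.fixture(scope="module")
def binding_odesys():
    return generate_odes(parse_scheme("E + I -> EI ; k0"))


class TestIntegrate:
    def test_enzyme_conservation_excess_substrate(self, mm_odesys):
        traj = kf.integrate(
            mm_odesys, {"k0": 1e5, "k1": 10.0, "k2": 1.0},
            {"E": 1e-6, "S": 1e-3, "ES": 0.0, "P": 0.0},
            np.linspace(0, 50, 101),
        )
        total = traj["E"] + traj["ES"]
        assert np.max(np.abs(total - total[0])) / total[0] <= 1e-8

    def test_limiting_reagent_exhaustion(self, binding_odesys):
        traj = kf.integrate(binding_odesys, {"k0": 1.0},
                            {"E": 2.0, "I": 1.0, "EI": 0.0},
                            np.linspace(0, 50, 51))
        assert traj["E"][-1] == pytest.approx(1.0, abs=1e-6)
        assert traj["I"][-1] == pytest.approx(0.0, abs=1e-6)

    def test_first_row_is_initial_condition(self, binding_odesys):
        traj = kf.integrate(binding_odesys, {"k0": 0.7},
                            {"E": 1.5, "I": 0.5, "EI": 0.0},
                            np.linspace(0, 5, 11))
        assert np.allclose(traj.states[0], [1.5, 0.5, 0.0])

    def test_matches_closed_form_at_random_conditions(self, binding_odesys):
        rng = np.random.default_rng(5)
        for _ in range(20):
            E0, I0, k0 = rng.uniform(0.5, 3.0, 3)
            t = np.linspace(0, 10.0 / (k0 * max(E0, I0)), 40)
            traj = kf.integrate(binding_odesys, {"k0": k0},
                                {"E": E0, "I": I0, "EI": 0.0}, t)
            ref = kf.closed_form_bimolecular(E0, I0, k0, t)
            assert np.max(np.abs(traj["E"] - ref) / np.abs(ref)) <= 1e-7

    def test_grid_refinement_consistent(self, mm_odesys):
        k = {"k0": 1e3, "k1": 5.0, "k2": 0.5}
        y0 = {"E": 0.01, "S": 2.0, "ES": 0.0, "P": 0.0}
        coarse = kf.integrate(mm_odesys, k, y0, np.linspace(0, 20, 21))
        fine = kf.integrate(mm_odesys, k, y0, np.linspace(0, 20, 41))
        assert np.allclose(fine.states[::2], coarse.states,
                           rtol=1e-7, atol=1e-10)

    def test_tightening_rtol_converges_to_reference(self, mm_odesys):
        k = {"k0": 1e3, "k1": 5.0, "k2": 0.5}
        y0 = {"E": 0.01, "S": 2.0, "ES": 0.0, "P": 0.0}
        t = np.linspace(0, 20, 21)
        ref = kf.integrate(mm_odesys, k, y0, t, rtol=1e-12, atol=1e-14)
        errs = [
            np.max(np.abs(kf.integrate(mm_odesys, k, y0, t,
                                       rtol=r, atol=1e-14).states
                          - ref.states))
            for r in (1e-6, 1e-8, 1e-10)
        ]
        assert errs[0] > errs[1] > errs[2]

    @pytest.mark.parametrize("times", [[0.0], [0.0, 1.0, 1.0], [1.0, 0.0]])
    def test_bad_grids_rejected(self, binding_odesys, times):
        with pytest.raises(ValueError, match="strictly increasing"):
            kf.integrate(binding_odesys, {"k0": 1.0},
                         {"E": 1, "I": 1, "EI": 0}, times)

    def test_missing_species_and_negative_inputs(self, binding_odesys):
        grid = [0.0, 1.0]
        with pytest.raises(ValueError, match="missing initial"):
            kf.integrate(binding_odesys, {"k0": 1.0}, {"E": 1, "I": 1}, grid)
        with pytest.raises(ValueError, match="non-negative"):
            kf.integrate(binding_odesys, {"k0": 1.0},
                         {"E": -1, "I": 1, "EI": 0}, grid)
        with pytest.raises(ValueError, match="non-negative"):
            kf.integrate(binding_odesys, {"k0": -1.0},
                         {"E": 1, "I": 1, "EI": 0}, grid)

    def test_rhs_budget_exceeded_raises(self, mm_odesys):
        with pytest.raises(kf.IntegrationError, match="abandoned"):
            kf.integrate(mm_odesys, {"k0": 1e5, "k1": 10.0, "k2": 1.0},
                         {"E": 1e-6, "S": 1e-3, "ES": 0.0, "P": 0.0},
                         np.linspace(0, 50, 11), max_rhs_calls=10)


class TestObserve:
    def test_single_species_identity(self, mm_odesys):
        traj = kf.integrate(mm_odesys, {"k0": 10, "k1": 1, "k2": 1},
                            {"E": 0.1, "S": 1.0, "ES": 0, "P": 0},
                            np.linspace(0, 5, 11))
        sig = kf.observe(traj, kf.Observable(weights={"P": 1.0}))
        assert np.array_equal(sig, traj["P"])

    def test_weighted_sum_and_scale(self, mm_odesys):
        traj = kf.integrate(mm_odesys, {"k0": 10, "k1": 1, "k2": 1},
                            {"E": 0.1, "S": 1.0, "ES": 0, "P": 0},
                            np.linspace(0, 5, 11))
        sig = kf.observe(traj, kf.Observable(weights={"E": 1.0, "ES": 1.0},
                                             scale=0.64))
        assert np.allclose(sig, 0.64 * (traj["E"] + traj["ES"]))

    def test_unknown_species_rejected(self, mm_odesys):
        traj = kf.integrate(mm_odesys, {"k0": 10, "k1": 1, "k2": 1},
                            {"E": 0.1, "S": 1.0, "ES": 0, "P": 0},
                            np.linspace(0, 5, 11))
        with pytest.raises(KeyError):
            kf.observe(traj, kf.Observable(weights={"Q": 1.0}))

    def test_observable_validation(self):
        with pytest.raises(ValueError, match="nonzero weight"):
            kf.Observable(weights={"E": 0.0})
        with pytest.raises(ValueError, match="scale"):
            kf.Observable(weights={"E": 1.0}, scale=0.0)


class TestClosedFormBimolecular:
    def test_initial_condition(self):
        assert kf.closed_form_bimolecular(1.7, 0.9, 2.0, 0.0) == pytest.approx(1.7)

    def test_equimolar_half_life(self):
        E0, k0 = 0.8, 3.0
        assert kf.closed_form_bimolecular(E0, E0, k0, 1.0 / (k0 * E0)) \
            == pytest.approx(E0 / 2)

    def test_long_time_limit_is_excess(self):
        assert kf.closed_form_bimolecular(2.0, 1.0, 1.0, 1e3) \
            == pytest.approx(1.0, rel=1e-9)

    def test_near_equimolar_is_stable(self):
        # expm1 formulation must not cancel catastrophically
        e = kf.closed_form_bimolecular(1.0, 1.0 - 1e-12, 1.0, 5.0)
        assert e == pytest.approx(1.0 / 6.0, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kf.closed_form_bimolecular(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            kf.closed_form_bimolecular(1.0, 1.0, 1.0, -1.0)


class TestReducedMM:
    def test_saturation_limit(self):
        m = kf.ReducedMMModel(K=2.0, k2=3.0, Etot=0.5)
        _, dP = kf.reduced_mm_rhs(m, 1e9)
        assert dP == pytest.approx(3.0 * 0.5, rel=1e-8)

    def test_half_saturation(self):
        m = kf.ReducedMMModel(K=2.0, k2=3.0, Etot=0.5)
        dS, dP = kf.reduced_mm_rhs(m, 2.0)
        assert dP == pytest.approx(3.0 * 0.5 / 2)
        assert dS == -dP

    def test_rapid_equilibrium_limit_of_full_model(self, mm_odesys):
        """Full mass-action product curves approach the reduced rate law
        as binding becomes fast at fixed K = k1/k0."""
        K, k2, Etot, S0 = 2.0, 1.0, 0.05, 5.0
        t = np.linspace(0, 120, 121)
        red = kf.ReducedMMModel(K=K, k2=k2, Etot=Etot)
        sol = solve_ivp(lambda _, y: [kf.reduced_mm_rhs(red, y[0])[0]],
                        (0, 120), [S0], t_eval=t, rtol=1e-10, atol=1e-12,
                        method="LSODA")
        P_red = S0 - sol.y[0]
        sups = []
        for mult in (1, 10, 100, 1000):
            traj = kf.integrate(mm_odesys,
                                {"k0": mult, "k1": K * mult, "k2": k2},
                                {"E": Etot, "S": S0, "ES": 0, "P": 0}, t)
            sups.append(np.max(np.abs(traj["P"] - P_red)))
        assert sups == sorted(sups, reverse=True)

    def test_invalid(self):
        with pytest.raises(ValueError):
            kf.ReducedMMModel(K=-1.0, k2=1.0, Etot=1.0)
        m = kf.ReducedMMModel(K=1.0, k2=1.0, Etot=1.0)
        with pytest.raises(ValueError):
            kf.reduced_mm_rhs(m, -0.5)
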