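"""Forward simulation of mass-action systems and closed-form oracles.

The integrator is adaptive and stiff-capable (LSODA with the analytic
mass-action Jacobian): enzyme schemes routinely mix diffusion-limited
association (~1e8 /M/min) with slow catalysis (~0.1 /min), a stiffness
ratio of many orders of magnitude.  Default tolerances are rtol=1e-8,
atol=1e-12.  Units are the caller's responsibility: the package never
converts s<->min or molar<->absorbance.

Two closed-form references are included for validation: the exact
solution of the irreversible bimolecular reaction E + I -> EI, and the
rapid-equilibrium (reduced) Michaelis-Menten rate law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .odegen import ODESystem

__all__ = [
    "Trajectory",
    "Observable",
    "ReducedMMModel",
    "IntegrationError",
    "integrate",
    "observe",
    "closed_form_bimolecular",
    "reduced_mm_rhs",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


class IntegrationError(RuntimeError):
    """Integration failed (e.g. step-size collapse); carries the time
    reached before failure in ``time_reached``."""

    def __init__(self, message: str, time_reached: float | None = None):
        super().__init__(message)
        self.time_reached = time_reached


@dataclass(frozen=True)
class Trajectory:
    """Solution states on the requested time grid (times x species)."""

    times: np.ndarray
    states: np.ndarray
    species_names: tuple[str, ...]

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            j = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        return self.states[:, j]

    def clamped(self) -> np.ndarray:
        """States with tiny negative integration excursions set to 0
        (reporting convenience; the raw states are kept unclamped)."""
        return np.clip(self.states, 0.0, None)


@dataclass(frozen=True)
class Observable:
    """A measured signal: scale * sum_s weights[s] * [s](t).

    Progress-curve signals are linear in concentrations (absorbance,
    fluorescence); ``scale`` converts concentration units to signal
    units (e.g. OD/min per molar of active enzyme).
    """

    weights: Mapping[str, float]
    scale: float = 1.0

    def __post_init__(self):
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("observable needs at least one nonzero weight")
        if not self.scale > 0:
            raise ValueError("observable scale must be positive")


def integrate(
    odesys: ODESystem,
    constants: Mapping[str, float],
    y0: Mapping[str, float],
    times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    max_rhs_calls: int = 400_000,
) -> Trajectory:
    """Integrate the system and return states at exactly ``times``.

    Every species needs an initial value (>= 0); ``times`` must be
    strictly increasing and start at the experiment start.  The solver
    runs unclamped; a negative excursion beyond 100*atol triggers a
    warning rather than silent clipping, since real model errors show
    up there first.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    missing = [n for n in odesys.species_names if n not in y0]
    if missing:
        raise ValueError(f"missing initial values for species: {missing}")
    y0_vec = np.array([float(y0[n]) for n in odesys.species_names])
    if np.any(y0_vec < 0):
        raise ValueError("initial concentrations must be non-negative")

    f_raw = odesys.rhs(constants)  # validates constants >= 0
    jac = odesys.jacobian(constants)

    # Budget guard: absurd parameter regions visited during fitting can
    # make the solver grind for minutes; abort and let the caller treat
    # it as an integration failure.  Well-posed solves use ~1e3 calls.
    calls = [0]

    def f(t: float, y: np.ndarray) -> np.ndarray:
        calls[0] += 1
        if calls[0] > max_rhs_calls:
            raise IntegrationError(
                f"integration abandoned after {max_rhs_calls} RHS "
                f"evaluations near t={t:g}", float(t)
            )
        return f_raw(t, y)

    sol = solve_ivp(
        f,
        (times[0], times[-1]),
        y0_vec,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=jac if method in ("LSODA", "BDF", "Radau") else None,
    )
    if not sol.success:
        sol_t = np.asarray(sol.t)
        reached = float(sol_t[-1]) if sol_t.size else float(times[0])
        raise IntegrationError(
            f"integration failed at t={reached:g}: {sol.message}", reached
        )
    states = sol.y.T
    if states.min() < -100.0 * atol:
        warnings.warn(
            f"trajectory dips to {states.min():.3g}, below -100*atol; "
            "check the model or tighten tolerances",
            RuntimeWarning,
            stacklevel=2,
        )
    return Trajectory(times=times, states=states,
                      species_names=odesys.species_names)


def observe(traj: Trajectory, obs: Observable) -> np.ndarray:
    """Map a trajectory to its measured signal at each time point."""
    sig = np.zeros(len(traj.times))
    for name, w in obs.weights.items():
        if w != 0:
            sig += w * traj[name]
    return obs.scale * sig


def closed_form_bimolecular(E0: float, I0: float, k0: float, t) -> np.ndarray | float:
    """Exact E(t) for the irreversible bimolecular reaction E + I -> EI.

    With the conserved difference D = E0 - I0, dE/dt = -k0*E*(E - D)
    integrates to

        E(t) = D / ( D/E0 + (I0/E0) * (1 - exp(-k0*D*t)) )

    (written via expm1 for stability near E0 = I0), and degenerates to
    E(t) = E0 / (1 + k0*E0*t) at exactly E0 = I0.
    """
    if not (E0 > 0 and I0 > 0 and k0 > 0):
        raise ValueError("E0, I0 and k0 must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    D = E0 - I0
    if D == 0:
        out = E0 / (1.0 + k0 * E0 * t)
    else:
        denom = D / E0 + (I0 / E0) * (-np.expm1(-k0 * D * t))
        out = D / denom
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ReducedMMModel:
    """Rapid-equilibrium Michaelis-Menten model: E and ES equilibrate
    instantly with equilibrium constant K = k1/k0, giving the single
    saturable rate law dP/dt = k2 * Etot * S / (K + S)."""

    K: float
    k2: float
    Etot: float

    def __post_init__(self):
        if not (self.K > 0 and self.k2 > 0 and self.Etot > 0):
            raise ValueError("K, k2 and Etot must be positive")


def reduced_mm_rhs(model: ReducedMMModel, S) -> tuple[np.ndarray, np.ndarray]:
    """(dS/dt, dP/dt) of the reduced model at substrate concentration S."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    dP = model.k2 * model.Etot * S / (model.K + S)
    return -dP, dP
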