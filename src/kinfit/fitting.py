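"""Constrained global least-squares fitting of kinetic models.

One :class:`FitProblem` bundles an ODE system, any number of progress
curves (each with its own initial-concentration map and observable),
and a parameter table.  Rate constants are shared across all curves;
initial concentrations are per-curve parameters named
``curve<i>:<Species>`` unless fixed or tied.  Parameters can be

* free within box bounds (default [0, 1e20]),
* fixed, or
* tied: ``dependent = alpha * master`` with alpha > 0, chains allowed
  as long as the tie graph is acyclic.  Ties let a single constant
  govern several steps (e.g. k14 = k8 = k6 = k0) or encode known
  activation ratios (k10 = 2*k4), shrinking the number of unknowns.

The minimizer is bounded trust-region least squares (scipy TRF) with a
finite-difference Jacobian; unit weights per data point.  Standard
errors come from the linearized covariance s^2 (J^T J)^-1 at the
optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .io import ProgressCurve
from .odegen import ODESystem
from .simulate import IntegrationError, Observable, integrate, observe

__all__ = [
    "Parameter",
    "ParameterSet",
    "ConstraintSet",
    "Experiment",
    "FitProblem",
    "FitResult",
    "resolve_constraints",
    "residuals",
    "fit",
    "standard_errors",
]

DEFAULT_LOWER = 0.0
DEFAULT_UPPER = 1e20
PENALTY = 1e8  # residual fill-in when integration fails mid-search


@dataclass
class Parameter:
    """One fittable quantity: a rate constant or ``curve<i>:<Species>``."""

    name: str
    value: float = 0.0
    lower: float = DEFAULT_LOWER
    upper: float = DEFAULT_UPPER
    fixed: bool = False
    tie: tuple[str, float] | None = None  # (master name, multiplier alpha)

    def __post_init__(self):
        if self.tie is not None:
            master, alpha = self.tie
            if not alpha > 0:
                raise ValueError(f"tie multiplier for {self.name!r} must be > 0")
            if master == self.name:
                raise ValueError(f"parameter {self.name!r} tied to itself")
        elif not self.fixed and not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter {self.name!r}: value {self.value} outside "
                f"bounds [{self.lower}, {self.upper}]"
            )

    @property
    def is_free(self) -> bool:
        return not self.fixed and self.tie is None


class ParameterSet:
    """Ordered, name-addressable collection of :class:`Parameter`."""

    def __init__(self, params: Sequence[Parameter] = ()):
        self._params: dict[str, Parameter] = {}
        for p in params:
            self.add(p)

    def add(self, p: Parameter) -> None:
        if p.name in self._params:
            raise ValueError(f"duplicate parameter {p.name!r}")
        self._params[p.name] = p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    @property
    def free(self) -> list[Parameter]:
        return [p for p in self if p.is_free]

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free]

    def constraint_set(self) -> "ConstraintSet":
        return ConstraintSet(
            [(p.name, p.tie[0], p.tie[1]) for p in self if p.tie is not None]
        )


@dataclass
class ConstraintSet:
    """Proportionality ties ``dependent = alpha * master``."""

    ties: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        deps = [d for d, _, _ in self.ties]
        if len(deps) != len(set(deps)):
            raise ValueError("a parameter may have at most one tie")
        for _, _, alpha in self.ties:
            if not alpha > 0:
                raise ValueError("tie multipliers must be > 0")
        self._as_map()  # raises on cycles

    def _as_map(self) -> dict[str, tuple[str, float]]:
        m = {d: (mst, a) for d, mst, a in self.ties}
        for start in m:
            seen = {start}
            cur = start
            while cur in m:
                cur = m[cur][0]
                if cur in seen:
                    raise ValueError(f"cyclic tie chain through {start!r}")
                seen.add(cur)
        return m


def resolve_constraints(
    constraints: ConstraintSet, free_values: Mapping[str, float]
) -> dict[str, float]:
    """Expand tie chains on top of the free/fixed values.

    Every dependent becomes alpha times its recursively resolved
    master; non-tied entries pass through unchanged.  Raises ``KeyError``
    if a chain bottoms out on a name absent from ``free_values``.
    """
    ties = constraints._as_map()
    out = dict(free_values)

    def value_of(name: str) -> float:
        if name in out:
            return out[name]
        if name not in ties:
            raise KeyError(f"tie master {name!r} has no value")
        master, alpha = ties[name]
        out[name] = alpha * value_of(master)
        return out[name]

    for dep in ties:
        value_of(dep)
    return out


@dataclass
class Experiment:
    """One progress curve with its initial conditions and observable.

    ``y0`` maps every scheme species to either a number (fixed initial
    concentration) or a parameter name registered in the problem's
    ParameterSet (fitted initial concentration).
    """

    curve: ProgressCurve
    y0: Mapping[str, float | str]
    observable: Observable


@dataclass
class FitProblem:
    """Global multi-curve fit: shared rate constants, per-curve y0."""

    odesys: ODESystem
    experiments: list[Experiment]
    parameters: ParameterSet
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self):
        for label in self.odesys.rate_labels:
            if label not in self.parameters:
                raise ValueError(f"no parameter block for rate constant {label!r}")
        for i, exp in enumerate(self.experiments):
            for name in self.odesys.species_names:
                if name not in exp.y0:
                    raise ValueError(
                        f"experiment {i}: no initial condition for {name!r}"
                    )
                ref = exp.y0[name]
                if isinstance(ref, str) and ref not in self.parameters:
                    raise ValueError(
                        f"experiment {i}: y0 parameter {ref!r} not declared"
                    )
        self.constraints = self.parameters.constraint_set()

    # -- packing ------------------------------------------------------
    @property
    def free_names(self) -> list[str]:
        return self.parameters.free_names

    def initial_free_vector(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters.free])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.lower for p in self.parameters.free])
        hi = np.array([p.upper for p in self.parameters.free])
        return lo, hi

    def full_values(self, free_vector: Sequence[float]) -> dict[str, float]:
        """All parameter values (free, fixed and tie-resolved)."""
        free_vector = np.asarray(free_vector, dtype=float)
        base = {p.name: p.value for p in self.parameters if p.fixed}
        base.update(zip(self.free_names, free_vector))
        return resolve_constraints(self.constraints, base)

    def _experiment_y0(self, exp: Experiment, values: Mapping[str, float]) -> dict[str, float]:
        out = {}
        for name in self.odesys.species_names:
            ref = exp.y0[name]
            out[name] = values[ref] if isinstance(ref, str) else float(ref)
        return out

    def model_signal(self, exp: Experiment, values: Mapping[str, float]) -> np.ndarray:
        constants = {lab: values[lab] for lab in self.odesys.rate_labels}
        traj = integrate(
            self.odesys, constants, self._experiment_y0(exp, values),
            exp.curve.times, rtol=self.rtol, atol=self.atol,
        )
        return observe(traj, exp.observable)

    @property
    def n_data(self) -> int:
        return sum(len(e.curve.times) for e in self.experiments)

    # -- forward sensitivities ---------------------------------------
    def _dk_dtheta(self) -> np.ndarray:
        """d(rate constant of reaction r)/d(free parameter j), constant
        under the linear tie structure."""
        free = self.free_names
        col = {n: j for j, n in enumerate(free)}
        ties = self.constraints._as_map()
        nr = self.odesys.n_reactions
        out = np.zeros((nr, len(free)))

        def root_of(label: str) -> tuple[str, float]:
            alpha = 1.0
            while label in ties:
                master, a = ties[label]
                alpha *= a
                label = master
            return label, alpha

        for r, rxn in enumerate(self.odesys.scheme.reactions):
            root, alpha = root_of(rxn.rate_label)
            if root in col:
                out[r, col[root]] = alpha
        return out

    def signal_jacobian(self, exp: Experiment,
                        free_vector: Sequence[float],
                        param_scale: np.ndarray | None = None) -> np.ndarray:
        """d(model signal)/d(free parameters) on the experiment's grid,
        computed exactly by integrating the forward sensitivity system
        S' = (df/dy) S + df/dtheta alongside the states.

        Finite differencing the solver output leaves derivative noise
        at the integration-tolerance level, which drowns the gradient
        along sloppy parameter combinations; the sensitivity route does
        not.
        """
        from scipy.integrate import solve_ivp

        values = self.full_values(free_vector)
        free = self.free_names
        nf = len(free)
        ns = self.odesys.n_species
        constants = {lab: values[lab] for lab in self.odesys.rate_labels}
        y0_map = self._experiment_y0(exp, values)
        y0 = np.array([y0_map[n] for n in self.odesys.species_names])

        dK = self._dk_dtheta()                     # (nr, nf)
        S0 = np.zeros((ns, nf))
        col = {n: j for j, n in enumerate(free)}
        for i_sp, sp in enumerate(self.odesys.species_names):
            ref = exp.y0[sp]
            if isinstance(ref, str) and ref in col:
                S0[i_sp, col[ref]] = 1.0
        if param_scale is not None:
            # differentiate wrt scaled parameters (e.g. log-space):
            # d/du_j = theta_j d/dtheta_j keeps sensitivities on the
            # same magnitude scale as the states
            dK = dK * param_scale[None, :]
            S0 = S0 * param_scale[None, :]

        f = self.odesys.rhs(constants)
        jac_y = self.odesys.jacobian(constants)
        monomials = self.odesys.reaction_monomials
        N_T = self.odesys.matrices.net_change.T.astype(float)

        def aug(t, z):
            y = z[:ns]
            S = z[ns:].reshape(ns, nf)
            dS = jac_y(t, y) @ S + N_T @ (monomials(y)[:, None] * dK)
            return np.concatenate([f(t, y), dS.ravel()])

        times = exp.curve.times
        sol = solve_ivp(aug, (times[0], times[-1]),
                        np.concatenate([y0, S0.ravel()]),
                        method="LSODA", t_eval=times,
                        rtol=self.rtol, atol=self.atol)
        if not sol.success:
            raise IntegrationError(
                f"sensitivity integration failed: {sol.message}")
        S_t = sol.y[ns:, :].T.reshape(len(times), ns, nf)
        w = np.array([exp.observable.weights.get(n, 0.0)
                      for n in self.odesys.species_names])
        return exp.observable.scale * np.einsum("s,tsj->tj", w, S_t)


def residuals(problem: FitProblem, free_vector: Sequence[float]) -> np.ndarray:
    """Concatenated (observed - model) over all experiments, unit weights.

    If integration fails for one experiment, its block is filled with a
    large constant penalty and a warning is emitted, so the trust region
    can retreat instead of aborting the whole fit.
    """
    values = problem.full_values(free_vector)
    blocks = []
    for i, exp in enumerate(problem.experiments):
        try:
            model = problem.model_signal(exp, values)
            blocks.append(exp.curve.values - model)
        except IntegrationError as err:
            warnings.warn(
                f"experiment {i} ({exp.curve.name}): {err}; "
                "assigning penalty residuals",
                RuntimeWarning,
                stacklevel=2,
            )
            blocks.append(np.full(len(exp.curve.times), PENALTY))
    return np.concatenate(blocks)


@dataclass
class FitResult:
    """Converged estimates and their uncertainty.

    ``estimates`` covers every parameter (tied entries are exactly
    alpha * master); ``standard_errors`` are linearized 1-sigma values
    (0 for fixed parameters, NaN when J^T J is singular); ``trace``
    lists (ssq, full parameter snapshot) for each accepted improvement.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    ssq: float
    converged: bool
    iterations: int
    trace: list[tuple[float, dict[str, float]]]
    free_names: list[str]
    message: str = ""

    def fitted_curves(self, problem: FitProblem) -> list[np.ndarray]:
        """Model signals at the optimum on each experiment's grid."""
        return [problem.model_signal(e, self.estimates)
                for e in problem.experiments]


def standard_errors(
    jac: np.ndarray, resid: np.ndarray, free_names: Sequence[str]
) -> dict[str, float]:
    """Linearized standard errors for the free parameters.

    SE_i = sqrt(s^2 [(J^T J)^-1]_ii) with s^2 = ssq / (rows - n_free).
    A singular J^T J (non-identifiable parameters) yields NaN entries
    and a warning.
    """
    n_free = len(free_names)
    rows = len(resid)
    if rows <= n_free:
        raise ValueError("need more data rows than free parameters")
    if n_free == 0:
        return {}
    s2 = float(resid @ resid) / (rows - n_free)
    JTJ = jac.T @ jac
    try:
        cov = np.linalg.inv(JTJ)
        diag = np.diag(cov)
        if np.any(diag < 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError("indefinite J^T J")
        se = np.sqrt(s2 * diag)
    except np.linalg.LinAlgError:
        warnings.warn(
            "J^T J is singular: some parameters are not identifiable; "
            "standard errors are undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        se = np.full(n_free, np.nan)
    return dict(zip(free_names, se))


def _extend_errors(problem: FitProblem, se_free: dict[str, float]) -> dict[str, float]:
    """Propagate SEs to fixed (0) and tied (alpha * master) parameters."""
    ties = problem.constraints._as_map()
    out = dict(se_free)
    for p in problem.parameters:
        if p.fixed:
            out[p.name] = 0.0

    def se_of(name: str) -> float:
        if name in out:
            return out[name]
        master, alpha = ties[name]
        out[name] = alpha * se_of(master)
        return out[name]

    for dep in ties:
        se_of(dep)
    return out


def fit(
    problem: FitProblem,
    *,
    ftol: float = 1e-10,
    xtol: float = 1e-14,
    gtol: float = 1e-10,
    max_iter: int = 500,
    jac: str = "fd",
) -> FitResult:
    """Bounded trust-region least squares over the free parameters.

    ``jac`` selects the Jacobian route: ``"fd"`` (default) finite-
    differences the residuals; ``"sensitivity"`` integrates the forward
    sensitivity equations for an exact Jacobian — slower per iteration
    but immune to the derivative noise that can stall fits of sloppy
    multi-step mechanisms.

    Deterministic given identical inputs and starting estimates.  With
    every parameter fixed or tied to fixed roots, this is a zero-
    iteration "first approximation": the model is evaluated once at the
    supplied values.  Non-convergence within the iteration budget
    returns ``converged=False`` at the best point found — rerun from
    different starting estimates in that case.
    """
    free_names = problem.free_names
    if problem.n_data <= len(free_names):
        raise ValueError("need more data rows than free parameters")

    if not free_names:
        r = residuals(problem, np.empty(0))
        ssq = float(r @ r)
        est = problem.full_values(np.empty(0))
        return FitResult(
            estimates=est,
            standard_errors=_extend_errors(problem, {}),
            ssq=ssq, converged=True, iterations=0,
            trace=[(ssq, est)], free_names=[],
            message="all parameters fixed; first approximation only",
        )

    evals: list[tuple[float, np.ndarray]] = []
    x0 = problem.initial_free_vector()
    lo, hi = problem.bounds()

    # Rate constants and concentrations are positive and span many
    # decades; optimizing their logarithms turns the long curved
    # valleys typical of correlated kinetic parameters into far better
    # conditioned ones.  Parameters starting at 0 (or with negative
    # bounds) stay in linear space.
    use_log = (x0 > 0) & (lo >= 0)

    def to_external(u: np.ndarray) -> np.ndarray:
        x = u.copy()
        x[use_log] = np.exp(u[use_log])
        return x

    u0 = x0.copy()
    u0[use_log] = np.log(x0[use_log])
    with np.errstate(divide="ignore"):  # log(0) -> -inf is the open bound
        ulo = np.where(use_log, np.log(np.maximum(lo, 0.0)), lo)
        uhi = np.where(use_log & (hi > 0), np.log(hi), hi)

    def objective(u: np.ndarray) -> np.ndarray:
        x = to_external(u)
        r = residuals(problem, x)
        evals.append((float(r @ r), x))
        return r

    if jac not in ("fd", "sensitivity"):
        raise ValueError("jac must be 'fd' or 'sensitivity'")
    jac_kw: dict = {"jac": "2-point"}
    if jac == "sensitivity":
        def jac_fn(u: np.ndarray) -> np.ndarray:
            x = to_external(u)
            pscale = np.where(use_log, x, 1.0)
            blocks = []
            for exp in problem.experiments:
                try:
                    blocks.append(-problem.signal_jacobian(exp, x, pscale))
                except IntegrationError:
                    # flat block: the penalty residuals already push
                    # the trust region back out of this area
                    blocks.append(np.zeros((len(exp.curve.times), len(u))))
            return np.vstack(blocks)

        jac_kw = {"jac": jac_fn}

    scale = np.where(use_log, 1.0, np.where(np.abs(x0) > 0, np.abs(x0), 1.0))
    budget = max_iter * (len(x0) + 1)
    res = None
    prev_ssq = None
    # restarting resets the trust region, which reliably unsticks the
    # solver after a run of rejected steps deep in a narrow valley
    for _ in range(6):
        res = least_squares(
            objective,
            u0 if res is None else res.x,
            bounds=(ulo, uhi),
            method="trf",
            x_scale=scale,
            ftol=ftol,
            xtol=xtol,
            gtol=gtol,
            max_nfev=max(budget - len(evals), len(x0) + 2),
            **jac_kw,
        )
        ssq_now = float(2.0 * res.cost)
        if prev_ssq is not None and not ssq_now < prev_ssq * (1.0 - 10 * ftol):
            break
        prev_ssq = ssq_now
        if len(evals) >= budget:
            break

    # accepted iterations = prefix minima of the evaluation log
    trace: list[tuple[float, dict[str, float]]] = []
    best = np.inf
    for ssq_i, x_i in evals:
        if ssq_i < best:
            best = ssq_i
            trace.append((ssq_i, problem.full_values(x_i)))

    x_opt = to_external(res.x)
    estimates = problem.full_values(x_opt)
    # chain rule back to linear space: dr/dx = dr/du / x for log params
    jac_lin = np.asarray(res.jac).copy()
    jac_lin[:, use_log] /= x_opt[use_log]
    se_free = standard_errors(jac_lin, res.fun, free_names)
    return FitResult(
        estimates=estimates,
        standard_errors=_extend_errors(problem, se_free),
        ssq=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        iterations=len(trace),
        trace=trace,
        free_names=list(free_names),
        message=str(res.message),
    )
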