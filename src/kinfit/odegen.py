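"""Mass-action ODE systems generated from reaction schemes.

Each elementary reaction r with rate constant k_r contributes the flux

    v_r = k_r * prod_s [s]^(order_{r,s})

where order_{r,s} is the stoichiometric coefficient of species s on the
reactant side of r (0, 1 or 2).  The species balance is then

    d[s]/dt = sum_r net_{r,s} * v_r,    net = products - reactants.

A reactant coefficient of 2 yields a plain [s]^2 rate law (no
combinatorial 1/2 factor).  Conservation laws are integer vectors w in
the left null space of the net-change matrix: w . d[c]/dt == 0 for every
state, e.g. [E]+[ES] and [S]+[ES]+[P] for the Michaelis-Menten scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy

from .scheme import ReactionScheme, validate_scheme

__all__ = [
    "StoichiometryMatrices",
    "ODESystem",
    "ConservationLaw",
    "generate_odes",
    "render_equations",
    "conservation_laws",
]


@dataclass(frozen=True)
class StoichiometryMatrices:
    """Reactant-order and net-change matrices, shape (reactions, species)."""

    reactant_orders: np.ndarray
    net_change: np.ndarray


@dataclass(frozen=True)
class ODESystem:
    """A compiled mass-action right-hand side for one scheme."""

    scheme: ReactionScheme
    matrices: StoichiometryMatrices
    species_names: tuple[str, ...]
    rate_labels: tuple[str, ...]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return self.matrices.net_change.shape[0]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def rate_vector(self, constants: Mapping[str, float]) -> np.ndarray:
        """Per-reaction rate constants resolved from a label->value map."""
        missing = [r.rate_label for r in self.scheme.reactions
                   if r.rate_label not in constants]
        if missing:
            raise KeyError(f"missing rate constants: {sorted(set(missing))}")
        k = np.array([float(constants[r.rate_label])
                      for r in self.scheme.reactions])
        if np.any(k < 0):
            raise ValueError("rate constants must be non-negative")
        return k

    def fluxes(self, k: np.ndarray, y: np.ndarray) -> np.ndarray:
        R = self.matrices.reactant_orders
        return k * np.prod(y[None, :] ** R, axis=1)

    def rhs(self, constants: Mapping[str, float]) -> Callable[[float, np.ndarray], np.ndarray]:
        """Return f(t, y) -> dy/dt for the given rate constants."""
        k = self.rate_vector(constants)
        N_T = self.matrices.net_change.T.astype(float)

        def f(t: float, y: np.ndarray) -> np.ndarray:
            return N_T @ self.fluxes(k, np.asarray(y, dtype=float))

        return f

    def jacobian(self, constants: Mapping[str, float]) -> Callable[[float, np.ndarray], np.ndarray]:
        """Analytic Jacobian d(dy/dt)/dy; exact for mass-action fluxes."""
        k = self.rate_vector(constants)
        R = self.matrices.reactant_orders
        N_T = self.matrices.net_change.T.astype(float)
        # per reaction: list of (species index, order) with order > 0
        terms = [[(j, int(R[i, j])) for j in np.nonzero(R[i])[0]]
                 for i in range(R.shape[0])]

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            y = np.asarray(y, dtype=float)
            dv = np.zeros_like(R, dtype=float)  # (reactions, species)
            for i, tl in enumerate(terms):
                for j, order in tl:
                    d = k[i] * order * y[j] ** (order - 1)
                    for j2, o2 in tl:
                        if j2 != j:
                            d *= y[j2] ** o2
                    dv[i, j] = d
            return N_T @ dv

        return jac


    def reaction_monomials(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction concentration monomials prod_s y_s^order — the
        flux of each reaction divided by its rate constant."""
        R = self.matrices.reactant_orders
        return np.prod(np.asarray(y, dtype=float)[None, :] ** R, axis=1)


def generate_odes(scheme: ReactionScheme) -> ODESystem:
    """Expand a validated scheme into its mass-action ODE system.

    Raises ``ValueError`` listing the diagnostics if the scheme has
    validation errors (warnings are allowed).
    """
    errors = [d for d in validate_scheme(scheme) if d.is_error]
    if errors:
        raise ValueError(
            "scheme has errors: " + "; ".join(d.message for d in errors)
        )
    names = scheme.species_names
    idx = {n: i for i, n in enumerate(names)}
    nr, ns = len(scheme.reactions), len(names)
    R = np.zeros((nr, ns), dtype=int)
    P = np.zeros((nr, ns), dtype=int)
    for i, r in enumerate(scheme.reactions):
        for name, coef in r.reactants:
            R[i, idx[name]] += coef
        for name, coef in r.products:
            P[i, idx[name]] += coef
    return ODESystem(
        scheme=scheme,
        matrices=StoichiometryMatrices(reactant_orders=R, net_change=P - R),
        species_names=tuple(names),
        rate_labels=tuple(scheme.rate_labels),
    )


def _monomial(label: str, species: Sequence[str], orders: np.ndarray) -> str:
    parts = [label]
    for j in np.nonzero(orders)[0]:
        parts.extend([f"[{species[j]}]"] * int(orders[j]))
    return "*".join(parts)


def render_equations(odesys: ODESystem) -> list[str]:
    """Render one canonical ``d[X]/dt = ...`` line per species.

    Terms appear in reaction order; a net coefficient of +-c > 1 renders
    as ``c*k*[..]``.  The output is deterministic, suitable for golden
    files.
    """
    R = odesys.matrices.reactant_orders
    N = odesys.matrices.net_change
    names = odesys.species_names
    lines = []
    for j, sp in enumerate(names):
        terms: list[tuple[int, str]] = []
        for i, rxn in enumerate(odesys.scheme.reactions):
            c = int(N[i, j])
            if c == 0:
                continue
            mono = _monomial(rxn.rate_label, names, R[i])
            terms.append((c, f"{abs(c)}*{mono}" if abs(c) > 1 else mono))
        if not terms:
            rhs = "0"
        else:
            first_c, first_t = terms[0]
            rhs = ("-" if first_c < 0 else "") + first_t
            for c, t in terms[1:]:
                rhs += (" - " if c < 0 else " + ") + t
        lines.append(f"d[{sp}]/dt = {rhs}")
    return lines


@dataclass(frozen=True)
class ConservationLaw:
    """Integer species weights w with w . d[c]/dt identically zero."""

    coefficients: tuple[int, ...]
    species_names: tuple[str, ...]

    def total(self, y: Mapping[str, float] | Sequence[float]) -> float:
        """Conserved total w . y for a concentration state."""
        if isinstance(y, Mapping):
            vec = [float(y.get(n, 0.0)) for n in self.species_names]
        else:
            vec = list(y)
        return float(np.dot(self.coefficients, vec))

    def __str__(self) -> str:
        parts = []
        for c, n in zip(self.coefficients, self.species_names):
            if c == 0:
                continue
            parts.append(f"[{n}]" if c == 1 else f"{c}*[{n}]")
        return " + ".join(parts)


def conservation_laws(odesys: ODESystem) -> list[ConservationLaw]:
    """Integer basis of the left null space of the net-change matrix.

    Computed over the rationals, reduced to a canonical (RREF) basis,
    scaled to smallest integers with a positive leading entry, and
    ordered by the index of the first species with nonzero weight.
    Returns an empty list when the scheme conserves nothing.
    """
    N = sympy.Matrix(odesys.matrices.net_change.tolist())
    basis = N.nullspace()  # vectors w with N w = 0, i.e. w . dy/dt == 0
    if not basis:
        return []
    B = sympy.Matrix.hstack(*basis).T.rref()[0]
    laws = []
    for i in range(B.rows):
        row = list(B.row(i))
        if all(v == 0 for v in row):
            continue
        lcm = 1
        for v in row:
            lcm = sympy.ilcm(lcm, sympy.Rational(v).q)
        row = [int(sympy.Rational(v) * lcm) for v in row]
        g = 0
        for v in row:
            g = sympy.igcd(g, v)
        row = [v // g for v in row]
        lead = next(v for v in row if v != 0)
        if lead < 0:
            row = [-v for v in row]
        laws.append(ConservationLaw(tuple(row), odesys.species_names))
    laws.sort(key=lambda l: next(j for j, c in enumerate(l.coefficients) if c))
    return laws
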