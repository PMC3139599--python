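"""Reaction schemes and their plain-text DSL.

A scheme is a list of elementary reactions between named species, each
governed by a rate-constant label.  The DSL puts one reaction per line::

    E + S <-> ES ; k0, k1     # reversible: forward label, reverse label
    ES -> E + P ; k2          # irreversible
    ES -> 2 E ; k3            # integer stoichiometric coefficients

``#`` starts a comment, blank lines are ignored, and ``E + E`` is
normalized to ``2 E``.  Species names are case-sensitive (``SE`` and
``ES`` are different species) and may not contain whitespace or the DSL
metacharacters ``+ > < ; # ,``.  Total reactant molecularity of an
elementary step is at most 2 — enzyme mechanisms are built from uni- and
bimolecular steps only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Species",
    "Reaction",
    "ReactionScheme",
    "Diagnostic",
    "SchemeError",
    "parse_scheme",
    "render_scheme",
    "validate_scheme",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")


class SchemeError(ValueError):
    """Raised for malformed scheme text or invalid scheme structure."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Species:
    """A chemical species, identified by its short label (E, S, ES, ...)."""

    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Reaction:
    """One elementary step: reactants -> products with a rate label.

    ``reactants`` and ``products`` are tuples of (species name, integer
    coefficient >= 1).  ``rate_label`` names the mass-action rate
    constant; the same label may govern several steps.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_label: str

    @property
    def molecularity(self) -> int:
        return sum(c for _, c in self.reactants)


@dataclass
class ReactionScheme:
    """An ordered collection of species and elementary reactions."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def rate_labels(self) -> list[str]:
        """Distinct rate-constant labels in first-use order."""
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.rate_label, None)
        return list(seen)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionScheme):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions


def _check_name(name: str, line: int | None) -> str:
    if not _NAME_RE.match(name):
        raise SchemeError(
            f"invalid species name {name!r} (letters, digits and _ only; "
            "must not start with a digit)",
            line,
        )
    return name


def _parse_side(text: str, line: int, *, allow_empty: bool) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        if allow_empty:
            return ()
        raise SchemeError("empty product side is not allowed", line)
    counts: dict[str, int] = {}
    for raw in text.split("+"):
        term = raw.strip()
        if not term:
            raise SchemeError(f"empty term in side {text!r}", line)
        m = _TERM_RE.match(term)
        if m is None:
            raise SchemeError(
                f"malformed term {term!r} (expected '[int] Name')", line
            )
        coef_s, name = m.groups()
        if re.fullmatch(r"\d+", name):
            raise SchemeError(
                f"malformed term {term!r}: species name cannot be a number "
                "(duplicate coefficient?)",
                line,
            )
        coef = int(coef_s) if coef_s else 1
        if coef < 1:
            raise SchemeError(f"coefficient must be >= 1 in term {term!r}", line)
        _check_name(name, line)
        counts[name] = counts.get(name, 0) + coef
    return tuple(counts.items())


def parse_scheme(text: str) -> ReactionScheme:
    """Parse scheme-DSL source into a :class:`ReactionScheme`.

    Species are registered in first-mention order; a reversible line
    expands into a forward and a reverse :class:`Reaction` (in that
    order); omitted coefficients default to 1.

    Raises :class:`SchemeError` with the offending line number for
    syntax errors, molecularity > 2, or a reversible arrow without
    exactly two rate labels.
    """
    if not text.strip():
        raise SchemeError("scheme text is empty")
    species_order: dict[str, None] = {}
    reactions: list[Reaction] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ";" not in line:
            raise SchemeError("missing ';' before rate label(s)", lineno)
        body, label_part = line.rsplit(";", 1)
        labels = [t.strip() for t in label_part.split(",") if t.strip()]
        if "<->" in body:
            arrow = "<->"
            if len(labels) != 2:
                raise SchemeError(
                    "reversible reaction needs exactly two rate labels "
                    f"(got {len(labels)})",
                    lineno,
                )
        elif "->" in body:
            arrow = "->"
            if len(labels) != 1:
                raise SchemeError(
                    f"irreversible reaction needs exactly one rate label "
                    f"(got {len(labels)})",
                    lineno,
                )
        else:
            raise SchemeError("missing reaction arrow '->' or '<->'", lineno)
        for lab in labels:
            _check_name(lab, lineno)
        lhs_text, rhs_text = body.split(arrow, 1)
        lhs = _parse_side(lhs_text, lineno, allow_empty=True)
        rhs = _parse_side(rhs_text, lineno, allow_empty=False)
        if sum(c for _, c in lhs) > 2:
            raise SchemeError(
                "total reactant molecularity exceeds 2; elementary steps "
                "must be uni- or bimolecular",
                lineno,
            )
        if arrow == "<->" and sum(c for _, c in rhs) > 2:
            raise SchemeError(
                "reverse direction has molecularity > 2", lineno
            )
        for name, _ in (*lhs, *rhs):
            species_order.setdefault(name, None)
        reactions.append(Reaction(lhs, rhs, labels[0]))
        if arrow == "<->":
            reactions.append(Reaction(rhs, lhs, labels[1]))

    if not reactions:
        raise SchemeError("scheme contains no reactions")
    return ReactionScheme(
        species=[Species(n) for n in species_order],
        reactions=reactions,
    )


def _render_side(side: tuple[tuple[str, int], ...]) -> str:
    return " + ".join(f"{c} {n}" if c > 1 else n for n, c in side)


def render_scheme(scheme: ReactionScheme) -> str:
    """Serialize a scheme back to DSL text (one irreversible line per
    reaction).  ``parse_scheme(render_scheme(s)) == s`` for any valid
    scheme."""
    lines = [
        f"{_render_side(r.reactants)} -> {_render_side(r.products)} ; {r.rate_label}"
        for r in scheme.reactions
    ]
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Diagnostic:
    """A validation finding: ``level`` is 'error' or 'warning'."""

    level: str
    message: str

    @property
    def is_error(self) -> bool:
        return self.level == "error"


def validate_scheme(scheme: ReactionScheme) -> list[Diagnostic]:
    """Structural validation; returns diagnostics (empty list = clean).

    Errors break the mass-action contract (bad coefficients, unknown
    species, molecularity > 2, no reactions).  Warnings flag suspicious
    but legal structure: terminal products, pure reactants, a rate label
    shared between steps, or a source term with no reactants.
    """
    out: list[Diagnostic] = []
    err = lambda m: out.append(Diagnostic("error", m))
    warn = lambda m: out.append(Diagnostic("warning", m))

    declared = set()
    for sp in scheme.species:
        if not _NAME_RE.match(sp.name):
            err(f"invalid species name {sp.name!r}")
        if sp.name in declared:
            err(f"duplicate species {sp.name!r}")
        declared.add(sp.name)
    if not scheme.reactions:
        err("scheme has no reactions")

    produced: set[str] = set()
    consumed: set[str] = set()
    label_use: dict[str, int] = {}
    for i, r in enumerate(scheme.reactions):
        for name, coef in (*r.reactants, *r.products):
            if name not in declared:
                err(f"reaction {i}: species {name!r} not declared in scheme")
            if coef < 1:
                err(f"reaction {i}: coefficient {coef} for {name!r} must be >= 1")
        if r.molecularity > 2:
            err(f"reaction {i}: molecularity {r.molecularity} exceeds 2")
        if not r.reactants:
            warn(f"reaction {i}: source term (no reactants)")
        if not r.products:
            err(f"reaction {i}: no products")
        consumed.update(n for n, _ in r.reactants)
        produced.update(n for n, _ in r.products)
        label_use[r.rate_label] = label_use.get(r.rate_label, 0) + 1

    for name in scheme.species_names:
        if name not in produced and name in consumed:
            warn(f"species {name!r} is never produced")
        if name not in consumed and name in produced:
            warn(f"species {name!r} is never consumed")
        if name not in produced and name not in consumed:
            warn(f"species {name!r} is not used by any reaction")
    for lab, n in label_use.items():
        if n > 1:
            warn(f"rate label {lab!r} governs {n} reactions")
    return out
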