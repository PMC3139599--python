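"""Derive the mass-action ODE system of a reaction scheme.

Builds the classic single-intermediate enzyme scheme (E + S <-> ES -> E + P)
from its one-line-per-reaction text form, prints the automatically
generated differential equations, and lists the conservation laws found
in the stoichiometry.
"""

from kinfit import conservation_laws, generate_odes, parse_scheme, render_equations

scheme = parse_scheme("""
E + S <-> ES ; k0, k1    # binding / dissociation
ES -> E + P ; k2         # catalysis
""")
odesys = generate_odes(scheme)

print("Differential equations:")
for line in render_equations(odesys):
    print(" ", line)

print("\nConservation laws (linear combinations with zero time derivative):")
for law in conservation_laws(odesys):
    print("  d/dt (", law, ") = 0")

# The first law is total enzyme ([E] + [ES]), the second total substrate
# moiety ([S] + [ES] + [P]): together they reduce the 4-dimensional
# system to 2 independent state variables.
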