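from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import kinfit as kf
from kinfit import synth

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GOLDEN = Path(__file__).parent / "golden"

MM_SCHEME = "E + S <-> ES ; k0, k1\nES -> E + P ; k2\n"


@pytest.fixture(scope="session")
def mm_odesys():
    return kf.generate_odes(kf.parse_scheme(MM_SCHEME))


@pytest.fixture(scope="session")
def autoactivation_odesys():
    return kf.generate_odes(kf.parse_scheme(synth.AUTOACTIVATION_SCHEME))


@pytest.fixture(scope="session")
def cholinesterase_odesys():
    return kf.generate_odes(kf.parse_scheme(synth.CHOLINESTERASE_SCHEME))


def mm_rhs_oracle(k, y):
    """Hand-coded Michaelis-Menten derivatives, species order E,S,ES,P."""
    E, S, ES, P = y
    k0, k1, k2 = k["k0"], k["k1"], k["k2"]
    v = k0 * E * S
    return np.array([-v + (k1 + k2) * ES,
                     -v + k1 * ES,
                     v - (k1 + k2) * ES,
                     k2 * ES])


def autoactivation_rhs_oracle(k, y):
    """Hand-coded autocatalytic activation derivatives, order E,S,ES."""
    E, S, ES = y
    k0, k1, k2 = k["k0"], k["k1"], k["k2"]
    v = k0 * E * S
    return np.array([-v + k1 * ES + 2.0 * k2 * ES,
                     -v + k1 * ES,
                     v - (k1 + k2) * ES])


def cholinesterase_rhs_oracle(k, y):
    """Hand-coded derivatives for the two-site cholinesterase scheme,
    species order E, S, SE, ES, EA, P, SES, SEA, EAS, SEAS."""
    E, S, SE, ES, EA, P, SES, SEA, EAS, SEAS = y
    g = lambda n: k[f"k{n}"]
    return np.array([
        -g(0)*E*S + g(1)*SE + g(5)*EA,                                  # E
        (-g(0)*E*S + g(1)*SE - g(6)*ES*S + g(7)*SES
         - g(8)*EA*S + g(9)*SEA - g(14)*EAS*S + g(15)*SEAS),            # S
        g(0)*E*S - (g(1) + g(2))*SE + g(3)*ES + g(11)*SEA,              # SE
        g(2)*SE - (g(3) + g(4))*ES - g(6)*ES*S + g(7)*SES,              # ES
        g(4)*ES - g(5)*EA - g(8)*EA*S + g(9)*SEA,                       # EA
        g(4)*ES + g(10)*SES,                                            # P
        g(6)*ES*S - (g(7) + g(10))*SES,                                 # SES
        (g(8)*EA*S - g(9)*SEA + g(10)*SES - g(11)*SEA
         - g(12)*SEA + g(13)*EAS),                                      # SEA
        g(12)*SEA - g(13)*EAS - g(14)*EAS*S + g(15)*SEAS,               # EAS
        g(14)*EAS*S - g(15)*SEAS,                                       # SEAS
    ])


RHS_ORACLES = {
    "mm": (MM_SCHEME, mm_rhs_oracle),
    "autoactivation": (synth.AUTOACTIVATION_SCHEME, autoactivation_rhs_oracle),
    "cholinesterase": (synth.CHOLINESTERASE_SCHEME, cholinesterase_rhs_oracle),
}
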