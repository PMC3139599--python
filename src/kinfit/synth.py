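"""Synthetic progress-curve datasets for three classic kinetics studies.

Each generator forward-simulates a scheme at known ("truth") parameter
values on realistic grids, adds i.i.d. Gaussian noise on the observed
signal, and records every generating value, so that fits can be scored
against an exact oracle.  The three scenarios:

``titration``
    Active-site titration of acetylcholinesterase with the tight-binding
    inhibitor TMTFA: E + I -> EI, effectively irreversible, second-order
    k0 ~ 4.7e4 /M/s.  Three curves at titrant levels 0.11/0.165/0.22 uM
    with approximately equimolar enzyme; the signal is residual activity
    (OD/min) proportional to free E.  Times in seconds.

``autoactivation``
    Zymogen autoactivation (procathepsin B): E + S <-> ES, ES -> 2 E.
    Diffusion-limited k0 = 1e8 /M/min (fixed when fitting), Ks = k1/k0
    ~ 1.9 uM, kcat = k2 ~ 0.11 /min.  The measured species is E + ES
    (complex dissociates instantly in the assay); the curves show the
    lag-burst-plateau shape of autocatalysis.  Times in minutes.

``cholinesterase``
    Butyrylcholinesterase with butyrylthiocholine: a 10-species scheme
    with peripheral (PAS) and catalytic (CAS) substrate sites, covalent
    acyl-enzyme EA, substrate activation (k10 = 2*k4, k11 = 50*k5) and
    high-substrate inhibition through the dead-end SEAS complex.  The
    16 rate labels obey the tie set k14=k8=k6=k0, k15=k9=k7=k2=k1,
    k13=k3, k10=2*k4, k11=50*k5 with k0 fixed at 8.8e6 /M/s.  Fourteen
    substrate levels from 2 uM to 20 mM; thiocholine (P) is measured
    and each curve stops once ~70 uM of product has formed (or the
    substrate is exhausted).  Times in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fitting import (
    DEFAULT_UPPER,
    Experiment,
    FitProblem,
    Parameter,
    ParameterSet,
)
from .io import ProgressCurve, write_progress_curve
from .odegen import ODESystem, generate_odes
from .scheme import parse_scheme
from .simulate import Observable, integrate, observe

__all__ = [
    "TITRATION_SCHEME",
    "AUTOACTIVATION_SCHEME",
    "CHOLINESTERASE_SCHEME",
    "CHOLINESTERASE_TIES",
    "ScenarioSpec",
    "SyntheticDataset",
    "titration_spec",
    "autoactivation_spec",
    "cholinesterase_spec",
    "make_titration",
    "make_autoactivation",
    "make_cholinesterase",
    "make_scenario",
    "write_scenario",
]

TITRATION_SCHEME = "E + I -> EI ; k0\n"

AUTOACTIVATION_SCHEME = "E + S <-> ES ; k0, k1\nES -> 2 E ; k2\n"

CHOLINESTERASE_SCHEME = """\
# substrate binds the peripheral site (PAS), descends to the catalytic
# site (CAS), acylates the enzyme releasing thiocholine P; a second
# substrate on the PAS accelerates acylation and deacylation; substrate
# on the CAS of the acyl-enzyme blocks deacylation (dead end via SEAS)
E + S <-> SE ; k0, k1
SE <-> ES ; k2, k3
ES -> EA + P ; k4
EA -> E ; k5
ES + S <-> SES ; k6, k7
EA + S <-> SEA ; k8, k9
SES -> SEA + P ; k10
SEA -> SE ; k11
SEA <-> EAS ; k12, k13
EAS + S <-> SEAS ; k14, k15
"""

# dependent -> (master, multiplier)
CHOLINESTERASE_TIES: list[tuple[str, str, float]] = [
    ("k6", "k0", 1.0),
    ("k8", "k0", 1.0),
    ("k14", "k0", 1.0),
    ("k2", "k1", 1.0),
    ("k7", "k1", 1.0),
    ("k9", "k1", 1.0),
    ("k15", "k1", 1.0),
    ("k13", "k3", 1.0),
    ("k10", "k4", 2.0),
    ("k11", "k5", 50.0),
]

PRODUCT_CEILING = 7.0e-5  # M of thiocholine; assay window ends here


@dataclass
class ScenarioSpec:
    """Fully determined recipe for one synthetic dataset."""

    scenario: str
    scheme_text: str
    constants: dict[str, float]
    initial_conditions: list[dict[str, float]]  # one map per curve
    time_grids: list[np.ndarray]
    observable: Observable
    noise_sd: float
    seed: int
    fixed_constants: tuple[str, ...] = ()
    ties: list[tuple[str, str, float]] = field(default_factory=list)
    free_y0: list[tuple[str, float, float]] = field(default_factory=list)
    # free_y0: (species, lower, upper) fitted per curve; others fixed

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g in self.time_grids:
            g = np.asarray(g)
            if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
                raise ValueError("time grids must be strictly increasing")
        if len(self.time_grids) != len(self.initial_conditions):
            raise ValueError("one time grid per curve is required")
        for dep, master, alpha in self.ties:
            want = alpha * self.constants[master]
            have = self.constants[dep]
            if not np.isclose(have, want, rtol=1e-12, atol=0.0):
                raise ValueError(
                    f"constants violate tie {dep} = {alpha:g}*{master}: "
                    f"{have:g} != {want:g}"
                )


@dataclass
class SyntheticDataset:
    """Generated curves plus the truth record that produced them."""

    spec: ScenarioSpec
    odesys: ODESystem
    curves: list[ProgressCurve]
    clean_signals: list[np.ndarray]
    truth: dict

    def fit_problem(self, perturb: float = 1.0, *, noise_free: bool = False,
                    rtol: float = 1e-8, atol: float = 1e-12) -> FitProblem:
        """Build the matching fit problem with the scenario's fixed/tie
        structure.

        Starting estimates are the truth values alternately multiplied
        and divided by ``perturb`` (deterministic), emulating rough
        initial guesses.  ``noise_free=True`` fits against the clean
        signals instead of the noisy curves.
        """
        spec = self.spec
        params = ParameterSet()
        ties = {dep: (master, alpha) for dep, master, alpha in spec.ties}
        flip = 0

        def start(v: float) -> float:
            nonlocal flip
            f = perturb if flip % 2 == 0 else 1.0 / perturb
            flip += 1
            return v * f

        for label in self.odesys.rate_labels:
            if label in ties:
                params.add(Parameter(label, tie=ties[label]))
            elif label in spec.fixed_constants:
                params.add(Parameter(label, value=spec.constants[label],
                                     fixed=True))
            else:
                params.add(Parameter(label, value=start(spec.constants[label]),
                                     lower=0.0, upper=DEFAULT_UPPER))

        free_y0 = {sp: (lo, hi) for sp, lo, hi in spec.free_y0}
        experiments = []
        for i, (curve, y0_true) in enumerate(zip(self.curves,
                                                 spec.initial_conditions)):
            if noise_free:
                curve = ProgressCurve(curve.name, curve.times,
                                      self.clean_signals[i])
            y0: dict[str, float | str] = {}
            for sp in self.odesys.species_names:
                if sp in free_y0:
                    lo, hi = free_y0[sp]
                    pname = f"curve{i}:{sp}"
                    params.add(Parameter(pname, value=start(y0_true[sp]),
                                         lower=lo, upper=hi))
                    y0[sp] = pname
                else:
                    y0[sp] = y0_true[sp]
            experiments.append(Experiment(curve=curve, y0=y0,
                                          observable=spec.observable))
        return FitProblem(odesys=self.odesys, experiments=experiments,
                          parameters=params, rtol=rtol, atol=atol)


def _generate(spec: ScenarioSpec, *, rtol: float = 1e-10,
              atol: float = 1e-16) -> SyntheticDataset:
    # atol well below the nM-scale species of the built-in scenarios
    odesys = generate_odes(parse_scheme(spec.scheme_text))
    rng = np.random.default_rng(spec.seed)
    curves, clean = [], []
    for i, (y0, grid) in enumerate(zip(spec.initial_conditions,
                                       spec.time_grids)):
        traj = integrate(odesys, spec.constants, y0, grid,
                         rtol=rtol, atol=atol)
        signal = observe(traj, spec.observable)
        clean.append(signal)
        noisy = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape) \
            if spec.noise_sd > 0 else signal.copy()
        curves.append(ProgressCurve(f"{spec.scenario}{i + 1}.dat",
                                    np.asarray(grid, dtype=float), noisy))
    truth = {
        "scenario": spec.scenario,
        "constants": {k: float(v) for k, v in spec.constants.items()},
        "initial_conditions": [
            {k: float(v) for k, v in y0.items()}
            for y0 in spec.initial_conditions
        ],
        "observable": {"weights": dict(spec.observable.weights),
                       "scale": spec.observable.scale},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "fixed_constants": list(spec.fixed_constants),
        "ties": [list(t) for t in spec.ties],
        "free_y0": [list(t) for t in spec.free_y0],
    }
    return SyntheticDataset(spec=spec, odesys=odesys, curves=curves,
                            clean_signals=clean, truth=truth)


# -- scenario 1: active-site titration -------------------------------

TITRATION_K0 = 4.7228e4          # /M/s, second-order association
TITRATION_I0 = (0.11e-6, 0.165e-6, 0.22e-6)   # M added titrant
TITRATION_E0 = (0.15e-6, 0.21e-6, 0.28e-6)    # M, approximately equimolar
TITRATION_SCALE = 2.6e6          # OD/min of activity per M free enzyme


def titration_spec(seed: int = 0, noise_sd: float = 0.005) -> ScenarioSpec:
    """Three titration curves, 0-600 s sampled every 5 s; the signal is
    residual activity in OD/min (~1% noise at the default sd)."""
    grid = np.arange(0.0, 600.0 + 2.5, 5.0)
    return ScenarioSpec(
        scenario="titration",
        scheme_text=TITRATION_SCHEME,
        constants={"k0": TITRATION_K0},
        initial_conditions=[
            {"E": e0, "I": i0, "EI": 0.0}
            for e0, i0 in zip(TITRATION_E0, TITRATION_I0)
        ],
        time_grids=[grid.copy() for _ in TITRATION_E0],
        observable=Observable(weights={"E": 1.0}, scale=TITRATION_SCALE),
        noise_sd=noise_sd,
        seed=seed,
        free_y0=[("E", 0.0, DEFAULT_UPPER), ("I", 0.0, DEFAULT_UPPER)],
    )


def make_titration(spec: ScenarioSpec | None = None, *, seed: int = 0,
                   noise_sd: float = 0.005) -> SyntheticDataset:
    return _generate(spec or titration_spec(seed=seed, noise_sd=noise_sd))


# -- scenario 2: zymogen autoactivation ------------------------------

AUTOACTIVATION_CONSTANTS = {"k0": 1.0e8, "k1": 190.0, "k2": 0.11}
# /M/min, /min, /min -> Ks = k1/k0 = 1.9 uM, kcat = 0.11 /min
AUTOACTIVATION_S0 = (1.5e-6, 3.0e-6, 6.0e-6, 1.2e-5)   # M precursor
AUTOACTIVATION_E0 = (2.0e-8, 5.0e-8, 8.0e-8, 1.0e-7)   # M active at t=0


def autoactivation_spec(seed: int = 0, noise_sd: float = 5e-8) -> ScenarioSpec:
    """Four precursor concentrations, 0-300 min sampled every minute;
    total protein per curve is known and fixed, the initial active
    fraction is fitted per curve (it depends on sample age)."""
    grid = np.arange(0.0, 300.0 + 0.5, 1.0)
    return ScenarioSpec(
        scenario="autoactivation",
        scheme_text=AUTOACTIVATION_SCHEME,
        constants=dict(AUTOACTIVATION_CONSTANTS),
        initial_conditions=[
            {"E": e0, "S": s0, "ES": 0.0}
            for e0, s0 in zip(AUTOACTIVATION_E0, AUTOACTIVATION_S0)
        ],
        time_grids=[grid.copy() for _ in AUTOACTIVATION_S0],
        observable=Observable(weights={"E": 1.0, "ES": 1.0}, scale=1.0),
        noise_sd=noise_sd,
        seed=seed,
        fixed_constants=("k0",),           # diffusion limited, fixed
        free_y0=[("E", 0.0, 1.0)],         # fitted in [0, 1]
    )


def make_autoactivation(spec: ScenarioSpec | None = None, *, seed: int = 0,
                        noise_sd: float = 5e-8) -> SyntheticDataset:
    return _generate(spec or autoactivation_spec(seed=seed,
                                                 noise_sd=noise_sd))


# -- scenario 3: cholinesterase with substrate activation/inhibition --

CHOLINESTERASE_FREE_CONSTANTS = {
    "k0": 8.8e6,    # /M/s, PAS association (fixed when fitting)
    "k1": 3000.0,   # /s, PAS dissociation
    "k3": 1500.0,   # /s, CAS -> PAS backward partition
    "k4": 300.0,    # /s, acylation
    "k5": 500.0,    # /s, deacylation
    "k12": 2000.0,  # /s, descent to the CAS of the acyl-enzyme
}
CHOLINESTERASE_E0 = 2.6e-9  # M, from independent active-site titration
CHOLINESTERASE_S0 = (
    2e-6, 5e-6, 1e-5, 2e-5, 4.35e-6, 7.63e-6,
    1.6e-4, 5e-4, 1e-3, 2e-3, 5e-3, 1e-2, 2e-2, 5e-3,
)  # M, the 14 assay substrate levels
_CHOL_TMAX = 6000.0   # s, absolute assay cutoff
_CHOL_NPOINTS = 121   # samples per curve


def _cholinesterase_constants(free: dict[str, float]) -> dict[str, float]:
    out = dict(free)
    for dep, master, alpha in CHOLINESTERASE_TIES:
        out[dep] = alpha * out[master]
    return out


def cholinesterase_spec(seed: int = 0, noise_sd: float = 3e-7,
                        constants: dict[str, float] | None = None) -> ScenarioSpec:
    """Fourteen substrate levels spanning 2 uM - 20 mM at 2.6 nM enzyme.

    Per-curve grids are computed from the truth model: each curve ends
    when ~70 uM product has formed or the substrate is 98% consumed
    (whichever first, capped at 6000 s), emulating the limited assay
    window of the colorimetric detection.  ``constants`` may override
    the full 16-label map but must satisfy the tie set exactly.
    """
    constants = constants or _cholinesterase_constants(
        CHOLINESTERASE_FREE_CONSTANTS
    )
    odesys = generate_odes(parse_scheme(CHOLINESTERASE_SCHEME))
    ics, grids = [], []
    for s0 in CHOLINESTERASE_S0:
        y0 = {sp: 0.0 for sp in odesys.species_names}
        y0["E"] = CHOLINESTERASE_E0
        y0["S"] = s0
        ics.append(y0)
        # dense truth run to locate the end of the assay window
        dense = np.linspace(0.0, _CHOL_TMAX, 2401)
        traj = integrate(odesys, constants, y0, dense, rtol=1e-8, atol=1e-14)
        p = traj["P"]
        target = min(PRODUCT_CEILING, 0.98 * s0)
        above = np.nonzero(p >= target)[0]
        if above.size and above[0] > 0:
            j = above[0]
            # linear interpolation of the crossing time
            t_end = dense[j - 1] + (dense[j] - dense[j - 1]) * (
                (target - p[j - 1]) / (p[j] - p[j - 1])
            )
        else:
            t_end = _CHOL_TMAX
        grids.append(np.linspace(0.0, float(t_end), _CHOL_NPOINTS))
    return ScenarioSpec(
        scenario="cholinesterase",
        scheme_text=CHOLINESTERASE_SCHEME,
        constants=constants,
        initial_conditions=ics,
        time_grids=grids,
        observable=Observable(weights={"P": 1.0}, scale=1.0),
        noise_sd=noise_sd,
        seed=seed,
        fixed_constants=("k0",),
        ties=list(CHOLINESTERASE_TIES),
        free_y0=[],  # all initial concentrations independently known
    )


def make_cholinesterase(spec: ScenarioSpec | None = None, *, seed: int = 0,
                        noise_sd: float = 3e-7) -> SyntheticDataset:
    return _generate(spec or cholinesterase_spec(seed=seed,
                                                 noise_sd=noise_sd))


_MAKERS = {
    "titration": make_titration,
    "autoactivation": make_autoactivation,
    "cholinesterase": make_cholinesterase,
}


def make_scenario(name: str, *, seed: int = 0, **kw) -> SyntheticDataset:
    """Generate one of the built-in scenarios by name."""
    try:
        maker = _MAKERS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_MAKERS)}"
        ) from None
    return maker(seed=seed, **kw)


# -- on-disk scenario directories ------------------------------------

def write_scenario(ds: SyntheticDataset, outdir: str | Path,
                   *, start_perturb: float = 10.0) -> Path:
    """Write a ready-to-run scenario directory: the scheme file, one
    two-column .dat per curve, a fit config with perturbed starting
    estimates, and the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = ds.spec
    (outdir / "model.scheme").write_text(spec.scheme_text)
    for curve in ds.curves:
        write_progress_curve(outdir / curve.name, curve.times, curve.values)

    ties = {dep: (master, alpha) for dep, master, alpha in spec.ties}
    flip = 0

    def start(v: float) -> float:
        nonlocal flip
        f = start_perturb if flip % 2 == 0 else 1.0 / start_perturb
        flip += 1
        return v * f

    params: dict = {}
    for label in ds.odesys.rate_labels:
        if label in ties:
            master, alpha = ties[label]
            params[label] = {"tie": {"master": master, "factor": alpha}}
        elif label in spec.fixed_constants:
            params[label] = {"value": spec.constants[label], "fixed": True}
        else:
            params[label] = {"value": start(spec.constants[label]),
                             "bounds": [0.0, DEFAULT_UPPER]}

    free_y0 = {sp: (lo, hi) for sp, lo, hi in spec.free_y0}
    experiments = []
    for curve, y0 in zip(ds.curves, spec.initial_conditions):
        initial: dict = {}
        for sp in ds.odesys.species_names:
            if sp in free_y0:
                lo, hi = free_y0[sp]
                initial[sp] = {"value": start(y0[sp]), "bounds": [lo, hi]}
            else:
                initial[sp] = float(y0[sp])
        experiments.append({
            "curve": curve.name,
            "initial": initial,
            "measured": dict(spec.observable.weights),
            "scale": float(spec.observable.scale),
        })

    config = {
        "scheme": "model.scheme",
        "parameters": params,
        "experiments": experiments,
        "solver": {"rtol": 1e-8, "atol": 1e-12, "max_iter": 500},
    }
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=False)
    )
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=2) + "\n")
    return outdir
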