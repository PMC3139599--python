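"""Progress-curve files, fit configs and reports.

A progress curve is a two-column text file — time in the first column,
measured signal in the second — separated by any run of spaces or tabs.
Lines starting with ``#`` and blank lines are skipped.  Scientific
notation is accepted; comma decimal separators are not.  Multiple
curves can be bundled in a .zip archive, one member file per curve.

A fit config is a YAML document declaring the scheme file, one block
per rate constant (value / bounds / fixed / tie), one block per
experiment (curve file, initial concentrations, measured species,
response scale) and solver settings.  ``synth.write_scenario`` emits a
ready-to-run example for each built-in scenario.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import yaml

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .fitting import FitProblem, FitResult

__all__ = [
    "ProgressCurve",
    "CurveFormatError",
    "read_progress_curve",
    "read_curve_archive",
    "write_progress_curve",
    "NormalizationCurve",
    "titration_normalization",
    "FitConfig",
    "load_fit_config",
    "build_problem",
    "report_dict",
    "write_report",
    "write_fitted_curves",
]

REPORT_FORMAT_VERSION = 1


class CurveFormatError(ValueError):
    """Malformed progress-curve text."""


@dataclass(frozen=True)
class ProgressCurve:
    """One measured time course: strictly increasing times, >= 2 rows."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise CurveFormatError(f"{self.name}: columns of unequal length")
        if len(t) < 2:
            raise CurveFormatError(f"{self.name}: need at least 2 rows")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise CurveFormatError(f"{self.name}: non-finite entries")
        if np.any(np.diff(t) <= 0):
            raise CurveFormatError(f"{self.name}: times must strictly increase")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


def _parse_curve_text(text: str, name: str) -> ProgressCurve:
    times, values = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise CurveFormatError(
                f"{name}, line {lineno}: expected 2 columns, got {len(tokens)}"
            )
        try:
            t, v = float(tokens[0]), float(tokens[1])
        except ValueError:
            raise CurveFormatError(
                f"{name}, line {lineno}: non-numeric token in {line!r}"
            ) from None
        times.append(t)
        values.append(v)
    if len(times) < 2:
        raise CurveFormatError(f"{name}: fewer than 2 data rows")
    return ProgressCurve(name, np.array(times), np.array(values))


def read_progress_curve(path: str | Path) -> ProgressCurve:
    """Read one two-column progress-curve file."""
    path = Path(path)
    return _parse_curve_text(path.read_text(), path.name)


def read_curve_archive(path: str | Path) -> list[ProgressCurve]:
    """Read every parseable member of a .zip archive, ordered by member
    name; non-text/garbled members are skipped with a warning."""
    import warnings

    curves = []
    with zipfile.ZipFile(path) as zf:
        for info in sorted(zf.infolist(), key=lambda i: i.filename):
            if info.is_dir():
                continue
            data = zf.read(info)
            try:
                text = data.decode("utf-8")
                curves.append(_parse_curve_text(text, Path(info.filename).name))
            except (UnicodeDecodeError, CurveFormatError) as err:
                warnings.warn(
                    f"skipping archive member {info.filename!r}: {err}",
                    stacklevel=2,
                )
    if not curves:
        raise CurveFormatError(f"{path}: no parseable progress curves in archive")
    return curves


def write_progress_curve(path: str | Path, times, values, header: str | None = None) -> None:
    """Write a two-column curve in the same dialect the reader accepts."""
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(f"{t:.10g}\t{v:.10g}" for t, v in zip(times, values))
    Path(path).write_text("\n".join(lines) + "\n")


# -- active-site titration normalization -----------------------------


@dataclass(frozen=True)
class NormalizationCurve:
    """Linear map between titrant concentration and signal amplitude.

    Built from active-site titration: the drop between initial activity
    and the plateau, plotted against known added titrant, is linear;
    its slope converts any activity reading into an active-site
    concentration.
    """

    slope: float
    intercept: float

    def to_concentration(self, activity: float) -> float:
        return (activity - self.intercept) / self.slope

    def to_activity(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


def titration_normalization(
    amplitudes, concentrations, *, through_origin: bool = True
) -> NormalizationCurve:
    """Least-squares line through (concentration, amplitude) pairs.

    The intercept is forced to zero by default (no titrant, no
    amplitude); pass ``through_origin=False`` for an unconstrained line.
    """
    a = np.asarray(amplitudes, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if a.shape != c.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need >= 2 (amplitude, concentration) pairs")
    if np.ptp(c) == 0 and not through_origin:
        raise ValueError("concentrations have zero variance")
    if through_origin:
        if np.all(c == 0):
            raise ValueError("all concentrations are zero")
        slope = float(c @ a / (c @ c))
        return NormalizationCurve(slope=slope, intercept=0.0)
    A = np.column_stack([c, np.ones_like(c)])
    (slope, intercept), *_ = np.linalg.lstsq(A, a, rcond=None)
    return NormalizationCurve(slope=float(slope), intercept=float(intercept))


# -- fit configuration ------------------------------------------------


@dataclass
class FitConfig:
    """Parsed fit configuration (paths resolved against ``base_dir``)."""

    scheme_path: Path
    parameters: dict
    experiments: list[dict]
    solver: dict
    base_dir: Path


def load_fit_config(path: str | Path) -> FitConfig:
    """Load and structurally validate a YAML fit config."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("scheme", "parameters", "experiments"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key {key!r}")
    if not isinstance(doc["experiments"], list) or not doc["experiments"]:
        raise ValueError(f"{path}: 'experiments' must be a non-empty list")
    return FitConfig(
        scheme_path=path.parent / doc["scheme"],
        parameters=dict(doc["parameters"]),
        experiments=list(doc["experiments"]),
        solver=dict(doc.get("solver", {})),
        base_dir=path.parent,
    )


def _param_from_block(name: str, block) -> "object":
    from .fitting import DEFAULT_LOWER, DEFAULT_UPPER, Parameter

    if isinstance(block, (int, float)):
        return Parameter(name, value=float(block), fixed=True)
    if not isinstance(block, dict):
        raise ValueError(f"parameter {name!r}: block must be a number or mapping")
    if "tie" in block:
        tie = block["tie"]
        return Parameter(
            name, tie=(str(tie["master"]), float(tie.get("factor", 1.0)))
        )
    lo, hi = block.get("bounds", (DEFAULT_LOWER, DEFAULT_UPPER))
    return Parameter(
        name,
        value=float(block["value"]),
        lower=float(lo),
        upper=float(hi),
        fixed=bool(block.get("fixed", False)),
    )


def build_problem(config: FitConfig) -> "FitProblem":
    """Assemble a :class:`~kinfit.fitting.FitProblem` from a config."""
    from .fitting import Experiment, FitProblem, Parameter, ParameterSet
    from .odegen import generate_odes
    from .scheme import parse_scheme
    from .simulate import Observable

    scheme = parse_scheme(Path(config.scheme_path).read_text())
    odesys = generate_odes(scheme)

    params = ParameterSet()
    for label in odesys.rate_labels:
        if label not in config.parameters:
            raise ValueError(f"config has no parameter block for {label!r}")
        params.add(_param_from_block(label, config.parameters[label]))

    experiments = []
    for i, block in enumerate(config.experiments):
        curve_path = config.base_dir / block["curve"]
        if not curve_path.exists():
            raise FileNotFoundError(f"experiment {i}: curve file {curve_path}")
        curve = read_progress_curve(curve_path)
        y0: dict[str, float | str] = {}
        for sp in odesys.species_names:
            spec = block.get("initial", {}).get(sp, 0.0)
            if isinstance(spec, dict):
                pname = f"curve{i}:{sp}"
                params.add(_param_from_block(pname, spec))
                y0[sp] = pname
            else:
                y0[sp] = float(spec)
        weights = block.get("measured", {})
        if isinstance(weights, str):
            weights = {weights: 1.0}
        obs = Observable(weights=dict(weights),
                         scale=float(block.get("scale", 1.0)))
        experiments.append(Experiment(curve=curve, y0=y0, observable=obs))

    solver = config.solver
    return FitProblem(
        odesys=odesys,
        experiments=experiments,
        parameters=params,
        rtol=float(solver.get("rtol", 1e-8)),
        atol=float(solver.get("atol", 1e-12)),
    )


# -- reporting --------------------------------------------------------


def report_dict(result: "FitResult", *, include_trace: bool = True) -> dict:
    """JSON-ready fit report."""
    out = {
        "format_version": REPORT_FORMAT_VERSION,
        "converged": result.converged,
        "iterations": result.iterations,
        "ssq": result.ssq,
        "message": result.message,
        "free_parameters": list(result.free_names),
        "estimates": {k: float(v) for k, v in result.estimates.items()},
        "standard_errors": {k: float(v)
                            for k, v in result.standard_errors.items()},
    }
    if include_trace:
        out["trace"] = [
            {"ssq": s, "parameters": {k: float(v) for k, v in p.items()}}
            for s, p in result.trace
        ]
    return out


def write_report(result: "FitResult", path: str | Path, **kw) -> None:
    Path(path).write_text(json.dumps(report_dict(result, **kw), indent=2) + "\n")


def write_fitted_curves(result: "FitResult", problem: "FitProblem",
                        outdir: str | Path) -> list[Path]:
    """Write the model signal at the optimum, one two-column file per
    experiment, on each experiment's own time grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for exp, signal in zip(problem.experiments, result.fitted_curves(problem)):
        stem = Path(exp.curve.name).stem
        p = outdir / f"{stem}.fit.dat"
        write_progress_curve(p, exp.curve.times, signal,
                             header=f"fitted curve for {exp.curve.name}")
        paths.append(p)
    return paths
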