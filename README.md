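# kinfit

Mass-action ODE generation and global progress-curve fitting for enzyme
kinetics.

## The problem

The basic experiment in enzyme kinetics is a *progress curve*: the time
course of a measured signal (absorbance, fluorescence) that is linearly
related to the concentration of one or more reaction species.  Classical
initial-rate analysis throws away most of the information in such
curves, and closed-form solutions exist only for the simplest
single-step mechanisms.  The practical route is numerical: write the
mass-action differential equations of a proposed mechanism, integrate
them, and fit the rate constants to the measured curves — then repeat
for each rival mechanism.  Writing the ODE system by hand for every
mechanistic variant is tedious and error-prone; `kinfit` automates the
whole loop for anyone analyzing time-resolved enzyme (or general
chemical/pharmacokinetic) data.

## The model

A mechanism is a set of elementary uni- or bimolecular reactions.  For
reaction *r* with rate constant *k_r* and reactant stoichiometry
*o_{rs}*, mass action gives the flux

    v_r = k_r * prod_s [s]^(o_rs)

and the species balances

    d[s]/dt = sum_r (p_rs - o_rs) * v_r

where *p_rs* are product coefficients.  `kinfit` builds this system
from a one-line-per-reaction text scheme, e.g. the Michaelis–Menten
mechanism:

```
E + S <-> ES ; k0, k1
ES -> E + P ; k2
```

It also extracts the integer conservation laws (left null space of the
stoichiometry matrix, e.g. [E]+[ES] and [S]+[ES]+[P]), integrates the
stiff ODE system (LSODA, analytic Jacobian, rtol 1e-8 / atol 1e-12 by
default), and estimates parameters by bounded trust-region nonlinear
least squares over any number of curves at once.  Rate constants are
global; initial concentrations are per-curve.  Each parameter can be
free within bounds (default [0, 1e20]), fixed, or *tied* to another as
`dependent = alpha * master` — the standard way to encode known
equalities (k6 = k0) or activation ratios (k10 = 2*k4) and shrink the
number of unknowns.  Standard errors come from the linearized
covariance s²(JᵀJ)⁻¹ at the optimum.

A `synth` module generates three fully specified synthetic studies
(active-site titration, zymogen autoactivation, a 10-species
cholinesterase mechanism with substrate activation and inhibition) with
known ground truth, so every layer of the pipeline can be tested
without laboratory data.

## Worked example

Fit the shared association rate constant and per-curve initial
concentrations of a three-curve active-site titration (synthetic data,
~1% noise, starting estimates off by 10x):

```python
from kinfit import fit, synth

dataset = synth.make_titration(seed=1)
problem = dataset.fit_problem(perturb=10.0)
result = fit(problem, ftol=1e-14)
```

Output of `python examples/03_fit_titration.py`:

```
converged: True  accepted steps: 33
residual sum of squares: 0.007438

 parameter     estimate    std err        truth
        k0        47298        374        47228
  curve0:E   1.5022e-07   6.15e-10      1.5e-07
  curve0:I   1.1036e-07   8.07e-10      1.1e-07
  curve1:E   2.0911e-07   7.36e-10      2.1e-07
  curve1:I   1.6433e-07   8.41e-10     1.65e-07
  curve2:E   2.7949e-07   8.83e-10      2.8e-07
  curve2:I   2.1963e-07    8.8e-10      2.2e-07
```

`k0` is recovered as 47298 ± 374 M⁻¹s⁻¹ against a generating value of
4.7228e4; the fitted initial enzyme and titrant concentrations (molar)
land within a fraction of a percent of truth.  The other examples cover
equation generation, validation against the closed-form bimolecular
solution, fixed/free/per-curve parameters in the autoactivation model,
and tie constraints on the cholinesterase scheme.

## Command line

The same workflow is exposed as a thin CLI:

```bash
kinfit equations mm.scheme                     # print ODEs + conservation laws
kinfit simulate mm.scheme -k k0=1e5 -k k1=10 -k k2=1 \
       -y E=1e-6 -y S=1e-4 --times 0:600:5 --observable P
kinfit synth titration out/ --seed 1           # synthetic scenario directory
kinfit fit out/config.yaml                     # JSON report + fitted curves
```

Exit status 0 on success, 1 on user error, 2 on numerical failure.

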