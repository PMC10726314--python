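# triwater

Multiobjective parameterization and analysis of classical three-site
rigid water models.

Three-site rigid models (SPC, TIP3P, OPC3, TIP3P-FB, ...) describe water
with five parameters — the O–H bond length d_OH, the H–H distance d_HH,
the oxygen charge q_O (hydrogens carry −q_O/2), and the Lennard-Jones
σ and ε of the oxygen site.  Automatically optimizing those parameters
against experimental data is a multiobjective problem: microscopic
structure (the O–O, O–H and H–H radial distribution functions) pulls in
one direction, macroscopic observables (density ρ, static dielectric
constant ε) in another.  `triwater` provides the full toolchain for
studying this problem on a desk:

- **Models and moments** — presets with full-precision literature
  parameters; analytic dipole μ = 2(−q_O/2) d_OH cos(θ/2) and traceless
  quadrupoles Q_t = (Θ_xx−Θ_yy)/2, Q_0 = Θ_zz in the C2v frame.
- **Scoring** — a squared-cost Earth-mover's (Wasserstein) distance
  between RDFs, exactly computed by the 1-D monotone coupling, combined
  with relative density/dielectric errors into a weighted score
  S = 0.5·⟨EMD²/EMD²_ref⟩ + 0.3·⟨|Δρ|/ρ⟩ + 0.2·⟨|Δε|/ε⟩.
- **Observables** — density, dipole-fluctuation dielectric constant and
  its DMS scaling ε_λ = 1 + λ²(ε−1) with λ = μ_DMS/μ_PES, Einstein
  self-diffusion with 1/L finite-size extrapolation, vaporization
  enthalpy with depolarization correction, fluctuation-formula c_p,
  α_T, κ_T, slab surface tension, a rectilinear-diameter + Wegner
  critical-point fit (β = 0.325, Δ = 0.50), and the temperature of
  maximum density.
- **Optimizer** — bounded particle-swarm optimization (15 or 26
  particles) with optional per-particle self-tuning, swarm-collapse
  termination, and seeded multi-run ensembles.
- **Surrogate** — an analytic stand-in for the MD evaluator whose
  outputs depend on charge and geometry *only through the dipole
  μ = q·d*, reproducing the intrinsic degeneracy of three-site
  optimization with known ground truth and no simulations.
- **Ensemble analysis** — PCA of solution sets, KDE density isolines,
  and a degeneracy report contrasting CV(μ) with CV(q_O), CV(d_OH).

## Worked example

Electrostatic moments of the bundled models
(`python examples/electrostatic_moments.py`):

```
model       mu [D]  Q_t [D*A]  Q_0 [B]   angle
SPC           2.27       1.97     0.00 109.47deg
SPCE          2.35       2.04     0.00 109.47deg
SPCEb         2.37       2.08     0.00 109.47deg
TIP3P         2.35       1.72     0.23 104.52deg
TIP3P-FB      2.42       2.05     0.07 108.15deg
OPC3          2.43       2.06     0.00 109.47deg
```

μ is the molecular dipole in Debye; Q_t and Q_0 are the tetrahedral and
linear quadrupole moments (1 B = 1 D·Å).  Models constrained to the
tetrahedral angle have Q_0 = 0 exactly.

The dipole degeneracy (`python examples/dipole_degeneracy.py`, ~1–2 min):
six independent swarm optimizations against surrogate targets generated
from OPC3 at 280/298/343 K converge to *different* parameter sets with
the *same* dipole:

```
run   mu [D]   q_O [e]   d_OH [nm]   score
  0   2.4296   -1.0091    0.10084  0.00069
  1   2.4296   -0.7253    0.10635  0.00070
  2   2.4296   -0.9065    0.09339  0.00069
  3   2.4296   -1.0003    0.09657  0.00069
  4   2.4296   -1.0052    0.09437  0.00070
  5   2.4296   -1.0168    0.10065  0.00069

reference dipole: 2.4300 D
CV(mu)   = 0.00000
CV(q_O)  = 0.11086
CV(d_OH) = 0.04500
degenerate: True
```

The optimization is sharp in the composite variable μ = q·d but
ill-posed in charge and geometry individually: larger charges pair with
smaller molecules and vice versa, all scoring alike.  Other examples
cover the composite score (`score_rdfs.py`), the fluctuation estimators
(`fluctuation_observables.py`), and the critical-point fit
(`critical_point.py`).

## Command line

A thin CLI wraps the library:

```sh
triwater model --preset OPC3 --moments
triwater surrogate --model OPC3 --temps 280 298 343 --out targets/
triwater score --sim-rdf gOO.dat gOH.dat gHH.dat --target-rdf ... \
    --rho 0.997 --eps 88.7 --target-rho 1.0 --target-eps 78.4
triwater observables critfit coexistence.dat
triwater optimize --config run.yaml --seed 3 --out run3.json
triwater ensemble --runs runs/ --report report.txt --plot-data pca.dat
```

## Layout

```
src/triwater/      models, observables, scoring, swarm, surrogate,
                   ensemble, workflow, io, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property, end-to-end)
docs/methods.md    models, conventions, numerical choices, limitations
```
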