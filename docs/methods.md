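# Methods

`triwater` implements the parameterization and analysis machinery for
classical three-site rigid water models: the model representation and its
analytic electrostatic moments, the composite structural + thermodynamic
score used to rank candidate models, a bounded particle-swarm optimizer,
the standard suite of NpT fluctuation observables and coexistence fits,
and an analytic surrogate evaluator that makes the whole optimization
loop runnable without molecular dynamics.  This note records the models,
conventions, numerical choices and known limitations.

## Model representation and electrostatic moments

A three-site rigid water model is the 5-tuple (d_OH, d_HH, q_O, σ,
ε_LJ): O–H bond length and H–H distance in nm (together fixing the
H–O–H angle θ = 2 arcsin(d_HH/2d_OH)), oxygen partial charge in e
(hydrogens carry −q_O/2 each by neutrality and C2v symmetry), and the
Lennard-Jones parameters of the single oxygen-centred site (σ in nm,
ε_LJ in kJ/mol).  Validation enforces the triangle inequality
d_HH < 2 d_OH, 0 < d_OH < 0.2 nm, 0 < d_HH < 0.3 nm, σ, ε_LJ > 0 and
q_O < 0.

The molecular frame places O at the origin, the C2 (dipole) axis along
+z and the hydrogens mirror-symmetric in the xz-plane.  The dipole is
μ = 2·(−q_O/2)·d_OH·cos(θ/2), converted with 1 e·Å = 4.803205 D.  The
quadrupole convention is the traceless tensor
Θ_αβ = ½ Σᵢ qᵢ(3 r_iα r_iβ − rᵢ² δ_αβ) evaluated in that frame, from
which the two moments conventionally quoted for water are Q_0 = Θ_zz
(linear quadrupole, Buckingham = D·Å) and Q_t = (Θ_xx − Θ_yy)/2
(tetrahedral quadrupole, D·Å).  This is the unique simple convention
that reproduces the published values for all six bundled presets (SPC,
SPC/E, SPC/Eb, TIP3P, TIP3P-FB, OPC3); it was verified against those
values before being frozen.  Q_0 vanishes identically at the
tetrahedral angle (cos²(θ/2) = 1/3), which is why tetrahedrally
constrained models print Q_0 = 0.00.  Presets carry the full-precision
parameters from the original model publications, not 3-digit roundings.

## Composite score

Structural discrepancy between a simulated and a reference radial
distribution function is an optimal-transport distance with the
*squared* radial separation (r_i − r_j)² as the transport cost, which
up-weights long-range structure and avoids overfitting the classically
irreproducible first peak.  Curves are normalized to unit total mass on
the simulation grid (the reference is linearly interpolated onto it if
the grids differ); no 4πr² shell weighting is applied — the bins'
g-values are the masses.  For one-dimensional distributions with a
convex cost the monotone (quantile) coupling is optimal, so the score
is computed exactly by merging the two cumulative distributions and
paying (x_p − x_q)² on each quantile slice; tests verify bit-level
agreement (1e-9) with a dense linear-program transport solution.

The multi-target score combines three dimensionless terms, averaged
over the three site pairs (OO, OH, HH) and over the training
temperatures (defaults 280, 298, 343 K):

    S = w_EMD ⟨EMD²/EMD²_ref⟩ + w_ρ ⟨|ρ−ρ*|/ρ*⟩ + w_ε ⟨|ε−ε*|/ε*⟩

with default weights 0.5/0.3/0.2.  EMD²_ref is the transport distance
between the reference curve and the featureless g ≡ 1 curve, making the
structural term commensurate with the relative errors.  Aggregation
(means rather than sums) and normalization are this package's choices;
only ranking behaviour, not absolute score values, should be compared
across implementations.  S = 0 iff every simulated quantity equals its
target; a 10% density error alone scores exactly 0.03 under the default
weights.

## Observables

All estimators consume plain time series (volume nm³, box enthalpy
kJ/mol, box dipole e·nm, pressures bar, MSD nm², time ps) or tables;
they never touch raw trajectories with electrostatics.  Series
statistics use the full series — no automatic equilibration detection;
the caller truncates.

- Density: ρ = N·m/(N_A⟨V⟩), g/cm³.
- Static dielectric constant: ε = 1 + (⟨M·M⟩ − ⟨M⟩·⟨M⟩)/(3 ε₀ V k_B T).
- Dipole-moment-surface scaling: charges optimal for the potential
  energy surface underestimate polarization, so λ = μ_DMS/μ_PES with
  μ_DMS = 2.9 D (liquid-phase experimental dipole) rescales the
  dielectric constant as ε_λ = 1 + λ²(ε_PES − 1).  The λ² form follows
  from the fluctuation formula being quadratic in the box dipole, which
  is linear in the charges.
- Self-diffusion: Einstein relation, least-squares MSD slope over a
  fractional window (default 10–50% of the series, skipping the
  ballistic start and poorly averaged tail) divided by 6; finite-box
  values D_PBC(L) extrapolate to D_0 as the OLS intercept in 1/L.
- Enthalpy of vaporization: ΔH_vap = −U_liq + RT − p_sat·V_liq − E_pol
  + C(T), treating the vapor as ideal; E_pol = (μ − μ_gas)²/(2 α_gas)
  is the depolarization energy (μ_gas = 1.855 D, α_gas = 1.47 Å³
  polarizability volume by default).  C(T) collects tabulated
  vibrational/non-ideality corrections; the bundled correction table is
  zero by default and editable, so the estimator is usable without
  transcribing any external table.  Interpolation is linear and
  strictly within the tabulated temperature range.
- Heat capacity, expansivity, compressibility: the standard NpT
  (co)variance formulas c_p = Var(H)/(N k_B T²) (per mole, plus an
  additive quantum correction for the modes a rigid classical model
  misses), α_T = Cov(H,V)/(⟨V⟩ k_B T²), κ_T = Var(V)/(⟨V⟩ k_B T).
  Box-total enthalpy fluctuations are used, divided by N.
- Surface tension: γ = (L_z/2)(⟨P_zz⟩ − (⟨P_xx⟩+⟨P_yy⟩)/2) for a slab
  with two interfaces normal to z; 1 bar·nm = 0.1 mN/m.
- RDF: minimum-image pair histogram with ideal-gas normalization on the
  production grid of 500 bins to a 10 Å cutoff (cutoff must not exceed
  half the shortest box edge).

### Critical point

Coexistence densities are fit jointly with the law of rectilinear
diameters plus a three-term Wegner expansion,

    ρ_{l,v}(T) = ρ_c + C₂τ ± ½(B₀τ^β + B₁τ^{β+Δ}),  τ = 1 − T/T_c,

with the exponents fixed at their renormalization-group values
β = 0.325, Δ = 0.50.  The five free parameters are found by
Levenberg-style least squares with a multistart around T_c initialized
5% above the highest tabulated temperature (the τ^β singularity can
trap a single start); non-convergence from every start raises.  On
noise-free synthetic tables the fit is an exact round trip (4
significant digits).  Precision degrades quickly when the data stop far
below T_c: with 1% multiplicative density noise, a 350–550 K table
(step 25) scatters T_c by ~17 K RMS, whereas a table reaching 10 K
below T_c (350–620 K, step 10) keeps every fit within ±4 K.  The
synthetic coexistence fixtures therefore extend to 10 K below the true
T_c.

### Temperature of maximum density

The TMD is the vertex of a quadratic fit over up to 11 grid points
(±5) around the table maximum — ±10 K on the conventional 2 K scan.
A 5-point window was tried first and is too noisy: at a realistic
density noise of 1e-4 g/cm³ its vertex scatter is 1.5 K std, while the
11-point window achieves 0.26 K and stays within the ±1 K grid
uncertainty in every repeat.  ρ(T) is parabolic to excellent
approximation over ±10 K around the maximum, so the wider window adds
no model bias at this grid.  Monotone tables (no interior maximum)
raise.

## Swarm optimizer

Standard global-best PSO over the box-bounded 5-parameter space:
v ← w·v + c₁r₁(p_best − x) + c₂r₂(g_best − x) with constriction-style
defaults w = 0.72, c₁ = c₂ = 1.49; positions are clamped to the bounds
and the offending velocity component zeroed.  An optional self-tuning
mode linearly adapts (w, c₁, c₂) per particle from two normalized
signals (relative excess fitness over the global best, normalized
distance to it): far/poor particles explore, close/good particles
exploit.  This is a deliberately simple adaptation policy behind an
isolated interface, so a fuzzy-rule self-tuning scheme can be swapped
in without touching the optimizer loop.  Termination is by iteration
budget or swarm collapse: maximum pairwise particle distance,
normalized by the bounds extent, below `collapse_radius` (default
1e-3; the collapse threshold is a convention, not a published value).
Evaluators must be total on the box — geometrically invalid vectors
(d_HH ≥ 2 d_OH) receive a large finite penalty (1e6, growing with the
violation) rather than an exception.  With a fixed seed, trajectories
are bit-reproducible.

Default swarm sizes are 15 (multi-temperature workflows) and 26
(single-temperature), mirroring the two published setups; both live in
configuration, not code.

## Analytic surrogate

The surrogate replaces the MD engine in the loop with closed-form,
water-like responses, so the full optimize/score/analyze pipeline runs
in minutes with known ground truth.  Its defining contract encodes the
physics that makes three-site optimization ill-posed: every output
depends on (q_O, d_OH, d_HH) *only through the molecular dipole μ*
(plus σ and ε_LJ).  Two models with equal (μ, σ, ε_LJ) are exactly
indistinguishable.

On the production RDF grid the surrogate emits three-peak curves
g(r) = S(r)·[1 + Σ_k (−1)^{k+1} A_k exp(−(r−r_k)²/2s_k²)] with the
first peak at r₁ = 2^{1/6}σ_Å(1 − 0.02(μ−2.3)), overtones at 1.63 r₁
and 2.45 r₁, amplitudes A₁ = 1 + 0.4(μ−2.3) + 0.2(ε_LJ/0.65 − 1)
(A₂ = 0.15 A₁, A₃ = 0.05 A₁), temperature-broadened widths
s_k = (0.11 + 0.02k)√(T/298) Å and a logistic onset switch centred at
0.9 r₁ with 0.1 Å width; O–H and H–H curves rescale r₁ by 0.70/0.88
and A₁ by 1.3/0.9.  Density and dielectric responses are
ρ = 0.997(1 + 0.05(μ−2.3) − 0.8(σ_Å−3.17)/3.17)(1 − 2.5e-4(T−298)) and
ε = 1 + 87.7·μ²ρ/(2.3²·0.997)·(298/T).  All coefficients are frozen in
one table; they are calibrated to water-like magnitudes (first O–O peak
near 2.8 Å, ρ ≈ 0.997 g/cm³, ε ≈ 88 at the anchor) but make **no claim
of quantitative physical fidelity** — the surrogate exists to exercise
the machinery and the degeneracy phenomenon.  Noise, when requested, is
multiplicative Gaussian applied after the deterministic evaluation,
reproducible under the config seed.

What the surrogate deliberately does not emulate: sampling noise
correlations between observables, thermodynamic consistency between ρ,
ε and the RDFs, pressure coupling, and any dependence of structure on
(q, d) beyond μ.  Passing tests therefore demonstrate that the
optimization and analysis machinery behaves correctly under a known
ground truth with the dipole degeneracy built in — not that any
particular water model is accurate.

Gaussian fixture generators accompany the surrogate: a box-dipole
series whose fluctuation estimator converges to a prescribed ε, a
correlated (H, V) pair with prescribed first and second moments for the
c_p/α_T/κ_T estimators, and Wegner-exact coexistence tables with
optional multiplicative noise.

## Degeneracy experiment

The desk-scale analogue of repeated production optimizations: six swarm
runs (15 particles, up to 300 iterations) with distinct seeds against a
shared target set generated from a reference model at 280/298/343 K.
The targets carry 2% multiplicative noise, emulating the statistical
noise of sampled reference data: no candidate then scores exactly zero,
and the runs settle onto a common nonzero floor, making "comparable
score" a meaningful statement (with noise-free targets all runs reach
~0 and score ratios are numerically meaningless).  The analysis
standardizes the 5 parameters to zero mean and unit variance before PCA
(they have incommensurate units), draws Gaussian-KDE density isolines
on the 2-D projection (Scott's-rule bandwidth by default; contour
polylines extracted from the evaluated grid), and reports coefficients
of variation: the ensemble is flagged dipole-degenerate when CV(μ) is
smaller than both CV(q_O) and CV(d_OH).  Under these conditions the six
runs recover the reference dipole to <0.1% while q_O scatters by ~11%.

## Numerical conventions

- Internal units nm/ps/e/kJ/mol/K; conversions only at I/O boundaries;
  RDF grids in Å.  CODATA 2018 constants, one constants module.
- Writers emit the dialect their readers consume; round trips preserve
  values to 10 significant digits; writes are atomic (temp file +
  rename).
- XVG-dialect series: '#'/'@' lines skipped, whitespace-separated
  columns, first column time in ps.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; no global state.

## Problem sizes

The bundled experiments are sized for a single CPU: transport-score
oracle checks use ≤50-bin histograms; fluctuation fixtures use 1e5
samples (sampling error ~0.5%, tested at 3%); the sphere benchmark uses
15 particles × 200 iterations × 20 seeds; the degeneracy experiment
6 runs × 15 particles × 300 iterations (a couple of minutes).  These
sizes are the package's test conditions; production optimizations
against a real MD evaluator would use the same interfaces with larger
budgets.

## Known limitations

- No MD engine integration is bundled: pressure tensors, box dipoles
  and MSDs are inputs, produced elsewhere.
- The vaporization-enthalpy correction table ships empty (zeros);
  users supply tabulated vibrational/non-ideality corrections for
  quantitative work.
- The heat-capacity estimator assumes box-total enthalpy fluctuations
  divided by N; per-molecule input series must be rescaled by the
  caller.
- The self-tuning PSO mode is a linear stand-in, not a fuzzy rule base;
  it shares only the intent (per-particle adaptation) with fuzzy
  self-tuning PSO.
- Four- and five-site geometries are out of representation scope.
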