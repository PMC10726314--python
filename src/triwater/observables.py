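"""Thermodynamic, dielectric, structural and transport observables.

Every estimator here operates on plain time series or tables, not on raw
trajectories with electrostatics: the intended workflow is that an MD
engine (or the analytic surrogate in :mod:`triwater.surrogate`) produces
series of volume, enthalpy, box dipole, pressure-tensor diagonal or MSD,
and this module turns them into the macroscopic quantities used to judge a
water model:

* mass density from the mean box volume;
* static dielectric constant from total-dipole fluctuations,
  eps = 1 + (<M.M> - <M>.<M>) / (3 eps0 V kB T);
* the dipole-moment-surface scaling lambda = mu_DMS / mu_PES and the
  scaled dielectric eps_lambda = 1 + lambda^2 (eps_PES - 1);
* self-diffusion from the Einstein relation (MSD slope / 6) with the
  finite-box extrapolation D_PBC(L) -> D_0 linear in 1/L;
* enthalpy of vaporization with the depolarization-energy correction
  E_pol = (mu - mu_gas)^2 / (2 alpha_gas);
* isobaric heat capacity, thermal expansivity and isothermal
  compressibility from (co)variance fluctuation formulas;
* surface tension from the anisotropy of the pressure-tensor diagonal;
* the liquid-vapor critical point from a law-of-rectilinear-diameters +
  three-term Wegner expansion fit with fixed exponents beta = 0.325,
  Delta = 0.50;
* the temperature of maximum density from a local quadratic fit.

Series units follow the package convention: volume nm^3, box dipole e*nm,
enthalpy/energy kJ/mol (of the whole box, i.e. already multiplied by
Avogadro's number), pressure bar, MSD nm^2, time ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    ANGSTROM,
    AVOGADRO,
    BAR,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    GAS_CONSTANT,
    NM,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "RDFCurve",
    "ObservableSeries",
    "CoexistenceTable",
    "CorrectionTable",
    "compute_rdf",
    "density",
    "static_dielectric",
    "dielectric_scaling",
    "scaled_dielectric",
    "self_diffusion",
    "extrapolate_D0",
    "enthalpy_vaporization",
    "heat_capacity_isobaric",
    "thermal_expansion",
    "isothermal_compressibility",
    "surface_tension",
    "critical_point_fit",
    "CriticalPointFit",
    "temperature_of_max_density",
]

_VECTOR_KINDS = {"dipole_vector", "pressure_diagonal"}
_KINDS = {"volume", "enthalpy", "potential_energy", "dipole_vector", "pressure_diagonal", "msd"}


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class RDFCurve:
    """A binned radial distribution function g(r) on an equally spaced grid.

    ``bin_centers`` are in Angstrom; ``g_values`` are dimensionless and
    nonnegative.  The default production grid is 500 bins up to a 10 A
    cutoff.
    """

    bin_centers: np.ndarray
    g_values: np.ndarray
    cutoff: float
    pair_label: str  # "OO", "OH" or "HH"

    def __post_init__(self) -> None:
        r = np.asarray(self.bin_centers, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        object.__setattr__(self, "bin_centers", r)
        object.__setattr__(self, "g_values", g)
        if r.ndim != 1 or g.shape != r.shape:
            raise ValueError("bin_centers and g_values must be equal-length 1-D arrays")
        if len(r) >= 2:
            dr = np.diff(r)
            if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-8):
                raise ValueError("bin_centers must be strictly increasing, equally spaced")
        if np.any(g < 0) or not np.all(np.isfinite(g)):
            raise ValueError("g(r) must be finite and nonnegative")
        if self.pair_label not in {"OO", "OH", "HH"}:
            raise ValueError(f"pair_label must be OO/OH/HH, got {self.pair_label!r}")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


@dataclass(frozen=True)
class ObservableSeries:
    """A sampled time series of a scalar or 3-vector observable.

    ``values`` has shape (n,) for scalars or (n, 3) for the two vector
    kinds (box dipole, pressure-tensor diagonal); ``dt`` is the sampling
    interval in ps.
    """

    values: np.ndarray
    dt: float
    units: str
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.kind in _VECTOR_KINDS:
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValueError(f"{self.kind} series must have shape (n, 3)")
        elif v.ndim != 1:
            raise ValueError(f"{self.kind} series must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


@dataclass(frozen=True)
class CoexistenceTable:
    """Liquid/vapor coexistence densities (g/cm^3) versus temperature (K)."""

    temperatures: np.ndarray
    rho_liq: np.ndarray
    rho_vap: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        rl = np.asarray(self.rho_liq, dtype=float)
        rv = np.asarray(self.rho_vap, dtype=float)
        for name, arr in (("temperatures", t), ("rho_liq", rl), ("rho_vap", rv)):
            object.__setattr__(self, name, arr)
        if not (t.shape == rl.shape == rv.shape) or t.ndim != 1:
            raise ValueError("coexistence columns must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(rl <= rv):
            raise ValueError("rho_liq must exceed rho_vap at every temperature")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class CorrectionTable:
    """Temperature-tabulated additive corrections and gas-phase molecular data.

    ``dhvap_corr`` (kJ/mol) collects the vibrational/non-ideality terms of
    the vaporization enthalpy; ``cp_corr`` (J/mol/K) the quantum correction
    to the classical heat capacity.  ``mu_gas`` (D) and ``alpha_gas``
    (polarizability volume, A^3) parameterize the depolarization energy.
    Values default to zero/gas-phase-water so the estimators are usable
    without transcribing any external table; interpolation is linear and
    strictly within the tabulated range.
    """

    temperatures: np.ndarray = field(default_factory=lambda: np.array([200.0, 400.0]))
    dhvap_corr: np.ndarray = field(default_factory=lambda: np.zeros(2))
    cp_corr: np.ndarray = field(default_factory=lambda: np.zeros(2))
    mu_gas: float = 1.855
    alpha_gas: float = 1.47

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "dhvap_corr", np.asarray(self.dhvap_corr, dtype=float))
        object.__setattr__(self, "cp_corr", np.asarray(self.cp_corr, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise ValueError("correction temperatures must be strictly increasing")

    def _interp(self, column: np.ndarray, T: float) -> float:
        t = self.temperatures
        if not (t[0] <= T <= t[-1]):
            raise ValueError(
                f"T={T} K outside correction table range [{t[0]}, {t[-1]}] K; "
                "no extrapolation is performed"
            )
        return float(np.interp(T, t, column))

    def dhvap_correction(self, T: float) -> float:
        return self._interp(self.dhvap_corr, T)

    def cp_correction(self, T: float) -> float:
        return self._interp(self.cp_corr, T)


# ---------------------------------------------------------------------------
# structure


def compute_rdf(
    frames: Sequence,
    pair: str,
    cutoff: float = 10.0,
    n_bins: int = 500,
) -> RDFCurve:
    """Radial distribution function between O/H sites over a set of frames.

    ``frames`` are :class:`triwater.io.Frame` objects (or anything with
    ``positions`` (nm), ``names`` and orthorhombic ``box`` (nm)).  Distances
    use the minimum-image convention; normalization is the standard
    ideal-gas one, shell count / (N_pairs * shell volume / V).
    """
    if pair not in {"OO", "OH", "HH"}:
        raise ValueError(f"pair must be OO/OH/HH, got {pair!r}")
    if len(frames) == 0:
        raise ValueError("at least one frame is required")

    edges_A = np.linspace(0.0, cutoff, n_bins + 1)
    centers = 0.5 * (edges_A[:-1] + edges_A[1:])
    hist = np.zeros(n_bins)
    norm = 0.0

    for frame in frames:
        box = np.asarray(frame.box, dtype=float)
        if cutoff * 0.1 > box.min() / 2.0 + 1e-12:  # cutoff in A, box in nm
            raise ValueError(
                f"cutoff {cutoff} A exceeds half the shortest box edge "
                f"({box.min() / 2.0 * 10.0:.3f} A)"
            )
        names = np.asarray([n[0].upper() for n in frame.names])
        pos = np.asarray(frame.positions, dtype=float)
        sel_a = pos[names == pair[0]]
        sel_b = pos[names == pair[1]]
        if len(sel_a) == 0 or len(sel_b) == 0:
            raise ValueError(f"empty selection for pair {pair!r}")

        if pair[0] == pair[1]:
            iu = np.triu_indices(len(sel_a), k=1)
            diff = sel_a[iu[0]] - sel_a[iu[1]]
            n_pairs = len(sel_a) * (len(sel_a) - 1) / 2.0
        else:
            diff = (sel_a[:, None, :] - sel_b[None, :, :]).reshape(-1, 3)
            n_pairs = float(len(sel_a) * len(sel_b))
        diff -= box * np.round(diff / box)
        dist_A = np.linalg.norm(diff, axis=1) * 10.0
        hist += np.histogram(dist_A, bins=edges_A)[0]
        volume_A3 = float(np.prod(box)) * 1000.0
        norm += n_pairs / volume_A3  # accumulated pair density

    shell_vol = 4.0 / 3.0 * np.pi * (edges_A[1:] ** 3 - edges_A[:-1] ** 3)
    expected = shell_vol * norm
    g = np.where(expected > 0, hist / expected, 0.0)
    return RDFCurve(bin_centers=centers, g_values=g, cutoff=cutoff, pair_label=pair)


# ---------------------------------------------------------------------------
# thermodynamics from time series


def _require_kind(series: ObservableSeries, kind: str) -> None:
    if series.kind != kind:
        raise ValueError(f"expected a {kind!r} series, got {series.kind!r}")


def density(n_molecules: int, molar_mass: float, volume_series: ObservableSeries) -> float:
    """Mass density rho = N m / (N_A <V>) in g/cm^3 (volume in nm^3)."""
    _require_kind(volume_series, "volume")
    v = volume_series.values
    if np.any(v <= 0):
        raise ValueError("volume series must be strictly positive")
    mean_v_cm3 = float(np.mean(v)) * 1e-21
    return n_molecules * molar_mass / (AVOGADRO * mean_v_cm3)


def static_dielectric(dipole_series: ObservableSeries, volume: float, T: float) -> float:
    """Static dielectric constant from box-dipole fluctuations.

    eps = 1 + (<M.M> - <M>.<M>) / (3 eps0 V kB T), with M in e*nm and V in
    nm^3.
    """
    _require_kind(dipole_series, "dipole_vector")
    if len(dipole_series) < 2:
        raise ValueError("at least two dipole samples are required")
    if volume <= 0 or T <= 0:
        raise ValueError("volume and temperature must be positive")
    m_si = dipole_series.values * ELEMENTARY_CHARGE * NM  # C m
    mean = m_si.mean(axis=0)
    fluct = float(np.mean(np.sum(m_si**2, axis=1)) - mean @ mean)
    v_si = volume * NM**3
    return 1.0 + fluct / (3.0 * VACUUM_PERMITTIVITY * v_si * BOLTZMANN * T)


def dielectric_scaling(mu_pes: float, mu_dms: float = 2.9) -> float:
    """Charge-scaling factor lambda = mu_DMS / mu_PES (both in D).

    mu_DMS defaults to 2.9 D, the liquid-phase dipole of the real water
    molecule; mu_PES is the dipole of the simulated model.
    """
    if mu_pes <= 0:
        raise ValueError("mu_pes must be positive")
    return mu_dms / mu_pes


def scaled_dielectric(eps_pes: float, lam: float) -> float:
    """Dielectric constant re-evaluated with DMS-scaled charges.

    Since the fluctuation formula is quadratic in the box dipole, scaling
    all charges by lambda multiplies the fluctuation term by lambda^2:
    eps_lambda = 1 + lambda^2 (eps_PES - 1).
    """
    if eps_pes < 1.0:
        raise ValueError("eps_pes must be >= 1")
    return 1.0 + lam**2 * (eps_pes - 1.0)


def self_diffusion(
    msd_series: ObservableSeries, fit_window: tuple[float, float] = (0.1, 0.5)
) -> float:
    """Self-diffusion coefficient from the Einstein relation, in 1e-5 cm^2/s.

    Least-squares slope of MSD (nm^2) versus time over the fractional
    window of the series (default 10-50%, skipping the ballistic start and
    the poorly averaged tail), divided by 6.
    """
    _require_kind(msd_series, "msd")
    msd = msd_series.values
    if np.any(msd < 0):
        raise ValueError("MSD must be nonnegative")
    lo, hi = fit_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("fit_window must satisfy 0 <= lo < hi <= 1")
    i0, i1 = int(lo * len(msd)), max(int(hi * len(msd)), 1)
    if i1 - i0 < 3:
        raise ValueError("fit window must contain at least 3 points")
    t = msd_series.times[i0:i1]
    slope = np.polyfit(t, msd[i0:i1], 1)[0]  # nm^2/ps
    d_cm2_s = slope / 6.0 * (NM**2 / 1e-4) / 1e-12  # -> cm^2/s
    return d_cm2_s / 1e-5


def extrapolate_D0(points: Sequence[tuple[float, float]]) -> float:
    """Infinite-box diffusion coefficient by linear extrapolation in 1/L.

    ``points`` are (box edge L in nm, D_PBC) pairs; finite-size theory
    predicts D_PBC = D_0 - k/L, so D_0 is the OLS intercept at 1/L -> 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("at least two (L, D_PBC) points are required")
    inv_l = 1.0 / pts[:, 0]
    if np.ptp(inv_l) == 0:
        raise ValueError("at least two distinct box sizes are required")
    slope, intercept = np.polyfit(inv_l, pts[:, 1], 1)
    return float(intercept)


def enthalpy_vaporization(
    U_liq: float,
    V_liq: float,
    T: float,
    p_sat: float,
    mu_model: float,
    corrections: CorrectionTable | None = None,
) -> float:
    """Enthalpy of vaporization (kJ/mol of molecules).

    dH_vap = -U_liq + R T - p_sat V_liq - E_pol + C(T), treating the vapor
    as ideal (enthalpy R T per mole) and subtracting the liquid pV term.
    E_pol = (mu_model - mu_gas)^2 / (2 alpha_gas) is the depolarization
    energy of bringing the model dipole (D) back to the gas-phase value,
    with alpha_gas a polarizability volume in A^3.

    U_liq in kJ/mol, V_liq in L/mol, p_sat in bar, T in K.
    """
    if corrections is None:
        corrections = CorrectionTable()
    c_t = corrections.dhvap_correction(T)
    rt = GAS_CONSTANT * T / 1000.0  # kJ/mol
    pv = p_sat * BAR * V_liq * 1e-3 / 1000.0  # bar * L/mol -> kJ/mol
    e_pol = _depolarization_energy(mu_model, corrections.mu_gas, corrections.alpha_gas)
    return -U_liq + rt - pv - e_pol + c_t


def _depolarization_energy(mu_model: float, mu_gas: float, alpha_gas: float) -> float:
    """E_pol = (mu - mu_gas)^2 / (2 alpha) in kJ/mol (mu in D, alpha in A^3)."""
    from .constants import DEBYE

    d_mu = (mu_model - mu_gas) * DEBYE  # C m
    alpha_si = 4.0 * np.pi * VACUUM_PERMITTIVITY * alpha_gas * ANGSTROM**3  # C^2 m^2 / J
    return d_mu**2 / (2.0 * alpha_si) * AVOGADRO / 1000.0


def heat_capacity_isobaric(
    enthalpy_series: ObservableSeries,
    T: float,
    n_molecules: int,
    correction: float = 0.0,
) -> float:
    """Isobaric heat capacity from enthalpy fluctuations, in J/mol/K.

    c_p = (<H^2> - <H>^2) / (N kB T^2) per molecule, converted to molar
    units, plus the additive quantum ``correction`` (rigid models miss
    intramolecular vibrations and stiff intermolecular modes).
    Enthalpy series in kJ/mol of the whole box.
    """
    _require_kind(enthalpy_series, "enthalpy")
    if len(enthalpy_series) < 2:
        raise ValueError("at least two enthalpy samples are required")
    if T <= 0:
        raise ValueError("temperature must be positive")
    var_molar = float(np.var(enthalpy_series.values))  # (kJ/mol)^2
    var_j = var_molar * (1e3 / AVOGADRO) ** 2  # J^2 per box
    cp_box = var_j / (BOLTZMANN * T**2)  # J/K for the box
    return cp_box / n_molecules * AVOGADRO + correction


def thermal_expansion(
    enthalpy_series: ObservableSeries, volume_series: ObservableSeries, T: float
) -> float:
    """Thermal expansion coefficient alpha_T (1/K) from H-V covariance.

    alpha_T = (<H V> - <H><V>) / (<V> kB T^2); enthalpy kJ/mol of box,
    volume nm^3.
    """
    _require_kind(enthalpy_series, "enthalpy")
    _require_kind(volume_series, "volume")
    if len(enthalpy_series) != len(volume_series):
        raise ValueError("enthalpy and volume series must have equal length")
    if T <= 0:
        raise ValueError("temperature must be positive")
    h_j = enthalpy_series.values * 1e3 / AVOGADRO  # J per box
    v_m3 = volume_series.values * NM**3
    cov = float(np.mean(h_j * v_m3) - np.mean(h_j) * np.mean(v_m3))
    return cov / (float(np.mean(v_m3)) * BOLTZMANN * T**2)


def isothermal_compressibility(volume_series: ObservableSeries, T: float) -> float:
    """Isothermal compressibility kappa_T (1/bar) from volume fluctuations.

    kappa_T = (<V^2> - <V>^2) / (<V> kB T); volume in nm^3.
    """
    _require_kind(volume_series, "volume")
    if len(volume_series) < 2:
        raise ValueError("at least two volume samples are required")
    if T <= 0:
        raise ValueError("temperature must be positive")
    v_m3 = volume_series.values * NM**3
    kappa_pa = float(np.var(v_m3)) / (float(np.mean(v_m3)) * BOLTZMANN * T)
    return kappa_pa * BAR  # 1/Pa -> 1/bar


def surface_tension(pressure_diag_series: ObservableSeries, L_z: float) -> float:
    """Surface tension (mN/m) from the pressure-tensor anisotropy.

    gamma = (L_z / 2) (<P_zz> - (<P_xx> + <P_yy>)/2) for a slab with two
    interfaces normal to z; pressures in bar, L_z in nm
    (1 bar*nm = 0.1 mN/m).
    """
    _require_kind(pressure_diag_series, "pressure_diagonal")
    if L_z <= 0:
        raise ValueError("L_z must be positive")
    p = pressure_diag_series.values.mean(axis=0)
    gamma_bar_nm = (L_z / 2.0) * (p[2] - (p[0] + p[1]) / 2.0)
    return gamma_bar_nm * BAR * NM * 1e3  # -> mN/m


# ---------------------------------------------------------------------------
# critical point and TMD


@dataclass(frozen=True)
class CriticalPointFit:
    """Result of the rectilinear-diameter + Wegner coexistence fit."""

    T_c: float
    rho_c: float
    B_0: float
    B_1: float
    C_2: float
    residual: float


def wegner_densities(
    T: np.ndarray,
    T_c: float,
    rho_c: float,
    B_0: float,
    B_1: float,
    C_2: float,
    beta: float = 0.325,
    delta: float = 0.50,
) -> tuple[np.ndarray, np.ndarray]:
    """Coexisting liquid/vapor densities from the combined expansion.

    rho_{l,v}(T) = rho_c + C_2 tau +- (B_0 tau^beta + B_1 tau^(beta+delta))/2
    with tau = 1 - T/T_c; the symmetric part is the rectilinear diameter,
    the antisymmetric part the Wegner expansion of the width of the
    coexistence curve.
    """
    tau = 1.0 - np.asarray(T, dtype=float) / T_c
    if np.any(tau <= 0):
        raise ValueError("all temperatures must be below T_c")
    diam = rho_c + C_2 * tau
    width = B_0 * tau**beta + B_1 * tau ** (beta + delta)
    return diam + width / 2.0, diam - width / 2.0


def critical_point_fit(
    table: CoexistenceTable,
    beta: float = 0.325,
    delta: float = 0.50,
    n_starts: int = 8,
    seed: int = 0,
) -> CriticalPointFit:
    """Locate (T_c, rho_c) by nonlinear least squares on both branches.

    The critical exponents are held at their renormalization-group values
    (beta = 0.325, Delta = 0.50).  A multistart around an initial T_c guess
    5% above the highest tabulated temperature guards against the
    tau^beta singularity trapping the solver.
    """
    if len(table) < 4:
        raise ValueError("at least 4 coexistence rows are required")
    t, rl, rv = table.temperatures, table.rho_liq, table.rho_vap
    t_max = t[-1]

    def residuals(p: np.ndarray) -> np.ndarray:
        t_c, rho_c, b0, b1, c2 = p
        tau = 1.0 - t / t_c
        diam = rho_c + c2 * tau
        width = b0 * tau**beta + b1 * tau ** (beta + delta)
        return np.concatenate([diam + width / 2.0 - rl, diam - width / 2.0 - rv])

    rng = np.random.default_rng(seed)
    rho_c0 = float((rl[-1] + rv[-1]) / 2.0)
    b0_0 = float(rl[0] - rv[0])
    best = None
    for k in range(n_starts):
        jitter = 1.0 if k == 0 else float(rng.uniform(0.8, 1.3))
        x0 = np.array([1.05 * t_max * jitter, rho_c0, b0_0, 0.0, 0.0])
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=([t_max * (1.0 + 1e-6), 0.0, 0.0, -np.inf, -np.inf], np.inf),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("critical-point fit failed to converge from any start")
    t_c, rho_c, b0, b1, c2 = best.x
    return CriticalPointFit(
        T_c=float(t_c),
        rho_c=float(rho_c),
        B_0=float(b0),
        B_1=float(b1),
        C_2=float(c2),
        residual=float(np.sqrt(2.0 * best.cost / (2 * len(table)))),
    )


def temperature_of_max_density(density_vs_T: Sequence[tuple[float, float]]) -> float:
    """TMD (K) as the vertex of a local quadratic fit around the grid maximum.

    Uses up to 11 grid points (+-5) centred on the maximum of the (T, rho)
    table - on a 2 K scan that is a +-10 K window, wide enough to average
    out realistic density noise while rho(T) is still parabolic; errors out
    if the maximum sits at either end (no interior extremum).  The 2 K grid
    convention gives a +-1 K uncertainty.
    """
    rows = np.asarray(density_vs_T, dtype=float)
    if rows.ndim != 2 or len(rows) < 5:
        raise ValueError("at least 5 (T, rho) rows are required")
    order = np.argsort(rows[:, 0])
    t, rho = rows[order, 0], rows[order, 1]
    i_max = int(np.argmax(rho))
    if i_max in (0, len(rho) - 1):
        raise ValueError("density table has no interior maximum")
    lo, hi = max(0, i_max - 5), min(len(rho), i_max + 6)
    a, b, _ = np.polyfit(t[lo:hi], rho[lo:hi], 2)
    if a >= 0:
        raise ValueError("local fit is not concave; no maximum")
    return float(-b / (2.0 * a))
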