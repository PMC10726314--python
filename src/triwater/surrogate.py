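"""Analytic surrogate for the MD evaluator, with a built-in mu = q*d degeneracy.

Optimizing a water model normally requires an MD simulation per candidate.
This module replaces that loop with closed-form, water-like responses so
the whole optimize/score/analyze machinery can run at desk scale with a
known ground truth.  Its defining contract mirrors the physics that makes
three-site optimization ill-posed: every output depends on the charge and
geometry parameters (q_O, d_OH, d_HH) *only through the molecular dipole*
mu = |q| d_OH cos(theta/2) (plus sigma and epsilon_lj).  Two models with
equal (mu, sigma, epsilon_lj) are therefore exactly indistinguishable to
the surrogate - the testable embodiment of the dipole degeneracy that
repeated optimizations of real models run into.

The coefficients are frozen, water-like magnitudes (first g_OO peak near
2.8 A, density near 0.997 g/cm^3, dielectric constant near 88 at 298 K)
with no claim of quantitative fidelity.  Gaussian fixture generators for
the fluctuation-formula estimators and the coexistence-curve fit live
here too, each with a prescribed expectation for its downstream estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np

from .constants import BOLTZMANN, ELEMENTARY_CHARGE, NM, VACUUM_PERMITTIVITY
from .models import WaterModel, dipole_moment
from .observables import CoexistenceTable, ObservableSeries, RDFCurve, wegner_densities
from .scoring import PAIRS, StatePoint

__all__ = [
    "SurrogateConfig",
    "surrogate_rdfs",
    "surrogate_density",
    "surrogate_dielectric",
    "surrogate_state_point",
    "gen_dipole_series",
    "gen_fluctuation_series",
    "gen_coexistence_table",
]

# All surrogate coefficients in one frozen table.
COEFFS = MappingProxyType(
    {
        "mu_ref": 2.3,  # D; anchor dipole of the response expansions
        "rho_ref": 0.997,  # g/cm^3 at the anchor point, 298 K
        "sigma_ref": 3.17,  # A
        "eps_amp": 87.7,  # dielectric response amplitude at the anchor
        "rho_mu_slope": 0.05,
        "rho_sigma_slope": 0.8,
        "rho_T_slope": 2.5e-4,  # 1/K
        "peak_mu_shift": 0.02,
        "amp_mu_slope": 0.4,
        "amp_eps_slope": 0.2,
        "eps_lj_ref": 0.65,  # kJ/mol
        "r2_factor": 1.63,
        "r3_factor": 2.45,
        "amp2_factor": 0.15,
        "amp3_factor": 0.05,
        "width_base": 0.11,  # A
        "width_step": 0.02,  # A
        "switch_center_factor": 0.9,
        "switch_width": 0.1,  # A
        "oh_r1_scale": 0.70,
        "hh_r1_scale": 0.88,
        "oh_amp_scale": 1.3,
        "hh_amp_scale": 0.9,
    }
)


@dataclass(frozen=True)
class SurrogateConfig:
    """Reference temperatures, noise level and seed for surrogate outputs."""

    temperatures: tuple[float, ...] = (280.0, 298.0, 343.0)
    noise: float = 0.0
    seed: int = 0
    cutoff: float = 10.0  # A
    n_bins: int = 500

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive")
        if self.noise < 0:
            raise ValueError("noise level must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _grid(config: SurrogateConfig) -> np.ndarray:
    edges = np.linspace(0.0, config.cutoff, config.n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _pair_curve(
    r: np.ndarray, mu: float, sigma_A: float, eps_lj: float, T: float, pair: str
) -> np.ndarray:
    c = COEFFS
    r1 = 2.0 ** (1.0 / 6.0) * sigma_A * (1.0 - c["peak_mu_shift"] * (mu - c["mu_ref"]))
    a1 = 1.0 + c["amp_mu_slope"] * (mu - c["mu_ref"]) + c["amp_eps_slope"] * (
        eps_lj / c["eps_lj_ref"] - 1.0
    )
    if pair == "OH":
        r1 *= c["oh_r1_scale"]
        a1 *= c["oh_amp_scale"]
    elif pair == "HH":
        r1 *= c["hh_r1_scale"]
        a1 *= c["hh_amp_scale"]

    peaks = (r1, c["r2_factor"] * r1, c["r3_factor"] * r1)
    amps = (a1, c["amp2_factor"] * a1, c["amp3_factor"] * a1)
    g = np.ones_like(r)
    for k, (rk, ak) in enumerate(zip(peaks, amps), start=1):
        sk = (c["width_base"] + c["width_step"] * k) * np.sqrt(T / 298.0)
        g += ak * np.exp(-((r - rk) ** 2) / (2.0 * sk**2)) * (-1.0) ** (k + 1)
    switch = 1.0 / (1.0 + np.exp(-(r - c["switch_center_factor"] * r1) / c["switch_width"]))
    return np.clip(switch * g, 0.0, None)


def surrogate_rdfs(
    model: WaterModel, T: float, config: SurrogateConfig | None = None
) -> dict[str, RDFCurve]:
    """Water-like g_OO/g_OH/g_HH triplet on the standard 500-bin, 10 A grid.

    Charge and geometry enter only through mu; sigma sets the peak
    positions and epsilon_lj modulates the first-shell amplitude.
    """
    config = config or SurrogateConfig()
    r = _grid(config)
    mu = dipole_moment(model)
    rng = config.rng() if config.noise > 0 else None
    curves = {}
    for pair in PAIRS:
        g = _pair_curve(r, mu, model.sigma * 10.0, model.epsilon_lj, T, pair)
        if rng is not None:
            g = np.clip(g * (1.0 + config.noise * rng.standard_normal(g.shape)), 0.0, None)
        curves[pair] = RDFCurve(bin_centers=r, g_values=g, cutoff=config.cutoff, pair_label=pair)
    return curves


def surrogate_density(
    model: WaterModel, T: float, config: SurrogateConfig | None = None
) -> float:
    """Analytic density response (g/cm^3), linear in mu, sigma and T."""
    c = COEFFS
    mu = dipole_moment(model)
    sigma_a = model.sigma * 10.0
    rho = (
        c["rho_ref"]
        * (
            1.0
            + c["rho_mu_slope"] * (mu - c["mu_ref"])
            - c["rho_sigma_slope"] * (sigma_a - c["sigma_ref"]) / c["sigma_ref"]
        )
        * (1.0 - c["rho_T_slope"] * (T - 298.0))
    )
    if config is not None and config.noise > 0:
        rho *= 1.0 + config.noise * float(config.rng().standard_normal())
    return float(rho)


def surrogate_dielectric(
    model: WaterModel, T: float, config: SurrogateConfig | None = None
) -> float:
    """Analytic dielectric response, quadratic in mu and Curie-like in T."""
    c = COEFFS
    mu = dipole_moment(model)
    rho = surrogate_density(model, T)  # noiseless density inside eps
    eps = 1.0 + c["eps_amp"] * (mu**2 * rho) / (c["mu_ref"] ** 2 * c["rho_ref"]) * (298.0 / T)
    if config is not None and config.noise > 0:
        eps *= 1.0 + config.noise * float(config.rng().standard_normal())
    return float(eps)


def surrogate_state_point(
    model: WaterModel, T: float, config: SurrogateConfig | None = None
) -> StatePoint:
    """Bundle RDFs, density and dielectric at one temperature."""
    return StatePoint(
        temperature=T,
        rdfs=surrogate_rdfs(model, T, config),
        density=surrogate_density(model, T, config),
        dielectric=surrogate_dielectric(model, T, config),
    )


# ---------------------------------------------------------------------------
# Gaussian fixture generators with prescribed estimator expectations


def gen_dipole_series(
    target_eps: float, V: float, T: float, n: int, seed: int, dt: float = 1.0
) -> ObservableSeries:
    """Box-dipole series (e*nm) whose fluctuation estimator converges to
    ``target_eps``.

    Components are i.i.d. zero-mean Gaussians with per-component variance
    (target_eps - 1) eps0 V kB T, so <M.M> - <M>.<M> matches the
    fluctuation formula exactly in expectation.
    """
    if target_eps <= 1.0:
        raise ValueError("target_eps must exceed 1")
    if n < 2:
        raise ValueError("need at least 2 samples")
    var_si = (target_eps - 1.0) * VACUUM_PERMITTIVITY * (V * NM**3) * BOLTZMANN * T
    sigma_e_nm = np.sqrt(var_si) / (ELEMENTARY_CHARGE * NM)
    rng = np.random.default_rng(seed)
    m = rng.normal(scale=sigma_e_nm, size=(n, 3))
    return ObservableSeries(values=m, dt=dt, units="e*nm", kind="dipole_vector")


def gen_fluctuation_series(
    kind: str,
    mean: tuple[float, float],
    variance: tuple[float, float],
    covariance: float = 0.0,
    n: int = 1000,
    seed: int = 0,
    dt: float = 1.0,
) -> tuple[ObservableSeries, ObservableSeries]:
    """Correlated Gaussian (enthalpy, volume) pair with prescribed moments.

    ``kind`` selects the labels of the output pair; currently only the
    "enthalpy_volume" combination used by the c_p / alpha_T / kappa_T
    estimators is provided.  The 2x2 covariance matrix
    [[var_H, cov], [cov, var_V]] must be positive semidefinite.
    """
    if kind != "enthalpy_volume":
        raise ValueError(f"unsupported fixture kind {kind!r}")
    if n < 1:
        raise ValueError("need at least 1 sample")
    cov = np.array([[variance[0], covariance], [covariance, variance[1]]])
    if np.any(np.linalg.eigvalsh(cov) < -1e-12 * max(1.0, abs(cov).max())):
        raise ValueError("covariance matrix is not positive semidefinite")
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(mean, cov, size=n, method="svd")
    h = ObservableSeries(values=samples[:, 0], dt=dt, units="kJ/mol", kind="enthalpy")
    v = ObservableSeries(values=samples[:, 1], dt=dt, units="nm^3", kind="volume")
    return h, v


def gen_coexistence_table(
    T_c: float,
    rho_c: float,
    B_0: float,
    B_1: float,
    C_2: float,
    temperatures,
    noise: float = 0.0,
    seed: int = 0,
) -> CoexistenceTable:
    """Coexistence densities from the Wegner form, optionally noised.

    Noise is multiplicative, (1 + noise * N(0,1)) per table entry.
    """
    t = np.asarray(temperatures, dtype=float)
    if np.any(t >= T_c):
        raise ValueError("all temperatures must lie strictly below T_c")
    rl, rv = wegner_densities(t, T_c, rho_c, B_0, B_1, C_2)
    if noise > 0:
        rng = np.random.default_rng(seed)
        rl = rl * (1.0 + noise * rng.standard_normal(rl.shape))
        rv = rv * (1.0 + noise * rng.standard_normal(rv.shape))
    return CoexistenceTable(temperatures=t, rho_liq=rl, rho_vap=rv)
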