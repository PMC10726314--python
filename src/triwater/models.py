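"""Three-site rigid water models: geometry and electrostatic moments.

A three-site rigid water model is fully specified by five parameters: the
O-H bond length ``d_OH``, the H-H distance ``d_HH`` (together fixing the
H-O-H angle), the oxygen partial charge ``q_O`` (hydrogens carry ``-q_O/2``
each by neutrality and C2v symmetry), and the Lennard-Jones ``sigma`` and
``epsilon_lj`` of the single oxygen-centred site.

The molecular frame places the oxygen at the origin with the C2 (dipole)
axis along +z and the hydrogens mirror-symmetric in the xz-plane.  In that
frame the dipole is mu = 2*(-q_O/2)*d_OH*cos(theta/2) and the traceless
quadrupole tensor Theta_ab = 1/2 sum_i q_i (3 r_ia r_ib - r_i^2 delta_ab)
yields the two independent moments conventionally quoted for water:

    Q_0 = Theta_zz          (linear quadrupole, Buckingham = D*A)
    Q_t = (Theta_xx - Theta_yy) / 2   (tetrahedral quadrupole, D*A)

Q_0 vanishes identically at the tetrahedral angle (cos^2(theta/2) = 1/3),
which is the geometric constraint some published models impose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import E_ANGSTROM_TO_DEBYE

__all__ = [
    "WaterModel",
    "SiteGeometry",
    "ElectrostaticMoments",
    "build_geometry",
    "dipole_moment",
    "quadrupole_moments",
    "electrostatic_moments",
    "preset",
    "available_presets",
    "InvalidGeometryError",
]


class InvalidGeometryError(ValueError):
    """Raised when the three sites cannot form a valid bent molecule."""


@dataclass(frozen=True)
class WaterModel:
    """Five-parameter description of a three-site rigid water model.

    Lengths in nm, charge in e (oxygen, negative), LJ epsilon in kJ/mol.
    """

    name: str
    d_OH: float
    d_HH: float
    q_O: float
    sigma: float
    epsilon_lj: float

    def __post_init__(self) -> None:
        if not (0.0 < self.d_OH < 0.2):
            raise ValueError(f"d_OH must be in (0, 0.2) nm, got {self.d_OH}")
        if not (0.0 < self.d_HH < 0.3):
            raise ValueError(f"d_HH must be in (0, 0.3) nm, got {self.d_HH}")
        if self.d_HH >= 2.0 * self.d_OH:
            raise InvalidGeometryError(
                f"triangle inequality violated: d_HH={self.d_HH} nm >= "
                f"2*d_OH={2.0 * self.d_OH} nm (linear/impossible molecule)"
            )
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.epsilon_lj <= 0.0:
            raise ValueError(f"epsilon_lj must be positive, got {self.epsilon_lj}")
        if self.q_O >= 0.0:
            raise ValueError(f"q_O must be negative, got {self.q_O}")

    @property
    def q_H(self) -> float:
        """Hydrogen charge (e); exactly -q_O/2 by neutrality."""
        return -self.q_O / 2.0

    @property
    def hoh_angle(self) -> float:
        """H-O-H angle in degrees."""
        return math.degrees(2.0 * math.asin(self.d_HH / (2.0 * self.d_OH)))

    def with_(self, **changes) -> "WaterModel":
        return replace(self, **changes)


@dataclass(frozen=True)
class SiteGeometry:
    """Cartesian site coordinates (nm) in the molecular frame.

    O at the origin, C2 axis along +z, hydrogens in the xz-plane.
    """

    oxygen: np.ndarray
    hydrogen1: np.ndarray
    hydrogen2: np.ndarray
    hoh_angle: float  # degrees


@dataclass(frozen=True)
class ElectrostaticMoments:
    """Molecular multipoles: dipole mu (D), quadrupoles q_t and q_0 (D*A)."""

    mu: float
    q_t: float
    q_0: float


def build_geometry(model: WaterModel) -> SiteGeometry:
    """Place the three sites in the molecular frame.

    The hydrogens sit at (+-d_HH/2, 0, z_H) with z_H chosen so that
    |H-O| = d_OH; the dipole then points along +z (the oxygen is negative).
    """
    half = model.d_HH / 2.0
    # WaterModel validation already guarantees half < d_OH
    z_h = math.sqrt(model.d_OH**2 - half**2)
    geom = SiteGeometry(
        oxygen=np.zeros(3),
        hydrogen1=np.array([half, 0.0, z_h]),
        hydrogen2=np.array([-half, 0.0, z_h]),
        hoh_angle=model.hoh_angle,
    )
    return geom


def dipole_moment(model: WaterModel) -> float:
    """Molecular dipole moment in Debye.

    mu = 2 * q_H * d_OH * cos(theta/2); with the oxygen at the origin this
    equals |sum_i q_i r_i| in the molecular frame.
    """
    theta = math.radians(model.hoh_angle)
    mu_e_nm = 2.0 * model.q_H * model.d_OH * math.cos(theta / 2.0)
    return mu_e_nm * 10.0 * E_ANGSTROM_TO_DEBYE  # nm -> A, e*A -> D


def _traceless_quadrupole(model: WaterModel) -> np.ndarray:
    """Traceless quadrupole tensor (D*A) in the molecular frame."""
    geom = build_geometry(model)
    charges = (model.q_O, model.q_H, model.q_H)
    sites = (geom.oxygen, geom.hydrogen1, geom.hydrogen2)
    theta = np.zeros((3, 3))
    for q, r_nm in zip(charges, sites):
        r = r_nm * 10.0  # A
        r2 = float(r @ r)
        theta += 0.5 * q * (3.0 * np.outer(r, r) - r2 * np.eye(3))
    return theta * E_ANGSTROM_TO_DEBYE


def quadrupole_moments(model: WaterModel) -> tuple[float, float]:
    """(Q_t, Q_0) in D*A: tetrahedral and linear quadrupole moments."""
    theta = _traceless_quadrupole(model)
    q_0 = float(theta[2, 2])
    q_t = float((theta[0, 0] - theta[1, 1]) / 2.0)
    return q_t, q_0


def electrostatic_moments(model: WaterModel) -> ElectrostaticMoments:
    """Dipole and quadrupole moments of the model in one record."""
    q_t, q_0 = quadrupole_moments(model)
    return ElectrostaticMoments(mu=dipole_moment(model), q_t=q_t, q_0=q_0)


def _d_hh(d_oh: float, angle_deg: float) -> float:
    return 2.0 * d_oh * math.sin(math.radians(angle_deg) / 2.0)


_TETRAHEDRAL = math.degrees(2.0 * math.asin(math.sqrt(2.0 / 3.0)))  # 109.4712...

# Full-precision parameters from the original model publications.  The
# running-text 3-digit roundings are deliberately not used here; tests that
# compare against rounded literature numbers allow +-0.03 D.
_PRESETS: dict[str, WaterModel] = {
    "SPC": WaterModel("SPC", 0.1, _d_hh(0.1, 109.47), -0.82, 0.3166, 0.650),
    "SPCE": WaterModel("SPCE", 0.1, _d_hh(0.1, 109.47), -0.8476, 0.3166, 0.650),
    "SPCEb": WaterModel("SPCEb", 0.101, _d_hh(0.101, 109.47), -0.8476, 0.3166, 0.650),
    "TIP3P": WaterModel(
        "TIP3P", 0.09572, _d_hh(0.09572, 104.52), -0.834, 0.315061, 0.6364
    ),
    "TIP3P-FB": WaterModel(
        "TIP3P-FB",
        0.101181082494,
        _d_hh(0.101181082494, 108.14844252),
        -0.848448,
        0.317796456355,
        0.652143528104,
    ),
    "OPC3": WaterModel(
        "OPC3", 0.097888, _d_hh(0.097888, _TETRAHEDRAL), -0.89517, 0.317427, 0.683690
    ),
}


def available_presets() -> tuple[str, ...]:
    return tuple(_PRESETS)


def preset(name: str) -> WaterModel:
    """Return a bundled literature parameter set by model name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown water model {name!r}; available three-site presets: "
            f"{', '.join(_PRESETS)}"
        ) from None
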