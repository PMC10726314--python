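"""Degeneracy analysis of repeated optimization solutions.

Repeated swarm optimizations of a three-site water model under identical
constraints do not converge to one parameter vector but to a family of
near-equivalent solutions.  This module quantifies that behaviour: the
solutions are projected with PCA (on standardized parameters, since the
five have incommensurate units), the projected cloud is summarized with
kernel-density isolines, and the conservation of the composite dipole
mu = q*d is contrasted with the spread of the raw charge and geometry
parameters.  A solution set is flagged as dipole-degenerate when the
coefficient of variation of mu across solutions is smaller than that of
both q_O and d_OH individually - different (q, d) combinations, same
dipole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from skimage import measure
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .models import WaterModel, dipole_moment
from .swarm import WATER_PARAM_NAMES, SolutionEnsemble

__all__ = [
    "PCAProjection",
    "DegeneracyReport",
    "pca_project",
    "density_isolines",
    "degeneracy_report",
]


@dataclass(frozen=True)
class PCAProjection:
    coordinates: np.ndarray  # (n_solutions, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_components, ndim), rows are components


@dataclass(frozen=True)
class DegeneracyReport:
    """Per-solution dipoles and dispersion statistics of the ensemble."""

    mu: np.ndarray
    q_O: np.ndarray
    d_OH: np.ndarray
    fitness: np.ndarray
    cv_mu: float
    cv_q: float
    cv_d: float
    degenerate: bool  # CV(mu) below both CV(q_O) and CV(d_OH)


def pca_project(ensemble: SolutionEnsemble, n_components: int = 2) -> PCAProjection:
    """PCA of the solution set on standardized (zero-mean, unit-variance)
    parameters."""
    x = np.asarray(ensemble.positions, dtype=float)
    if len(x) < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} solutions for {n_components} components"
        )
    z = StandardScaler().fit_transform(x)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(z)
    return PCAProjection(
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_,
    )


def density_isolines(
    coordinates: np.ndarray,
    levels,
    grid_resolution: int = 100,
    bandwidth: float | str = "scott",
    padding: float = 0.15,
):
    """Closed contour polylines of a 2-D Gaussian KDE of the projection.

    Returns ``(contours, (xx, yy, density))`` where ``contours`` maps each
    requested level to a list of polylines in data coordinates.  The KDE
    bandwidth follows Scott's rule by default; the evaluated density
    integrates to ~1 over the (padded) grid.
    """
    pts = np.asarray(coordinates, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("need at least 5 two-dimensional points")
    if isinstance(bandwidth, (int, float)) and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    span = pts.max(axis=0) - pts.min(axis=0)
    pad = padding * np.where(span > 0, span, 1.0) + 3.0 * np.sqrt(np.diag(kde.covariance))
    lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad
    xs = np.linspace(lo[0], hi[0], grid_resolution)
    ys = np.linspace(lo[1], hi[1], grid_resolution)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)

    dx, dy = xs[1] - xs[0], ys[1] - ys[0]
    contours: dict[float, list[np.ndarray]] = {}
    for level in np.atleast_1d(levels):
        polylines = []
        for seg in measure.find_contours(dens, float(level)):
            # convert from grid indices to data coordinates
            polylines.append(np.column_stack([lo[0] + seg[:, 0] * dx, lo[1] + seg[:, 1] * dy]))
        contours[float(level)] = polylines
    return contours, (xx, yy, dens)


def _cv(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0.0:
        return 0.0 if float(np.std(values)) == 0.0 else np.inf
    return float(np.std(values) / abs(mean))


def degeneracy_report(ensemble: SolutionEnsemble) -> DegeneracyReport:
    """Contrast the spread of mu against the spread of q_O and d_OH.

    Dipoles are computed through :func:`triwater.models.dipole_moment` on
    each solution row, so the report and the model module share a single
    definition of mu.
    """
    if len(ensemble) < 2:
        raise ValueError("degeneracy analysis needs at least 2 solutions")
    names = ensemble.names or WATER_PARAM_NAMES
    idx = {n: i for i, n in enumerate(names)}
    pos = ensemble.positions
    mu = np.array(
        [
            dipole_moment(
                WaterModel(
                    name=f"solution-{k}",
                    d_OH=row[idx["d_OH"]],
                    d_HH=row[idx["d_HH"]],
                    q_O=row[idx["q_O"]],
                    sigma=row[idx["sigma"]],
                    epsilon_lj=row[idx["epsilon_lj"]],
                )
            )
            for k, row in enumerate(pos)
        ]
    )
    q = pos[:, idx["q_O"]]
    d = pos[:, idx["d_OH"]]
    cv_mu, cv_q, cv_d = _cv(mu), _cv(q), _cv(d)
    return DegeneracyReport(
        mu=mu,
        q_O=q,
        d_OH=d,
        fitness=np.asarray(ensemble.fitnesses),
        cv_mu=cv_mu,
        cv_q=cv_q,
        cv_d=cv_d,
        degenerate=bool(cv_mu < cv_q and cv_mu < cv_d),
    )
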