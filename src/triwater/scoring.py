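"""Squared-cost Earth-mover's score on RDFs and the weighted composite.

The structural discrepancy between a simulated and a reference radial
distribution function is measured with an optimal-transport distance in
which the cost of moving probability mass between bins i and j is the
*square* of the radial separation, (r_i - r_j)^2.  Squaring up-weights
discrepancies at large r, which emphasizes the long-range structure of
liquid water and avoids overfitting the (classically irreproducible) first
peak.  For one-dimensional distributions with a convex cost the monotone
(quantile) coupling is optimal, so the score is computed exactly without a
linear program.

The composite multi-target score combines the transport term with relative
errors on mass density and static dielectric constant, each weighted
(defaults 0.5 / 0.3 / 0.2) and averaged over the temperatures in the
training set.  The transport term is normalized per curve by the distance
between the reference curve and the featureless g = 1 curve, which makes
the three terms commensurate dimensionless numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .observables import RDFCurve

__all__ = [
    "ScoreWeights",
    "ScoreBreakdown",
    "StatePoint",
    "emd_squared",
    "score_micro",
    "score_multi",
]

PAIRS = ("OO", "OH", "HH")


@dataclass(frozen=True)
class ScoreWeights:
    """Relative weights of the RDF, density and dielectric terms."""

    w_emd: float = 0.5
    w_rho: float = 0.3
    w_eps: float = 0.2

    def __post_init__(self) -> None:
        if min(self.w_emd, self.w_rho, self.w_eps) < 0:
            raise ValueError("weights must be nonnegative")
        if self.w_emd + self.w_rho + self.w_eps <= 0:
            raise ValueError("at least one weight must be positive")


@dataclass(frozen=True)
class StatePoint:
    """RDF triplet plus macroscopic observables at one temperature."""

    temperature: float
    rdfs: Mapping[str, RDFCurve]
    density: float
    dielectric: float

    def __post_init__(self) -> None:
        missing = [p for p in PAIRS if p not in self.rdfs]
        if missing:
            raise ValueError(f"state point at {self.temperature} K missing RDFs: {missing}")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-term decomposition of the composite score.

    ``emd_by_pair_and_T`` holds the normalized per-curve transport scores;
    ``emd_term``/``rho_term``/``eps_term`` are the unweighted averages and
    ``total`` their weighted sum.
    """

    emd_by_pair_and_T: dict[tuple[float, str], float]
    emd_term: float
    rho_term: float
    eps_term: float
    weights: ScoreWeights = field(default_factory=ScoreWeights)

    @property
    def total(self) -> float:
        w = self.weights
        return w.w_emd * self.emd_term + w.w_rho * self.rho_term + w.w_eps * self.eps_term


def _normalized_mass(curve: RDFCurve, grid: np.ndarray) -> np.ndarray:
    g = curve.g_values
    if not np.array_equal(curve.bin_centers, grid):
        if abs(curve.bin_centers[0] - grid[0]) > grid[-1] or abs(
            curve.bin_centers[-1] - grid[-1]
        ) > grid[-1]:
            raise ValueError("RDF grids are too dissimilar to resample")
        g = np.interp(grid, curve.bin_centers, g)
    total = g.sum()
    if total <= 0:
        raise ValueError("RDF curve has zero total mass")
    return g / total


def _emd_squared_masses(x: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Exact squared-cost transport between two unit-mass histograms on x.

    Monotone coupling: merge the two cumulative distributions and pay
    (x_p - x_q)^2 on each quantile slice.  Optimal for any convex cost.
    """
    cp, cq = np.cumsum(p), np.cumsum(q)
    cp[-1] = cq[-1] = 1.0
    u = np.union1d(cp, cq)
    du = np.diff(np.concatenate(([0.0], u)))
    um = u - du / 2.0  # interior point of each quantile slice
    ip = np.searchsorted(cp, um, side="left")
    iq = np.searchsorted(cq, um, side="left")
    return float(np.sum(du * (x[ip] - x[iq]) ** 2))


def emd_squared(sim: RDFCurve, target: RDFCurve) -> float:
    """Squared-cost Wasserstein distance between two RDF curves, in A^2.

    Both curves are normalized to unit total mass over the simulation
    grid (the target is linearly resampled onto it if the grids differ);
    bin values are used as-is, with no shell-volume weighting.
    """
    grid = sim.bin_centers
    p = _normalized_mass(sim, grid)
    q = _normalized_mass(target, grid)
    return _emd_squared_masses(grid, p, q)


def emd_to_flat(target: RDFCurve) -> float:
    """Transport distance from the target curve to the featureless g = 1."""
    flat = RDFCurve(
        bin_centers=target.bin_centers,
        g_values=np.ones_like(target.g_values),
        cutoff=target.cutoff,
        pair_label=target.pair_label,
    )
    return emd_squared(flat, target)


def score_micro(
    sim_rdfs: Mapping[str, RDFCurve], target_rdfs: Mapping[str, RDFCurve]
) -> float:
    """Purely structural score: mean of the three per-pair transport terms."""
    for p in PAIRS:
        if p not in sim_rdfs or p not in target_rdfs:
            raise ValueError(f"missing RDF for pair {p!r}")
    return float(np.mean([emd_squared(sim_rdfs[p], target_rdfs[p]) for p in PAIRS]))


def score_multi(
    sim: Sequence[StatePoint],
    target: Sequence[StatePoint],
    weights: ScoreWeights | None = None,
) -> ScoreBreakdown:
    """Composite micro + macro score over a set of temperatures.

    total = w_emd <EMD/EMD_ref> + w_rho <|rho_sim - rho_ref|/rho_ref>
          + w_eps <|eps_sim - eps_ref|/eps_ref>,
    with averages over the three pairs and all shared temperatures.  The
    total is zero iff every simulated quantity matches its target.
    """
    weights = weights or ScoreWeights()
    sim_by_t = {round(s.temperature, 6): s for s in sim}
    tgt_by_t = {round(s.temperature, 6): s for s in target}
    if set(sim_by_t) != set(tgt_by_t):
        raise ValueError(
            f"temperature sets differ: sim {sorted(sim_by_t)} vs target {sorted(tgt_by_t)}"
        )

    emd_table: dict[tuple[float, str], float] = {}
    rho_errs, eps_errs = [], []
    for t in sorted(sim_by_t):
        s, g = sim_by_t[t], tgt_by_t[t]
        for p in PAIRS:
            ref = emd_to_flat(g.rdfs[p])
            raw = emd_squared(s.rdfs[p], g.rdfs[p])
            emd_table[(t, p)] = raw / ref if ref > 0 else raw
        rho_errs.append(abs(s.density - g.density) / abs(g.density))
        eps_errs.append(abs(s.dielectric - g.dielectric) / abs(g.dielectric))

    return ScoreBreakdown(
        emd_by_pair_and_T=emd_table,
        emd_term=float(np.mean(list(emd_table.values()))),
        rho_term=float(np.mean(rho_errs)),
        eps_term=float(np.mean(eps_errs)),
        weights=weights,
    )
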