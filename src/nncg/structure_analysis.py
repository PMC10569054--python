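"""Structural observables: RDF, PMF, angular distributions, three-body maps.

The RDF normalization divides each bin's pair count by the ideal-gas
expectation N(N-1)/2 * 4 pi r^2 dr / V with the shell volume evaluated at
the bin center (an exact-shell alternative is a flag).  The PMF is the
Boltzmann inversion -kT ln g with the zero-RDF core replaced by a linear
repulsive ramp continuous at the first populated bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config_io import PeriodicConfiguration, minimum_image
from .descriptors import DescriptorSpec, g2_matrix
from .network import NetworkParams, total_energy

__all__ = [
    "RDFGrid",
    "RDFCurve",
    "PMFTable",
    "rdf",
    "pmf_from_rdf",
    "pmf_total_energy",
    "angular_distribution",
    "three_body_map",
]


@dataclass(frozen=True)
class RDFGrid:
    """Uniform radial grid from 0 to r_max; bin a covers [a*dr, (a+1)*dr)."""

    r_max: float
    n_bins: int
    exact_shell: bool = False

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.n_bins < 1:
            raise ValueError("r_max must be > 0 and n_bins >= 1")

    @property
    def dr(self) -> float:
        return self.r_max / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dr

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.dr

    def ideal_counts(self, n_sites: int, volume: float) -> np.ndarray:
        """Expected pair count per bin for an ideal gas of n_sites in volume."""
        npairs = n_sites * (n_sites - 1) / 2
        if self.exact_shell:
            e = self.edges
            shell = 4.0 / 3.0 * np.pi * (e[1:] ** 3 - e[:-1] ** 3)
        else:
            shell = 4.0 * np.pi * self.centers**2 * self.dr
        return npairs * shell / volume

    def compatible(self, other: "RDFGrid") -> bool:
        return (
            self.n_bins == other.n_bins
            and abs(self.r_max - other.r_max) < 1e-9
        )


@dataclass
class RDFCurve:
    grid: RDFGrid
    g: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.float64)
        if self.g.shape != (self.grid.n_bins,):
            raise ValueError("g length must match the grid")
        if np.any(self.g < -1e-12):
            raise ValueError("g must be non-negative")

    @property
    def r(self) -> np.ndarray:
        return self.grid.centers


@dataclass
class PMFTable:
    """-kT ln g with a linear repulsive core; finite everywhere.

    ``core_index`` is the first bin with nonzero g (alpha_0); ``core_slope``
    the per-bin increment dV used below it.
    """

    grid: RDFGrid
    values: np.ndarray
    core_index: int
    core_slope: float

    def as_pair_potential(self):
        from .mc_sampler import TabulatedPairPotential

        return TabulatedPairPotential(self.values, self.grid.dr)


def rdf(
    frames: Sequence[PeriodicConfiguration],
    grid: RDFGrid,
    allow_small_box: bool = False,
) -> RDFCurve:
    """Frame-averaged radial distribution function."""
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame list")
    acc = np.zeros(grid.n_bins)
    for cfg in frames:
        if cfg.n_sites < 2:
            raise ValueError("frames must contain at least 2 sites")
        if not allow_small_box and grid.r_max > min(cfg.box) / 2 + 1e-9:
            raise ValueError(
                "grid r_max exceeds half the smallest box length; "
                "pass allow_small_box=True to override"
            )
        r = cfg.pair_distances()
        iu = np.triu_indices(cfg.n_sites, k=1)
        counts, _ = np.histogram(r[iu], bins=grid.n_bins, range=(0.0, grid.r_max))
        norm = grid.ideal_counts(cfg.n_sites, float(np.prod(cfg.box)))
        acc += counts / norm
    return RDFCurve(grid, acc / len(frames))


def pmf_from_rdf(ref: RDFCurve, thermo) -> PMFTable:
    """Boltzmann inversion with a linear core extrapolation.

    V(r_a) = -kT ln g(r_a) on populated bins; below the first populated bin
    alpha_0, V(r_a) = V(r_{a0}) + (a0 - a) * dV with
    dV = V(r_{a0}) - V(r_{a0 + 1}).
    """
    g = ref.g
    nonzero = np.where(g > 0)[0]
    if nonzero.size == 0:
        raise ValueError("RDF is zero everywhere; cannot build a PMF")
    kt = 1.0 / thermo.beta  # energies in reduced units
    a0 = int(nonzero[0])
    v = np.zeros_like(g)
    pop = g > 0
    v[pop] = -kt * np.log(g[pop])
    if a0 + 1 < g.size and g[a0 + 1] > 0:
        dv = v[a0] - v[a0 + 1]
    else:
        dv = kt  # single populated bin: fall back to a kT-per-bin ramp
    if dv <= 0:
        dv = abs(dv) if dv != 0 else kt
    alphas = np.arange(a0)
    v[:a0] = v[a0] + (a0 - alphas) * dv
    # interior zero-g holes (possible in undersampled references): bridge
    # linearly between populated neighbors so the table stays finite
    holes = np.where(~pop[a0:])[0] + a0
    if holes.size:
        populated = np.where(pop)[0]
        v[holes] = np.interp(holes, populated, v[populated])
    return PMFTable(grid=ref.grid, values=v, core_index=a0, core_slope=dv)


def pmf_total_energy(config: PeriodicConfiguration, pmf: PMFTable) -> float:
    """Sum of tabulated pair energies; pairs beyond the grid contribute 0."""
    r = config.pair_distances()
    iu = np.triu_indices(config.n_sites, k=1)
    rr = r[iu]
    idx = np.floor(rr / pmf.grid.dr).astype(np.int64)
    ok = (idx < pmf.grid.n_bins) & np.isfinite(rr)
    return float(pmf.values[idx[ok]].sum())


def _triplet_angles(cfg: PeriodicConfiguration, r_shell: float) -> np.ndarray:
    """Angles (deg) at each central site over all unordered neighbor pairs."""
    angles = []
    pos = cfg.positions
    for n in range(cfg.n_sites):
        d = minimum_image(np.delete(pos, n, axis=0) - pos[n], cfg.box)
        r = np.sqrt((d**2).sum(axis=1))
        near = d[r < r_shell]
        m = near.shape[0]
        if m < 2:
            continue
        u = near / np.sqrt((near**2).sum(axis=1))[:, None]
        cosang = u @ u.T
        iu = np.triu_indices(m, k=1)
        angles.append(np.degrees(np.arccos(np.clip(cosang[iu], -1.0, 1.0))))
    if not angles:
        return np.empty(0)
    return np.concatenate(angles)


def angle_histogram(angles: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-bin probability over [0, 180] deg, multiplied by n_bins.

    The x n_bins convention makes the curve independent of the binning
    (a flat angle distribution maps to 1.0 in every bin).
    """
    if angles.size == 0:
        raise ValueError("no triplets found within the shell")
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    return counts / counts.sum() * n_bins


def angular_distribution(
    frames: Sequence[PeriodicConfiguration],
    r_shell: float = 6.2,
    n_bins: int = 90,
) -> tuple[np.ndarray, np.ndarray]:
    """Triplet-angle density in the first coordination shell.

    For every central site, all unordered pairs of neighbors within
    ``r_shell`` define an angle at the center; the pooled histogram is
    normalized to per-bin probability and multiplied by ``n_bins``.
    Returns (bin centers in degrees, curve).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame list")
    if r_shell > min(min(f.box) for f in frames) / 2 + 1e-9:
        raise ValueError("r_shell exceeds half the smallest box length")
    pooled = [_triplet_angles(f, r_shell) for f in frames]
    angles = np.concatenate([a for a in pooled if a.size] or [np.empty(0)])
    centers = (np.arange(n_bins) + 0.5) * 180.0 / n_bins
    return centers, angle_histogram(angles, n_bins)


def three_body_map(
    spec: DescriptorSpec,
    params: NetworkParams,
    r12: float,
    half_extent: float = 8.0,
    n_grid: int = 41,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three-body energy component of the network on an in-plane grid.

    Two sites sit at +-r12/2 on the x axis of a box large enough that no
    periodic image is within the cutoff; a third site scans the z=0 plane.
    dE3(p) = E(1,2,p) - E(1,2) - E(1,p) - E(2,p), with each pair energy
    evaluated for the isolated pair.  For a linear (no-hidden-layer)
    network dE3 vanishes identically because site energies are sums over
    pair terms.  Returns (x grid, y grid, dE3 map shaped (ny, nx)).
    """
    box_l = 4.0 * spec.r_c + r12 + 2 * half_extent
    box = np.array([box_l, box_l, box_l])
    c = box_l / 2.0
    p1 = np.array([c - r12 / 2.0, c, 0.0])
    p2 = np.array([c + r12 / 2.0, c, 0.0])

    def energy(points: list[np.ndarray]) -> float:
        cfg = PeriodicConfiguration(np.vstack(points), box)
        return total_energy(
            g2_matrix(cfg, spec, allow_small_box=True), params
        ).total

    e12 = energy([p1, p2])
    xs = np.linspace(c - r12 / 2.0 - half_extent, c + r12 / 2.0 + half_extent, n_grid)
    ys = np.linspace(c - half_extent, c + half_extent, n_grid)
    out = np.empty((ys.size, xs.size))
    for jy, y in enumerate(ys):
        for jx, x in enumerate(xs):
            p3 = np.array([x, y, 0.0])
            e123 = energy([p1, p2, p3])
            e13 = energy([p1, p3])
            e23 = energy([p2, p3])
            out[jy, jx] = e123 - e12 - e13 - e23
    return xs - c, ys - c, out
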