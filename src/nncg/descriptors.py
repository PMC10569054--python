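"""Radial symmetry functions G2 with a smooth cosine cutoff.

Each CG site n gets a K-vector of descriptors

    G2_{n,i} = sum_{k != n} exp(-eta_i (r_nk - rs_i)^2) * fc(r_nk)

with the Behler-Parrinello cutoff fc(r) = 0.5*(cos(pi r / r_c) + 1) for
r <= r_c and 0 beyond.  Distances use the minimum-image convention in an
orthorhombic box.  The descriptors are invariant to rigid translations and
rotations and permutation-equivariant in the site index.

A piecewise-constant "indicator" variant (a hard pair-distance histogram
per site, no smooth cutoff) exists solely for the linear-network/IMC
equivalence analysis and is rejected by the MC sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config_io import PeriodicConfiguration, minimum_image

__all__ = ["DescriptorSpec", "cutoff_fc", "g2_site", "g2_matrix", "g2_delta"]


@dataclass
class DescriptorSpec:
    """A set of (eta, rs) Gaussian parameters sharing one cutoff r_c.

    eta in A^-2, rs and r_c in A.  kind is "gaussian" (production) or
    "indicator" (piecewise-constant bins centered at rs, width = rs spacing;
    analysis only).  smooth_cutoff=False drops fc inside r_c (hard cutoff),
    used when comparing against histogram-based energies.
    """

    eta: np.ndarray
    rs: np.ndarray
    r_c: float
    kind: str = "gaussian"
    smooth_cutoff: bool = True

    def __post_init__(self) -> None:
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=np.float64))
        self.rs = np.atleast_1d(np.asarray(self.rs, dtype=np.float64))
        if self.eta.shape != self.rs.shape:
            raise ValueError("eta and rs must have the same length")
        if self.eta.size < 1:
            raise ValueError("at least one descriptor is required")
        if self.r_c <= 0:
            raise ValueError("cutoff r_c must be positive")
        if np.any(self.eta < 0):
            raise ValueError("eta must be non-negative")
        if np.any((self.rs < 0) | (self.rs >= self.r_c)):
            raise ValueError("rs must satisfy 0 <= rs < r_c")
        if self.kind not in ("gaussian", "indicator"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")

    @property
    def n_descriptors(self) -> int:
        return int(self.eta.size)

    # -- built-in production sets ------------------------------------------

    @classmethod
    def set1(cls, r_c: float = 10.0) -> "DescriptorSpec":
        """8 G2 functions: one wide at 0 A (eta=0.125 A^-2) plus seven
        eta=4.0 A^-2 Gaussians centered 3.0-6.0 A in 0.5 A steps."""
        eta = [0.125] + [4.0] * 7
        rs = [0.0] + [3.0 + 0.5 * k for k in range(7)]
        return cls(np.array(eta), np.array(rs), r_c)

    @classmethod
    def set2(cls, r_c: float = 10.0) -> "DescriptorSpec":
        """24 G2 functions: Set 1 plus a wider eta=0.02 A^-2 at 0 A, nine
        eta=16.0 A^-2 between 3 and 5 A (0.25 A steps) and six eta=2.0 A^-2
        between 3 and 8 A (1.0 A steps)."""
        s1 = cls.set1(r_c)
        eta = np.concatenate(
            [s1.eta, [0.02], [16.0] * 9, [2.0] * 6]
        )
        rs = np.concatenate(
            [s1.rs, [0.0], 3.0 + 0.25 * np.arange(9), 3.0 + 1.0 * np.arange(6)]
        )
        return cls(eta, rs, r_c)

    @classmethod
    def indicator_bins(cls, dr: float, n_bins: int) -> "DescriptorSpec":
        """Histogram-like basis: bin alpha covers [alpha*dr, (alpha+1)*dr)."""
        centers = (np.arange(n_bins) + 0.5) * dr
        return cls(
            np.zeros(n_bins), centers, r_c=n_bins * dr, kind="indicator",
            smooth_cutoff=False,
        )

    # -- per-pair response --------------------------------------------------

    def pair_terms(self, r: np.ndarray) -> np.ndarray:
        """K-vector contribution of pair distance(s) r; shape (..., K)."""
        r = np.asarray(r, dtype=np.float64)
        if self.kind == "indicator":
            width = self.rs[1] - self.rs[0] if self.rs.size > 1 else 2 * self.rs[0]
            idx = np.floor(r[..., None] / width).astype(int)
            k = np.arange(self.n_descriptors)
            out = (idx == k) & (r[..., None] < self.r_c)
            return out.astype(np.float64)
        fc = cutoff_fc(r, self.r_c) if self.smooth_cutoff else (
            (r < self.r_c).astype(np.float64)
        )
        return np.exp(-self.eta * (r[..., None] - self.rs) ** 2) * fc[..., None]


def cutoff_fc(r: np.ndarray | float, r_c: float) -> np.ndarray | float:
    """Smooth cosine cutoff: 0.5*(cos(pi r/r_c)+1) inside r_c, 0 beyond."""
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    r = np.asarray(r, dtype=np.float64)
    out = np.where(r < r_c, 0.5 * (np.cos(np.pi * np.minimum(r, r_c) / r_c) + 1.0), 0.0)
    return out if out.ndim else float(out)


def _check_cutoff(spec: DescriptorSpec, box: np.ndarray, override: bool) -> None:
    if not override and spec.r_c > min(box) / 2 + 1e-9:
        raise ValueError(
            f"descriptor cutoff {spec.r_c} exceeds half the smallest box "
            f"length ({min(box) / 2:.3f}); pass allow_small_box=True to override"
        )


def g2_site(
    config: PeriodicConfiguration,
    n: int,
    spec: DescriptorSpec,
    allow_small_box: bool = False,
) -> np.ndarray:
    """Descriptor K-vector of site n (minimum-image distances)."""
    _check_cutoff(spec, config.box, allow_small_box)
    delta = minimum_image(
        np.delete(config.positions, n, axis=0) - config.positions[n], config.box
    )
    r = np.sqrt((delta**2).sum(axis=1))
    return spec.pair_terms(r).sum(axis=0)


def g2_matrix(
    config: PeriodicConfiguration,
    spec: DescriptorSpec,
    allow_small_box: bool = False,
) -> np.ndarray:
    """Full N x K descriptor matrix."""
    _check_cutoff(spec, config.box, allow_small_box)
    r = config.pair_distances()
    near = r < spec.r_c
    n = config.n_sites
    out = np.zeros((n, spec.n_descriptors))
    for i in range(n):
        ri = r[i][near[i]]
        if ri.size:
            out[i] = spec.pair_terms(ri).sum(axis=0)
    return out


def g2_delta(
    config: PeriodicConfiguration,
    moved_site: int,
    old_pos: np.ndarray,
    new_pos: np.ndarray,
    spec: DescriptorSpec,
    cache: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Incremental descriptor update for a single-site move.

    ``cache`` is the N x K matrix consistent with ``config`` *before* the
    move (site ``moved_site`` at ``old_pos``).  Returns ``(updated, rows,
    delta)`` where ``rows`` are the indices whose descriptor rows changed
    and ``delta`` the corresponding row changes; ``updated`` equals a full
    recomputation after the move.
    """
    pos = config.positions
    box = config.box
    old_pos = np.asarray(old_pos, dtype=np.float64)
    new_pos = np.asarray(new_pos, dtype=np.float64)
    others = np.arange(config.n_sites) != moved_site
    idx = np.where(others)[0]
    d_old = minimum_image(pos[others] - old_pos, box)
    d_new = minimum_image(pos[others] - new_pos, box)
    r_old = np.sqrt((d_old**2).sum(axis=1))
    r_new = np.sqrt((d_new**2).sum(axis=1))
    affected = (r_old < spec.r_c) | (r_new < spec.r_c)

    updated = cache.copy()
    term_new = spec.pair_terms(r_new[affected])
    term_old = spec.pair_terms(r_old[affected])
    row_changes = term_new - term_old
    updated[idx[affected]] += row_changes
    new_row = term_new.sum(axis=0) if affected.any() else np.zeros(spec.n_descriptors)
    # contributions of unaffected far neighbors to the moved row are zero
    updated[moved_site] = new_row

    rows = np.concatenate([[moved_site], idx[affected]])
    delta = np.vstack([new_row - cache[moved_site], row_changes])
    return updated, rows, delta
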