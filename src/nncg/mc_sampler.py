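"""Metropolis Monte Carlo sampling of CG configurations.

Single-particle displacement moves (uniform in a cube of half-width
``max_disp``), accepted with min(1, exp(-beta*dE)).  Energies are in
k_B*T so beta = 1; ``ThermoState`` carries the physical temperature for
unit conversions elsewhere.  Non-finite trial energy changes are
rejected.  The step size adapts multiplicatively toward the target
acceptance ratio during equilibration only and is frozen for production
(adapting while accumulating would violate detailed balance).

Besides the RDF, the sampler can accumulate the fluctuation averages
needed by the inverse-Monte-Carlo style loss gradient: <dE/dw_i>,
<g_alpha * dE/dw_i> (network models), or the pair-histogram second
moments <S_alpha S_gamma> (tabulated models, for the IMC baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .config_io import PeriodicConfiguration, RunConfig, minimum_image
from .descriptors import DescriptorSpec, g2_delta, g2_matrix
from .network import NetworkParams, total_energy

__all__ = [
    "ThermoState",
    "LennardJonesPotential",
    "TabulatedPairPotential",
    "NetworkPotential",
    "SamplingAccumulators",
    "metropolis_step",
    "run_sampling",
    "multi_system_sampling",
]

BOLTZMANN_KJ = 0.0083144626  # kJ/(mol K), for callers converting units


@dataclass
class ThermoState:
    """Temperature in K; beta in reciprocal reduced-energy units.

    The package works in k_B*T energy units, so beta defaults to 1; a
    caller using another energy scale can override it.
    """

    temperature: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


# ---------------------------------------------------------------------------
# energy models


@dataclass
class LennardJonesPotential:
    """Truncated (not shifted) LJ pair potential; epsilon in k_B*T units."""

    epsilon: float
    sigma: float
    cutoff: float

    def pair_energy(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=np.float64)
        s6 = (self.sigma / r) ** 6
        return np.where(r < self.cutoff, 4.0 * self.epsilon * (s6 * s6 - s6), 0.0)

    def total_energy(self, config: PeriodicConfiguration) -> float:
        r = config.pair_distances()
        iu = np.triu_indices(config.n_sites, k=1)
        return float(self.pair_energy(r[iu]).sum())

    def delta_energy(
        self, config: PeriodicConfiguration, i: int, new_pos: np.ndarray
    ) -> float:
        return _pair_delta(self, config, i, new_pos)


@dataclass
class TabulatedPairPotential:
    """Pair potential on uniform bins [a*dr, (a+1)*dr); zero beyond the grid."""

    values: np.ndarray
    dr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.dr <= 0:
            raise ValueError("dr must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains non-finite values")

    @property
    def cutoff(self) -> float:
        return self.values.size * self.dr

    def pair_energy(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=np.float64)
        idx = np.floor(r / self.dr).astype(np.int64)
        ok = (idx >= 0) & (idx < self.values.size) & np.isfinite(r)
        return np.where(ok, self.values[np.minimum(idx, self.values.size - 1)], 0.0)

    def total_energy(self, config: PeriodicConfiguration) -> float:
        r = config.pair_distances()
        iu = np.triu_indices(config.n_sites, k=1)
        return float(self.pair_energy(r[iu]).sum())

    def delta_energy(
        self, config: PeriodicConfiguration, i: int, new_pos: np.ndarray
    ) -> float:
        return _pair_delta(self, config, i, new_pos)


def _pair_delta(model, config: PeriodicConfiguration, i: int, new_pos) -> float:
    pos = config.positions
    others = np.arange(config.n_sites) != i
    r_old = np.sqrt(
        (minimum_image(pos[others] - pos[i], config.box) ** 2).sum(axis=1)
    )
    r_new = np.sqrt(
        (minimum_image(pos[others] - np.asarray(new_pos), config.box) ** 2).sum(axis=1)
    )
    return float(model.pair_energy(r_new).sum() - model.pair_energy(r_old).sum())


@dataclass
class NetworkPotential:
    """Behler-Parrinello style energy: site network over G2 descriptors."""

    spec: DescriptorSpec
    params: NetworkParams

    def __post_init__(self) -> None:
        if self.spec.kind != "gaussian" or not self.spec.smooth_cutoff:
            raise ValueError(
                "only smooth Gaussian descriptors are sampled; the indicator "
                "variant is for static analysis"
            )
        if self.spec.n_descriptors != self.params.n_inputs:
            raise ValueError("descriptor count != network input width")

    def total_energy(self, config: PeriodicConfiguration) -> float:
        return total_energy(
            g2_matrix(config, self.spec, allow_small_box=True), self.params
        ).total

    def delta_energy(
        self, config: PeriodicConfiguration, i: int, new_pos: np.ndarray
    ) -> float:
        cache = g2_matrix(config, self.spec, allow_small_box=True)
        updated, rows, _ = g2_delta(
            config, i, config.positions[i], new_pos, self.spec, cache
        )
        e_old = total_energy(cache[rows], self.params).total
        e_new = total_energy(updated[rows], self.params).total
        return e_new - e_old


# ---------------------------------------------------------------------------


@dataclass
class SamplingAccumulators:
    """Post-equilibration averages from one sampling leg.

    ``mean_g`` is the RDF on the run's grid; for network runs
    ``mean_dEdw`` and ``cross_g_dEdw`` hold <dE/dw_i> and
    <g_alpha dE/dw_i>; for covariance runs ``mean_S``/``mean_SS`` hold the
    raw pair-histogram first and second moments.
    """

    r_centers: np.ndarray
    mean_g: np.ndarray
    n_samples: int
    acceptance_ratio: float
    final_max_disp: float
    final_config: PeriodicConfiguration
    mean_hist: np.ndarray
    norm: np.ndarray
    mean_dEdw: np.ndarray | None = None
    cross_g_dEdw: np.ndarray | None = None
    mean_S: np.ndarray | None = None
    mean_SS: np.ndarray | None = None
    frames: list = field(default_factory=list)
    final_energy: float | None = None


def _rdf_norm(n_sites: int, box: np.ndarray, r_max: float, n_bins: int) -> tuple:
    dr = r_max / n_bins
    centers = (np.arange(n_bins) + 0.5) * dr
    volume = float(np.prod(box))
    norm = n_sites * (n_sites - 1) / 2 * 4 * np.pi * centers**2 * dr / volume
    return centers, norm


def metropolis_step(
    config: PeriodicConfiguration,
    model,
    max_disp: float,
    thermo: ThermoState,
    rng: np.random.Generator,
) -> tuple[PeriodicConfiguration, float, bool]:
    """One single-particle trial move; returns (config', dE, accepted)."""
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    i = int(rng.integers(config.n_sites))
    disp = rng.uniform(-max_disp, max_disp, size=3)
    new_pos = config.positions[i] + disp
    new_pos -= config.box * np.floor(new_pos / config.box)
    d_e = model.delta_energy(config, i, new_pos)
    accepted = False
    if np.isfinite(d_e):
        if d_e <= 0 or rng.random() < np.exp(-thermo.beta * d_e):
            accepted = True
    if accepted:
        pos = config.positions.copy()
        pos[i] = new_pos
        return PeriodicConfiguration(pos, config.box, config.species), d_e, True
    return config, d_e, False


def run_sampling(
    start: PeriodicConfiguration,
    model,
    run: RunConfig,
    seed: int | None = None,
    collect_weight_gradient: bool = False,
    collect_histogram_covariance: bool = False,
    n_frames: int = 0,
) -> SamplingAccumulators:
    """Full MC leg: equilibrate (adapting step size), then accumulate.

    Dispatches to the numba kernels for the three model classes.
    """
    if start.n_sites < 2:
        raise ValueError("need at least 2 sites to sample pair structure")
    run.validate_box(start.box)
    seed = run.seed if seed is None else seed
    seed = int(seed) % (2**31 - 1)
    n_bins = run.rdf_n_bins
    dr = run.rdf_r_max / n_bins
    pos0 = start.wrapped().positions
    box = start.box

    if isinstance(model, NetworkPotential):
        sizes = np.asarray(model.params.layer_sizes, dtype=np.int64)
        (
            pos,
            hist_sum,
            sum_dEdw,
            sum_cross,
            n_samples,
            acc,
            max_disp,
            frames,
            fidx,
            final_e,
        ) = _kernels.mc_network(
            pos0,
            box,
            model.spec.eta,
            model.spec.rs,
            float(model.spec.r_c),
            model.params.weights,
            sizes,
            run.n_steps,
            run.n_equil,
            run.output_freq,
            run.adapt_interval,
            run.target_acceptance,
            run.max_disp,
            dr,
            n_bins,
            collect_weight_gradient,
            run.refresh_interval,
            n_frames,
            seed,
        )
        sum_SS = None
    else:
        if isinstance(model, LennardJonesPotential):
            kind = _kernels.KIND_LJ
            eps4 = 4.0 * model.epsilon
            sig2 = model.sigma**2
            rc2 = model.cutoff**2
            table = np.zeros(1)
            dr_t = 1.0
        elif isinstance(model, TabulatedPairPotential):
            kind = _kernels.KIND_TABLE
            eps4 = 0.0
            sig2 = 1.0
            rc2 = 0.0
            table = model.values
            dr_t = model.dr
        else:
            raise TypeError(f"unsupported energy model {type(model).__name__}")
        (
            pos,
            hist_sum,
            sum_SS,
            n_samples,
            acc,
            max_disp,
            frames,
            fidx,
        ) = _kernels.mc_pair(
            pos0,
            box,
            kind,
            eps4,
            sig2,
            rc2,
            table,
            dr_t,
            run.n_steps,
            run.n_equil,
            run.output_freq,
            run.adapt_interval,
            run.target_acceptance,
            run.max_disp,
            dr,
            n_bins,
            collect_histogram_covariance,
            n_frames,
            seed,
        )
        sum_dEdw = sum_cross = None
        final_e = None

    if n_samples == 0:
        raise RuntimeError("no post-equilibration samples were accumulated")
    centers, norm = _rdf_norm(start.n_sites, box, run.rdf_r_max, n_bins)
    mean_hist = hist_sum / n_samples
    mean_g = mean_hist / norm
    acc_obj = SamplingAccumulators(
        r_centers=centers,
        mean_g=mean_g,
        n_samples=int(n_samples),
        acceptance_ratio=float(acc),
        final_max_disp=float(max_disp),
        final_config=PeriodicConfiguration(pos, box.copy(), start.species),
        mean_hist=mean_hist,
        norm=norm,
        frames=[
            PeriodicConfiguration(frames[j].copy(), box.copy(), start.species)
            for j in range(fidx)
        ],
        final_energy=None if final_e is None else float(final_e),
    )
    if collect_weight_gradient and sum_dEdw is not None:
        acc_obj.mean_dEdw = sum_dEdw / n_samples
        # cross term accumulated in raw histogram counts; convert to g units
        acc_obj.cross_g_dEdw = (sum_cross / n_samples) / norm[:, None]
    if collect_histogram_covariance and sum_SS is not None:
        acc_obj.mean_S = mean_hist
        acc_obj.mean_SS = sum_SS / n_samples
    return acc_obj


def derive_seed(master: int, *indices: int) -> int:
    """Deterministic sub-stream seed, kept below 2**31."""
    s = int(master) % 2147483647
    for j, ix in enumerate(indices):
        s = (s * 1000003 + (ix + 1) * (7919 + 104729 * j)) % 2147483647
    return s


def multi_system_sampling(
    systems: Sequence[tuple[PeriodicConfiguration, object]],
    run: RunConfig,
    master_seed: int | None = None,
    seeds: Sequence[int] | None = None,
    **kwargs,
) -> list[SamplingAccumulators]:
    """Sample several (start, model) systems with independent seeded streams.

    Results are independent of execution order: each system's seed is a
    pure function of the master seed and its index.  Any failure aborts the
    whole call with the offending system index.
    """
    if master_seed is None:
        master_seed = run.seed
    out = []
    for idx, (start, model) in enumerate(systems):
        seed = seeds[idx] if seeds is not None else derive_seed(master_seed, idx)
        try:
            out.append(run_sampling(start, model, run, seed=seed, **kwargs))
        except Exception as exc:
            raise RuntimeError(f"sampling failed for system {idx}: {exc}") from exc
    return out
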