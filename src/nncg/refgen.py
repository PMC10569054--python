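"""Self-contained Lennard-Jones reference generator.

Replaces atomistic reference simulations with an exactly known model: a
truncated LJ fluid sampled by the same Metropolis engine used for
training.  A single state point yields a reference RDF plus equilibrated
frames; a state-point series (densities and optionally well depths
varying together) gives the trainer the "one network, many reference
RDFs" problem shape of a concentration series.

Default liquid-argon parameters: sigma = 3.405 A, eps/k_B = 119.8 K at
T = 95 K and rho = 1374 kg/m^3 (512 atoms in a ~29.1 A cubic box).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config_io import PeriodicConfiguration, RunConfig
from .mc_sampler import LennardJonesPotential, run_sampling
from .structure_analysis import RDFCurve, RDFGrid

__all__ = ["StatePoint", "ReferenceBundle", "lj_reference", "state_series", "ARGON"]

AVOGADRO = 6.02214076e23


@dataclass
class StatePoint:
    """Thermodynamic state + LJ parameters for one reference system.

    Either ``box_length`` (A) or ``density`` (kg/m^3, with ``mass`` in
    g/mol) fixes the cubic box; giving both requires consistency.
    """

    n_particles: int = 512
    temperature: float = 95.0
    epsilon_k: float = 119.8      # LJ well depth as eps/k_B, Kelvin
    sigma: float = 3.405          # A
    cutoff: float = 10.0          # A
    density: float | None = 1374.0  # kg/m^3
    mass: float = 39.948          # g/mol
    box_length: float | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        box_from_density = None
        if self.density is not None:
            # V [A^3] = N * m[g/mol] / (N_A * rho[g/cm^3]) * 1e24
            rho_gcm3 = self.density / 1000.0
            vol = self.n_particles * self.mass / (AVOGADRO * rho_gcm3) * 1e24
            box_from_density = vol ** (1.0 / 3.0)
        if self.box_length is None:
            if box_from_density is None:
                raise ValueError("give either density (+mass) or box_length")
            self.box_length = box_from_density
        elif box_from_density is not None and not np.isclose(
            self.box_length, box_from_density, rtol=1e-3
        ):
            raise ValueError(
                f"box_length {self.box_length} inconsistent with density "
                f"(implies {box_from_density:.4f} A)"
            )
        if self.cutoff > self.box_length / 2 + 1e-9:
            raise ValueError("LJ cutoff must be <= half the box length")

    @property
    def epsilon_kt(self) -> float:
        """Well depth in k_B*T units at this state point's temperature."""
        return self.epsilon_k / self.temperature

    @property
    def box(self) -> np.ndarray:
        return np.array([self.box_length] * 3)

    def potential(self) -> LennardJonesPotential:
        return LennardJonesPotential(
            epsilon=self.epsilon_kt, sigma=self.sigma, cutoff=self.cutoff
        )

    def lattice_start(self) -> PeriodicConfiguration:
        """Simple-cubic initial placement (deterministic, overlap-free)."""
        n_side = int(np.ceil(self.n_particles ** (1.0 / 3.0)))
        spacing = self.box_length / n_side
        idx = np.arange(n_side)
        gx, gy, gz = np.meshgrid(idx, idx, idx, indexing="ij")
        pts = np.column_stack([g.ravel() for g in (gx, gy, gz)]).astype(float)
        pts = (pts + 0.5) * spacing
        return PeriodicConfiguration(pts[: self.n_particles], self.box)


ARGON = StatePoint()  # the liquid-argon defaults above


@dataclass
class ReferenceBundle:
    """Everything the trainer needs about one reference state point."""

    label: str
    state: StatePoint
    rdf: RDFCurve
    frames: list[PeriodicConfiguration]
    log: dict = field(default_factory=dict)


def default_run(sp: StatePoint, production_scale: bool = False) -> RunConfig:
    """Reference-generation MC budget.

    Desk default 2e7 steps (1e6 equilibration); ``production_scale``
    switches to the full 1.2e9-step / 6e7-equilibration protocol with
    1e6-step output.
    """
    if production_scale:
        return RunConfig(
            n_steps=1_200_000_000,
            n_equil=60_000_000,
            temperature=sp.temperature,
            output_freq=1_000_000,
            rdf_r_max=min(10.0, sp.box_length / 2),
            rdf_n_bins=400,
        )
    return RunConfig(
        n_steps=20_000_000,
        n_equil=1_000_000,
        temperature=sp.temperature,
        output_freq=1000,
        rdf_r_max=min(10.0, sp.box_length / 2),
        rdf_n_bins=400,
    )


def lj_reference(
    sp: StatePoint,
    run: RunConfig | None = None,
    seed: int = 0,
    n_frames: int = 200,
    label: str = "lj",
) -> ReferenceBundle:
    """Equilibrate and sample the exact LJ fluid; save evenly spaced frames."""
    if run is None:
        run = default_run(sp)
    start = sp.lattice_start()
    acc = run_sampling(
        start, sp.potential(), run, seed=seed, n_frames=n_frames
    )
    grid = RDFGrid(run.rdf_r_max, run.rdf_n_bins)
    curve = RDFCurve(grid, acc.mean_g)
    return ReferenceBundle(
        label=label,
        state=sp,
        rdf=curve,
        frames=acc.frames,
        log={
            "acceptance_ratio": acc.acceptance_ratio,
            "final_max_disp": acc.final_max_disp,
            "n_samples": acc.n_samples,
            "seed": seed,
        },
    )


def state_series(
    base: StatePoint,
    densities: list[float],
    labels: list[str] | None = None,
    epsilons_k: list[float] | None = None,
    run: RunConfig | None = None,
    seed: int = 0,
    n_frames: int = 200,
) -> list[ReferenceBundle]:
    """Reference bundles at several densities (kg/m^3), optionally with
    per-state LJ well depths — the multi-state-point training family."""
    if len(densities) < 1:
        raise ValueError("need at least one state point")
    if labels is None:
        labels = [f"rho{d:g}" for d in densities]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate state-point labels")
    if len(labels) != len(densities):
        raise ValueError("one label per density required")
    if epsilons_k is not None and len(epsilons_k) != len(densities):
        raise ValueError("one epsilon per density required")
    out = []
    for j, (rho, lab) in enumerate(zip(densities, labels)):
        eps = epsilons_k[j] if epsilons_k is not None else base.epsilon_k
        sp = replace(base, density=rho, box_length=None, epsilon_k=eps)
        sp_run = run
        if sp_run is not None and sp_run.rdf_r_max > sp.box_length / 2:
            raise ValueError(
                f"state point {lab!r}: RDF range exceeds half box"
            )
        out.append(
            lj_reference(
                sp,
                run=sp_run,
                seed=seed + 97 * j,
                n_frames=n_frames,
                label=lab,
            )
        )
    return out
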