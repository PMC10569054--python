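"""Classic inverse Monte Carlo with a tabulated pair potential.

The total energy is E = sum_alpha w_alpha S_alpha where S_alpha is the
unordered pair-distance histogram on the RDF grid and w_alpha the
potential value in bin alpha.  The same fluctuation relation the network
trainer uses is exact in this basis:

    d<S_a>/dw_g = -beta * ( <S_a S_g> - <S_a><S_g> )

so one IMC iteration solves Cov * dw = <dS>/beta (pseudo-inverse,
relative singular-value cutoff 1e-10) and applies a regularized fraction
of dw.  A linear G2 network degenerates to exactly this scheme when its
descriptors are pair-distance bin indicators — `linear_nn_imc_equivalence`
quantifies the correspondence, including how close narrow Gaussians come
to the histogram basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config_io import PeriodicConfiguration, RunConfig
from .descriptors import DescriptorSpec, g2_matrix
from .mc_sampler import TabulatedPairPotential, ThermoState, run_sampling
from .network import NetworkParams, total_energy
from .structure_analysis import RDFCurve, RDFGrid, pmf_from_rdf

__all__ = [
    "pair_histogram",
    "imc_iterate",
    "run_imc",
    "linear_nn_imc_equivalence",
    "EquivalenceReport",
]

PINV_RCOND = 1e-10


def pair_histogram(config: PeriodicConfiguration, grid: RDFGrid) -> np.ndarray:
    """Integer pair counts S_alpha on the grid (minimum-image distances)."""
    r = config.pair_distances()
    iu = np.triu_indices(config.n_sites, k=1)
    counts, _ = np.histogram(r[iu], bins=grid.n_bins, range=(0.0, grid.r_max))
    return counts.astype(np.int64)


@dataclass
class IMCDiagnostics:
    loss: float
    sampled: RDFCurve
    delta_w_norm: float
    acceptance_ratio: float


def imc_iterate(
    reference: RDFCurve,
    table: TabulatedPairPotential,
    start: PeriodicConfiguration,
    run: RunConfig,
    regularization: float,
    thermo: ThermoState | None = None,
    seed: int = 0,
) -> tuple[TabulatedPairPotential, IMCDiagnostics]:
    """One IMC update of the tabulated potential toward the reference RDF."""
    if not (0.0 < regularization <= 1.0):
        raise ValueError("regularization must be in (0, 1]")
    grid = reference.grid
    if abs(table.dr - grid.dr) > 1e-9 or table.values.size != grid.n_bins:
        raise ValueError("potential table and reference RDF grids differ")
    if thermo is None:
        thermo = ThermoState(run.temperature)
    acc = run_sampling(
        start, table, run, seed=seed, collect_histogram_covariance=True
    )
    mean_S = acc.mean_S
    cov = acc.mean_SS - np.outer(mean_S, mean_S)
    if not np.any(cov):
        raise RuntimeError("all-zero histogram covariance; cannot update")
    s_ref = reference.g * acc.norm
    delta_s = mean_S - s_ref
    # d<S>/dw = -beta Cov  =>  Cov dw = delta_s / beta cancels the deviation
    delta_w = np.linalg.pinv(cov, rcond=PINV_RCOND) @ delta_s / thermo.beta
    new_values = table.values + regularization * delta_w
    sampled = RDFCurve(grid, acc.mean_g)
    diag = IMCDiagnostics(
        loss=float(((acc.mean_g - reference.g) ** 2).sum()),
        sampled=sampled,
        delta_w_norm=float(np.linalg.norm(regularization * delta_w)),
        acceptance_ratio=acc.acceptance_ratio,
    )
    return TabulatedPairPotential(new_values, table.dr), diag


def run_imc(
    reference: RDFCurve,
    starts: list[PeriodicConfiguration],
    run: RunConfig,
    schedule: list[tuple[int, float]] = ((5, 0.5), (5, 1.0)),
    thermo: ThermoState | None = None,
    initial: TabulatedPairPotential | None = None,
    seed: int = 0,
) -> tuple[TabulatedPairPotential, list[IMCDiagnostics]]:
    """Iterate IMC with a (n_iterations, regularization) schedule.

    Starts from the PMF of the reference RDF unless an initial table is
    given; each iteration restarts MC from a rotating start frame.
    """
    if thermo is None:
        thermo = ThermoState(run.temperature)
    table = initial
    if table is None:
        pmf = pmf_from_rdf(reference, thermo)
        table = TabulatedPairPotential(pmf.values, reference.grid.dr)
    history: list[IMCDiagnostics] = []
    it = 0
    for n_iter, reg in schedule:
        for _ in range(n_iter):
            start = starts[it % len(starts)]
            table, diag = imc_iterate(
                reference, table, start, run, reg, thermo, seed=seed + 31 * it
            )
            history.append(diag)
            it += 1
    return table, history


# ---------------------------------------------------------------------------
# linear-network / IMC equivalence


@dataclass
class EquivalenceReport:
    """Linear-G2-network vs pair-histogram comparison on a config set.

    ``energy_max_abs_dev`` / ``energy_rms_rel_dev`` compare per-config
    total energies; ``gradient_max_abs_dev`` compares the fluctuation
    d<g>/dw rows against the IMC covariance rows over the same configs
    (populated in indicator mode, where the two are the same estimator).
    """

    energies_nn: np.ndarray
    energies_hist: np.ndarray
    energy_max_abs_dev: float
    energy_rms_rel_dev: float
    gradient_max_abs_dev: float | None = None
    details: dict = field(default_factory=dict)


def _hist_set(configs, grid: RDFGrid) -> np.ndarray:
    return np.array([pair_histogram(c, grid) for c in configs], dtype=np.float64)


def linear_nn_imc_equivalence(
    grid: RDFGrid,
    configs: list[PeriodicConfiguration],
    table_weights: np.ndarray,
    eta: float | None = None,
    thermo: ThermoState | None = None,
) -> EquivalenceReport:
    """Compare a linear G2 network against the histogram (IMC) energy form.

    ``table_weights`` w_alpha is the pair potential per bin; the network
    carries w_alpha / 2 per descriptor because every pair enters two site
    sums.  With ``eta=None`` the descriptors are exact bin indicators and
    the correspondence is an identity (checked to round-off, gradient rows
    included).  With a finite ``eta``, Gaussians sit at the bin centers and
    the network's soft pair counts are compared to the hard histogram
    after dividing by the mean Gaussian bin mass sqrt(pi/eta)/dr.
    """
    if thermo is None:
        thermo = ThermoState(300.0)
    table_weights = np.asarray(table_weights, dtype=np.float64)
    if table_weights.size != grid.n_bins:
        raise ValueError("one weight per grid bin required")
    S = _hist_set(configs, grid)                  # (n_cfg, n_bins)
    energies_hist = S @ table_weights

    if eta is None:
        spec = DescriptorSpec.indicator_bins(grid.dr, grid.n_bins)
        scale = 1.0
    else:
        spec = DescriptorSpec(
            eta=np.full(grid.n_bins, float(eta)),
            rs=grid.centers,
            r_c=grid.r_max,
            smooth_cutoff=False,
        )
        scale = np.sqrt(np.pi / eta) / grid.dr
    params = NetworkParams((grid.n_bins, 1), table_weights / 2.0)

    g2_sets = [g2_matrix(c, spec, allow_small_box=True) for c in configs]
    energies_nn = np.array(
        [total_energy(G, params).total for G in g2_sets]
    ) / scale

    dev = energies_nn - energies_hist
    rms_hist = float(np.sqrt(np.mean(energies_hist**2)))
    report = EquivalenceReport(
        energies_nn=energies_nn,
        energies_hist=energies_hist,
        energy_max_abs_dev=float(np.max(np.abs(dev))),
        energy_rms_rel_dev=float(np.sqrt(np.mean(dev**2)) / rms_hist),
    )

    if eta is None:
        # gradient rows: treat the config set as the sampled ensemble.
        # network side: dE/dw_i = sum_n G2_{n,i} = 2 S_i; fluctuation rows
        # -beta Cov(g_a, 2 S_i)/2 per network weight map onto IMC rows
        # -beta Cov(S_a, S_g) after the same unit conversions.
        norm = grid.ideal_counts(
            configs[0].n_sites, float(np.prod(configs[0].box))
        )
        g_set = S / norm
        dEdw = np.array([G.sum(axis=0) for G in g2_sets])  # = 2 S
        nn_rows = -thermo.beta * (
            (g_set.T @ dEdw) / len(configs)
            - np.outer(g_set.mean(axis=0), dEdw.mean(axis=0))
        )
        imc_cov = -thermo.beta * (
            (S.T @ S) / len(configs) - np.outer(S.mean(axis=0), S.mean(axis=0))
        )
        imc_rows = 2.0 * imc_cov / norm[:, None]
        report.gradient_max_abs_dev = float(np.max(np.abs(nn_rows - imc_rows)))
        report.details["nn_rows"] = nn_rows
        report.details["imc_rows"] = imc_rows
    return report
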