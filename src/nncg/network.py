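"""Bias-free feed-forward energy network over per-site descriptors.

Every CG site shares one network: the K symmetry functions of site n enter
the input layer and a single linear output neuron returns the site energy
E_n; the total energy is E = sum_n E_n (fixed, ascending site order).
Hidden layers use ReLU (with the subgradient at 0 defined as 0); there are
no bias parameters anywhere, so the energy of an isolated site (all-zero
descriptors) is exactly zero and the network is positively homogeneous in
its inputs.

Weight layout: layer l maps width ``sizes[l]`` to ``sizes[l+1]`` with a
matrix stored row-major as ``W[out, in]``; matrices are concatenated in
layer order into one flat vector.  This layout is shared with the numba
sampling kernels and the model file format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config_io import expected_weight_count

__all__ = [
    "NetworkParams",
    "EnergyEvaluation",
    "site_energy",
    "total_energy",
    "energy_weight_gradient",
]


@dataclass
class NetworkParams:
    """Layer widths [K, h1, ..., 1] and the flat weight vector (no biases)."""

    layer_sizes: tuple[int, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer width must be exactly 1")
        n = expected_weight_count(self.layer_sizes)
        if self.weights.size != n:
            raise ValueError(
                f"weight vector has {self.weights.size} entries, layer sizes "
                f"{self.layer_sizes} require {n}"
            )

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_weights(self) -> int:
        return self.weights.size

    @property
    def is_linear(self) -> bool:
        return len(self.layer_sizes) == 2

    def layer_matrices(self) -> list[np.ndarray]:
        """Views of the flat vector as (out, in) matrices, layer by layer."""
        mats = []
        off = 0
        for l in range(len(self.layer_sizes) - 1):
            nin, nout = self.layer_sizes[l], self.layer_sizes[l + 1]
            mats.append(self.weights[off : off + nin * nout].reshape(nout, nin))
            off += nin * nout
        return mats

    @classmethod
    def create(
        cls,
        n_inputs: int,
        hidden: Sequence[int] = (),
        rng: np.random.Generator | None = None,
    ) -> "NetworkParams":
        """Random initialization, uniform in [-1, +1] (seedable)."""
        sizes = (int(n_inputs), *[int(h) for h in hidden], 1)
        n = expected_weight_count(sizes)
        if rng is None:
            w = np.zeros(n)
        else:
            w = rng.uniform(-1.0, 1.0, size=n)
        return cls(sizes, w)

    def with_weights(self, weights: np.ndarray) -> "NetworkParams":
        return NetworkParams(self.layer_sizes, weights)

    @classmethod
    def embed_linear(
        cls,
        linear: "NetworkParams",
        hidden: Sequence[int],
        rng: np.random.Generator | None = None,
        noise: float = 0.01,
    ) -> "NetworkParams":
        """Warm-start a deep net so it initially computes a given linear net.

        Because descriptors and hidden activations are nonnegative, a ReLU
        layer with identity sub-blocks passes the K inputs through
        unchanged, so the deep network's initial energy surface equals the
        linear model's exactly (up to the ``noise`` perturbation on the
        spare capacity, which breaks symmetry so training can use it).
        Requires every hidden width >= K.
        """
        if not linear.is_linear:
            raise ValueError("expected a linear (no-hidden-layer) model")
        k = linear.n_inputs
        if any(h < k for h in hidden):
            raise ValueError("hidden widths must be >= the descriptor count")
        sizes = (k, *[int(h) for h in hidden], 1)
        mats = []
        prev = k
        for h in hidden:
            w = np.zeros((h, prev))
            w[:k, :k] = np.eye(k)
            mats.append(w)
            prev = h
        w_out = np.zeros((1, prev))
        w_out[0, :k] = linear.weights
        mats.append(w_out)
        flat = np.concatenate([m.ravel() for m in mats])
        if rng is not None and noise > 0:
            mask = flat == 0.0
            flat = flat + mask * rng.uniform(-noise, noise, size=flat.size)
        return cls(sizes, flat)


@dataclass
class EnergyEvaluation:
    """Per-site energies, their exact sum, and optionally dE/dw."""

    per_site: np.ndarray
    total: float
    weight_gradient: np.ndarray | None = None


def _check(desc: np.ndarray, params: NetworkParams) -> np.ndarray:
    desc = np.atleast_2d(np.asarray(desc, dtype=np.float64))
    if desc.shape[1] != params.n_inputs:
        raise ValueError(
            f"descriptor width {desc.shape[1]} != network input width "
            f"{params.n_inputs}"
        )
    if not np.all(np.isfinite(params.weights)):
        raise ValueError("network weights contain non-finite values")
    return desc


def _forward_all(desc: np.ndarray, params: NetworkParams) -> list[np.ndarray]:
    """Activations per layer for all sites at once; ReLU on hidden layers."""
    acts = [desc]
    mats = params.layer_matrices()
    a = desc
    for l, w in enumerate(mats):
        a = a @ w.T
        if l < len(mats) - 1:
            a = np.maximum(a, 0.0)
        acts.append(a)
    return acts


def site_energy(g2: np.ndarray, params: NetworkParams) -> float:
    """Energy contribution of one site from its descriptor vector."""
    desc = _check(np.atleast_2d(g2), params)
    return float(_forward_all(desc, params)[-1][0, 0])


def total_energy(
    desc: np.ndarray, params: NetworkParams, with_gradient: bool = False
) -> EnergyEvaluation:
    """Sum of site energies over an N x K descriptor matrix."""
    desc = _check(desc, params)
    acts = _forward_all(desc, params)
    per_site = acts[-1][:, 0]
    total = float(per_site.sum())
    grad = None
    if with_gradient:
        grad = _backward_all(acts, params)
    return EnergyEvaluation(per_site=per_site, total=total, weight_gradient=grad)


def energy_weight_gradient(desc: np.ndarray, params: NetworkParams) -> np.ndarray:
    """dE/dw of the summed energy, by reverse accumulation over all sites.

    ReLU' (0) := 0 so the gradient is deterministic everywhere.
    """
    desc = _check(desc, params)
    acts = _forward_all(desc, params)
    return _backward_all(acts, params)


def _backward_all(acts: list[np.ndarray], params: NetworkParams) -> np.ndarray:
    mats = params.layer_matrices()
    n_layers = len(mats)
    n_sites = acts[0].shape[0]
    grad = np.zeros_like(params.weights)
    # dE/d(output of last layer) = 1 for every site
    delta = np.ones((n_sites, 1))
    off = params.n_weights
    for l in range(n_layers - 1, -1, -1):
        w = mats[l]
        off -= w.size
        grad[off : off + w.size] = (delta.T @ acts[l]).ravel()
        if l > 0:
            delta = delta @ w
            # acts[l] are post-ReLU hidden activations; mask where inactive
            delta = np.where(acts[l] > 0.0, delta, 0.0)
    return grad
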