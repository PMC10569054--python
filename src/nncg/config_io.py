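"""File formats, configurations and model serialization.

Coordinates are Angstrom throughout; energies are in units of k_B*T (the
sampler and trainer only ever use beta*E, so the energy unit cancels).
Trajectory frames use a minimal extended-XYZ dialect: the comment line
carries an orthorhombic box as ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"``.
Model files are self-describing JSON so a trained network (descriptor
parameters + layer sizes + flat weight vector) is portable across runs.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PeriodicConfiguration",
    "RunConfig",
    "ModelFile",
    "read_trajectory",
    "write_trajectory",
    "map_com",
    "save_model",
    "load_model",
    "load_rdf_table",
    "save_rdf_table",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message names the offending line."""


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold displacement vector(s) into the nearest periodic image."""
    return delta - box * np.round(delta / box)


@dataclass
class PeriodicConfiguration:
    """N coarse-grained sites in an orthorhombic periodic box.

    Parameters
    ----------
    positions : (N, 3) array, Angstrom
    box : (3,) array of box edge lengths, Angstrom
    species : single CG type tag shared by all sites
    """

    positions: np.ndarray
    box: np.ndarray
    species: str = "CG"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if np.any(~np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if np.any(self.box <= 0):
            raise ValueError("all box lengths must be positive")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def wrapped(self) -> "PeriodicConfiguration":
        """Return a copy with all positions folded into [0, box)."""
        pos = self.positions - self.box * np.floor(self.positions / self.box)
        return PeriodicConfiguration(pos, self.box.copy(), self.species)

    def pair_distances(self) -> np.ndarray:
        """All-pair minimum-image distance matrix (diagonal set to +inf)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        d = minimum_image(d, self.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        np.fill_diagonal(r, np.inf)
        return r


@dataclass
class RunConfig:
    """Monte Carlo run settings for one sampling leg.

    ``n_equil`` steps equilibrate (with step-size adaptation toward
    ``target_acceptance``); observables are accumulated every
    ``output_freq`` steps afterwards, with the step size frozen.
    """

    n_steps: int
    n_equil: int
    temperature: float = 95.0
    output_freq: int = 1000
    target_acceptance: float = 0.5
    max_disp: float = 0.5
    adapt_interval: int = 1000
    refresh_interval: int = 200_000
    rdf_r_max: float = 10.0
    rdf_n_bins: int = 400
    seed: int = 0
    allow_small_box: bool = False

    def __post_init__(self) -> None:
        if self.n_equil >= self.n_steps:
            raise ValueError("equilibration steps must be < total steps")
        if self.output_freq < 1:
            raise ValueError("output frequency must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")

    def validate_box(self, box: np.ndarray) -> None:
        if not self.allow_small_box and self.rdf_r_max > min(box) / 2 + 1e-9:
            raise ValueError(
                f"rdf_r_max={self.rdf_r_max} exceeds half the smallest box "
                f"length ({min(box) / 2:.3f}); set allow_small_box to override"
            )


# ---------------------------------------------------------------------------
# extended-XYZ trajectory I/O

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _parse_box(comment: str, lineno: int) -> np.ndarray:
    m = _LATTICE_RE.search(comment)
    if m is None:
        raise TrajectoryParseError(
            f"line {lineno}: comment line lacks a Lattice=\"...\" box"
        )
    vals = m.group(1).split()
    if len(vals) != 9:
        raise TrajectoryParseError(
            f"line {lineno}: Lattice must contain 9 numbers, got {len(vals)}"
        )
    lat = np.array([float(v) for v in vals]).reshape(3, 3)
    off = lat - np.diag(np.diag(lat))
    if np.any(np.abs(off) > 1e-8):
        raise TrajectoryParseError(
            f"line {lineno}: only orthorhombic (diagonal) lattices are supported"
        )
    return np.diag(lat).copy()


def read_trajectory(path: str | Path) -> list[PeriodicConfiguration]:
    """Read an extended-XYZ trajectory; all frames must share a particle count."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[PeriodicConfiguration] = []
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if n < 1:
            raise TrajectoryParseError(f"line {i + 1}: atom count must be >= 1")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryParseError(
                f"line {i + 1}: frame particle count {n} != first frame {n_expected}"
            )
        if i + 1 >= len(lines):
            raise TrajectoryParseError(f"line {i + 2}: missing comment line")
        box = _parse_box(lines[i + 1], i + 2)
        if i + 1 + n >= len(lines):
            raise TrajectoryParseError(
                f"line {len(lines)}: truncated frame (expected {n} atom lines)"
            )
        pos = np.empty((n, 3))
        species = "CG"
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"line {i + 3 + k}: expected 'species x y z'"
                )
            species = parts[0]
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"line {i + 3 + k}: non-numeric coordinate"
                ) from exc
        frames.append(PeriodicConfiguration(pos, box, species))
        i += 2 + n
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    return frames


def write_trajectory(
    path: str | Path, frames: Sequence[PeriodicConfiguration]
) -> None:
    path = Path(path)
    out: list[str] = []
    for cfg in frames:
        b = cfg.box
        out.append(str(cfg.n_sites))
        out.append(
            f'Lattice="{b[0]:.8f} 0.0 0.0 0.0 {b[1]:.8f} 0.0 0.0 0.0 {b[2]:.8f}" '
            "Properties=species:S:1:pos:R:3"
        )
        for p in cfg.positions:
            out.append(f"{cfg.species} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# center-of-mass mapping


def map_com(
    atom_positions: np.ndarray,
    masses: np.ndarray,
    groups: Sequence[Sequence[int]],
    box: np.ndarray,
    species: str = "CG",
) -> PeriodicConfiguration:
    """Map atom groups to one CG site each at the mass-weighted mean position.

    Groups may straddle the periodic boundary: each group is unwrapped
    relative to its first atom (minimum-image convention) before averaging,
    and the resulting site is wrapped back into the box.
    """
    atom_positions = np.asarray(atom_positions, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64).reshape(3)
    seen: set[int] = set()
    sites = np.empty((len(groups), 3))
    for gi, group in enumerate(groups):
        idx = list(group)
        if not idx:
            raise ValueError(f"group {gi} is empty")
        if seen.intersection(idx):
            raise ValueError("groups must be disjoint")
        seen.update(idx)
        m = masses[idx]
        total = m.sum()
        if total <= 0:
            raise ValueError(f"group {gi} has zero total mass")
        anchor = atom_positions[idx[0]]
        unwrapped = anchor + minimum_image(atom_positions[idx] - anchor, box)
        sites[gi] = (m[:, None] * unwrapped).sum(axis=0) / total
    sites -= box * np.floor(sites / box)
    return PeriodicConfiguration(sites, box, species)


# ---------------------------------------------------------------------------
# model serialization


@dataclass
class ModelFile:
    """Serializable bundle: descriptor spec + architecture + flat weights."""

    eta: np.ndarray          # A^-2, one per G2 function
    rs: np.ndarray           # A, Gaussian centers
    r_c: float               # A, shared cutoff
    layer_sizes: tuple[int, ...]
    weights: np.ndarray      # flat, row-major (out, in) per layer, concatenated
    hidden_activation: str = "relu"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=np.float64)
        self.rs = np.asarray(self.rs, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        n_expected = expected_weight_count(self.layer_sizes)
        if self.weights.size != n_expected:
            raise ValueError(
                f"weight vector length {self.weights.size} does not match "
                f"layer sizes {self.layer_sizes} (expected {n_expected})"
            )
        if self.layer_sizes[0] != self.eta.size:
            raise ValueError(
                f"descriptor count {self.eta.size} != first layer width "
                f"{self.layer_sizes[0]}"
            )
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer width must be 1")


def expected_weight_count(layer_sizes: Sequence[int]) -> int:
    return int(
        sum(layer_sizes[i] * layer_sizes[i + 1] for i in range(len(layer_sizes) - 1))
    )


def config_hash(obj: dict) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_model(path: str | Path, model: ModelFile) -> None:
    """Write a model as self-describing JSON (weights at full precision)."""
    doc = {
        "format": "nncg-model",
        "version": 1,
        "descriptors": {
            "eta": model.eta.tolist(),
            "rs": model.rs.tolist(),
            "r_c": model.r_c,
        },
        "layer_sizes": list(model.layer_sizes),
        "hidden_activation": model.hidden_activation,
        # float hex is binary-exact under round trip, unlike decimal text
        "weights_hex": [float(w).hex() for w in model.weights],
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: str | Path) -> ModelFile:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "nncg-model":
        raise ValueError(f"{path}: not an nncg model file")
    weights = np.array([float.fromhex(h) for h in doc["weights_hex"]])
    return ModelFile(
        eta=np.array(doc["descriptors"]["eta"]),
        rs=np.array(doc["descriptors"]["rs"]),
        r_c=float(doc["descriptors"]["r_c"]),
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=weights,
        hidden_activation=doc.get("hidden_activation", "relu"),
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# two-column tables (RDFs, angular distributions, pair potentials)


def load_rdf_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column whitespace table (bin center, value)."""
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return data[:, 0].copy(), data[:, 1].copy()


def save_rdf_table(path: str | Path, r: np.ndarray, values: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([r, values]), fmt="%.10g")
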