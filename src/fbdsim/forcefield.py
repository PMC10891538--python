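"""Bonded, excluded-volume and confinement interactions.

All quantities are in reduced units: epsilon = 1 (energy), sigma = 1
(length), k_B T = 1.  The interactions are

* FENE bond about the equilibrium length sigma:
      U(d) = -1/2 K R^2 ln[1 - ((d - sigma)/R)^2],  K = 30, R = 1.5
* harmonic bond:  U(d) = 1/2 k_bond (d - sigma)^2,  k_bond = 100
* WCA (purely repulsive LJ) between nonbonded beads, cut at 2^{1/6} sigma
* a 10-4 wall potential acting within sigma of the cylindrical side
  surface and of each flat cap; contributions from different surfaces
  are computed separately and summed.

Scalar energy/force functions are numpy-vectorized and raise on domain
violations; :func:`total_forces` evaluates the full system through the
compiled kernels (cell-list neighbor search, 1-2 exclusion for WCA).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .errors import (EscapedBeadError, InvalidParameterError, OverlapError,
                     OverstretchError)

__all__ = [
    "ForceFieldParams", "CylinderGeometry",
    "fene_energy", "fene_force", "harmonic_energy", "harmonic_force",
    "wca_energy", "wca_force", "wall_energy", "wall_force", "total_forces",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants (reduced units)."""

    epsilon: float = 1.0
    sigma: float = 1.0
    fene_K: float = 30.0
    fene_R: float = 1.5
    k_bond: float = 100.0
    wall_cutoff: float = 1.0
    bond_type: str = "fene"

    def __post_init__(self):
        for name in ("epsilon", "sigma", "fene_K", "fene_R", "k_bond",
                     "wall_cutoff"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.bond_type not in ("fene", "harmonic"):
            raise InvalidParameterError(
                f"bond_type must be 'fene' or 'harmonic', "
                f"got {self.bond_type!r}")

    @property
    def wca_cutoff(self) -> float:
        """Fixed at 2^(1/6) sigma (the WCA minimum)."""
        return WCA_CUTOFF * self.sigma

    def with_bond_type(self, bond_type: str) -> "ForceFieldParams":
        return replace(self, bond_type=bond_type)


@dataclass(frozen=True)
class CylinderGeometry:
    """Cylindrical confinement, axis along z, centered at the origin."""

    radius: float = 14.75
    length_z: float = 50.75

    def __post_init__(self):
        if self.radius <= 0 or self.length_z <= 0:
            raise InvalidParameterError(
                "cylinder radius and length must be positive")

    @property
    def half_length(self) -> float:
        return 0.5 * self.length_z

    def wall_distances(self, positions: np.ndarray) -> np.ndarray:
        """(n, 3) distances to side surface, top cap, bottom cap."""
        rho = np.hypot(positions[:, 0], positions[:, 1])
        return np.column_stack([self.radius - rho,
                                self.half_length - positions[:, 2],
                                positions[:, 2] + self.half_length])

    def contains(self, positions: np.ndarray) -> bool:
        return bool((self.wall_distances(positions) > 0).all())


# ---------------------------------------------------------------------------
# Scalar potentials (vectorized)
# ---------------------------------------------------------------------------

def _as_array(x):
    a = np.asarray(x, dtype=np.float64)
    return a, (np.ndim(x) == 0)


def _maybe_scalar(a, scalar):
    return float(a) if scalar else a


def fene_energy(d, params: ForceFieldParams = ForceFieldParams()):
    """FENE energy at bond length d; diverges as |d - sigma| -> R."""
    d, scalar = _as_array(d)
    x = (d - params.sigma) / params.fene_R
    if np.any(x * x >= 1.0):
        bad = int(np.argmax(x * x >= 1.0))
        raise OverstretchError(bad)
    u = -0.5 * params.fene_K * params.fene_R ** 2 * np.log1p(-(x * x))
    return _maybe_scalar(u, scalar)


def fene_force(d, params: ForceFieldParams = ForceFieldParams()):
    """Scalar force -dU/dd; negative (restoring) for d > sigma."""
    d, scalar = _as_array(d)
    x = (d - params.sigma) / params.fene_R
    if np.any(x * x >= 1.0):
        raise OverstretchError(int(np.argmax(x * x >= 1.0)))
    f = -params.fene_K * (d - params.sigma) / (1.0 - x * x)
    return _maybe_scalar(f, scalar)


def harmonic_energy(d, params: ForceFieldParams = ForceFieldParams()):
    d, scalar = _as_array(d)
    if np.any(d <= 0):
        raise InvalidParameterError("bond length must be positive")
    u = 0.5 * params.k_bond * (d - params.sigma) ** 2
    return _maybe_scalar(u, scalar)


def harmonic_force(d, params: ForceFieldParams = ForceFieldParams()):
    d, scalar = _as_array(d)
    if np.any(d <= 0):
        raise InvalidParameterError("bond length must be positive")
    return _maybe_scalar(-params.k_bond * (d - params.sigma), scalar)


def wca_energy(r, params: ForceFieldParams = ForceFieldParams()):
    """Purely repulsive WCA pair energy; zero at and beyond 2^(1/6) sigma."""
    r, scalar = _as_array(r)
    if np.any(r < 1e-6 * params.sigma):
        raise OverlapError(int(np.argmax(r < 1e-6 * params.sigma)))
    sr6 = (params.sigma / r) ** 6
    u = np.where(r <= params.wca_cutoff,
                 4.0 * params.epsilon * (sr6 ** 2 - sr6) + params.epsilon,
                 0.0)
    return _maybe_scalar(u, scalar)


def wca_force(r, params: ForceFieldParams = ForceFieldParams()):
    """Scalar force -dU/dr (repulsive, >= 0 inside the cutoff)."""
    r, scalar = _as_array(r)
    if np.any(r < 1e-6 * params.sigma):
        raise OverlapError(int(np.argmax(r < 1e-6 * params.sigma)))
    sr6 = (params.sigma / r) ** 6
    f = np.where(r <= params.wca_cutoff,
                 24.0 * params.epsilon * (2.0 * sr6 ** 2 - sr6) / r,
                 0.0)
    return _maybe_scalar(f, scalar)


def wall_energy(r_iw, params: ForceFieldParams = ForceFieldParams()):
    """10-4 wall energy at distance r_iw from one wall surface."""
    r, scalar = _as_array(r_iw)
    if np.any(r <= 0):
        raise EscapedBeadError(int(np.argmax(r <= 0)))
    sr = params.sigma / r
    u = np.where(r <= params.wall_cutoff,
                 2.0 * np.pi * params.epsilon
                 * (0.4 * sr ** 10 - sr ** 4 + 0.6),
                 0.0)
    return _maybe_scalar(u, scalar)


def wall_force(r_iw, params: ForceFieldParams = ForceFieldParams()):
    """Scalar force along the inward normal, -dU/dr_iw (>= 0 inside cutoff)."""
    r, scalar = _as_array(r_iw)
    if np.any(r <= 0):
        raise EscapedBeadError(int(np.argmax(r <= 0)))
    sr = params.sigma / r
    f = np.where(r <= params.wall_cutoff,
                 (8.0 * np.pi * params.epsilon / r) * (sr ** 10 - sr ** 4),
                 0.0)
    return _maybe_scalar(f, scalar)


# ---------------------------------------------------------------------------
# Full system
# ---------------------------------------------------------------------------

def _raise_for_status(status, bad, step=None):
    if status == _kernels.STATUS_OVERSTRETCH:
        raise OverstretchError(bad, step=step)
    if status == _kernels.STATUS_OVERLAP:
        raise OverlapError(bad, step=step)
    if status == _kernels.STATUS_ESCAPED:
        raise EscapedBeadError(bad, step=step)


def total_forces(config, topology, params: ForceFieldParams | None = None,
                 geometry: CylinderGeometry | None = None,
                 ) -> tuple[np.ndarray, float]:
    """Per-bead forces (exact negative gradient) and total potential energy.

    Nonbonded WCA pairs are found through a linked-cell search; directly
    bonded pairs are excluded from WCA (1-2 exclusion).  With
    ``geometry=None`` the system is unconfined.
    """
    params = params or ForceFieldParams()
    pos = np.ascontiguousarray(config.positions, dtype=np.float64)
    adj = topology.adjacency()
    max_pairs = max(1024, pos.shape[0] * 100)
    pairs, npairs = _kernels.build_pairs(pos, params.wca_cutoff, max_pairs)
    if npairs < 0:
        pairs, npairs = _kernels.build_pairs(pos, params.wca_cutoff,
                                             pos.shape[0] * 600)
        if npairs < 0:
            raise OverlapError(-1)
    forces = np.empty_like(pos)
    use_walls = geometry is not None
    energy, status, bad = _kernels.compute_forces(
        pos, topology.bonds, adj, pairs, npairs,
        params.bond_type == "fene", params.fene_K, params.fene_R,
        params.k_bond, params.epsilon, params.sigma, params.wca_cutoff,
        use_walls,
        geometry.radius if use_walls else 0.0,
        geometry.half_length if use_walls else 0.0,
        params.wall_cutoff, forces)
    _raise_for_status(status, bad)
    return forces, float(energy)
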