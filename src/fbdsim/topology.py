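"""Bottle-brush polymer connectivity and initial configurations.

The model is a minimal coarse-grained bacterial nucleoid: a linear
backbone of ``n_backbone`` beads, each decorated with one side loop of
``loop_size`` beads.  Every loop is a ring closed through its backbone
bead (both loop termini bond to it), following the structured-polymer
model this geometry is taken from.  Bead ordering is deterministic:
backbone beads 0..n_backbone-1 first, then the loops in backbone order.

Counts for arbitrary sizes:

    beads = n_backbone * (1 + loop_size)
    bonds = (n_backbone - 1) + n_backbone * (loop_size + 1)

Initial configurations lay the backbone along a helix about the cylinder
axis with each loop as a planar ring through its backbone bead, then run
a short capped steepest-descent relaxation to remove residual overlaps.
A helical start is unbiased for this model (its equilibrium density is
itself helical) and cheap to equilibrate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from ._kernels import build_pairs, relax_overlaps
from .errors import GeometryInfeasibleError, InvalidParameterError

__all__ = [
    "ROLE_BACKBONE", "ROLE_LOOP", "PolymerTopology", "Configuration",
    "build_bottle_brush", "initial_configuration", "save_topology",
    "load_topology",
]

ROLE_BACKBONE = 0
ROLE_LOOP = 1


@dataclass(frozen=True)
class PolymerTopology:
    """Connectivity of one bottle-brush polymer.

    bonds are index pairs (i < j not guaranteed; stored as built),
    bead_role is 0 for backbone and 1 for loop beads, bead_radius is in
    units of the bead diameter sigma (default sigma/2).
    """

    n_backbone: int
    loop_size: int
    bonds: np.ndarray
    bead_role: np.ndarray
    bead_radius: float = 0.5

    @property
    def n_beads(self) -> int:
        return self.bead_role.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    def backbone_mid_index(self) -> int:
        """The conventional 'middle of the backbone' bead."""
        return self.n_backbone // 2

    def end_loop_bead_index(self) -> int:
        """Middle bead of the loop attached to backbone end bead 0."""
        return self.n_backbone + self.loop_size // 2

    def adjacency(self) -> np.ndarray:
        """(n_beads, max_degree) bonded-neighbor table, -1 padded."""
        counts = np.zeros(self.n_beads, dtype=np.int64)
        for i, j in self.bonds:
            counts[i] += 1
            counts[j] += 1
        adj = np.full((self.n_beads, int(counts.max())), -1, dtype=np.int64)
        fill = np.zeros(self.n_beads, dtype=np.int64)
        for i, j in self.bonds:
            adj[i, fill[i]] = j
            fill[i] += 1
            adj[j, fill[j]] = i
            fill[j] += 1
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_beads, dtype=np.int64)
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def topology_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.int64(self.n_backbone).tobytes())
        h.update(np.int64(self.loop_size).tobytes())
        h.update(np.ascontiguousarray(self.bonds, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(self.bead_role,
                                      dtype=np.int64).tobytes())
        return h.hexdigest()


@dataclass
class Configuration:
    """Bead positions (in sigma) at one time step."""

    positions: np.ndarray
    step_index: int = 0
    box: "object" = None  # CylinderGeometry or None

    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.step_index, self.box)


def build_bottle_brush(n_backbone: int, loop_size: int) -> PolymerTopology:
    """Build the bottle-brush bond graph.

    Backbone beads form a single linear chain; each backbone bead carries
    one ring of ``loop_size`` beads closed through it (loop_size + 1 bonds
    per loop).
    """
    n_backbone = int(n_backbone)
    loop_size = int(loop_size)
    if n_backbone < 2:
        raise InvalidParameterError(
            f"n_backbone must be >= 2, got {n_backbone}")
    if loop_size < 2:
        raise InvalidParameterError(f"loop_size must be >= 2, got {loop_size}")

    n_beads = n_backbone * (1 + loop_size)
    bonds = []
    for i in range(n_backbone - 1):
        bonds.append((i, i + 1))
    for i in range(n_backbone):
        first = n_backbone + i * loop_size
        ring = [i] + list(range(first, first + loop_size))
        for a, b in zip(ring, ring[1:]):
            bonds.append((a, b))
        bonds.append((ring[-1], i))  # close the ring through the backbone
    role = np.full(n_beads, ROLE_LOOP, dtype=np.int64)
    role[:n_backbone] = ROLE_BACKBONE
    return PolymerTopology(n_backbone=n_backbone, loop_size=loop_size,
                           bonds=np.asarray(bonds, dtype=np.int64),
                           bead_role=role)


# ---------------------------------------------------------------------------
# Initial placement
# ---------------------------------------------------------------------------

def _ring_points(p, theta, psi, r_loop, loop_size, rng):
    """Loop ring through backbone bead p, in the horizontal plane.

    The ring center sits r_loop away from p along a horizontal direction
    at angle psi from the inward radial direction; consecutive loop beads
    are adjacent on the ring.
    """
    ang = theta + np.pi + psi  # direction from p to the ring center
    d_hat = np.array([np.cos(ang), np.sin(ang), 0.0])
    center = p + r_loop * d_hat
    e1 = (p - center) / r_loop
    e2 = np.array([-e1[1], e1[0], 0.0])
    phis = 2.0 * np.pi * np.arange(1, loop_size + 1) / (loop_size + 1)
    pts = (center[None, :]
           + r_loop * (np.cos(phis)[:, None] * e1[None, :]
                       + np.sin(phis)[:, None] * e2[None, :]))
    pts[:, 2] += rng.uniform(-0.02, 0.02, size=loop_size)
    return pts


def _place_brush(topology, geometry, rng):
    n_bb = topology.n_backbone
    loop = topology.loop_size
    margin = min(1.0, 0.25 * geometry.radius, 0.25 * geometry.length_z)
    r_use = geometry.radius - margin
    h_use = 0.5 * geometry.length_z - margin
    if r_use < 0.5 or h_use <= 0.05:
        raise GeometryInfeasibleError(
            f"confinement radius {geometry.radius} / length "
            f"{geometry.length_z} too small for any placement")

    bead_volume = topology.n_beads * (np.pi / 6.0)
    box_volume = np.pi * geometry.radius ** 2 * geometry.length_z
    if bead_volume / box_volume > 0.35:
        raise GeometryInfeasibleError(
            f"bead volume fraction {bead_volume / box_volume:.2f} exceeds "
            "0.35; the polymer cannot fit")

    r_loop = (loop + 1) / (2.0 * np.pi)
    # helix radius: prefer mid-cylinder, adjust so the rings fit radially
    r_h = float(np.clip(0.35 * r_use, 0.5, r_use))
    psi0 = None
    for psi_try in (0.7, 0.35, 0.0):
        c_norm = np.sqrt(r_h ** 2 + r_loop ** 2
                         - 2.0 * r_h * r_loop * np.cos(psi_try))
        if c_norm + r_loop <= r_use - 0.05:
            psi0 = psi_try
            break
    if psi0 is None:
        r_h2 = float(np.clip(r_loop, 0.5, r_use))
        if abs(r_h2 - r_loop) + r_loop <= r_use - 0.05:
            r_h, psi0 = r_h2, 0.0
        else:
            raise GeometryInfeasibleError(
                f"loop rings of radius {r_loop:.2f} cannot fit inside "
                f"usable radius {r_use:.2f}")

    dz = min(0.9 * 2.0 * h_use / max(n_bb - 1, 1), 0.7)
    horiz = np.sqrt(max(1.0 - dz * dz, 1e-4))
    dtheta = horiz / r_h
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    z0 = -0.5 * dz * (n_bb - 1)

    pos = np.empty((topology.n_beads, 3))
    for i in range(n_bb):
        theta = theta0 + i * dtheta
        p = np.array([r_h * np.cos(theta), r_h * np.sin(theta),
                      z0 + i * dz])
        pos[i] = p
        psi = psi0 if i % 2 == 0 else -psi0
        first = n_bb + i * loop
        pos[first:first + loop] = _ring_points(p, theta, psi, r_loop,
                                               loop, rng)
    pos += rng.uniform(-0.02, 0.02, size=pos.shape)
    # jitter must not push anything outside the usable region
    rho = np.sqrt(pos[:, 0] ** 2 + pos[:, 1] ** 2)
    over = rho > (geometry.radius - 0.5 * margin)
    if over.any():
        scale = (geometry.radius - 0.5 * margin) / rho[over]
        pos[over, 0] *= scale
        pos[over, 1] *= scale
    np.clip(pos[:, 2], -(0.5 * geometry.length_z - 0.5 * margin),
            0.5 * geometry.length_z - 0.5 * margin, out=pos[:, 2])
    return pos, margin


def _min_nonbonded_and_bond_dev(pos, topology):
    adj = topology.adjacency()
    max_pairs = max(64, pos.shape[0] * 80)
    pairs, npair = build_pairs(pos, 1.3, max_pairs)
    if npair < 0:
        pairs, npair = build_pairs(pos, 1.3, pos.shape[0] * 400)
    min_nb = np.inf
    for p in range(npair):
        i, j = pairs[p]
        if j in adj[i]:
            continue
        d = float(np.linalg.norm(pos[j] - pos[i]))
        min_nb = min(min_nb, d)
    dvec = pos[topology.bonds[:, 1]] - pos[topology.bonds[:, 0]]
    dev = np.abs(np.linalg.norm(dvec, axis=1) - 1.0)
    return min_nb, float(dev.max())


def initial_configuration(topology: PolymerTopology, geometry,
                          seed: int, max_retries: int = 3,
                          ) -> Configuration:
    """Place the polymer inside the cylinder and relax overlaps.

    Contract: every bond within 10% of sigma, every bead strictly inside
    the confinement, and no nonbonded pair closer than 0.9 sigma.
    Deterministic for a given seed.

    Raises
    ------
    GeometryInfeasibleError
        If the cylinder cannot hold the polymer, or placement still
        violates the contract after ``max_retries`` relaxation attempts.
    """
    adj = topology.adjacency()
    last = (np.inf, 0.0)
    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(int(seed), spawn_key=(attempt,)))
        pos, margin = _place_brush(topology, geometry, rng)
        max_pairs = max(1024, topology.n_beads * 120)
        for k_rep, rc_rep, n_iter in ((10.0, 1.05, 2500), (25.0, 0.96, 2000)):
            res = relax_overlaps(
                pos, topology.bonds, adj, geometry.radius,
                0.5 * geometry.length_z, 0.6 * margin,
                k_rep, rc_rep, 100.0, 1.0, 0.004, 0.03,
                n_iter, 25, 1.4, max_pairs)
            if res[0] < 0:
                max_pairs *= 4
                res = relax_overlaps(
                    pos, topology.bonds, adj, geometry.radius,
                    0.5 * geometry.length_z, 0.6 * margin,
                    k_rep, rc_rep, 100.0, 1.0, 0.004, 0.03,
                    n_iter, 25, 1.4, max_pairs)
        min_nb, bond_dev = _min_nonbonded_and_bond_dev(pos, topology)
        rho = np.sqrt(pos[:, 0] ** 2 + pos[:, 1] ** 2)
        inside = (rho < geometry.radius).all() and (
            np.abs(pos[:, 2]) < 0.5 * geometry.length_z).all()
        if min_nb >= 0.9 and bond_dev < 0.1 and inside:
            return Configuration(positions=pos, step_index=0, box=geometry)
        last = (min_nb, bond_dev)
    raise GeometryInfeasibleError(
        f"could not reach a valid configuration after {max_retries} "
        f"attempts (min nonbonded {last[0]:.3f}, "
        f"max bond deviation {last[1]:.3f})")


# ---------------------------------------------------------------------------
# Plain-text export
# ---------------------------------------------------------------------------

def save_topology(topology: PolymerTopology, bonds_path, header_path) -> None:
    """Write the bond list (two 0-based integer columns) + JSON header."""
    np.savetxt(bonds_path, topology.bonds, fmt="%d")
    header = {
        "n_backbone": topology.n_backbone,
        "loop_size": topology.loop_size,
        "n_beads": topology.n_beads,
        "n_bonds": topology.n_bonds,
        "bead_radius": topology.bead_radius,
        "topology_hash": topology.topology_hash(),
    }
    with open(header_path, "w") as fh:
        json.dump(header, fh, indent=2)


def load_topology(bonds_path, header_path) -> PolymerTopology:
    with open(header_path) as fh:
        header = json.load(fh)
    rebuilt = build_bottle_brush(header["n_backbone"], header["loop_size"])
    bonds = np.loadtxt(bonds_path, dtype=np.int64).reshape(-1, 2)
    if not np.array_equal(bonds, rebuilt.bonds):
        raise InvalidParameterError(
            "bond list does not match the bottle-brush connectivity "
            "declared in the header")
    return rebuilt
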