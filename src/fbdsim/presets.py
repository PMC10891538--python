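"""Reference systems and run protocols used throughout tests and scripts.

``full_scale`` is the full-size reference model: 200 backbone beads,
40-bead loops
(8,200 beads) in a cylinder of radius 14.75 sigma and length 50.75 sigma.
``scaled`` keeps the loop size, cylinder radius and bead volume fraction
(12.4%) but shortens the backbone to 30 beads and the cylinder to
7.6125 sigma, which brings a full equilibration + production protocol to
desk scale while preserving the local brush environment every bead sees.
"""

from __future__ import annotations

import numpy as np

from .forcefield import CylinderGeometry, ForceFieldParams
from .integrator import SimulationConfig, Trajectory, run
from .topology import build_bottle_brush, initial_configuration

__all__ = [
    "full_scale_topology", "full_scale_geometry", "scaled_topology",
    "scaled_geometry", "run_scaled_brush", "run_free_beads", "derive_seed",
]

FULL_N_BACKBONE = 200
SCALED_N_BACKBONE = 30
LOOP_SIZE = 40
CYLINDER_RADIUS = 14.75
FULL_CYLINDER_LENGTH = 50.75


def full_scale_topology():
    return build_bottle_brush(FULL_N_BACKBONE, LOOP_SIZE)


def full_scale_geometry():
    return CylinderGeometry(radius=CYLINDER_RADIUS,
                            length_z=FULL_CYLINDER_LENGTH)


def scaled_topology():
    return build_bottle_brush(SCALED_N_BACKBONE, LOOP_SIZE)


def scaled_geometry():
    # length proportional to bead count => identical volume fraction
    scale = SCALED_N_BACKBONE / FULL_N_BACKBONE
    return CylinderGeometry(radius=CYLINDER_RADIUS,
                            length_z=FULL_CYLINDER_LENGTH * scale)


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed (< 2^31) for an independent random domain."""
    ss = np.random.SeedSequence(int(seed),
                                spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_scaled_brush(bond_type: str, hurst: float, seed: int,
                     n_equil: int = 20_000, n_production: int = 100_000,
                     track="mid-backbone",
                     frame_record_interval: int = 100) -> Trajectory:
    """Equilibrate and run the scaled bottle-brush system.

    ``track`` selects per-step-recorded beads: "mid-backbone",
    "end-loop", a tuple of indices, or None.
    """
    topo = scaled_topology()
    geom = scaled_geometry()
    if track == "mid-backbone":
        track_beads = (topo.backbone_mid_index(),)
    elif track == "end-loop":
        track_beads = (topo.end_loop_bead_index(),)
    elif track is None:
        track_beads = ()
    else:
        track_beads = tuple(track)
    params = ForceFieldParams(bond_type=bond_type)
    sim = SimulationConfig(n_steps=n_production, hurst=hurst,
                           n_equil=n_equil, seed=seed,
                           frame_record_interval=frame_record_interval,
                           track_beads=track_beads)
    init = initial_configuration(topo, geom, seed=derive_seed(seed, 9))
    return run(topo, init, sim, params=params, geometry=geom)


def run_free_beads(hurst: float, n_steps: int, seed: int,
                   n_beads: int = 1, dt: float = 0.01) -> Trajectory:
    """Force-free, unconfined beads — the closed-form oracle case."""
    from .topology import Configuration

    sim = SimulationConfig(n_steps=n_steps, hurst=hurst, dt=dt, seed=seed,
                           track_beads=tuple(range(n_beads)))
    init = Configuration(positions=np.zeros((n_beads, 3)))
    return run(None, init, sim)
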