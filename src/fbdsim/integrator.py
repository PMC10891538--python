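"""Overdamped position-update dynamics driven by fractional Gaussian noise.

One step of the dynamics is

    r(n+1) = r(n) + (dt / zeta) F(n) + sqrt(2 kBT dt / zeta) xi(n),

with friction zeta = 6 pi eta a_bead on each bead and xi(n) a vector of
three independent standardized fGn increments.  With the default reduced
units (kBT = 1, eta = 200/(3 pi sigma), a_bead = sigma/2) the friction is
zeta = 200, the free diffusion coefficient D = kBT/zeta = 0.005 sigma^2
per unit time and the per-axis noise displacement per step is exactly
0.01 sigma at dt = 0.01.

Protocol: runs begin with an equilibration phase driven by uncorrelated
noise (the H = 1/2 limit of fGn, i.e. standard Brownian dynamics)
regardless of the target Hurst parameter, followed by a production phase
at the target H.  Only the last ``analysis_fraction`` of production is
marked analysis-eligible.  Production noise is fully pre-generated (exact
covariance); the white equilibration noise is drawn per step from its own
seeded stream, which is the same process as a pre-generated H = 1/2
tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import InvalidParameterError, NumericalBlowupError
from .fgn import ChunkPolicy, generate_noise_tensor, iter_noise_blocks
from .forcefield import CylinderGeometry, ForceFieldParams, _raise_for_status
from .topology import Configuration, PolymerTopology

__all__ = ["SimulationConfig", "Trajectory", "step", "run"]

_NEIGHBOR_SKIN = 0.3

# spawn-key domains for deriving independent streams from the run seed
_DOMAIN_EQUIL = 0
_DOMAIN_PRODUCTION = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Integration parameters in reduced units.

    viscosity_eta defaults to 200/(3 pi) (in units of 1/sigma), the
    reading of the cytoplasm viscosity that yields a clean friction
    zeta = 6 pi eta a_bead = 200; it is a plain field and can be
    overridden.
    """

    n_steps: int
    hurst: float = 0.5
    dt: float = 0.01
    kBT: float = 1.0
    viscosity_eta: float = 200.0 / (3.0 * math.pi)
    bead_radius: float = 0.5
    seed: int = 0
    n_equil: int = 0
    energy_record_interval: int = 100
    frame_record_interval: int = 100
    track_beads: tuple = ()
    analysis_fraction: float = 0.8
    noise_block_length: int | None = None

    def __post_init__(self):
        if self.dt <= 0 or self.kBT <= 0 or self.viscosity_eta <= 0 \
                or self.bead_radius <= 0:
            raise InvalidParameterError(
                "dt, kBT, viscosity and bead radius must be positive")
        if self.n_steps < 1 or self.n_equil < 0:
            raise InvalidParameterError("invalid step counts")
        if not (0.0 < self.analysis_fraction <= 1.0):
            raise InvalidParameterError(
                "analysis_fraction must lie in (0, 1]")
        object.__setattr__(self, "track_beads",
                           tuple(int(b) for b in self.track_beads))

    @property
    def friction_zeta(self) -> float:
        return 6.0 * math.pi * self.viscosity_eta * self.bead_radius

    @property
    def mobility(self) -> float:
        return self.dt / self.friction_zeta

    @property
    def noise_scale(self) -> float:
        return math.sqrt(2.0 * self.kBT * self.dt / self.friction_zeta)

    @property
    def diffusion_coefficient(self) -> float:
        """Free-bead D = kBT / zeta."""
        return self.kBT / self.friction_zeta


@dataclass
class Trajectory:
    """Recorded output of one run.

    frames hold all-bead positions at ``frame_record_interval`` during
    production (stamps are production step indices); tracked beads are
    recorded every production step.  Energies span both phases, with
    negative step stamps for equilibration.
    """

    frames: np.ndarray          # (F, n_beads, 3)
    frame_steps: np.ndarray     # (F,) production-step stamps
    energies: np.ndarray        # (E,)
    energy_steps: np.ndarray    # (E,) stamps; negative during equilibration
    config: SimulationConfig
    topology_hash: str | None = None
    tracked_beads: tuple = ()
    tracked: np.ndarray | None = None   # (n_steps + 1, n_tracked, 3)
    bond_type: str | None = None
    geometry: CylinderGeometry | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.frame_steps) <= 0):
            raise InvalidParameterError(
                "frame steps must be strictly increasing")
        if self.energies.size and not np.all(np.isfinite(self.energies)):
            raise InvalidParameterError("non-finite recorded energy")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    @property
    def frame_dt(self) -> float:
        """Time between recorded frames."""
        return self.config.dt * self.config.frame_record_interval

    @property
    def analysis_start_step(self) -> int:
        """First production step of the analysis-eligible window."""
        return int(round((1.0 - self.config.analysis_fraction)
                         * self.config.n_steps))

    def analysis_frames(self) -> np.ndarray:
        return self.frames[self.frame_steps >= self.analysis_start_step]

    def tracked_positions(self, bead: int) -> np.ndarray:
        """Per-step (n_steps + 1, 3) positions of a tracked bead."""
        if self.tracked is None or bead not in self.tracked_beads:
            raise InvalidParameterError(
                f"bead {bead} was not tracked per step "
                f"(tracked: {self.tracked_beads})")
        return self.tracked[:, self.tracked_beads.index(bead), :]


def step(config: Configuration, forces: np.ndarray, noise_slice: np.ndarray,
         sim_config: SimulationConfig) -> Configuration:
    """Advance one configuration by a single update (pure function)."""
    new_pos = (config.positions
               + sim_config.mobility * forces
               + sim_config.noise_scale * noise_slice)
    if not np.all(np.isfinite(new_pos)):
        raise NumericalBlowupError("non-finite position",
                                   step=config.step_index + 1)
    return Configuration(positions=new_pos,
                         step_index=config.step_index + 1,
                         box=config.box)


def _derived_seed(seed: int, domain: int) -> int:
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(domain),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


_SINGLE_PRECISION_ELEMENTS = 1 << 26  # ~6.7e7 noise values


def _noise_tensors(sim: SimulationConfig, n_beads: int):
    """Yield (start_step, values (n_beads, 3, block)) production noise.

    Very large tensors are held in single precision (the standardized
    increments enter the update at scale 0.01 sigma; a 1e-7 relative
    rounding is far below every other error source).
    """
    prod_seed = _derived_seed(sim.seed, _DOMAIN_PRODUCTION)
    dtype = (np.float32
             if 3 * n_beads * sim.n_steps > _SINGLE_PRECISION_ELEMENTS
             else np.float64)
    if sim.noise_block_length is not None:
        policy = ChunkPolicy(sim.noise_block_length)
        for start, tensor in iter_noise_blocks(
                n_beads, sim.n_steps, sim.hurst, prod_seed, policy,
                dtype=dtype):
            yield start, tensor.values
        return
    tensor = generate_noise_tensor(n_beads, sim.n_steps, sim.hurst,
                                   prod_seed, dtype=dtype)
    yield 0, tensor.values


def _run_free(pos0: np.ndarray, sim: SimulationConfig) -> Trajectory:
    """Force-free beads: the trajectory is the scaled fBm of the noise."""
    n = pos0.shape[0]
    prod_seed = _derived_seed(sim.seed, _DOMAIN_PRODUCTION)
    tensor = generate_noise_tensor(n, sim.n_steps, sim.hurst, prod_seed)
    disp = np.cumsum(tensor.values, axis=2)
    disp *= sim.noise_scale

    fint = sim.frame_record_interval
    fsteps = np.arange(0, sim.n_steps + 1, fint)
    if fsteps[-1] != sim.n_steps:
        fsteps = np.append(fsteps, sim.n_steps)
    frames = np.empty((fsteps.size, n, 3))
    frames[0] = pos0
    for k, s in enumerate(fsteps[1:], start=1):
        frames[k] = pos0 + disp[:, :, s - 1].reshape(n, 3)

    tracked = None
    if sim.track_beads:
        idx = np.asarray(sim.track_beads, dtype=np.int64)
        tracked = np.empty((sim.n_steps + 1, idx.size, 3))
        tracked[0] = pos0[idx]
        tracked[1:] = (pos0[idx][None, :, :]
                       + disp[idx].transpose(2, 0, 1))

    esteps = np.arange(0, sim.n_steps + 1, sim.energy_record_interval)
    return Trajectory(
        frames=frames, frame_steps=fsteps,
        energies=np.zeros(esteps.size), energy_steps=esteps,
        config=sim, topology_hash=None,
        tracked_beads=sim.track_beads, tracked=tracked,
        bond_type=None, geometry=None,
        metadata={"free": True, "noise_algorithm": tensor.algorithm})


class _Recorder:
    def __init__(self, sim: SimulationConfig, n_beads: int):
        self.sim = sim
        fint = sim.frame_record_interval
        self.frame_steps = list(range(0, sim.n_steps + 1, fint))
        if self.frame_steps[-1] != sim.n_steps:
            self.frame_steps.append(sim.n_steps)
        self.frames = np.empty((len(self.frame_steps), n_beads, 3))
        self._next_frame = 0
        self.energies = []
        self.energy_steps = []
        self.track_idx = np.asarray(sim.track_beads, dtype=np.int64)
        self.tracked = (np.empty((sim.n_steps + 1, self.track_idx.size, 3))
                        if sim.track_beads else None)

    def record_equil(self, global_step: int, energy: float):
        if (global_step + self.sim.n_equil) \
                % self.sim.energy_record_interval == 0:
            self.energy_steps.append(global_step)
            self.energies.append(energy)

    def record_production(self, p: int, pos: np.ndarray, energy: float):
        if p % self.sim.energy_record_interval == 0 or p == self.sim.n_steps:
            self.energy_steps.append(p)
            self.energies.append(energy)
        if (self._next_frame < len(self.frame_steps)
                and p == self.frame_steps[self._next_frame]):
            self.frames[self._next_frame] = pos
            self._next_frame += 1
        if self.tracked is not None:
            self.tracked[p] = pos[self.track_idx]

    def build(self, sim, topology, bond_type, geometry, extra) -> Trajectory:
        f = self._next_frame
        return Trajectory(
            frames=self.frames[:f],
            frame_steps=np.asarray(self.frame_steps[:f], dtype=np.int64),
            energies=np.asarray(self.energies),
            energy_steps=np.asarray(self.energy_steps, dtype=np.int64),
            config=sim,
            topology_hash=(topology.topology_hash() if topology else None),
            tracked_beads=sim.track_beads, tracked=self.tracked,
            bond_type=bond_type, geometry=geometry, metadata=extra)


def run(topology: PolymerTopology | None, initial: Configuration,
        sim_config: SimulationConfig,
        params: ForceFieldParams | None = None,
        geometry: CylinderGeometry | None = None) -> Trajectory:
    """Integrate a full equilibration + production protocol.

    ``topology=None`` runs independent force-free beads (closed-form
    reference case).  Errors raised mid-run carry the partial trajectory
    recorded so far in their ``partial_trajectory`` attribute.
    """
    sim = sim_config
    pos = np.array(initial.positions, dtype=np.float64, copy=True)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise InvalidParameterError("positions must be (n_beads, 3)")
    if topology is None:
        if sim.n_equil:
            sim = replace(sim, n_equil=0)
        return _run_free(pos, sim)

    params = params or ForceFieldParams()
    adj = topology.adjacency()
    bonds = topology.bonds
    use_fene = params.bond_type == "fene"
    use_walls = geometry is not None
    cyl_r = geometry.radius if use_walls else 0.0
    half_l = geometry.half_length if use_walls else 0.0
    rc_build = params.wca_cutoff + _NEIGHBOR_SKIN
    half_skin_sq = (0.5 * _NEIGHBOR_SKIN) ** 2

    n = pos.shape[0]
    forces = np.empty_like(pos)
    rec = _Recorder(sim, n)
    max_pairs = max(1024, n * 100)
    ref = np.empty_like(pos)
    state = {"pairs": None, "npairs": 0, "moved2": np.inf}

    def rebuild():
        pairs, npairs = _kernels.build_pairs(pos, rc_build, max_pairs)
        if npairs < 0:
            pairs, npairs = _kernels.build_pairs(pos, rc_build, n * 600)
        state["pairs"], state["npairs"] = pairs, npairs
        state["moved2"] = 0.0
        ref[:] = pos

    def force_eval(global_step):
        if state["moved2"] > half_skin_sq:
            rebuild()
        energy, status, bad = _kernels.compute_forces(
            pos, bonds, adj, state["pairs"], state["npairs"],
            use_fene, params.fene_K, params.fene_R, params.k_bond,
            params.epsilon, params.sigma, params.wca_cutoff,
            use_walls, cyl_r, half_l, params.wall_cutoff, forces)
        if status != _kernels.STATUS_OK:
            try:
                _raise_for_status(status, bad, step=global_step)
            except Exception as err:          # attach the flushed partial
                err.partial_trajectory = rec.build(
                    sim, topology, params.bond_type, geometry,
                    {"aborted_at_step": global_step})
                raise
        return energy

    rebuild()
    mobility = sim.mobility
    noise_scale = sim.noise_scale

    def blowup(global_step):
        err = NumericalBlowupError("non-finite position", step=global_step)
        err.partial_trajectory = rec.build(
            sim, topology, params.bond_type, geometry,
            {"aborted_at_step": global_step})
        return err

    # --- equilibration: standard Brownian dynamics (H = 1/2 noise) ---
    erng = np.random.default_rng(np.random.SeedSequence(
        int(sim.seed), spawn_key=(_DOMAIN_EQUIL,)))
    eq_block = 2000
    for b0 in range(0, sim.n_equil, eq_block):
        blen = min(eq_block, sim.n_equil - b0)
        white = erng.standard_normal((n, 3, blen))
        for k in range(blen):
            gstep = b0 + k - sim.n_equil
            energy = force_eval(gstep)
            rec.record_equil(gstep, energy)
            state["moved2"] = _kernels.apply_update(
                pos, forces, white, k, mobility, noise_scale, ref)
            if not math.isfinite(state["moved2"]):
                raise blowup(gstep)

    # --- production: fractional Brownian dynamics at the target H ---
    for start, xi in _noise_tensors(sim, n):
        for k in range(xi.shape[2]):
            p = start + k
            energy = force_eval(p)
            rec.record_production(p, pos, energy)
            state["moved2"] = _kernels.apply_update(
                pos, forces, xi, k, mobility, noise_scale, ref)
            if not math.isfinite(state["moved2"]):
                raise blowup(p)
    energy = force_eval(sim.n_steps)
    rec.record_production(sim.n_steps, pos, energy)

    extra = {"chunked_noise": sim.noise_block_length is not None}
    return rec.build(sim, topology, params.bond_type, geometry, extra)
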