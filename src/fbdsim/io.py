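"""Trajectory file formats and run manifests.

Two trajectory containers:

* multi-frame XYZ text (atom-count line, comment line carrying the
  production step and, when recorded at that step, the potential energy;
  the element column encodes the bead role, B = backbone, L = loop,
  C = untyped) — loads in standard molecular viewers;
* an HDF5 container that round-trips a :class:`~fbdsim.integrator.Trajectory`
  exactly, including the per-step tracked-bead record and the run
  configuration.

A :class:`RunManifest` JSON records everything needed to reproduce a run
bit-exactly: the full configuration, topology hash, seed, package version
and the SHA-256 of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import TrajectoryFormatError
from .integrator import SimulationConfig, Trajectory
from .forcefield import CylinderGeometry
from .topology import ROLE_BACKBONE, PolymerTopology

__all__ = ["write_xyz", "read_xyz", "write_trajectory_h5",
           "read_trajectory_h5", "RunManifest", "write_manifest",
           "read_manifest"]

_ROLE_ELEMENTS = {ROLE_BACKBONE: "B", 1: "L"}


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, trajectory: Trajectory,
              topology: PolymerTopology | None = None) -> None:
    energy_at = dict(zip(trajectory.energy_steps.tolist(),
                         trajectory.energies.tolist()))
    if topology is not None:
        elements = [_ROLE_ELEMENTS.get(int(r), "C")
                    for r in topology.bead_role]
    else:
        elements = ["C"] * trajectory.n_beads
    with open(path, "w") as fh:
        for frame, step in zip(trajectory.frames, trajectory.frame_steps):
            fh.write(f"{frame.shape[0]}\n")
            comment = f"step={int(step)}"
            if int(step) in energy_at:
                comment += f" energy={energy_at[int(step)]:.10g}"
            fh.write(comment + "\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.10g} {y:.10g} {z:.10g}\n")


def read_xyz(path):
    """Read a multi-frame XYZ file.

    Returns (frames (F, n, 3), elements, steps (F,), comments).
    Raises :class:`TrajectoryFormatError` with the offending frame/line
    on malformed or truncated input.
    """
    frames, steps, comments = [], [], []
    elements = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"expected an atom count, got {lines[i]!r}",
                frame=frame_no, line=i + 1)
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 2 + n > len(lines):
            raise TrajectoryFormatError(
                "file truncated inside frame", frame=frame_no, line=i + 1)
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        step = None
        for tok in comment.split():
            if tok.startswith("step="):
                try:
                    step = int(tok[5:])
                except ValueError:
                    raise TrajectoryFormatError(
                        f"bad step token {tok!r}", frame=frame_no,
                        line=i + 2)
        pos = np.empty((n, 3))
        els = []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise TrajectoryFormatError(
                    "file truncated inside frame", frame=frame_no,
                    line=ln + 1)
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"malformed atom line {lines[ln]!r}", frame=frame_no,
                    line=ln + 1)
            els.append(parts[0])
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryFormatError(
                    f"non-numeric coordinate in {lines[ln]!r}",
                    frame=frame_no, line=ln + 1)
        if elements is None:
            elements = els
        frames.append(pos)
        steps.append(step if step is not None else frame_no)
        comments.append(comment)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise TrajectoryFormatError("no frames found", frame=0, line=1)
    return np.asarray(frames), elements, np.asarray(steps), comments


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_trajectory_h5(path, trajectory: Trajectory) -> None:
    import h5py

    def dset(f, name, data):
        # no object timestamps: identical runs give bit-identical files
        f.create_dataset(name, data=data, track_times=False)

    with h5py.File(path, "w") as f:
        dset(f, "frames", trajectory.frames)
        dset(f, "frame_steps", trajectory.frame_steps)
        dset(f, "energies", trajectory.energies)
        dset(f, "energy_steps", trajectory.energy_steps)
        if trajectory.tracked is not None:
            dset(f, "tracked", trajectory.tracked)
            dset(f, "tracked_beads",
                 np.asarray(trajectory.tracked_beads, dtype=np.int64))
        f.attrs["config"] = json.dumps(
            dataclasses.asdict(trajectory.config))
        f.attrs["topology_hash"] = trajectory.topology_hash or ""
        f.attrs["bond_type"] = trajectory.bond_type or ""
        if trajectory.geometry is not None:
            f.attrs["cylinder_radius"] = trajectory.geometry.radius
            f.attrs["cylinder_length"] = trajectory.geometry.length_z
        f.attrs["metadata"] = json.dumps(trajectory.metadata)


def read_trajectory_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        cfg["track_beads"] = tuple(cfg.get("track_beads", ()))
        config = SimulationConfig(**cfg)
        geometry = None
        if "cylinder_radius" in f.attrs:
            geometry = CylinderGeometry(
                radius=float(f.attrs["cylinder_radius"]),
                length_z=float(f.attrs["cylinder_length"]))
        tracked = f["tracked"][...] if "tracked" in f else None
        tracked_beads = (tuple(int(b) for b in f["tracked_beads"][...])
                         if "tracked_beads" in f else ())
        return Trajectory(
            frames=f["frames"][...],
            frame_steps=f["frame_steps"][...],
            energies=f["energies"][...],
            energy_steps=f["energy_steps"][...],
            config=config,
            topology_hash=str(f.attrs["topology_hash"]) or None,
            tracked_beads=tracked_beads, tracked=tracked,
            bond_type=str(f.attrs["bond_type"]) or None,
            geometry=geometry,
            metadata=json.loads(f.attrs["metadata"]))


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    seed: int
    topology: dict = field(default_factory=dict)
    version: str = ""
    created: str = ""
    outputs: dict = field(default_factory=dict)


def write_manifest(path, config: SimulationConfig,
                   topology: PolymerTopology | None = None,
                   geometry: CylinderGeometry | None = None,
                   bond_type: str | None = None,
                   outputs: dict | None = None) -> RunManifest:
    from . import __version__

    topo = {}
    if topology is not None:
        topo = {"n_backbone": topology.n_backbone,
                "loop_size": topology.loop_size,
                "n_beads": topology.n_beads,
                "hash": topology.topology_hash()}
    cfg = dataclasses.asdict(config)
    if geometry is not None:
        cfg["cylinder_radius"] = geometry.radius
        cfg["cylinder_length"] = geometry.length_z
    if bond_type is not None:
        cfg["bond_type"] = bond_type
    manifest = RunManifest(
        config=cfg, seed=config.seed, topology=topo, version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs={name: {"path": str(p), "sha256": _sha256(p)}
                 for name, p in (outputs or {}).items()})
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest


def read_manifest(path) -> RunManifest:
    with open(path) as fh:
        return RunManifest(**json.load(fh))
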