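"""Langevin sampling of the coarse-grained model.

The integrator is a BAOAB splitting of underdamped Langevin dynamics at
reduced temperature T (k_B = 0.00831451 energy per temperature unit, so
T = 50 gives k_B T = 0.416 epsilon).  Friction is the inverse of the
thermostat coupling time.  The effective protein concentration is
realised as a cubic periodic box sized by ``box_from_concentration``.

Runs are exactly reproducible from their seed, checkpointable, and are
grouped into independent replicas sharing one parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, KB
from .energetics import EnergyModel

__all__ = [
    "SimulationConfig", "TrajectoryRecord", "Trajectory",
    "box_from_concentration", "initial_dimer_placement", "relax",
    "langevin_run", "run_replicas",
]


@dataclass
class SimulationConfig:
    temperature: float = 50.0       # reduced units
    dt: float = 0.0005              # reduced time
    coupling: float = 1.0           # thermostat coupling time; friction = 1/coupling
    steps: int = 10000
    n_replicas: int = 8
    seeds: list | None = None
    concentration: float = 0.005    # mol/L (5 mM)
    box: float | None = None        # cubic side in nm; from concentration if None
    stride: int = 100               # frame recording interval

    def resolved_box(self, n_molecules: int = 2) -> float:
        if self.box is not None:
            return self.box
        return box_from_concentration(n_molecules, self.concentration)


@dataclass
class TrajectoryRecord:
    frame: int
    time: float
    positions: np.ndarray  # (n_beads, 3) nm
    box: float
    replica_id: int
    seed: int


@dataclass
class Trajectory:
    """In-memory trajectory: frames, times, per-frame energy terms and
    kinetic energies, plus the final phase-space point for restarts."""

    frames: np.ndarray              # (n_frames, n_beads, 3)
    times: np.ndarray
    energies: np.ndarray            # (n_frames, 8) kernel energy layout
    kinetic: np.ndarray             # (n_frames,)
    box: float
    seed: int
    replica_id: int = 0
    final_positions: np.ndarray | None = None
    final_velocities: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def records(self):
        for k in range(self.n_frames):
            yield TrajectoryRecord(k, float(self.times[k]), self.frames[k],
                                   self.box, self.replica_id, self.seed)

    def kinetic_temperature(self, n_dof: int) -> np.ndarray:
        return 2.0 * self.kinetic / (n_dof * KB)

    def save_npz(self, path) -> None:
        np.savez_compressed(path, frames=self.frames, times=self.times,
                            energies=self.energies, kinetic=self.kinetic,
                            box=self.box, seed=self.seed, replica_id=self.replica_id)

    def save_xtc(self, path, model) -> None:
        """Export frames in XTC format (with an mdtraj topology built
        from the bead model) for use with standard MD tooling."""
        import mdtraj as md

        top = md.Topology()
        chain_map = {}
        for b in model.beads:
            if b.monomer not in chain_map:
                chain_map[b.monomer] = top.add_chain()
        from .constants import ONE_TO_THREE

        residue = None
        last = None
        for b in model.beads:
            key = (b.monomer, b.res_index)
            if key != last:
                residue = top.add_residue(ONE_TO_THREE.get(b.res_type, "UNK"),
                                          chain_map[b.monomer],
                                          resSeq=b.res_index)
                last = key
            name = "CA" if b.kind == "backbone" else "CB"
            top.add_atom(name, md.element.carbon, residue)
        traj = md.Trajectory(self.frames, top, time=self.times)
        if self.box:
            traj.unitcell_lengths = np.full((self.n_frames, 3), self.box)
            traj.unitcell_angles = np.full((self.n_frames, 3), 90.0)
        traj.save_xtc(str(path))

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        d = np.load(path)
        return cls(frames=d["frames"], times=d["times"], energies=d["energies"],
                   kinetic=d["kinetic"], box=float(d["box"]), seed=int(d["seed"]),
                   replica_id=int(d["replica_id"]))

    @staticmethod
    def concatenate(parts: list) -> "Trajectory":
        first = parts[0]
        return Trajectory(
            frames=np.concatenate([p.frames for p in parts]),
            times=np.concatenate([p.times for p in parts]),
            energies=np.concatenate([p.energies for p in parts]),
            kinetic=np.concatenate([p.kinetic for p in parts]),
            box=first.box, seed=first.seed, replica_id=first.replica_id,
            final_positions=parts[-1].final_positions,
            final_velocities=parts[-1].final_velocities,
        )


def box_from_concentration(n_molecules: int, concentration: float) -> float:
    """Cubic box side (nm) holding ``n_molecules`` at the given molar
    concentration: side = (n / (c N_A))^(1/3)."""
    if n_molecules < 1 or concentration <= 0:
        raise ValueError("need n_molecules >= 1 and positive concentration")
    litres = n_molecules / (concentration * AVOGADRO)
    return float((litres * 1e24) ** (1.0 / 3.0))  # 1 L = 1e24 nm^3


def relax(em: EnergyModel, xyz: np.ndarray, steps: int = 200,
          max_disp: float = 0.005) -> np.ndarray:
    """Capped gradient descent to remove steric clashes after placement."""
    x = np.array(xyz, dtype=float)
    for _ in range(steps):
        f, _e = em.forces(x)
        scale = np.max(np.linalg.norm(f, axis=1))
        if scale < 1e-6:
            break
        x = x + f * min(max_disp / scale, 1e-3)
    return x


def initial_dimer_placement(model, rng: np.random.Generator,
                            linkage=None,
                            min_separation: float = 1.0,
                            n_attempts: int = 30) -> np.ndarray:
    """Place two folded monomers at a random relative orientation.

    For the free model the second monomer sits a surface-to-surface
    distance ``min_separation`` away along a random direction.  For a
    linked model (``linkage`` is the topology's LinkageSpec) the proximal
    monomer is rotated randomly and translated so the linkage bond starts
    at its reference length; among ``n_attempts`` random orientations the
    least-overlapping one is kept (residual clashes are handled by
    :func:`relax`).
    """
    from scipy.spatial.transform import Rotation

    xyz = model.coords().copy()
    mono = model.monomer_labels()
    i0, i1 = mono == 0, mono == 1
    for idx in (i0, i1):
        xyz[idx] -= xyz[idx].mean(axis=0)

    if linkage is None or linkage.type == "free":
        quat = rng.standard_normal(4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        xyz[i1] = rot.apply(xyz[i1])
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        rad0 = np.max(np.linalg.norm(xyz[i0], axis=1))
        rad1 = np.max(np.linalg.norm(xyz[i1], axis=1))
        xyz[i1] += u * (rad0 + rad1 + min_separation)
        return xyz

    donor_pos = xyz[linkage.donor]
    base1 = xyz[i1].copy()
    best = None
    best_clashes = np.inf
    for _ in range(n_attempts):
        quat = rng.standard_normal(4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        cand = rot.apply(base1)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        # index of the acceptor within the proximal block
        acc_local = linkage.acceptor - np.sum(i0)
        shift = donor_pos + u * linkage.r0_link - cand[acc_local]
        cand = cand + shift
        d2 = np.sum((xyz[i0][:, None, :] - cand[None, :, :]) ** 2, axis=-1)
        clashes = int(np.sum(d2 < 0.35**2))
        if clashes < best_clashes:
            best_clashes = clashes
            best = cand
            if clashes == 0:
                break
    xyz[i1] = best
    return xyz


def _kinetic(v: np.ndarray, m: np.ndarray) -> float:
    return float(0.5 * np.sum(m[:, None] * v * v))


def langevin_run(em: EnergyModel, config: SimulationConfig, x0: np.ndarray,
                 seed: int, replica_id: int = 0, v0: np.ndarray | None = None,
                 checkpoint_path=None, checkpoint_every: int | None = None,
                 resume_from=None) -> Trajectory:
    """BAOAB Langevin trajectory.  Identical seed and inputs give
    bit-identical frames; ``resume_from`` continues a checkpoint exactly.
    """
    m = em.model.masses()
    kbt = KB * config.temperature
    gamma = 1.0 / config.coupling
    dt = config.dt
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sig = np.sqrt(kbt / m)[:, None]
    box = em.box if em.use_pbc else 0.0
    max_step = (box / 2.0) if em.use_pbc else 2.0

    if resume_from is not None:
        ck = np.load(resume_from, allow_pickle=False)
        x = ck["x"].copy()
        v = ck["v"].copy()
        start = int(ck["step"])
        rng = np.random.Generator(np.random.PCG64())
        rng.bit_generator.state = json.loads(str(ck["rng_state"]))
        frames = [a for a in ck["frames"]]
        times = list(ck["times"])
        energies = [a for a in ck["energies"]]
        kinetic = list(ck["kinetic"])
        f, e = em.forces(x)
    else:
        rng = np.random.Generator(np.random.PCG64(seed))
        x = np.array(x0, dtype=float)
        if v0 is None:
            v = rng.standard_normal(x.shape) * sig  # Maxwell-Boltzmann
        else:
            v = np.array(v0, dtype=float)
        start = 0
        f, e = em.forces(x)
        frames = [x.copy()]
        times = [0.0]
        energies = [_energy_vector(e)]
        kinetic = [_kinetic(v, m)]

    def save_checkpoint(step):
        if checkpoint_path is None:
            return
        np.savez(checkpoint_path, x=x, v=v, step=step,
                 rng_state=json.dumps(rng.bit_generator.state),
                 frames=np.array(frames), times=np.array(times),
                 energies=np.array(energies), kinetic=np.array(kinetic))

    for step in range(start + 1, config.steps + 1):
        v = v + 0.5 * dt * f / m[:, None]
        x_half = x + 0.5 * dt * v
        v = c1 * v + c2 * sig * rng.standard_normal(x.shape)
        x_new = x_half + 0.5 * dt * v
        disp = np.max(np.abs(x_new - x))
        if not np.isfinite(disp) or disp > max_step:
            raise RuntimeError(
                f"integration diverged at step {step}: max displacement "
                f"{disp:.3g} nm exceeds {max_step:.3g} nm (dt={dt}, T={config.temperature})"
            )
        x = x_new
        f, e = em.forces(x)
        v = v + 0.5 * dt * f / m[:, None]
        if step % config.stride == 0:
            frames.append(x.copy())
            times.append(step * dt)
            energies.append(_energy_vector(e))
            kinetic.append(_kinetic(v, m))
        if checkpoint_every and step % checkpoint_every == 0:
            save_checkpoint(step)

    traj = Trajectory(
        frames=np.array(frames), times=np.array(times),
        energies=np.array(energies), kinetic=np.array(kinetic),
        box=box, seed=seed, replica_id=replica_id,
        final_positions=x.copy(), final_velocities=v.copy(),
    )
    return traj


def _energy_vector(e) -> np.ndarray:
    return np.array([e.e_bond, e.e_angle, e.e_dihedral, e.e_contact,
                     e.e_repulsive, e.e_link, e.e_elec, e.e_hp])


def run_replicas(em: EnergyModel, config: SimulationConfig,
                 x0_provider, base_seed: int = 1000,
                 force_seeds: bool = False):
    """Run ``config.n_replicas`` independent simulations with one shared
    parameter set and distinct seeds.

    ``x0_provider(seed, rng)`` returns the initial conformation for one
    replica.  Returns (list of Trajectory, manifest dict).
    """
    from . import __version__

    seeds = config.seeds or [base_seed + k for k in range(config.n_replicas)]
    if len(set(seeds)) != len(seeds) and not force_seeds:
        raise ValueError("replica seeds collide; pass force_seeds=True to override")
    trajs = []
    for rid, seed in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(seed))
        x0 = x0_provider(seed, rng)
        trajs.append(langevin_run(em, config, x0, seed=seed, replica_id=rid))
    manifest = {
        "code_version": __version__,
        "seeds": list(map(int, seeds)),
        "temperature": config.temperature,
        "dt": config.dt,
        "coupling": config.coupling,
        "steps": config.steps,
        "stride": config.stride,
        "concentration": config.concentration,
        "box": em.box if em.use_pbc else None,
        "n_replicas": len(seeds),
    }
    return trajs, manifest
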