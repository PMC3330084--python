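"""Langevin and NVE dynamics in reduced units.

The integrator is the BAOAB splitting of Langevin dynamics (friction
γ = 1/coupling-time); it is second order in the time step and samples the
configurational Boltzmann distribution accurately.  Defaults follow the
model's reference protocol: dt = 0.0005 reduced time, coupling time 1.0,
T = 0.5.  Trajectories are bit-reproducible for a fixed seed.

To keep the integration loop in compiled code while preserving the numpy
PCG64 random stream, runs proceed in chunks: the Gaussian noise for each
chunk is pre-drawn and handed to the kernel.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .energetics import ForceField, force_field, total_energy
from .topology import Topology

_CHUNK_STEPS = 20_000
_ENERGY_ABORT = 1e8


@dataclass
class SimParams:
    """Simulation control parameters (reduced units)."""

    temperature: float = 0.5
    dt: float = 0.0005
    coupling_time: float = 1.0      # Langevin bath coupling; friction = 1/τ
    n_steps: int = 100_000
    seed: int = 0
    stride: int = 200               # steps between stored frames
    initial: str = "O"              # "O" | "A" | "H" | "coords"
    initial_coords: np.ndarray | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def friction(self) -> float:
        return 1.0 / self.coupling_time


@dataclass
class Trajectory:
    """Stored frames with per-frame potential (or total, for NVE) energy."""

    times: np.ndarray               # (n_frames,) reduced time, strictly increasing
    coords: np.ndarray              # (n_frames, n_beads, 3) Å
    energies: np.ndarray            # (n_frames,)
    params: SimParams
    final_coords: np.ndarray | None = None
    final_velocities: np.ndarray | None = None
    final_rng_state: dict | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def save(self, path) -> None:
        np.savez_compressed(
            path, times=self.times, coords=self.coords, energies=self.energies,
            temperature=self.params.temperature, dt=self.params.dt,
            coupling_time=self.params.coupling_time, seed=self.params.seed,
            stride=self.params.stride,
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path) as z:
            params = SimParams(
                temperature=float(z["temperature"]), dt=float(z["dt"]),
                coupling_time=float(z["coupling_time"]), seed=int(z["seed"]),
                stride=int(z["stride"]), n_steps=len(z["times"]) * int(z["stride"]),
            )
            return cls(times=z["times"].copy(), coords=z["coords"].copy(),
                       energies=z["energies"].copy(), params=params)


def initial_coordinates(topo: Topology, params: SimParams,
                        references: dict[str, np.ndarray] | None = None) -> np.ndarray:
    if params.initial == "coords":
        if params.initial_coords is None:
            raise ValueError("initial='coords' requires initial_coords")
        return np.array(params.initial_coords, dtype=float)
    if references and params.initial in references:
        return np.array(references[params.initial], dtype=float)
    if params.initial == "O":
        return np.array(topo.cg.coords, dtype=float)
    raise ValueError(
        f"initial state {params.initial!r} needs a reference coordinate set"
    )


def _ff_args(ff: ForceField):
    return (
        ff.bond_ij, ff.bond_r0, ff.bond_k,
        ff.ang_ijk, ff.ang_t0, ff.ang_k,
        ff.dih_ijkl, ff.dih_phi0, ff.dih_k1, ff.dih_k3,
        ff.con_ij, ff.con_r0, ff.con_eps, ff.con_form, ff.gauss_width,
        ff.rep_ij, ff.rep_sigma, ff.eps_rep,
        ff.chg_ij, ff.chg_qq, ff.dh_pref, ff.dh_kappa, ff.dh_rcut, ff.dh_ushift,
    )


def run_langevin(
    topo: Topology,
    params: SimParams,
    references: dict[str, np.ndarray] | None = None,
    ff: ForceField | None = None,
    velocities: np.ndarray | None = None,
    rng_state: dict | None = None,
) -> Trajectory:
    """Langevin (BAOAB) trajectory; deterministic for a fixed seed.

    Initial velocities are Maxwell-Boltzmann at the run temperature unless
    given explicitly; passing ``velocities`` and ``rng_state`` (from a
    checkpoint) continues a previous run bit-identically.  Aborts with a
    diagnostic if the potential energy diverges.
    """
    if ff is None:
        ff = force_field(topo)
    rng = np.random.default_rng(params.seed)
    if rng_state is not None:
        rng.bit_generator.state = rng_state
    coords = np.ascontiguousarray(initial_coordinates(topo, params, references))
    if not np.isfinite(coords).all():
        raise ValueError("non-finite initial coordinates")
    n = coords.shape[0]
    masses = ff.masses
    if velocities is not None:
        vels = np.array(velocities, dtype=float)
    else:
        vels = rng.standard_normal((n, 3)) * np.sqrt(params.temperature / masses[:, None])
    forces = np.zeros_like(coords)

    stride = params.stride
    chunk = stride * max(1, _CHUNK_STEPS // stride)
    n_frames = params.n_steps // stride
    out_coords = np.empty((n_frames, n, 3))
    out_energy = np.empty(n_frames)
    frame = 0
    step = 0
    while step < params.n_steps:
        todo = min(chunk, params.n_steps - step)
        noise = rng.standard_normal((todo, n, 3))
        k = todo // stride
        e_last = _kernels.langevin_baoab_chunk(
            coords, vels, forces, masses, params.dt, params.friction,
            params.temperature, noise, *_ff_args(ff),
            out_coords[frame:frame + k], out_energy[frame:frame + k], stride,
        )
        if not np.isfinite(e_last) or abs(e_last) > _ENERGY_ABORT:
            raise RuntimeError(
                f"energy divergence (E={e_last:.3g}) near step {step + todo}"
            )
        frame += k
        step += todo
    times = params.dt * stride * np.arange(1, n_frames + 1)
    return Trajectory(times=times, coords=out_coords, energies=out_energy,
                      params=params, final_coords=coords.copy(),
                      final_velocities=vels.copy(),
                      final_rng_state=rng.bit_generator.state)


def run_nve(
    topo: Topology,
    params: SimParams,
    references: dict[str, np.ndarray] | None = None,
    zero_velocities: bool = False,
    ff: ForceField | None = None,
) -> Trajectory:
    """Frictionless, bathless velocity-Verlet run (validation mode).

    Frame energies are TOTAL (potential + kinetic) for conservation checks.
    """
    if ff is None:
        ff = force_field(topo)
    rng = np.random.default_rng(params.seed)
    coords = np.ascontiguousarray(initial_coordinates(topo, params, references))
    n = coords.shape[0]
    masses = ff.masses
    if zero_velocities:
        vels = np.zeros((n, 3))
    else:
        vels = rng.standard_normal((n, 3)) * np.sqrt(params.temperature / masses[:, None])
    forces = np.zeros_like(coords)
    n_frames = params.n_steps // params.stride
    out_coords = np.empty((n_frames, n, 3))
    out_energy = np.empty(n_frames)
    e_last = _kernels.nve_chunk(
        coords, vels, forces, masses, params.dt, params.n_steps,
        *_ff_args(ff), out_coords, out_energy, params.stride,
    )
    if not np.isfinite(e_last) or abs(e_last) > _ENERGY_ABORT:
        raise RuntimeError(f"energy divergence (E={e_last:.3g})")
    times = params.dt * params.stride * np.arange(1, n_frames + 1)
    return Trajectory(times=times, coords=out_coords, energies=out_energy,
                      params=params, final_coords=coords.copy(),
                      final_velocities=vels.copy())


def run_temperature_scan(
    topo: Topology,
    temperatures: list[float],
    params: SimParams,
    references: dict[str, np.ndarray] | None = None,
) -> list[Trajectory]:
    """Independent seeded constant-T runs (for Cv / WHAM analysis).

    Seeds are derived from the base seed and differ across temperatures;
    each is recorded in its trajectory's params.
    """
    temps = list(temperatures)
    if any(t <= 0 for t in temps):
        raise ValueError("temperatures must be positive")
    if sorted(temps) != temps:
        raise ValueError("temperatures must be sorted ascending")
    ff = force_field(topo)
    out = []
    for i, t in enumerate(temps):
        p = replace(params, temperature=t, seed=(params.seed + 7919 * (i + 1)) % (2**31))
        out.append(run_langevin(topo, p, references, ff=ff))
    return out


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path, traj: Trajectory) -> None:
    """Persist final coordinates/velocities and the generator state."""
    with open(path, "wb") as fh:
        pickle.dump(
            {"coords": traj.final_coords, "velocities": traj.final_velocities,
             "params": traj.params, "rng_state": traj.final_rng_state},
            fh,
        )


def load_checkpoint(path) -> dict:
    with open(path, "rb") as fh:
        return pickle.load(fh)
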