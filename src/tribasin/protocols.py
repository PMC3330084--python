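"""Self-contained validation experiments.

Each function builds its own small system, runs it, and returns summary
numbers.  They back both the acceptance checks and quick sanity runs from a
shell; sizes are chosen so the full set completes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import landscape as ls
from .energetics import numerical_forces, total_energy
from .markov import make_markov_series
from .simulate import SimParams, run_langevin, run_nve
from .topology import ModelParams
from .toy import ToySpec, build_toy_system, toy_basin_definition


def force_consistency(seed: int = 0, n_configs: int = 100, scale: float = 0.08) -> float:
    """Max relative deviation between analytic and finite-difference forces
    over random perturbations of the toy reference geometry."""
    topo, refs, _, _ = build_toy_system(ToySpec(), ModelParams(eps_ligand=0.5))
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        coords = refs["O"] + scale * rng.standard_normal(refs["O"].shape)
        ana = total_energy(topo, coords).forces
        num = numerical_forces(topo, coords)
        err = np.abs(ana - num) / (np.abs(num) + 1e-3)
        worst = max(worst, float(err.max()))
    return worst


def nve_drift(seed: int = 0, n_steps: int = 100_000) -> float:
    """Relative total-energy drift of a bath-free run of the toy system."""
    topo, refs, _, _ = build_toy_system(ToySpec(), ModelParams(eps_ligand=0.5))
    rng = np.random.default_rng(seed)
    coords = refs["O"] + 0.02 * rng.standard_normal(refs["O"].shape)
    p = SimParams(temperature=0.5, dt=0.0005, n_steps=n_steps, stride=500,
                  seed=seed, initial="coords", initial_coords=coords)
    traj = run_nve(topo, p)
    e = traj.energies
    return float(np.abs(e - e[0]).max() / abs(e[0]))


def harmonic_dimer_statistics(seed: int = 0, k_bond: float = 100.0,
                              temperature: float = 0.5) -> dict[str, float]:
    """Positional variance, kinetic temperature and Boltzmann KS p-value for
    a two-bead harmonic bond sampled with the Langevin integrator."""
    from scipy import stats as sps

    from .contacts import MixedContactMap
    from .structures import CGStructure
    from .topology import BondedTerms, Topology

    r0 = 3.8
    cg = CGStructure(
        kind=np.array(["CA", "CA"]), res_index=np.array([1, 2]),
        res_name=np.array(["ALA", "ALA"], dtype="U5"),
        coords=np.array([[0.0, 0, 0], [r0, 0, 0]]),
        mass=np.ones(2), charge=np.zeros(2))
    bonded = BondedTerms(
        bond_ij=np.array([[0, 1]]), bond_r0=np.array([r0]),
        bond_k=np.array([k_bond]),
        angle_ijk=np.empty((0, 3), dtype=int), angle_t0=np.empty(0),
        angle_k=np.empty(0), angle_hinge=np.empty(0, dtype=bool),
        dihedral_ijkl=np.empty((0, 4), dtype=int), dihedral_phi0=np.empty(0),
        dihedral_k1=np.empty(0), dihedral_k3=np.empty(0),
        dihedral_hinge=np.empty(0, dtype=bool))
    topo = Topology(cg=cg, bonded=bonded, mixed_map=MixedContactMap(contacts=[]),
                    params=ModelParams(), hinge_residues=set())

    p = SimParams(temperature=temperature, dt=0.005, n_steps=2_000_000,
                  stride=200, seed=seed)
    traj = run_langevin(topo, p)
    r = np.linalg.norm(traj.coords[:, 1] - traj.coords[:, 0], axis=1)
    r = r[len(r) // 10:]
    var = float(r.var())
    n_eff = len(r) / 3
    var_se = var * np.sqrt(2.0 / n_eff)

    # kinetic temperature from independent short runs
    sq = []
    for s in range(100):
        ps = dataclasses.replace(p, n_steps=2000, stride=2000, seed=seed + 1000 + s)
        t2 = run_langevin(topo, ps)
        sq.append(float((t2.final_velocities ** 2).mean()))
    sq = np.asarray(sq)

    grid = np.linspace(r0 - 8 * np.sqrt(temperature / k_bond),
                       r0 + 8 * np.sqrt(temperature / k_bond), 4001)
    dens = grid**2 * np.exp(-k_bond * (grid - r0) ** 2 / (2 * temperature))
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    ks = sps.kstest(r, lambda v: np.interp(v, grid, cdf))
    return {
        "bond_variance": var,
        "bond_variance_expected": temperature / k_bond,
        "bond_variance_se": float(var_se),
        "kinetic_temperature": float(sq.mean()),
        "kinetic_temperature_se": float(sq.std(ddof=1) / np.sqrt(len(sq))),
        "temperature": temperature,
        "ks_pvalue": float(ks.pvalue),
    }


def kinetics_oracle_agreement(seed: int = 0, n_sequences: int = 1000) -> dict[str, float]:
    """Exact-match fraction of transition counting against a brute-force
    oracle on random visit sequences, plus Markov-generator recovery."""
    rng = np.random.default_rng(seed)
    states = "OAH"
    mismatches = 0
    for _ in range(n_sequences):
        n = rng.integers(2, 40)
        seq = [states[rng.integers(3)]]
        while len(seq) < n:
            nxt = states[rng.integers(3)]
            if nxt != seq[-1]:
                seq.append(nxt)
        lengths = rng.integers(1, 5, size=len(seq))
        labels, visits, pos = [], [], 0
        for s, ln in zip(seq, lengths):
            labels.extend([s] * int(ln))
            visits.append((s, pos, pos + int(ln) - 1))
            pos += int(ln)
        series = ls.StateSeries(labels=np.array(labels), visits=visits, dwell_filter=0)
        stats = ls.parse_transitions(series)
        counts = {a + b: 0 for a in states for b in states if a != b}
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a + b] += 1
        n_oah = sum(1 for i in range(len(seq) - 2) if seq[i:i + 3] == ["O", "A", "H"])
        if stats.counts != counts or stats.n_oah != n_oah:
            mismatches += 1

    q = np.array([[-0.4, 0.3, 0.1], [0.2, -0.5, 0.3], [0.1, 0.2, -0.3]])
    series, truth = make_markov_series(q, duration=40_000.0, seed=seed + 1,
                                       frame_time=0.05)
    stats = ls.parse_transitions(series, frame_time=0.05)
    max_z = 0.0
    for a_i, a in enumerate(states):
        for b_i, b in enumerate(states):
            if a == b:
                continue
            k_est = stats.rate(a, b)
            n = max(stats.counts[a + b], 1)
            se = np.sqrt(n) / (stats.probabilities[a] * stats.total_time)
            max_z = max(max_z, abs(k_est - q[a_i, b_i]) / se)
    return {
        "oracle_match_fraction": 1.0 - mismatches / n_sequences,
        "n_markov_events": float(sum(stats.counts.values())),
        "markov_rate_max_z": float(max_z),
    }


def double_well_fes_error(seed: int = 0) -> dict[str, float]:
    """Overdamped sampling of a known 2-D double well: max |F − V| on bins
    with ≥ 500 counts, and whether the minimax saddle matches the analytic
    barrier bin."""
    rng = np.random.default_rng(seed)
    t, h, ky = 1.0, 2.0, 4.0

    def grad(p):
        x, y = p[:, 0], p[:, 1]
        return np.column_stack([4 * h * x * (x * x - 1), ky * y])

    n_walkers, n_steps, dt = 200, 30_000, 0.002
    p = np.column_stack([rng.choice([-1.0, 1.0], n_walkers), np.zeros(n_walkers)])
    samples = []
    for step in range(n_steps):
        p = p - grad(p) * dt + np.sqrt(2 * t * dt) * rng.standard_normal(p.shape)
        if step % 10 == 0 and step > 2000:
            samples.append(p.copy())
    pts = np.concatenate(samples)
    fes = ls.free_energy_surface(pts[:, 0], pts[:, 1], temperature=t, bins=24,
                                 ranges=((-1.6, 1.6), (-1.2, 1.2)))
    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    vx, vy = np.meshgrid(xc, yc, indexing="ij")
    v = h * (vx**2 - 1) ** 2 + 0.5 * ky * vy**2
    well = fes.counts >= 500
    diff = (fes.free_energy - v)[well]
    diff = diff - diff.mean()
    minima, saddles = ls.locate_minima_saddles(fes)
    # saddle between the two deepest minima; sampling noise can add shallow
    # spurious minima with their own merge points
    saddle_x = None
    if saddles:
        key = tuple(sorted((minima[0], minima[1]))) if len(minima) >= 2 else None
        if key in saddles:
            i, j, _bar = saddles[key]
        else:
            i, j, _bar = max(saddles.values(), key=lambda v: v[2])
        saddle_x, _ = fes.bin_center(i, j)
    return {
        "fes_max_abs_error": float(np.abs(diff).max()),
        "n_well_sampled_bins": int(well.sum()),
        "n_minima": len(minima),
        "saddle_x": np.nan if saddle_x is None else float(saddle_x),
    }


def ligand_sweep(
    seed: int = 0,
    eps_values: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5),
    n_steps: int = 1_200_000,
    n_replicas: int = 3,
    stride: int = 500,
    dwell_filter: int = 5,
    burn_fraction: float = 1 / 3,
) -> dict[float, dict]:
    """Equilibrium toy-system sweep over the implicit ligand strength.

    For each ε_L: independent Langevin replicas at T = 0.5 initialized
    round-robin in the three native states (the model's standard protocol),
    each with its leading ``burn_fraction`` dropped; basin assignment with
    the calibrated toy regions; transition statistics pooled over replicas.
    """
    out = {}
    basins = toy_basin_definition()
    starts = ["O", "A", "H"]
    for eps_l in eps_values:
        params = ModelParams(eps_ligand=eps_l, angle_model="theta_OAH")
        topo, refs, _, _ = build_toy_system(ToySpec(), params)
        ff = None
        per_replica = []
        frame_time = None
        for rep in range(n_replicas):
            p = SimParams(temperature=0.5, n_steps=n_steps, stride=stride,
                          seed=(seed + 911 * rep + int(10 * eps_l)) % 2**31,
                          initial=starts[rep % 3])
            traj = run_langevin(topo, p, refs)
            burn = int(traj.n_frames * burn_fraction)
            fc = ls.compute_frame_coordinates(traj.coords[burn:], topo)
            series = ls.assign_basins(fc, basins=basins, dwell_filter=dwell_filter)
            frame_time = p.dt * stride
            per_replica.append(ls.parse_transitions(series, frame_time=frame_time))
        stats = ls.aggregate_transition_stats(per_replica)
        out[eps_l] = {
            "P_O": stats.probabilities["O"],
            "P_A": stats.probabilities["A"],
            "P_H": stats.probabilities["H"],
            "F_IF": stats.f_if,
            "F_PS": stats.f_ps,
            "n_transitions": sum(stats.counts.values()),
            "stats": stats,
        }
    return out


def phi_limit_deviation(seed: int = 0, n_frames: int = 40) -> dict[str, float]:
    """φ computed with TS := end (resp. start) ensemble must be 1 (resp. 0)."""
    topo, refs, _, _ = build_toy_system(
        ToySpec(), ModelParams(eps_ligand=0.5, angle_model="theta_OAH"))
    rng = np.random.default_rng(seed)
    start = refs["O"][None] + 0.15 * rng.standard_normal((n_frames, topo.n_beads, 3))
    end = refs["H"][None] + 0.15 * rng.standard_normal((n_frames, topo.n_beads, 3))
    as_end = ls.phi_values(start, end, end, topo, transition="OH")
    as_start = ls.phi_values(start, end, start, topo, transition="OH")
    dev_one = max(abs(v - 1.0) for v in as_end.phi.values())
    dev_zero = max(abs(v) for v in as_start.phi.values())
    return {"phi_end_limit_deviation": float(dev_one),
            "phi_start_limit_deviation": float(dev_zero),
            "n_reported_residues": float(len(as_end.phi))}
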