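"""Functional-landscape and kinetics analysis.

Everything downstream of a trajectory lives here: state-specific Q
coordinates and RMSDs, basin assignment with dwell filtering, transition
counting with the induced-fit / population-shift flux split, rate constants,
binned free-energy surfaces with minima/saddle location, transition-state
ensembles and their contact-probability maps, functional φ-values, cracking
scores, and heat capacity (direct fluctuation formula or WHAM).

Conventions
-----------
* A contact is *formed* in a frame when its bead distance is below 1.2·r0
  (configurable).
* The fractional flux of the induced-fit route is
  F_IF = N(O→H) / (N(O→H) + N(O→A→H)); F_PS = 1 − F_IF.
* Rate constants use the residence-time estimator k(X→Y) = N_XY / (P_X·T),
  in reciprocal reduced time.
* Free energies are reported in units of k_BT at the sampling temperature,
  min-shifted to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactClass
from .geometry import kabsch
from .topology import Topology

STATE_NAMES = ("O", "A", "H")
UNASSIGNED = "U"


# ---------------------------------------------------------------------------
# reaction coordinates

def q_fraction(
    coords: np.ndarray,
    contact_ij: np.ndarray,
    contact_r0: np.ndarray,
    criterion: float = 1.2,
) -> np.ndarray:
    """Fraction of the listed contacts formed in each frame.

    ``coords`` is (n_frames, n_beads, 3) or (n_beads, 3); a contact is
    formed when r < criterion · r0.
    """
    ij = np.asarray(contact_ij, dtype=int).reshape(-1, 2)
    if len(ij) == 0:
        raise ValueError("empty contact list: this state cannot be monitored")
    single = coords.ndim == 2
    c = coords[None] if single else coords
    d = np.linalg.norm(c[:, ij[:, 0]] - c[:, ij[:, 1]], axis=2)
    q = (d < criterion * np.asarray(contact_r0)).mean(axis=1)
    return float(q[0]) if single else q


def state_q_fractions(
    coords: np.ndarray,
    topo: Topology,
    criterion: float = 1.2,
) -> dict[str, np.ndarray]:
    """Q_O, Q_A, Q_H for a frame array, from the state-specific contacts."""
    out = {}
    for name, cls in zip(STATE_NAMES,
                         (ContactClass.O_SPEC, ContactClass.A_SPEC, ContactClass.H_SPEC)):
        idx = topo.contacts_of_class(cls)
        out[name] = q_fraction(coords, topo.con_ij[idx], topo.con_r0[idx], criterion)
    return out


def rmsd_to_state(
    coords: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Best-fit RMSD (Å) of each frame to a reference coordinate set.

    ``selection`` is an index array into the beads (default: all).
    """
    single = coords.ndim == 2
    c = coords[None] if single else coords
    ref = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        c = c[:, sel]
        ref = ref[sel]
    out = np.array([kabsch(frame, ref)[2] for frame in c])
    return float(out[0]) if single else out


@dataclass
class FrameCoordinates:
    """Per-frame reaction coordinates of one trajectory."""

    q: dict[str, np.ndarray]          # state → Q_X series in [0,1]
    rmsd: dict[str, np.ndarray] = field(default_factory=dict)
    energy: np.ndarray | None = None

    def __post_init__(self):
        for name, series in self.q.items():
            s = np.asarray(series)
            if ((s < -1e-9) | (s > 1 + 1e-9)).any():
                raise ValueError(f"Q_{name} outside [0,1]")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.q.values())))


def compute_frame_coordinates(
    traj_coords: np.ndarray,
    topo: Topology,
    references: dict[str, np.ndarray] | None = None,
    energies: np.ndarray | None = None,
    criterion: float = 1.2,
    with_rmsd: bool = False,
) -> FrameCoordinates:
    q = state_q_fractions(traj_coords, topo, criterion)
    rmsd = {}
    if with_rmsd and references:
        ca = topo.cg.ca_indices
        for name, ref in references.items():
            rmsd[name] = rmsd_to_state(traj_coords, ref, selection=ca)
    return FrameCoordinates(q=q, rmsd=rmsd, energy=energies)


# ---------------------------------------------------------------------------
# basins, transitions, fluxes, rates

@dataclass
class BasinDefinition:
    """Rectangular basin regions in Q space.

    ``bounds`` maps state name → {coordinate name: (lo, hi)}.  A frame
    belongs to a basin when every listed coordinate is inside its interval.
    Regions must be disjoint.
    """

    bounds: dict[str, dict[str, tuple[float, float]]]

    def validate(self) -> None:
        # pairwise disjointness: two basins overlap iff every shared (or
        # implied [0,1]) interval pair overlaps
        names = list(self.bounds)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = self.bounds[names[i]], self.bounds[names[j]]
                coords = set(a) | set(b)
                if all(
                    min(a.get(c, (0, 1))[1], b.get(c, (0, 1))[1])
                    > max(a.get(c, (0, 1))[0], b.get(c, (0, 1))[0])
                    for c in coords
                ):
                    raise ValueError(f"basins {names[i]} and {names[j]} overlap")

    def label(self, fc: FrameCoordinates) -> np.ndarray:
        n = fc.n_frames
        out = np.full(n, UNASSIGNED, dtype="U1")
        for name, spec in self.bounds.items():
            mask = np.ones(n, dtype=bool)
            for coord, (lo, hi) in spec.items():
                series = fc.q[coord]
                mask &= (series >= lo) & (series < hi)
            out[mask] = name
        return out


def default_basin_definition(threshold: float = 0.7) -> BasinDefinition:
    """Q_X > threshold and the other two below it (generic starting point;
    production analyses calibrate per system from the FES minima)."""
    t = threshold
    return BasinDefinition(bounds={
        "O": {"O": (t, 1.01), "A": (0.0, t), "H": (0.0, t)},
        "A": {"A": (t, 1.01), "O": (0.0, t), "H": (0.0, t)},
        "H": {"H": (t, 1.01), "O": (0.0, t), "A": (0.0, t)},
    })


@dataclass
class StateSeries:
    """Dwell-filtered per-frame basin labels and the visit sequence."""

    labels: np.ndarray                       # per frame, {O,A,H,U}
    visits: list[tuple[str, int, int]]       # (state, first frame, last frame)
    dwell_filter: int

    @property
    def visit_states(self) -> list[str]:
        return [v[0] for v in self.visits]


def assign_basins(
    fc: FrameCoordinates,
    basins: BasinDefinition | None = None,
    dwell_filter: int = 50,
) -> StateSeries:
    """Label frames by basin and suppress visits shorter than the filter.

    Unassigned (U) frames are attributed to the preceding visit; leading U
    frames are dropped from the visit list.  Visits shorter than
    ``dwell_filter`` frames are merged into the surrounding visit, which
    suppresses barrier recrossing noise.
    """
    if basins is None:
        basins = default_basin_definition()
    basins.validate()
    raw = basins.label(fc)

    # collapse to runs over assigned states, attributing U to the previous one
    runs: list[list] = []   # [state, start, end]
    for i, lab in enumerate(raw):
        if lab == UNASSIGNED:
            if runs:
                runs[-1][2] = i
            continue
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i
        else:
            runs.append([lab, i, i])

    # dwell filtering: drop runs whose ASSIGNED span is below the filter,
    # merging their frames into the previous visit; repeat until stable
    def assigned_span(run):
        s, e = run[1], run[2]
        return int(np.sum(raw[s:e + 1] == run[0]))

    changed = True
    while changed:
        changed = False
        for k, run in enumerate(runs):
            if assigned_span(run) < dwell_filter:
                del runs[k]
                if k > 0:
                    runs[k - 1][2] = run[2]   # absorb into the previous visit
                # merge now-adjacent identical states
                m = 1
                while m < len(runs):
                    if runs[m][0] == runs[m - 1][0]:
                        runs[m - 1][2] = runs[m][2]
                        del runs[m]
                    else:
                        m += 1
                changed = True
                break

    labels = np.full(len(raw), UNASSIGNED, dtype="U1")
    visits = []
    for state, start, end in runs:
        labels[start:end + 1] = state
        visits.append((state, start, end))
    return StateSeries(labels=labels, visits=visits, dwell_filter=dwell_filter)


@dataclass
class TransitionStats:
    """Counts, occupancies, rates and route fluxes of a basin series."""

    counts: dict[str, int]            # "OA", "AO", "OH", "HO", "AH", "HA"
    n_oah: int                        # sequential O→A→H path count
    residence_frames: dict[str, int]
    probabilities: dict[str, float]
    total_frames: int
    frame_time: float                 # reduced time per frame
    f_if: float | None = None
    f_ps: float | None = None

    @property
    def total_time(self) -> float:
        return self.total_frames * self.frame_time

    def rate(self, x: str, y: str) -> float | None:
        """k(X→Y) = N_XY / (P_X · T_total), reciprocal reduced time."""
        n = self.counts.get(x + y, 0)
        p = self.probabilities.get(x, 0.0)
        if p <= 0 or self.total_time <= 0:
            return None
        return n / (p * self.total_time)

    def rate_table(self) -> dict[str, float | None]:
        return {pair: self.rate(pair[0], pair[1]) for pair in self.counts}


def parse_transitions(series: StateSeries, frame_time: float = 1.0) -> TransitionStats:
    """Count direct transitions, O→A→H paths, occupancies and route fluxes."""
    states = series.visit_states
    counts = {a + b: 0 for a in STATE_NAMES for b in STATE_NAMES if a != b}
    for a, b in zip(states[:-1], states[1:]):
        counts[a + b] += 1
    n_oah = sum(
        1 for i in range(len(states) - 2)
        if states[i] == "O" and states[i + 1] == "A" and states[i + 2] == "H"
    )
    residence = {s: 0 for s in STATE_NAMES}
    for state, start, end in series.visits:
        residence[state] += end - start + 1
    total = len(series.labels)
    probs = {s: residence[s] / total if total else 0.0 for s in STATE_NAMES}
    stats = TransitionStats(
        counts=counts, n_oah=n_oah, residence_frames=residence,
        probabilities=probs, total_frames=total, frame_time=frame_time,
    )
    stats.f_if, stats.f_ps = fractional_flux(stats)
    return stats


def aggregate_transition_stats(all_stats: list[TransitionStats]) -> TransitionStats:
    """Pool counts, paths and residence over independent replicas.

    Probabilities and rates then refer to the pooled ensemble; fluxes are
    recomputed from the summed path counts.
    """
    if not all_stats:
        raise ValueError("no statistics to aggregate")
    frame_time = all_stats[0].frame_time
    counts = {k: sum(s.counts.get(k, 0) for s in all_stats) for k in all_stats[0].counts}
    n_oah = sum(s.n_oah for s in all_stats)
    residence = {x: sum(s.residence_frames[x] for s in all_stats) for x in STATE_NAMES}
    total = sum(s.total_frames for s in all_stats)
    probs = {x: residence[x] / total if total else 0.0 for x in STATE_NAMES}
    agg = TransitionStats(counts=counts, n_oah=n_oah, residence_frames=residence,
                          probabilities=probs, total_frames=total,
                          frame_time=frame_time)
    agg.f_if, agg.f_ps = fractional_flux(agg)
    return agg


def fractional_flux(stats: TransitionStats) -> tuple[float | None, float | None]:
    """(F_IF, F_PS): relative weight of direct O→H vs sequential O→A→H."""
    n_oh = stats.counts.get("OH", 0)
    denom = n_oh + stats.n_oah
    if denom == 0:
        return None, None
    f_if = n_oh / denom
    return f_if, 1.0 - f_if


def rate_constants(stats: TransitionStats) -> dict[str, float | None]:
    """Rate table k(X→Y); None where the source basin was never occupied."""
    return stats.rate_table()


# ---------------------------------------------------------------------------
# free-energy surfaces

@dataclass
class FES2D:
    """Binned 2-D free-energy surface in k_BT (min-shifted; empty bins masked)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray           # masked array, (nx, ny)
    counts: np.ndarray
    axes: tuple[str, str] = ("x", "y")
    temperature: float = 1.0

    def bin_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
            0.5 * (self.y_edges[j] + self.y_edges[j + 1]),
        )


def free_energy_surface(
    x: np.ndarray,
    y: np.ndarray,
    temperature: float = 1.0,
    bins: int | tuple[int, int] = 30,
    ranges=((0.0, 1.0), (0.0, 1.0)),
    axes: tuple[str, str] = ("x", "y"),
) -> FES2D:
    """F(bin) = −T·ln(count/total) over a 2-D histogram, shifted to min 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y series must have equal length")
    if len(x) < 100:
        warnings.warn("fewer than 100 frames: free-energy surface will be noisy")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges)
    with np.errstate(divide="ignore"):
        f = -temperature * np.log(counts / counts.sum())
    masked = np.ma.masked_invalid(f)
    masked -= masked.min()
    return FES2D(x_edges=xe, y_edges=ye, free_energy=masked, counts=counts,
                 axes=axes, temperature=temperature)


def locate_minima_saddles(fes: FES2D):
    """Local minima and inter-minimum saddles of a masked FES grid.

    Minima: bins not exceeded by any 8-neighbour.  Saddle between two minima:
    the highest bin on the minimax path over the bin graph, found by a
    union-find sweep in order of increasing free energy (the level at which
    the two basins first merge).  Ties are resolved by row-major order.

    Returns ``(minima, saddles)`` where minima is a list of (i, j) bins and
    saddles maps (min_a, min_b) → (i, j, barrier height from the lower min).
    """
    f = fes.free_energy
    nx, ny = f.shape
    valid = ~np.ma.getmaskarray(f)

    def neighbors(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and valid[a, b]:
                    yield a, b

    minima = []
    for i in range(nx):
        for j in range(ny):
            if not valid[i, j]:
                continue
            vals = [f[a, b] for a, b in neighbors(i, j)]
            if vals and all(f[i, j] < v for v in vals):
                minima.append((i, j))
    if not minima and valid.any():
        # degenerate flat/plateau surface: fall back to the global minimum bin
        flat = np.ma.masked_array(f).filled(np.inf)
        minima = [tuple(np.unravel_index(np.argmin(flat), f.shape))]
    # order by depth, ties row-major
    minima.sort(key=lambda p: (f[p], p))

    # union-find sweep
    order = sorted(
        ((i, j) for i in range(nx) for j in range(ny) if valid[i, j]),
        key=lambda p: (f[p], p),
    )
    parent: dict = {}
    min_of: dict = {}   # root → representative minimum (lowest added bin)

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    minima_set = set(minima)
    saddles = {}
    added = set()
    for p in order:
        parent[p] = p
        min_of[p] = p if p in minima_set else None
        roots = set()
        for nb in neighbors(*p):
            if nb in added:
                roots.add(find(nb))
        for r in roots:
            rp = find(p)
            if r == rp:
                continue
            ma, mb = min_of[r], min_of[rp]
            if ma is not None and mb is not None and ma != mb:
                key = tuple(sorted((ma, mb)))
                if key not in saddles:
                    barrier = float(f[p] - max(f[ma], f[mb]))
                    saddles[key] = (p[0], p[1], barrier)
            # merge, keeping the deeper representative minimum
            parent[rp] = r
            keep = ma
            if keep is None or (mb is not None and f[mb] < f[ma]):
                keep = mb
            min_of[r] = keep
        added.add(p)
    return minima, saddles


# ---------------------------------------------------------------------------
# transition-state ensembles and contact probabilities

def extract_ts_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    saddle_xy: tuple[float, float],
    window: float = 0.05,
    min_size: int = 200,
    max_widenings: int = 2,
) -> np.ndarray:
    """Frame indices whose (x, y) fall within ±window of the saddle point.

    The window is doubled (at most ``max_widenings`` times, with a warning)
    if fewer than ``min_size`` frames qualify.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    w = window
    for attempt in range(max_widenings + 1):
        sel = np.where(
            (np.abs(x - saddle_xy[0]) <= w) & (np.abs(y - saddle_xy[1]) <= w)
        )[0]
        if len(sel) >= min_size:
            if attempt:
                warnings.warn(f"TS window widened to ±{w:.3g} to reach {len(sel)} frames")
            return sel
        w *= 2
    if len(sel) == 0:
        raise ValueError("no frames near the saddle even after widening twice")
    warnings.warn(
        f"TS ensemble has only {len(sel)} frames (< {min_size}) after widening"
    )
    return sel


def contact_probability_map(
    ensemble_coords: np.ndarray,
    topo: Topology,
    classes: tuple[ContactClass, ...] = (
        ContactClass.O_SPEC, ContactClass.A_SPEC, ContactClass.H_SPEC),
    criterion: float = 1.2,
):
    """Formation probability of each state-specific contact in an ensemble.

    Returns a list of dicts: contact indices, residues, class, probability.
    """
    if len(ensemble_coords) == 0:
        raise ValueError("empty ensemble")
    rows = []
    for cls in classes:
        idx = topo.contacts_of_class(cls)
        if len(idx) == 0:
            continue
        ij = topo.con_ij[idx]
        r0 = topo.con_r0[idx]
        d = np.linalg.norm(
            ensemble_coords[:, ij[:, 0]] - ensemble_coords[:, ij[:, 1]], axis=2)
        probs = (d < criterion * r0).mean(axis=0)
        for k, p in zip(idx, probs):
            rows.append({
                "contact_index": int(k),
                "i": int(topo.con_ij[k, 0]), "j": int(topo.con_ij[k, 1]),
                "class": cls.value, "probability": float(p),
            })
    return rows


# ---------------------------------------------------------------------------
# functional phi values and cracking

def _residue_contact_counts(
    coords: np.ndarray, topo: Topology, criterion: float,
    include_classes: tuple[ContactClass, ...],
) -> dict[int, float]:
    """Thermal mean number of formed native contacts per residue."""
    idx = np.concatenate([topo.contacts_of_class(c) for c in include_classes]) \
        if include_classes else np.arange(len(topo.con_ij))
    idx = np.unique(idx)
    ij = topo.con_ij[idx]
    r0 = topo.con_r0[idx]
    d = np.linalg.norm(coords[:, ij[:, 0]] - coords[:, ij[:, 1]], axis=2)
    formed = (d < criterion * r0)            # (frames, contacts)
    res_of_bead = topo.cg.res_index
    counts: dict[int, float] = {int(r): 0.0 for r in np.unique(res_of_bead)}
    mean_formed = formed.mean(axis=0)
    for k, (i, j) in enumerate(ij):
        counts[int(res_of_bead[i])] += mean_formed[k]
        counts[int(res_of_bead[j])] += mean_formed[k]
    return counts


NATIVE_CLASSES = (ContactClass.CORE, ContactClass.O_SPEC, ContactClass.A_SPEC,
                  ContactClass.H_SPEC, ContactClass.PAIR_SHARED)


@dataclass
class PhiTable:
    """Per-residue thermal contact numbers and functional φ for one transition."""

    transition: str                         # e.g. "OH" (start → end)
    n_start: dict[int, float]
    n_end: dict[int, float]
    n_ts: dict[int, float]
    phi: dict[int, float]                   # residues passing the floor
    backtracking: set[int]                  # φ outside [0,1]
    excluded: set[int]                      # |Δn| below the floor


def phi_values(
    start_coords: np.ndarray,
    end_coords: np.ndarray,
    ts_coords: np.ndarray,
    topo: Topology,
    transition: str = "OH",
    criterion: float = 1.2,
    floor: float = 0.5,
    include_classes: tuple[ContactClass, ...] = NATIVE_CLASSES,
) -> PhiTable:
    """Functional φ per residue: (⟨n⟩_TS − ⟨n⟩_start) / (⟨n⟩_end − ⟨n⟩_start).

    Residues whose end/start contact-number difference is below ``floor``
    are excluded as insensitive; φ outside [0,1] flags backtracking
    (transient breaking of contacts shared by both end states).
    """
    for name, c in (("start", start_coords), ("end", end_coords), ("ts", ts_coords)):
        if len(c) == 0:
            raise ValueError(f"{name} ensemble is empty")
    n_s = _residue_contact_counts(start_coords, topo, criterion, include_classes)
    n_e = _residue_contact_counts(end_coords, topo, criterion, include_classes)
    n_t = _residue_contact_counts(ts_coords, topo, criterion, include_classes)
    phi: dict[int, float] = {}
    backtracking: set[int] = set()
    excluded: set[int] = set()
    for r in n_s:
        denom = n_e[r] - n_s[r]
        if abs(denom) < floor:
            excluded.add(r)
            continue
        val = (n_t[r] - n_s[r]) / denom
        phi[r] = val
        if not (0.0 <= val <= 1.0):
            backtracking.add(r)
    return PhiTable(transition=transition, n_start=n_s, n_end=n_e, n_ts=n_t,
                    phi=phi, backtracking=backtracking, excluded=excluded)


def local_bonded_energy_per_residue(coords: np.ndarray, topo: Topology) -> dict[int, float]:
    """Mean angle+dihedral energy attributed to each residue (k_BT units).

    Each term's energy is split evenly among the residues of its beads.
    """
    from . import _kernels

    b = topo.bonded
    res_of = topo.cg.res_index
    totals: dict[int, float] = {int(r): 0.0 for r in np.unique(res_of)}
    n_frames = len(coords)
    # angles
    for coords_f in coords:
        p = coords_f
        # angle energies, vectorized
        v1 = p[b.angle_ijk[:, 0]] - p[b.angle_ijk[:, 1]]
        v2 = p[b.angle_ijk[:, 2]] - p[b.angle_ijk[:, 1]]
        cosq = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        theta = np.arccos(np.clip(cosq, -1, 1))
        e_ang = 0.5 * b.angle_k * (theta - b.angle_t0) ** 2
        p0, p1, p2, p3 = (p[b.dihedral_ijkl[:, k]] for k in range(4))
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
        phi = np.arctan2(np.einsum("ij,ij->i", m1, n2), np.einsum("ij,ij->i", n1, n2))
        dphi = phi - b.dihedral_phi0
        e_dih = b.dihedral_k1 * (1 - np.cos(dphi)) + b.dihedral_k3 * (1 - np.cos(3 * dphi))
        for ijk, e in zip(b.angle_ijk, e_ang):
            share = e / 3.0
            for bead in ijk:
                totals[int(res_of[bead])] += share
        for ijkl, e in zip(b.dihedral_ijkl, e_dih):
            share = e / 4.0
            for bead in ijkl:
                totals[int(res_of[bead])] += share
    return {r: v / n_frames for r, v in totals.items()}


def cracking_scores(
    ts_coords: np.ndarray,
    basin_a_coords: np.ndarray,
    basin_b_coords: np.ndarray,
    topo: Topology,
    threshold: float = 1.0,
) -> tuple[dict[int, float], set[int]]:
    """Local-strain (cracking) score per residue, in k_BT.

    Score = mean local bonded energy (angle + dihedral terms centred on the
    residue) in the TS ensemble minus the larger of the same quantity in the
    two end-basin ensembles.  Residues above ``threshold`` are flagged as
    cracking sites — strain that would be relieved by local unfolding.
    """
    e_ts = local_bonded_energy_per_residue(ts_coords, topo)
    e_a = local_bonded_energy_per_residue(basin_a_coords, topo)
    e_b = local_bonded_energy_per_residue(basin_b_coords, topo)
    scores = {r: e_ts[r] - max(e_a[r], e_b[r]) for r in e_ts}
    flagged = {r for r, s in scores.items() if s > threshold}
    return scores, flagged


# ---------------------------------------------------------------------------
# heat capacity

def heat_capacity_direct(energies_by_t: dict[float, np.ndarray]):
    """Cv(T) = (⟨E²⟩−⟨E⟩²)/T² per run; returns (T array, Cv array, T_melt)."""
    temps = np.array(sorted(energies_by_t))
    cv = np.array([
        np.var(np.asarray(energies_by_t[t])) / t**2 for t in temps
    ])
    return temps, cv, float(temps[np.argmax(cv)])


def wham_heat_capacity(
    energies_by_t: dict[float, np.ndarray],
    n_bins: int = 200,
    t_grid: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
):
    """Multiple-histogram (WHAM) density of states → Cv on a fine T grid.

    Requires overlapping energy histograms from ≥ 3 temperatures bracketing
    the transition.  Returns (T grid, Cv, T_melt).
    """
    temps = sorted(energies_by_t)
    if len(temps) < 3:
        raise ValueError("WHAM needs at least 3 temperatures")
    all_e = np.concatenate([np.asarray(energies_by_t[t]) for t in temps])
    edges = np.linspace(all_e.min(), all_e.max() + 1e-9, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.array([np.histogram(energies_by_t[t], bins=edges)[0] for t in temps])
    n_samples = hists.sum(axis=1).astype(float)

    # check pairwise histogram overlap along the T ladder
    for k in range(len(temps) - 1):
        occ_a = hists[k] > 0
        occ_b = hists[k + 1] > 0
        if not np.any(occ_a & occ_b):
            raise ValueError(
                f"no energy-histogram overlap between T={temps[k]:g} "
                f"and T={temps[k+1]:g}"
            )

    beta = np.array([1.0 / t for t in temps])
    f = np.zeros(len(temps))
    h_tot = hists.sum(axis=0)
    occupied = h_tot > 0
    log_h = np.where(occupied, np.log(np.maximum(h_tot, 1)), -np.inf)
    for _ in range(max_iter):
        # log Ω(E) = log Σh − logsumexp_i( log N_i + f_i − β_i E )
        a = (np.log(n_samples)[:, None] + f[:, None]
             - beta[:, None] * centers[None, :])
        amax = a.max(axis=0)
        denom = amax + np.log(np.exp(a - amax).sum(axis=0))
        log_omega = np.where(occupied, log_h - denom, -np.inf)
        # f_i = −log Σ_E Ω e^{−β_i E}
        b = log_omega[None, :] - beta[:, None] * centers[None, :]
        bmax = b.max(axis=1)
        f_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    if t_grid is None:
        t_grid = np.linspace(temps[0], temps[-1], 200)
    cv = np.empty(len(t_grid))
    for k, t in enumerate(t_grid):
        w = log_omega - centers / t
        w = w[occupied]
        wmax = w.max()
        z = np.exp(w - wmax)
        e_mean = (centers[occupied] * z).sum() / z.sum()
        e2_mean = (centers[occupied] ** 2 * z).sum() / z.sum()
        cv[k] = (e2_mean - e_mean**2) / t**2
    return np.asarray(t_grid), cv, float(t_grid[np.argmax(cv)])


# ---------------------------------------------------------------------------
# tabular output

def write_transition_table(stats: TransitionStats, path, provenance: str = "") -> None:
    """TransitionStats as tab-separated text with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# tribasin transition statistics\n# {provenance}\n")
        fh.write("quantity\tvalue\n")
        for pair, n in sorted(stats.counts.items()):
            fh.write(f"N_{pair}\t{n}\n")
        fh.write(f"N_OAH\t{stats.n_oah}\n")
        for s, p in stats.probabilities.items():
            fh.write(f"P_{s}\t{p:.6g}\n")
        fh.write(f"T_total\t{stats.total_time:.6g}\n")
        for pair, k in stats.rate_table().items():
            fh.write(f"k_{pair}\t{'nan' if k is None else f'{k:.6g}'}\n")
        fh.write(f"F_IF\t{'nan' if stats.f_if is None else f'{stats.f_if:.6g}'}\n")
        fh.write(f"F_PS\t{'nan' if stats.f_ps is None else f'{stats.f_ps:.6g}'}\n")


def write_phi_table(table: PhiTable, path, provenance: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# tribasin functional phi values ({table.transition})\n# {provenance}\n")
        fh.write("residue\tn_start\tn_end\tn_ts\tphi\tbacktracking\n")
        for r in sorted(table.n_start):
            phi = table.phi.get(r)
            fh.write(
                f"{r}\t{table.n_start[r]:.4g}\t{table.n_end[r]:.4g}\t"
                f"{table.n_ts[r]:.4g}\t{'nan' if phi is None else f'{phi:.4g}'}\t"
                f"{int(r in table.backtracking)}\n"
            )


def write_fes(fes: FES2D, path, provenance: str = "") -> None:
    """Gridded text format: bin centers and free energy (NaN = empty)."""
    with open(path, "w") as fh:
        fh.write(f"# tribasin 2-D free-energy surface (k_BT), axes {fes.axes}\n")
        fh.write(f"# {provenance}\n")
        fh.write(f"# x_edges\t{' '.join(f'{v:.6g}' for v in fes.x_edges)}\n")
        fh.write(f"# y_edges\t{' '.join(f'{v:.6g}' for v in fes.y_edges)}\n")
        fh.write("i\tj\tx\ty\tfree_energy\tcount\n")
        nx, ny = fes.free_energy.shape
        for i in range(nx):
            for j in range(ny):
                x, y = fes.bin_center(i, j)
                v = fes.free_energy[i, j]
                vtxt = "nan" if np.ma.is_masked(v) else f"{float(v):.6g}"
                fh.write(f"{i}\t{j}\t{x:.6g}\t{y:.6g}\t{vtxt}\t{int(fes.counts[i,j])}\n")


def read_fes(path) -> FES2D:
    x_edges = y_edges = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# x_edges"):
                x_edges = np.array([float(v) for v in line.split("\t")[1].split()])
            elif line.startswith("# y_edges"):
                y_edges = np.array([float(v) for v in line.split("\t")[1].split()])
            elif line.startswith("#") or line.startswith("i\t"):
                continue
            else:
                rows.append(line.split("\t"))
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    f = np.full((nx, ny), np.nan)
    counts = np.zeros((nx, ny))
    for r in rows:
        i, j = int(r[0]), int(r[1])
        f[i, j] = float(r[4])
        counts[i, j] = float(r[5])
    return FES2D(x_edges=x_edges, y_edges=y_edges,
                 free_energy=np.ma.masked_invalid(f), counts=counts)
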