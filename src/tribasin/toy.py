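"""Synthetic two-domain three-state test systems.

The generator emulates, at miniature scale, the open / partially-closed /
fully-closed conformer triple of a two-domain binding protein: two compact
helical-coil "domains" joined by a short extended hinge, with the three
conformers produced by rigid rotation of the mobile block about the hinge
(closure angle, with an optional twist about the domain axis and an optional
azimuth of the closure axis) and a pseudo-ligand placed between the
approaching domain surfaces in the fully-closed (H) conformer.  Because only
hinge-driven geometry differs between conformers, intra-domain contacts are
shared (CORE) while the cross-hinge/inter-domain pattern changes with the
closure motion, producing nonempty O/A/H-specific and ligand classes after
classification.  The open basin of the resulting model is held mainly by the
backbone bias toward the open geometry; its specific-contact set is small,
as the open state has the least inter-domain interface.

All output is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import rotation_about_axis
from .structures import AtomicModel, DomainMap

#: residue types used by the generator (charged ones carry longer side chains)
_SIDE_ATOMS = {
    "ALA": ["CB"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
}


@dataclass
class ToySpec:
    """Parameters of the synthetic three-state system."""

    n_residues: int = 40
    hinge_residues: tuple[int, ...] = (19, 20, 21, 22)
    closure_angles: tuple[float, float, float] = (0.0, 36.0, 68.0)   # deg, O/A/H
    twist_angles: tuple[float, float, float] = (-30.0, 20.0, -70.0)  # deg about the domain-2 axis
    # azimuth of each conformer's closure axis in the x-y plane (deg); a
    # nonzero value swings domain 2 onto a different face of domain 1,
    # emulating a mixed closure/twist hinge mode
    closure_axis_azimuths: tuple[float, float, float] = (0.0, 0.0, 0.0)
    place_ligand: bool = True
    seed: int = 0
    # geometry of the compact helical coil forming each domain
    coil_radius: float = 4.5        # Å
    coil_rise: float = 0.7          # Å per residue
    coil_turn: float = 50.0         # deg per residue
    domain_tilt: float = 1.0        # y-component of the (downward) domain axes
    pivot_residue: int = 21         # hinge residue whose CA anchors the closure rotation
    ca_spacing: float = 3.8         # Å, consecutive CA distance in the hinge
    side_spacing: float = 0.85      # Å between successive side-chain heavy atoms
    contact_cutoff: float = 6.0     # Å, heavy-atom cutoff suited to the sparse toy atoms
    charged_positions: dict[int, str] = field(
        default_factory=lambda: {5: "LYS", 9: "GLU", 27: "GLU", 31: "LYS"}
    )

    def __post_init__(self):
        if len(set(self.closure_angles)) != len(self.closure_angles):
            raise ValueError("closure angles must be distinct")

    @property
    def domain1(self) -> range:
        return range(1, self.hinge_residues[0])

    @property
    def domain2(self) -> range:
        return range(self.hinge_residues[-1] + 1, self.n_residues + 1)

    def domain_map(self) -> DomainMap:
        return DomainMap(regions={
            "NTD": [(self.domain1.start, self.domain1.stop - 1)],
            "CTD": [(self.domain2.start, self.domain2.stop - 1)],
            "hinge": [(self.hinge_residues[0], self.hinge_residues[-1])],
        })


def _coil(n: int, spec: ToySpec, start: np.ndarray, axis: np.ndarray,
          phase: float = 0.0) -> np.ndarray:
    """CA positions of a compact helical coil of n residues along ``axis``."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = np.empty((n, 3))
    for k in range(n):
        ang = phase + np.deg2rad(spec.coil_turn) * k
        out[k] = (start + axis * spec.coil_rise * k
                  + u * spec.coil_radius * np.cos(ang)
                  + v * spec.coil_radius * np.sin(ang))
    return out


def _ca_trace(spec: ToySpec) -> np.ndarray:
    """Base (open, 0°) CA trace.

    The hinge runs along +y through the origin; both domains hang downward
    (−z) from the hinge ends, their axes tilted apart in ±y, so that rotating
    domain 2 about the hinge x-axis closes it onto domain 1.
    """
    n1 = len(spec.domain1)
    n_h = len(spec.hinge_residues)
    n2 = len(spec.domain2)
    hinge = np.array([[0.0, spec.ca_spacing * k, 0.0] for k in range(n_h)])
    t = spec.domain_tilt
    # domain 1: built outward from the hinge (residue order reversed so that
    # residue 1 is farthest from the hinge and residue n1 joins hinge[0])
    d1_axis = np.array([0.0, -t, -1.0])
    d1 = _coil(n1, spec, hinge[0], d1_axis, phase=0.3)[::-1]
    gap = hinge[0] - d1[-1]
    d1 = d1 + (gap - spec.ca_spacing * gap / np.linalg.norm(gap))
    # domain 2: outward from the hinge end, mirrored tilt
    d2_axis = np.array([0.0, t, -1.0])
    d2 = _coil(n2, spec, hinge[-1], d2_axis, phase=1.1)
    gap = d2[0] - hinge[-1]
    d2 = d2 - (gap - spec.ca_spacing * gap / np.linalg.norm(gap))
    return np.vstack([d1, hinge, d2])


def _residue_types(spec: ToySpec) -> list[str]:
    types = []
    for resid in range(1, spec.n_residues + 1):
        if resid in spec.hinge_residues:
            types.append("GLY")
        elif resid in spec.charged_positions:
            types.append(spec.charged_positions[resid])
        else:
            types.append("ALA")
    return types


def _build_atoms(spec: ToySpec, ca: np.ndarray, rng: np.random.Generator) -> AtomicModel:
    """Decorate a CA trace with backbone and side-chain heavy atoms."""
    types = _residue_types(spec)
    n = spec.n_residues
    # outward directions: radial from the local centroid (domain residues) or
    # perpendicular to the chain (hinge)
    centers = {}
    d1_idx = np.array(list(spec.domain1)) - 1
    d2_idx = np.array(list(spec.domain2)) - 1
    centers["d1"] = ca[d1_idx].mean(axis=0)
    centers["d2"] = ca[d2_idx].mean(axis=0)

    res_index, res_name, atom_name, element, coords = [], [], [], [], []

    def add(resid, rname, aname, pos):
        res_index.append(resid)
        res_name.append(rname)
        atom_name.append(aname)
        element.append(aname[0] if aname[0] in "NCOS" else "C")
        coords.append(pos)

    for p in range(n):
        resid = p + 1
        rname = types[p]
        prev_dir = (ca[p - 1] - ca[p]) if p > 0 else (ca[p] - ca[p + 1])
        next_dir = (ca[p + 1] - ca[p]) if p < n - 1 else (ca[p] - ca[p - 1])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        if resid in spec.domain1:
            out = ca[p] - centers["d1"]
        elif resid in spec.domain2:
            out = ca[p] - centers["d2"]
        else:
            # hinge: point side groups up (+z), away from the closing domains
            out = np.cross(np.array([1.0, 0.0, 0.0]), next_dir)
            if np.linalg.norm(out) < 1e-6:
                out = np.array([0.0, 0.0, 1.0])
            if out[2] < 0:
                out = -out
        out = out / np.linalg.norm(out)

        add(resid, rname, "N", ca[p] + 1.45 * prev_dir + 0.2 * out)
        add(resid, rname, "CA", ca[p])
        add(resid, rname, "C", ca[p] + 1.5 * next_dir + 0.2 * out)
        add(resid, rname, "O", ca[p] + 1.5 * next_dir + 1.4 * out)
        side = _SIDE_ATOMS[rname]
        perp = np.cross(out, next_dir)
        for k, aname in enumerate(side):
            jig = 0.35 * perp if aname in ("OE1",) else (-0.35 * perp if aname in ("OE2",) else 0.0)
            add(resid, rname, aname, ca[p] + (1.55 + spec.side_spacing * k) * out + jig)

    return AtomicModel(
        res_index=np.asarray(res_index, dtype=int),
        res_name=np.asarray(res_name, dtype="U5"),
        atom_name=np.asarray(atom_name, dtype="U5"),
        element=np.asarray(element, dtype="U2"),
        coords=np.asarray(coords, dtype=float),
        chain_id=np.full(len(res_index), "A", dtype="U4"),
    )


def _rotate_domain2(
    spec: ToySpec, model: AtomicModel, angle_deg: float, twist_deg: float = 0.0,
    axis_azimuth_deg: float = 0.0,
) -> AtomicModel:
    """Rigid motion of the mobile block: twist domain 2 about its own coil
    axis (through the first domain-2 CA), then rotate everything C-terminal
    of the pivot residue about the hinge x-axis through the pivot CA
    (negative sense closes domain 2 onto domain 1).  Rotating the block from
    mid-hinge means the hinge-top contacts with domain 1 exist only in the
    open conformer."""
    coords = model.coords.copy()
    d2 = np.isin(model.res_index, np.array(list(spec.domain2)))
    if twist_deg != 0.0:
        axis = np.array([0.0, spec.domain_tilt, -1.0])
        anchor = model.atom_coords(spec.domain2.start, ["CA"])[0]
        Rt = rotation_about_axis(axis, np.deg2rad(twist_deg))
        coords[d2] = (coords[d2] - anchor) @ Rt.T + anchor
    pivot = model.atom_coords(spec.pivot_residue, ["CA"])[0]
    block = model.res_index >= spec.pivot_residue
    psi = np.deg2rad(axis_azimuth_deg)
    axis = np.array([np.cos(psi), np.sin(psi), 0.0])
    R = rotation_about_axis(axis, -np.deg2rad(angle_deg))
    coords[block] = (coords[block] - pivot) @ R.T + pivot
    return AtomicModel(
        res_index=model.res_index, res_name=model.res_name,
        atom_name=model.atom_name, element=model.element,
        coords=coords, chain_id=model.chain_id,
    )


def _place_ligand(spec: ToySpec, holo: AtomicModel) -> AtomicModel:
    """Pseudo-ligand atoms at midpoints of close cross-domain CA pairs."""
    d1 = np.array(list(spec.domain1))
    d2 = np.array(list(spec.domain2))
    ca1 = np.array([holo.atom_coords(r, ["CA"])[0] for r in d1])
    ca2 = np.array([holo.atom_coords(r, ["CA"])[0] for r in d2])
    dmat = np.linalg.norm(ca1[:, None, :] - ca2[None, :, :], axis=2)
    # cross-domain pairs whose midpoint lies within reach of both residues
    cand = np.argwhere((dmat > 4.0) & (dmat < 9.0))
    if len(cand) == 0:
        raise ValueError("no cross-domain pocket found for the pseudo-ligand")
    order = np.argsort(dmat[cand[:, 0], cand[:, 1]])
    mids = []
    for idx in order[:4]:
        i, j = cand[idx]
        mids.append(0.5 * (ca1[i] + ca2[j]))
    mids = np.asarray(mids)
    return AtomicModel(
        res_index=holo.res_index, res_name=holo.res_name,
        atom_name=holo.atom_name, element=holo.element,
        coords=holo.coords, chain_id=holo.chain_id,
        ligand_res_name=np.full(len(mids), "LIG", dtype="U5"),
        ligand_atom_name=np.array([f"C{k+1}" for k in range(len(mids))], dtype="U5"),
        ligand_element=np.full(len(mids), "C", dtype="U2"),
        ligand_coords=mids,
    )


def _min_nonlocal_distance(model: AtomicModel) -> float:
    """Minimum heavy-atom distance between residues ≥ 2 apart (clash check)."""
    from scipy.spatial import cKDTree

    heavy = model.heavy_mask()
    coords = model.coords[heavy]
    resid = model.res_index[heavy]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2.5, output_type="ndarray")
    if len(pairs) == 0:
        return np.inf
    sep = np.abs(resid[pairs[:, 0]] - resid[pairs[:, 1]])
    far = pairs[sep >= 2]
    if len(far) == 0:
        return np.inf
    d = np.linalg.norm(coords[far[:, 0]] - coords[far[:, 1]], axis=1)
    return float(d.min())


def make_toy_three_state(
    spec: ToySpec | None = None,
) -> tuple[AtomicModel, AtomicModel, AtomicModel]:
    """Generate the (O, A, H) conformer triple; H carries the pseudo-ligand.

    Conformers share all bond lengths exactly (domain 2 is rigidly rotated);
    a spec producing steric clashes is retried with small seeded jitter of
    the coil phase, then rejected.
    """
    if spec is None:
        spec = ToySpec()
    rng = np.random.default_rng(spec.seed)
    last_err = None
    for attempt in range(5):
        s = spec if attempt == 0 else ToySpec(
            **{**spec.__dict__,
               "coil_turn": spec.coil_turn + float(rng.uniform(-3, 3)),
               "coil_rise": spec.coil_rise + float(rng.uniform(-0.1, 0.1))},
        )
        ca = _ca_trace(s)
        base = _build_atoms(s, ca, rng)
        models = [
            _rotate_domain2(s, base, ang, twist, azim)
            for ang, twist, azim in zip(
                s.closure_angles, s.twist_angles, s.closure_axis_azimuths)
        ]
        clash = min(_min_nonlocal_distance(m) for m in models)
        if clash < 1.8:
            last_err = ValueError(f"steric clash: min distance {clash:.2f} Å")
            continue
        o_model, a_model, h_model = models
        if s.place_ligand:
            h_model = _place_ligand(s, h_model)
        return o_model, a_model, h_model
    raise last_err


def build_toy_system(spec: ToySpec | None = None, params=None):
    """Full pipeline convenience: toy conformers → triple-basin topology.

    Returns ``(topology, references, mixed_map, ligand_contacts)`` where
    ``references`` maps state name → bead coordinate array (shared bead
    indexing across the three conformers).
    """
    from .contacts import classify_contacts, compute_contact_map, ligand_mediated_contacts
    from .structures import assign_charges, coarse_grain
    from .topology import ModelParams, build_topology

    if spec is None:
        spec = ToySpec()
    if params is None:
        params = ModelParams()
    o_model, a_model, h_model = make_toy_three_state(spec)
    cg_o = assign_charges(coarse_grain(o_model))
    cg_a = assign_charges(coarse_grain(a_model))
    cg_h = assign_charges(coarse_grain(h_model))
    cut = spec.contact_cutoff
    maps = [
        compute_contact_map(m, cutoff=cut, cg=cg)
        for m, cg in ((o_model, cg_o), (a_model, cg_a), (h_model, cg_h))
    ]
    mixed = classify_contacts(*maps, cg_o, eps_shared=params.eps_shared,
                              eps_spec=params.eps_spec)
    lig = ligand_mediated_contacts(h_model, spec.domain_map(), cutoff=cut, cg=cg_h)
    topo = build_topology(cg_o, cg_a, cg_h, mixed, params, ligand_contacts=lig)
    references = {"O": cg_o.coords.copy(), "A": cg_a.coords.copy(), "H": cg_h.coords.copy()}
    return topo, references, mixed, lig


def toy_basin_definition():
    """Basin regions in (Q_A, Q_H) calibrated for the default ToySpec.

    The open basin is the region where neither closed state's specific
    contacts are formed; the apo-closed (A) and holo-closed (H) basins
    require their own Q above threshold.  Calibrated from the free-energy
    surfaces of long default-parameter runs.
    """
    from .landscape import BasinDefinition

    return BasinDefinition(bounds={
        "O": {"A": (0.0, 0.30), "H": (0.0, 0.30)},
        "A": {"A": (0.55, 1.01), "H": (0.0, 0.50)},
        "H": {"H": (0.60, 1.01)},
    })
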