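"""Assembly of the triple-basin Hamiltonian specification.

The topology bundles, in array form ready for the energy kernels:

* bonded terms — harmonic bonds (consecutive CA-CA, SC to parent CA),
  harmonic pseudo-angles, cosine dihedrals (periodicities 1 and 3) over the
  CA trace plus one chirality dihedral per SC bead, with equilibrium values
  taken from the open reference structure;
* the mixed contact map (core / state-specific / pair-shared / ligand
  classes with their strengths);
* excluded-volume pairs, charges and Debye-Hückel parameters.

Hinge residues are detected from differences in CA pseudo-angles and
pseudo-dihedrals between the reference states; every bonded angle/dihedral
touching a hinge residue is hinge-flagged and its force constant rescaled by
γ ∈ (0, 1] (γ < 1 softens the hinge).  The ``theta_OAH`` angle-model variant
additionally flattens hinge terms so that all three states' native values lie
within 1 k_BT of the minimum at the reference temperature, removing the pure
open-state bias from the hinges.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .contacts import Contact, ContactClass, MixedContactMap
from .geometry import angle_diff, pseudo_angles, pseudo_dihedrals
from .structures import CGStructure

logger = logging.getLogger(__name__)

CLASS_CODE = {
    ContactClass.CORE: 0,
    ContactClass.O_SPEC: 1,
    ContactClass.A_SPEC: 2,
    ContactClass.H_SPEC: 3,
    ContactClass.PAIR_SHARED: 4,
    ContactClass.LIGAND: 5,
}
CODE_CLASS = {v: k for k, v in CLASS_CODE.items()}


@dataclass
class ModelParams:
    """All tunable parameters of the triple-basin model (reduced units).

    ε_L is the ligand-contact strength and acts as an implicit proxy for
    ligand concentration; the validated scan range is 0–1.5 (ε_L = 1 makes
    ligand contacts as strong as core contacts).
    """

    eps_shared: float = 1.0
    eps_spec: float = 0.4
    eps_ligand: float = 0.0
    gamma: float = 1.0
    angle_model: str = "theta_O"       # "theta_O" | "theta_OAH"
    contact_cutoff: float = 4.5        # Å
    min_seq_sep: int = 4
    dielectric: float = 80.0
    ionic_strength: float = 0.10       # mol/L
    contact_form: str = "lj1206"       # "lj1206" | "gaussian"
    # backbone force constants (reduced energy / Å² or / rad²)
    k_bond: float = 100.0
    k_angle: float = 20.0
    k_dihedral_1: float = 1.0
    k_dihedral_3: float = 0.5
    # excluded volume
    sigma_ca: float = 4.0              # Å
    sigma_sc: float = 2.0              # Å
    eps_repulsion: float = 1.0
    # reference temperature used by the theta_OAH flattening rule
    t_ref: float = 0.5

    def validate(self) -> None:
        if self.eps_ligand < 0:
            raise ValueError("eps_ligand must be >= 0")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.angle_model not in ("theta_O", "theta_OAH"):
            raise ValueError(f"unknown angle model {self.angle_model!r}")
        if self.eps_ligand > 1.5:
            warnings.warn("eps_ligand above the validated scan range [0, 1.5]")
        ratio = self.eps_spec / self.eps_shared
        if not (0.4 - 1e-12 <= ratio <= 0.6 + 1e-12):
            warnings.warn(
                f"eps_spec/eps_shared = {ratio:.3g} outside the validated band [0.4, 0.6]"
            )
        if not (40 <= self.dielectric <= 160):
            warnings.warn("dielectric outside the validated range [40, 160]")
        if not (0 <= self.ionic_strength <= 0.20):
            warnings.warn("ionic strength outside the validated range [0, 0.20] M")


@dataclass
class BondedTerms:
    """Bonds, angles and dihedrals in array form; force constants are final
    (γ and any theta_OAH flattening already applied)."""

    bond_ij: np.ndarray      # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_ijk: np.ndarray    # (na, 3) int
    angle_t0: np.ndarray     # rad
    angle_k: np.ndarray
    angle_hinge: np.ndarray  # bool
    dihedral_ijkl: np.ndarray  # (nd, 4) int
    dihedral_phi0: np.ndarray  # rad
    dihedral_k1: np.ndarray
    dihedral_k3: np.ndarray
    dihedral_hinge: np.ndarray  # bool


@dataclass
class Topology:
    """Complete parameterized Hamiltonian for one protein system."""

    cg: CGStructure                  # open-state reference geometry (+ charges)
    bonded: BondedTerms
    mixed_map: MixedContactMap
    params: ModelParams
    hinge_residues: set[int]
    # flattened contact arrays (ligand strength folded in as eps_L * eps_shared)
    con_ij: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    con_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    con_eps: np.ndarray = field(default_factory=lambda: np.empty(0))
    con_class: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    rep_ij: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    rep_sigma: np.ndarray = field(default_factory=lambda: np.empty(0))
    chg_ij: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    chg_qq: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_beads(self) -> int:
        return self.cg.n_beads

    def contacts_of_class(self, cls: ContactClass) -> np.ndarray:
        """Indices into the contact arrays for one class."""
        return np.where(self.con_class == CLASS_CODE[cls])[0]

    def validate(self) -> None:
        n = self.n_beads
        for arr in (self.bonded.bond_ij, self.bonded.angle_ijk,
                    self.bonded.dihedral_ijkl, self.con_ij, self.rep_ij):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError("bead index out of range in topology")


def detect_hinges(
    cg_o: CGStructure,
    cg_a: CGStructure,
    cg_h: CGStructure,
    angle_threshold: float = 15.0,
    dihedral_threshold: float = 30.0,
    rule: str = "or",
) -> set[int]:
    """Hinge residues from inter-state pseudo-angle/dihedral differences.

    A residue is a hinge if, for any pair of reference states, its CA
    pseudo-angle differs by more than ``angle_threshold`` degrees and/or the
    pseudo-dihedrals centred on it differ by more than ``dihedral_threshold``
    degrees (``rule`` = "or" | "and").
    """
    cas = [cg.coords[cg.ca_indices] for cg in (cg_o, cg_a, cg_h)]
    resids = cg_o.res_index[cg_o.ca_indices]
    if not (len(cas[0]) == len(cas[1]) == len(cas[2])):
        raise ValueError("reference states have different residue counts")
    n = len(cas[0])
    ang = [pseudo_angles(c) for c in cas]
    dih = [pseudo_dihedrals(c) for c in cas]
    ang_hit = np.zeros(n, dtype=bool)   # per residue position
    dih_hit = np.zeros(n, dtype=bool)
    ang_thr = np.deg2rad(angle_threshold)
    dih_thr = np.deg2rad(dihedral_threshold)
    for a in range(3):
        for b in range(a + 1, 3):
            d_ang = angle_diff(ang[a], ang[b]) > ang_thr        # positions 1..n-2
            d_dih = angle_diff(dih[a], dih[b]) > dih_thr        # quads 0..n-4
            ang_hit[1:-1] |= d_ang
            # a dihedral over positions p..p+3 is centred on p+1, p+2
            dih_hit[1:-2] |= d_dih
            dih_hit[2:-1] |= d_dih
    hits = (ang_hit | dih_hit) if rule == "or" else (ang_hit & dih_hit)
    return {int(resids[p]) for p in np.where(hits)[0]}


def _build_bonded(
    cg: CGStructure,
    cg_a: CGStructure,
    cg_h: CGStructure,
    params: ModelParams,
    hinge_residues: set[int],
) -> BondedTerms:
    ca = cg.ca_indices
    resid_of_bead = cg.res_index
    coords = cg.coords

    bond_ij, bond_r0 = [], []
    for p in range(len(ca) - 1):
        bond_ij.append((ca[p], ca[p + 1]))
    for resid in np.unique(cg.res_index):
        sc = cg.sc_index(int(resid))
        if sc is not None:
            bond_ij.append((cg.bead_index(int(resid), "CA"), sc))
    bond_ij = np.asarray(bond_ij, dtype=int)
    bond_r0 = np.linalg.norm(coords[bond_ij[:, 0]] - coords[bond_ij[:, 1]], axis=1)

    angle_ijk = []
    for p in range(1, len(ca) - 1):
        angle_ijk.append((ca[p - 1], ca[p], ca[p + 1]))
    for resid in np.unique(cg.res_index):
        sc = cg.sc_index(int(resid))
        if sc is None:
            continue
        cai = cg.bead_index(int(resid), "CA")
        pos = int(np.where(cg.res_index[ca] == resid)[0][0])
        nbr = ca[pos + 1] if pos + 1 < len(ca) else ca[pos - 1]
        angle_ijk.append((sc, cai, nbr))
    angle_ijk = np.asarray(angle_ijk, dtype=int)

    dihedral_ijkl = []
    for p in range(len(ca) - 3):
        dihedral_ijkl.append((ca[p], ca[p + 1], ca[p + 2], ca[p + 3]))
    for resid in np.unique(cg.res_index):
        sc = cg.sc_index(int(resid))
        if sc is None:
            continue
        pos = int(np.where(cg.res_index[ca] == resid)[0][0])
        if 1 <= pos < len(ca) - 1:
            # chirality dihedral fixing the SC bead relative to the CA trace
            dihedral_ijkl.append((ca[pos - 1], ca[pos], ca[pos + 1], sc))
    dihedral_ijkl = np.asarray(dihedral_ijkl, dtype=int)

    def _angles(c):
        b1 = c[angle_ijk[:, 0]] - c[angle_ijk[:, 1]]
        b2 = c[angle_ijk[:, 2]] - c[angle_ijk[:, 1]]
        cosang = np.einsum("ij,ij->i", b1, b2) / (
            np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1))
        return np.arccos(np.clip(cosang, -1, 1))

    def _dihedrals(c):
        p0, p1, p2, p3 = (c[dihedral_ijkl[:, k]] for k in range(4))
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
        return np.arctan2(np.einsum("ij,ij->i", m1, n2), np.einsum("ij,ij->i", n1, n2))

    angle_t0 = _angles(coords)
    dihedral_phi0 = _dihedrals(coords)

    angle_hinge = np.array(
        [any(int(resid_of_bead[b]) in hinge_residues for b in ijk) for ijk in angle_ijk]
    )
    dihedral_hinge = np.array(
        [any(int(resid_of_bead[b]) in hinge_residues for b in ijkl) for ijkl in dihedral_ijkl]
    )

    angle_k = np.full(len(angle_ijk), params.k_angle)
    dih_k1 = np.full(len(dihedral_ijkl), params.k_dihedral_1)
    dih_k3 = np.full(len(dihedral_ijkl), params.k_dihedral_3)

    if params.angle_model == "theta_OAH":
        # flatten hinge terms: force constants reduced so every state's native
        # value sits within 1 k_BT (at t_ref) of the open-state minimum
        t = params.t_ref
        a_o = angle_t0
        a_states = []
        d_states = []
        for other in (cg_a, cg_h):
            a_states.append(_angles(other.coords))
            d_states.append(_dihedrals(other.coords))
        max_dev_a = np.max(
            [angle_diff(a, a_o) for a in a_states], axis=0
        )
        sel = angle_hinge & (max_dev_a > 1e-9)
        angle_k[sel] = np.minimum(angle_k[sel], 2.0 * t / max_dev_a[sel] ** 2)
        for d_other in d_states:
            dev = angle_diff(d_other, dihedral_phi0)
            e_at_dev = dih_k1 * (1 - np.cos(dev)) + dih_k3 * (1 - np.cos(3 * dev))
            sel = dihedral_hinge & (e_at_dev > t)
            scale = t / np.maximum(e_at_dev, 1e-12)
            dih_k1[sel] *= scale[sel]
            dih_k3[sel] *= scale[sel]

    # hinge softening
    angle_k[angle_hinge] *= params.gamma
    dih_k1[dihedral_hinge] *= params.gamma
    dih_k3[dihedral_hinge] *= params.gamma

    return BondedTerms(
        bond_ij=bond_ij,
        bond_r0=bond_r0,
        bond_k=np.full(len(bond_ij), params.k_bond),
        angle_ijk=angle_ijk,
        angle_t0=angle_t0,
        angle_k=angle_k,
        angle_hinge=angle_hinge,
        dihedral_ijkl=dihedral_ijkl,
        dihedral_phi0=dihedral_phi0,
        dihedral_k1=dih_k1,
        dihedral_k3=dih_k3,
        dihedral_hinge=dihedral_hinge,
    )


def build_topology(
    cg_o: CGStructure,
    cg_a: CGStructure,
    cg_h: CGStructure,
    mixed_map: MixedContactMap,
    params: ModelParams,
    ligand_contacts: list[Contact] | None = None,
    hinge_residues: set[int] | None = None,
) -> Topology:
    """Assemble the full triple-basin topology.

    Equilibrium bonded values come from the open structure; the contact list
    is the mixed map plus ligand-mediated contacts at strength ε_L·ε_shared.
    Ligand entries duplicating a native residue pair are dropped (the native
    contact already covers the pair and classes must stay disjoint), as are
    all ligand entries when ε_L = 0 (so the energy is then independent of the
    ligand list).
    """
    params.validate()
    if hinge_residues is None:
        hinge_residues = detect_hinges(cg_o, cg_a, cg_h)
    bonded = _build_bonded(cg_o, cg_a, cg_h, params, hinge_residues)

    contacts = list(mixed_map.contacts)
    native_pairs = {(min(c.res_i, c.res_j), max(c.res_i, c.res_j)) for c in contacts}
    n_dropped = 0
    if ligand_contacts and params.eps_ligand > 0:
        for c in ligand_contacts:
            key = (min(c.res_i, c.res_j), max(c.res_i, c.res_j))
            if key in native_pairs:
                n_dropped += 1
                continue
            contacts.append(Contact(c.i, c.j, c.res_i, c.res_j, c.r0,
                                    ContactClass.LIGAND,
                                    params.eps_ligand * params.eps_shared))
            native_pairs.add(key)
    if n_dropped:
        logger.info("dropped %d ligand contacts duplicating native pairs", n_dropped)

    con_ij = np.asarray([[c.i, c.j] for c in contacts], dtype=int).reshape(-1, 2)
    con_r0 = np.asarray([c.r0 for c in contacts])
    con_class = np.asarray([CLASS_CODE[c.contact_class] for c in contacts], dtype=int)
    # strengths resolved from params (class table), ligand already folded
    strength_of = {
        0: params.eps_shared, 1: params.eps_spec, 2: params.eps_spec,
        3: params.eps_spec, 4: params.eps_shared,
        5: params.eps_ligand * params.eps_shared,
    }
    con_eps = np.asarray([strength_of[c] for c in con_class])

    n = cg_o.n_beads
    excluded = set()
    for i, j in bonded.bond_ij:
        excluded.add((min(i, j), max(i, j)))
    for ijk in bonded.angle_ijk:
        for a in range(3):
            for b in range(a + 1, 3):
                excluded.add((min(ijk[a], ijk[b]), max(ijk[a], ijk[b])))
    for ijkl in bonded.dihedral_ijkl:
        for a in range(4):
            for b in range(a + 1, 4):
                excluded.add((min(ijkl[a], ijkl[b]), max(ijkl[a], ijkl[b])))
    contact_pairs = {(min(i, j), max(i, j)) for i, j in con_ij}

    is_sc = cg_o.kind == "SC"
    rep_pairs = []
    rep_sigma = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded or (i, j) in contact_pairs:
                continue
            rep_pairs.append((i, j))
            rep_sigma.append(params.sigma_sc if (is_sc[i] or is_sc[j]) else params.sigma_ca)
    rep_ij = np.asarray(rep_pairs, dtype=int).reshape(-1, 2)
    rep_sigma = np.asarray(rep_sigma)

    charge = cg_o.charge
    chg_pairs, chg_qq = [], []
    charged = np.where(charge != 0)[0]
    nonelec = excluded
    for a_i in range(len(charged)):
        for b_i in range(a_i + 1, len(charged)):
            i, j = int(charged[a_i]), int(charged[b_i])
            if (i, j) in nonelec:
                continue
            chg_pairs.append((i, j))
            chg_qq.append(charge[i] * charge[j])
    chg_ij = np.asarray(chg_pairs, dtype=int).reshape(-1, 2)
    chg_qq = np.asarray(chg_qq)

    topo = Topology(
        cg=cg_o, bonded=bonded, mixed_map=mixed_map, params=params,
        hinge_residues=hinge_residues,
        con_ij=con_ij, con_r0=con_r0, con_eps=con_eps, con_class=con_class,
        rep_ij=rep_ij, rep_sigma=rep_sigma, chg_ij=chg_ij, chg_qq=chg_qq,
    )
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# JSON serialization (all lengths Å, energies in reduced units)

def topology_to_json(topo: Topology, path) -> None:
    b = topo.bonded
    doc = {
        "units": {"length": "angstrom", "energy": "reduced", "charge": "e"},
        "params": asdict(topo.params),
        "hinge_residues": sorted(topo.hinge_residues),
        "cg": {
            "kind": topo.cg.kind.tolist(),
            "res_index": topo.cg.res_index.tolist(),
            "res_name": topo.cg.res_name.tolist(),
            "coords": topo.cg.coords.tolist(),
            "mass": topo.cg.mass.tolist(),
            "charge": topo.cg.charge.tolist(),
        },
        "bonded": {
            "bond_ij": b.bond_ij.tolist(), "bond_r0": b.bond_r0.tolist(),
            "bond_k": b.bond_k.tolist(),
            "angle_ijk": b.angle_ijk.tolist(), "angle_t0": b.angle_t0.tolist(),
            "angle_k": b.angle_k.tolist(), "angle_hinge": b.angle_hinge.tolist(),
            "dihedral_ijkl": b.dihedral_ijkl.tolist(),
            "dihedral_phi0": b.dihedral_phi0.tolist(),
            "dihedral_k1": b.dihedral_k1.tolist(),
            "dihedral_k3": b.dihedral_k3.tolist(),
            "dihedral_hinge": b.dihedral_hinge.tolist(),
        },
        "contacts": {
            "ij": topo.con_ij.tolist(), "r0": topo.con_r0.tolist(),
            "eps": topo.con_eps.tolist(), "class": topo.con_class.tolist(),
            "res_ij": [[c.res_i, c.res_j] for c in topo.mixed_map.contacts],
        },
        "repulsion": {"ij": topo.rep_ij.tolist(), "sigma": topo.rep_sigma.tolist()},
        "electrostatics": {"ij": topo.chg_ij.tolist(), "qq": topo.chg_qq.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def topology_from_json(path) -> Topology:
    with open(path) as fh:
        doc = json.load(fh)
    cgd = doc["cg"]
    cg = CGStructure(
        kind=np.asarray(cgd["kind"], dtype="U2"),
        res_index=np.asarray(cgd["res_index"], dtype=int),
        res_name=np.asarray(cgd["res_name"], dtype="U5"),
        coords=np.asarray(cgd["coords"], dtype=float),
        mass=np.asarray(cgd["mass"], dtype=float),
        charge=np.asarray(cgd["charge"], dtype=float),
    )
    bd = doc["bonded"]
    bonded = BondedTerms(
        bond_ij=np.asarray(bd["bond_ij"], dtype=int).reshape(-1, 2),
        bond_r0=np.asarray(bd["bond_r0"]),
        bond_k=np.asarray(bd["bond_k"]),
        angle_ijk=np.asarray(bd["angle_ijk"], dtype=int).reshape(-1, 3),
        angle_t0=np.asarray(bd["angle_t0"]),
        angle_k=np.asarray(bd["angle_k"]),
        angle_hinge=np.asarray(bd["angle_hinge"], dtype=bool),
        dihedral_ijkl=np.asarray(bd["dihedral_ijkl"], dtype=int).reshape(-1, 4),
        dihedral_phi0=np.asarray(bd["dihedral_phi0"]),
        dihedral_k1=np.asarray(bd["dihedral_k1"]),
        dihedral_k3=np.asarray(bd["dihedral_k3"]),
        dihedral_hinge=np.asarray(bd["dihedral_hinge"], dtype=bool),
    )
    cd = doc["contacts"]
    con_ij = np.asarray(cd["ij"], dtype=int).reshape(-1, 2)
    con_r0 = np.asarray(cd["r0"])
    con_eps = np.asarray(cd["eps"])
    con_class = np.asarray(cd["class"], dtype=int)
    res_ij = cd["res_ij"]
    contacts = [
        Contact(int(ij[0]), int(ij[1]), int(rij[0]), int(rij[1]), float(r0),
                CODE_CLASS[int(cc)], float(eps))
        for ij, rij, r0, eps, cc in zip(con_ij, res_ij, con_r0, con_eps, con_class)
    ]
    params = ModelParams(**doc["params"])
    mixed = MixedContactMap(
        contacts=[c for c in contacts if c.contact_class is not ContactClass.LIGAND]
    )
    topo = Topology(
        cg=cg, bonded=bonded, mixed_map=mixed, params=params,
        hinge_residues=set(doc["hinge_residues"]),
        con_ij=con_ij, con_r0=con_r0, con_eps=con_eps, con_class=con_class,
        rep_ij=np.asarray(doc["repulsion"]["ij"], dtype=int).reshape(-1, 2),
        rep_sigma=np.asarray(doc["repulsion"]["sigma"]),
        chg_ij=np.asarray(doc["electrostatics"]["ij"], dtype=int).reshape(-1, 2),
        chg_qq=np.asarray(doc["electrostatics"]["qq"]),
    )
    topo.validate()
    return topo
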