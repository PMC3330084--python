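"""Native contact maps and their mixing into the triple-basin map.

A native contact is a residue pair with any heavy-atom pair within the cutoff
(default 4.5 Å, |Δres| ≥ 4).  Contacts found in all three reference states are
*core* contacts; contacts unique to one state are *state-specific*; contacts
shared by exactly two states are kept in a separate PAIR_SHARED class at the
shared strength so nothing is silently discarded.  Ligand-mediated contacts
are inter-domain pairs whose residues both touch the bound ligand in the
holo-closed structure; their strength scales with the implicit ligand
concentration ε_L.

Following the allosteric-protein observation that state-specific contacts are
systematically weaker than shared ones, the default strengths are
ε_shared = 1.0 and ε_spec = 0.4 (the model is well-behaved for ratios in
[0.4, 0.6]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .structures import AtomicModel, CGStructure, DomainMap, coarse_grain


class ContactClass(str, Enum):
    CORE = "CORE"
    O_SPEC = "O_SPEC"
    A_SPEC = "A_SPEC"
    H_SPEC = "H_SPEC"
    PAIR_SHARED = "PAIR_SHARED"
    LIGAND = "LIGAND"


SPEC_CLASS = {"O": ContactClass.O_SPEC, "A": ContactClass.A_SPEC, "H": ContactClass.H_SPEC}


@dataclass(frozen=True)
class ResiduePairContact:
    """A native contact at residue-pair resolution within one reference state."""

    res_i: int
    res_j: int
    sidechain_driven: bool  # side-chain atoms of both residues within cutoff
    d_caca: float           # CA-bead distance in this state, Å
    d_scsc: float | None    # SC-bead distance, if both residues carry SC beads


@dataclass
class Contact:
    """A bead-pair contact of the mixed map."""

    i: int                  # global bead ids (shared across conformers)
    j: int
    res_i: int
    res_j: int
    r0: float               # native distance, Å
    contact_class: ContactClass
    strength: float         # ε, dimensionless energy

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("native distance must be positive")
        if self.strength < 0:
            raise ValueError("contact strength must be non-negative")


@dataclass
class MixedContactMap:
    """Union of native contacts from all reference states, class-labelled."""

    contacts: list[Contact]
    strengths: dict[str, float] = field(default_factory=dict)

    def by_class(self, cls: ContactClass) -> list[Contact]:
        return [c for c in self.contacts if c.contact_class is cls]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.contacts:
            out[c.contact_class.value] = out.get(c.contact_class.value, 0) + 1
        return out

    def validate(self) -> None:
        seen: set[tuple[int, int]] = set()
        for c in self.contacts:
            key = (min(c.res_i, c.res_j), max(c.res_i, c.res_j))
            if key in seen:
                raise ValueError(f"residue pair {key} appears in two classes")
            seen.add(key)


def compute_contact_map(
    model: AtomicModel,
    cutoff: float = 4.5,
    min_seq_sep: int = 4,
    cg: CGStructure | None = None,
) -> dict[tuple[int, int], ResiduePairContact]:
    """All-heavy-atom native contacts of one conformer.

    Residue pairs with any heavy-atom pair within ``cutoff`` and
    ``|Δres| ≥ min_seq_sep`` become contacts; bead distances are recorded for
    both bead-pair realizations so the classifier can pick either.
    """
    if cg is None:
        cg = coarse_grain(model)
    heavy = model.heavy_mask()
    coords = model.coords[heavy]
    resid = model.res_index[heavy]
    is_backbone = np.isin(model.atom_name[heavy], ["N", "CA", "C", "O", "OXT"])

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: dict[tuple[int, int], ResiduePairContact] = {}
    if len(pairs) == 0:
        return out

    ri, rj = resid[pairs[:, 0]], resid[pairs[:, 1]]
    lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
    keep = (hi - lo) >= min_seq_sep
    sc_pair = ~is_backbone[pairs[:, 0]] & ~is_backbone[pairs[:, 1]]

    sidechain_driven: dict[tuple[int, int], bool] = {}
    for (a, b, sc) in zip(lo[keep], hi[keep], sc_pair[keep]):
        key = (int(a), int(b))
        sidechain_driven[key] = sidechain_driven.get(key, False) or bool(sc)

    ca_pos = {int(r): cg.coords[cg.bead_index(int(r), "CA")] for r in np.unique(resid)}
    for (a, b), sc_driven in sidechain_driven.items():
        d_caca = float(np.linalg.norm(ca_pos[a] - ca_pos[b]))
        sca, scb = cg.sc_index(a), cg.sc_index(b)
        d_scsc = (
            float(np.linalg.norm(cg.coords[sca] - cg.coords[scb]))
            if sca is not None and scb is not None
            else None
        )
        out[(a, b)] = ResiduePairContact(a, b, sc_driven, d_caca, d_scsc)
    return out


def _bead_pair(cg: CGStructure, rc: ResiduePairContact) -> tuple[int, int, bool]:
    """Bead ids for a residue-pair contact: SC-SC when side chains drive it."""
    use_sc = rc.sidechain_driven and rc.d_scsc is not None
    if use_sc:
        return cg.bead_index(rc.res_i, "SC"), cg.bead_index(rc.res_j, "SC"), True
    return cg.bead_index(rc.res_i, "CA"), cg.bead_index(rc.res_j, "CA"), False


def classify_contacts(
    map_o: dict[tuple[int, int], ResiduePairContact],
    map_a: dict[tuple[int, int], ResiduePairContact],
    map_h: dict[tuple[int, int], ResiduePairContact],
    cg: CGStructure,
    eps_shared: float = 1.0,
    eps_spec: float = 0.4,
) -> MixedContactMap:
    """Mix three per-state contact maps into the class-labelled union.

    Present in all three states → CORE at ε_shared with r0 averaged over the
    three states; in exactly one → that state's SPEC class at ε_spec with that
    state's r0; in exactly two → PAIR_SHARED at ε_shared, r0 averaged over the
    two.  Classes are disjoint by construction.
    """
    ratio = eps_spec / eps_shared
    if not (0.4 - 1e-12 <= ratio <= 0.6 + 1e-12):
        warnings.warn(
            f"eps_spec/eps_shared = {ratio:.3g} outside the validated band [0.4, 0.6]"
        )
    maps = {"O": map_o, "A": map_a, "H": map_h}
    all_keys = set(map_o) | set(map_a) | set(map_h)
    contacts: list[Contact] = []
    for key in sorted(all_keys):
        present = [s for s in ("O", "A", "H") if key in maps[s]]
        members = [maps[s][key] for s in present]
        # bead-kind choice: SC-SC only if available and side-chain driven in
        # the first contributing state (state order O, A, H)
        i, j, use_sc = _bead_pair(cg, members[0])
        dists = [(m.d_scsc if use_sc else m.d_caca) for m in members]
        if any(d is None for d in dists):  # pragma: no cover - d_scsc availability is uniform
            i, j = cg.bead_index(key[0], "CA"), cg.bead_index(key[1], "CA")
            dists = [m.d_caca for m in members]
        if len(present) == 3:
            cls, eps, r0 = ContactClass.CORE, eps_shared, float(np.mean(dists))
        elif len(present) == 1:
            cls, eps, r0 = SPEC_CLASS[present[0]], eps_spec, float(dists[0])
        else:
            cls, eps, r0 = ContactClass.PAIR_SHARED, eps_shared, float(np.mean(dists))
        contacts.append(Contact(i, j, key[0], key[1], r0, cls, eps))
    cmap = MixedContactMap(
        contacts=contacts,
        strengths={
            "CORE": eps_shared,
            "PAIR_SHARED": eps_shared,
            "O_SPEC": eps_spec,
            "A_SPEC": eps_spec,
            "H_SPEC": eps_spec,
        },
    )
    cmap.validate()
    return cmap


def ligand_mediated_contacts(
    holo: AtomicModel,
    domains: DomainMap,
    cutoff: float = 4.5,
    cg: CGStructure | None = None,
    ntd: str = "NTD",
    ctd: str = "CTD",
) -> list[Contact]:
    """Inter-domain contacts mediated by the bound ligand in the holo state.

    Residue pairs with one member in each domain where both residues have a
    heavy atom within ``cutoff`` of any ligand atom; r0 from the holo
    geometry.  Contact strength is filled in later as ε_L · ε_shared by the
    topology builder (so these entries carry strength 1.0 here).
    """
    if len(holo.ligand_coords) == 0:
        warnings.warn("holo model has no ligand atoms; no ligand-mediated contacts")
        return []
    if cg is None:
        cg = coarse_grain(holo)
    heavy = holo.heavy_mask()
    lig_heavy = holo.ligand_coords[holo.ligand_element != "H"]
    tree = cKDTree(lig_heavy)
    dists, _ = tree.query(holo.coords[heavy])
    touching = set(int(r) for r in np.unique(holo.res_index[heavy][dists <= cutoff]))

    ntd_res = domains.residues(ntd) & touching
    ctd_res = domains.residues(ctd) & touching
    out: list[Contact] = []
    for a in sorted(ntd_res):
        for b in sorted(ctd_res):
            ia = cg.sc_index(a)
            ib = cg.sc_index(b)
            if ia is None:
                ia = cg.bead_index(a, "CA")
            if ib is None:
                ib = cg.bead_index(b, "CA")
            r0 = float(np.linalg.norm(cg.coords[ia] - cg.coords[ib]))
            out.append(Contact(ia, ib, a, b, r0, ContactClass.LIGAND, 1.0))
    return out
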