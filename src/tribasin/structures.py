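"""Atomic structures, two-bead coarse-graining, charges, and superposition.

The in-memory containers are deliberately light: :class:`AtomicModel` holds an
all-atom conformer (protein atoms plus any ligand HETATM atoms kept aside) and
:class:`CGStructure` the mixed two-bead representation used by the model — one
CA bead per residue and, for every non-glycine residue under the default
scheme, one side-chain (SC) bead at the geometric centroid of the side-chain
heavy atoms.  Charges live on the SC beads of Lys/Arg (+1e) and Asp/Glu (−1e);
histidine is neutral at the modelled pH unless requested otherwise.

PDB reading/writing goes through biotite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import apply_transform, kabsch

logger = logging.getLogger(__name__)

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
POSITIVE_RESIDUES = {"LYS", "ARG"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}
WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomicModel:
    """One conformer: ordered protein atoms with ligand atoms kept separately."""

    res_index: np.ndarray       # (n_atoms,) 1-based author numbering
    res_name: np.ndarray        # (n_atoms,) 3-letter codes
    atom_name: np.ndarray       # (n_atoms,)
    element: np.ndarray         # (n_atoms,)
    coords: np.ndarray          # (n_atoms, 3) Å
    chain_id: np.ndarray        # (n_atoms,)
    ligand_res_name: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    ligand_atom_name: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    ligand_element: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U2"))
    ligand_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def n_atoms(self) -> int:
        return len(self.res_index)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.res_index)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def residue_name(self, resid: int) -> str:
        mask = self.res_index == resid
        if not mask.any():
            raise KeyError(f"residue {resid} not in model")
        return str(self.res_name[mask][0])

    def atom_coords(self, resid: int, names: list[str] | None = None) -> np.ndarray:
        mask = self.res_index == resid
        if names is not None:
            mask &= np.isin(self.atom_name, names)
        return self.coords[mask]

    def ca_coords(self) -> np.ndarray:
        """CA positions ordered by residue index."""
        out = []
        for resid in self.residue_ids:
            mask = (self.res_index == resid) & (self.atom_name == "CA")
            out.append(self.coords[mask][0])
        return np.asarray(out)

    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def validate(self) -> None:
        for resid in self.residue_ids:
            mask = self.res_index == resid
            if "CA" not in self.atom_name[mask]:
                name = self.res_name[mask][0]
                raise ValueError(f"residue {name}{resid} has no CA atom")


@dataclass
class CGStructure:
    """Mixed two-bead coarse-grained conformer."""

    kind: np.ndarray       # (n_beads,) "CA" | "SC"
    res_index: np.ndarray  # parent residue, 1-based
    res_name: np.ndarray
    coords: np.ndarray     # (n_beads, 3) Å
    mass: np.ndarray       # reduced units
    charge: np.ndarray     # elementary charges

    @property
    def n_beads(self) -> int:
        return len(self.kind)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.res_index))

    @property
    def ca_indices(self) -> np.ndarray:
        """Bead indices of CA beads ordered by residue."""
        idx = np.where(self.kind == "CA")[0]
        return idx[np.argsort(self.res_index[idx], kind="stable")]

    def sc_index(self, resid: int) -> int | None:
        hits = np.where((self.kind == "SC") & (self.res_index == resid))[0]
        return int(hits[0]) if len(hits) else None

    def bead_index(self, resid: int, kind: str) -> int:
        hits = np.where((self.kind == kind) & (self.res_index == resid))[0]
        if not len(hits):
            raise KeyError(f"no {kind} bead for residue {resid}")
        return int(hits[0])

    def copy_with_coords(self, coords: np.ndarray) -> "CGStructure":
        return CGStructure(
            kind=self.kind, res_index=self.res_index, res_name=self.res_name,
            coords=np.array(coords, dtype=float), mass=self.mass, charge=self.charge,
        )

    def validate(self) -> None:
        for resid in np.unique(self.res_index):
            kinds = self.kind[self.res_index == resid]
            if np.sum(kinds == "CA") != 1:
                raise ValueError(f"residue {resid} must have exactly one CA bead")
            if np.sum(kinds == "SC") > 1:
                raise ValueError(f"residue {resid} has more than one SC bead")
            name = self.res_name[self.res_index == resid][0]
            if name == "GLY" and np.any(kinds == "SC"):
                raise ValueError(f"glycine {resid} cannot carry an SC bead")


@dataclass
class DomainMap:
    """Named residue ranges (each a list of inclusive (lo, hi) tuples)."""

    regions: dict[str, list[tuple[int, int]]]

    def residues(self, name: str) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.regions[name]:
            out.update(range(lo, hi + 1))
        return out

    def region_of(self, resid: int, precedence: tuple[str, ...] = ()) -> str | None:
        """Region membership; names in ``precedence`` win on overlap."""
        hits = [n for n in self.regions if resid in self.residues(n)]
        for name in precedence:
            if name in hits:
                return name
        return hits[0] if hits else None

    def validate(self, n_residues: int) -> None:
        for name, ranges in self.regions.items():
            for lo, hi in ranges:
                if lo < 1 or hi > n_residues or lo > hi:
                    raise ValueError(f"region {name}: range ({lo},{hi}) outside [1,{n_residues}]")


#: MBP domain architecture in the protein's author numbering: two globular
#: domains (NTD/CTD) bridged by two linkers; the "balancing loop" (167-173)
#: and "balancing linker" (=linker2, 310-330) form the interface proposed to
#: switch domain closure.
MBP_DOMAINS = DomainMap(
    regions={
        "NTD": [(1, 94), (259, 310)],
        "CTD": [(113, 250), (331, 366)],
        "linker1": [(102, 112), (250, 260)],
        "linker2": [(310, 330)],
        "balancing_loop": [(167, 173)],
        "balancing_linker": [(310, 330)],
    }
)


def read_pdb(path, insertion_codes: str = "reject") -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    Alternate locations are resolved to the highest-occupancy conformer.
    HETATM records other than water are kept aside as ligand atoms.

    Parameters
    ----------
    path : str or Path
    insertion_codes : {"reject", "renumber"}
        "reject" raises on any insertion code; "renumber" renumbers all
        residues sequentially from 1.
    """
    import biotite.structure.io.pdb as pdb

    pdbfile = pdb.PDBFile.read(str(path))
    try:
        atoms = pdbfile.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"unreadable PDB record in {path}: {exc}") from exc

    ins = atoms.ins_code
    if np.any(ins != ""):
        if insertion_codes == "reject":
            bad = np.where(ins != "")[0][0]
            raise ValueError(
                f"insertion code '{ins[bad]}' at residue {atoms.res_id[bad]}; "
                "pass insertion_codes='renumber' to accept"
            )

    is_water = np.isin(atoms.res_name, list(WATER_NAMES))
    is_protein = np.isin(atoms.res_name, list(AMINO_ACIDS)) & ~atoms.hetero
    # hetero-flagged standard residues (e.g. MSE) stay protein
    is_protein |= np.isin(atoms.res_name, list(AMINO_ACIDS)) & atoms.hetero
    is_ligand = ~is_protein & ~is_water

    prot = atoms[is_protein]
    lig = atoms[is_ligand]

    res_index = prot.res_id.astype(int)
    if insertion_codes == "renumber" and np.any(atoms.ins_code != ""):
        # sequential renumber over (res_id, ins_code) blocks
        keys = list(zip(prot.chain_id, prot.res_id, prot.ins_code))
        seen: dict[tuple, int] = {}
        new = np.empty(len(keys), dtype=int)
        for i, k in enumerate(keys):
            if k not in seen:
                seen[k] = len(seen) + 1
            new[i] = seen[k]
        res_index = new

    model = AtomicModel(
        res_index=res_index,
        res_name=prot.res_name.astype("U5"),
        atom_name=prot.atom_name.astype("U5"),
        element=prot.element.astype("U2"),
        coords=np.asarray(prot.coord, dtype=float),
        chain_id=prot.chain_id.astype("U4"),
        ligand_res_name=lig.res_name.astype("U5"),
        ligand_atom_name=lig.atom_name.astype("U5"),
        ligand_element=lig.element.astype("U2"),
        ligand_coords=np.asarray(lig.coord, dtype=float),
    )
    model.validate()
    return model


def write_pdb(model: AtomicModel, path) -> None:
    """Write an :class:`AtomicModel` (protein + ligand atoms) to PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = model.n_atoms + len(model.ligand_coords)
    arr = struc.AtomArray(n)
    arr.coord[: model.n_atoms] = model.coords
    arr.res_id[: model.n_atoms] = model.res_index
    arr.res_name[: model.n_atoms] = model.res_name
    arr.atom_name[: model.n_atoms] = model.atom_name
    arr.element[: model.n_atoms] = model.element
    arr.chain_id[: model.n_atoms] = model.chain_id
    arr.hetero[: model.n_atoms] = False
    if len(model.ligand_coords):
        arr.coord[model.n_atoms:] = model.ligand_coords
        arr.res_id[model.n_atoms:] = (int(model.res_index.max()) + 1
                                      if model.n_atoms else 1)
        arr.res_name[model.n_atoms:] = model.ligand_res_name
        arr.atom_name[model.n_atoms:] = model.ligand_atom_name
        arr.element[model.n_atoms:] = model.ligand_element
        arr.chain_id[model.n_atoms:] = "L"
        arr.hetero[model.n_atoms:] = True
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def write_cg_pdb(cg: CGStructure, path) -> None:
    """Write a CG structure as pseudo-atoms (CA beads as CA, SC beads as CB)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = struc.AtomArray(cg.n_beads)
    arr.coord[:] = cg.coords
    arr.res_id[:] = cg.res_index
    arr.res_name[:] = cg.res_name
    arr.atom_name[:] = np.where(cg.kind == "CA", "CA", "CB")
    arr.element[:] = "C"
    arr.chain_id[:] = "A"
    arr.hetero[:] = False
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def coarse_grain(model: AtomicModel, two_bead_residues: set[str] | None = None) -> CGStructure:
    """Coarse-grain to the mixed two-bead representation.

    CA bead at the Cα position for every residue; SC bead at the geometric
    centroid of side-chain heavy atoms for every residue whose type is in
    ``two_bead_residues`` (default: all types except glycine).
    """
    model.validate()
    kinds, resids, names, coords = [], [], [], []
    for resid in model.residue_ids:
        mask = model.res_index == resid
        rname = str(model.res_name[mask][0])
        ca = model.coords[mask & (model.atom_name == "CA")][0]
        kinds.append("CA")
        resids.append(int(resid))
        names.append(rname)
        coords.append(ca)
        wants_sc = (rname != "GLY") if two_bead_residues is None else (rname in two_bead_residues)
        if wants_sc and rname != "GLY":
            sc_mask = (
                mask
                & ~np.isin(model.atom_name, list(BACKBONE_ATOMS))
                & (model.element != "H")
            )
            if not sc_mask.any():
                warnings.warn(
                    f"residue {rname}{resid}: no side-chain heavy atoms, SC bead skipped"
                )
                continue
            expected = _SIDECHAIN_HEAVY_COUNT.get(rname)
            if expected is not None and sc_mask.sum() < expected:
                logger.warning(
                    "residue %s%d: %d/%d side-chain heavy atoms present; "
                    "SC bead from available atoms", rname, resid, sc_mask.sum(), expected
                )
            kinds.append("SC")
            resids.append(int(resid))
            names.append(rname)
            coords.append(model.coords[sc_mask].mean(axis=0))
    cg = CGStructure(
        kind=np.asarray(kinds, dtype="U2"),
        res_index=np.asarray(resids, dtype=int),
        res_name=np.asarray(names, dtype="U5"),
        coords=np.asarray(coords, dtype=float),
        mass=np.ones(len(kinds)),
        charge=np.zeros(len(kinds)),
    )
    cg.validate()
    return cg


_SIDECHAIN_HEAVY_COUNT = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7, "PRO": 3,
    "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}


def assign_charges(cg: CGStructure, his_charge: float = 0.0) -> CGStructure:
    """Return a copy with ±1e charges on SC beads of charged residue types.

    Lys/Arg → +1e, Asp/Glu → −1e; His gets ``his_charge`` (default neutral).
    A charged residue without an SC bead is an error: the charge would have
    nowhere to live.
    """
    charge = np.zeros(cg.n_beads)
    charged = POSITIVE_RESIDUES | NEGATIVE_RESIDUES | ({"HIS"} if his_charge else set())
    for resid in np.unique(cg.res_index):
        rname = str(cg.res_name[cg.res_index == resid][0])
        if rname not in charged:
            continue
        sc = cg.sc_index(int(resid))
        if sc is None:
            raise ValueError(f"charged residue {rname}{resid} has no SC bead")
        if rname in POSITIVE_RESIDUES:
            charge[sc] = 1.0
        elif rname in NEGATIVE_RESIDUES:
            charge[sc] = -1.0
        else:
            charge[sc] = his_charge
    return CGStructure(
        kind=cg.kind, res_index=cg.res_index, res_name=cg.res_name,
        coords=cg.coords, mass=cg.mass, charge=charge,
    )


def _selection_coords(obj, selection) -> np.ndarray:
    """CA coordinates of the selected residues (sorted by residue index)."""
    sel = sorted(selection) if selection is not None else None
    if isinstance(obj, AtomicModel):
        resids = obj.residue_ids if sel is None else np.asarray(sel)
        return np.asarray(
            [obj.coords[(obj.res_index == r) & (obj.atom_name == "CA")][0] for r in resids]
        )
    if isinstance(obj, CGStructure):
        ca = obj.ca_indices
        if sel is None:
            return obj.coords[ca]
        resid_of = obj.res_index[ca]
        keep = np.isin(resid_of, np.asarray(sel))
        return obj.coords[ca[keep]]
    return np.asarray(obj, dtype=float)


def superpose(mobile, reference, selection=None):
    """Kabsch superposition of ``mobile`` onto ``reference`` over CA atoms.

    ``selection`` is a set of residue indices (default: all shared residues).
    Returns ``((R, t), rmsd)``; apply with ``coords @ R.T + t``.
    """
    m = _selection_coords(mobile, selection)
    r = _selection_coords(reference, selection)
    R, t, rmsd = kabsch(m, r)
    return (R, t), rmsd


def sidechain_displacement(
    a: AtomicModel,
    b: AtomicModel,
    residue: int,
    atom_names: list[str],
    fit_selection: set[int],
) -> float:
    """Displacement (Å) of a side-chain atom group between two conformers.

    ``b`` is superposed onto ``a`` over the CA atoms of ``fit_selection``;
    the result is the distance between the centroids of ``atom_names`` of
    ``residue`` in the two (now aligned) models.  Used e.g. for the E107
    carboxylate-oxygen shift between the open and closed states of MBP.
    """
    for model, tag in ((a, "a"), (b, "b")):
        got = model.atom_coords(residue, atom_names)
        if len(got) != len(atom_names):
            present = set(model.atom_name[model.res_index == residue])
            missing = [n for n in atom_names if n not in present]
            raise ValueError(f"model {tag}, residue {residue}: missing atoms {missing}")
    (R, t), _ = superpose(b, a, fit_selection)
    ca = a.atom_coords(residue, atom_names).mean(axis=0)
    cb_raw = b.atom_coords(residue, atom_names).mean(axis=0)
    cb = apply_transform(cb_raw[None, :], R, t)[0]
    return float(np.linalg.norm(ca - cb))
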