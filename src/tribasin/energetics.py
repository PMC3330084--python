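"""Hamiltonian evaluation: per-term energies and analytic forces.

The total energy splits into backbone (bond/angle/dihedral), non-bonded
(single-minimum contact attraction + r⁻¹² excluded volume) and Debye-Hückel
electrostatic terms.  The triple-basin character comes from the union of
class-labelled contacts in the mixed map, not from multi-welled pair
potentials.

Reduced units throughout.  The Coulomb prefactor maps the simulation
temperature T = 0.5 to 300 K, i.e. one reduced energy unit ≈ 2 k_B·300 K
≈ 1.192 kcal/mol, so B = 332.064/1.192 ≈ 278.5 ε·Å·e⁻².  The screening
length follows λ_D = 3.04·sqrt(ε_r/80)/sqrt(I[M]) Å (λ_D → ∞ as I → 0);
an optional finite-ion-size factor exp(κa)/(1+κa) can be enabled.
Electrostatics are cut off at 3 λ_D with a shift to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _kernels
from .topology import Topology

#: kcal·mol⁻¹·Å·e⁻² Coulomb constant over the reduced energy unit (see module docstring)
COULOMB_PREFACTOR = 332.0637 / (0.0019872041 * 300.0 / 0.5)
#: λ_D in Å at ε_r = 80, 300 K equals 3.04/sqrt(I[M])
_LAMBDA_80 = 3.04


@dataclass
class DHParams:
    """Debye-Hückel parameters; the screening length is derived from I."""

    dielectric: float = 80.0
    ionic_strength: float = 0.10     # mol/L
    ion_size: float = 0.0            # Å; > 0 enables the exp(κa)/(1+κa) factor
    cutoff_lambdas: float = 3.0      # electrostatic cutoff in units of λ_D

    def __post_init__(self):
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")

    @property
    def lambda_d(self) -> float:
        """Debye screening length, Å (inf at zero ionic strength)."""
        if self.ionic_strength == 0:
            return np.inf
        return _LAMBDA_80 * np.sqrt(self.dielectric / 80.0) / np.sqrt(self.ionic_strength)

    @property
    def kappa(self) -> float:
        lam = self.lambda_d
        return 0.0 if np.isinf(lam) else 1.0 / lam

    @property
    def prefactor(self) -> float:
        """Effective B/ε_r (reduced ε·Å·e⁻²), incl. optional ion-size factor."""
        b = COULOMB_PREFACTOR / self.dielectric
        if self.ion_size > 0 and self.kappa > 0:
            ka = self.kappa * self.ion_size
            b *= np.exp(ka) / (1.0 + ka)
        return b

    @property
    def r_cut(self) -> float:
        """Cutoff radius, Å; 0 disables the cutoff (I = 0 limit)."""
        lam = self.lambda_d
        return 0.0 if np.isinf(lam) else self.cutoff_lambdas * lam

    def pair_energy(self, q1: float, q2: float, r: float) -> float:
        """Unshifted closed form B·q1·q2·exp(−r/λ_D)/(ε_r·r)."""
        return self.prefactor * q1 * q2 * np.exp(-self.kappa * r) / r


@dataclass
class EnergyReport:
    """Per-term energies (reduced units) and forces (−∇U) per bead."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    contact: float = 0.0
    repulsion: float = 0.0
    electrostatic: float = 0.0
    forces: np.ndarray | None = None

    @property
    def bonded(self) -> float:
        return self.bond + self.angle + self.dihedral

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.contact
                + self.repulsion + self.electrostatic)

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond, "angle": self.angle, "dihedral": self.dihedral,
            "contact": self.contact, "repulsion": self.repulsion,
            "electrostatic": self.electrostatic, "total": self.total,
        }


class ForceField(NamedTuple):
    """Plain-array view of a topology, as consumed by the numba kernels."""

    bond_ij: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    ang_ijk: np.ndarray
    ang_t0: np.ndarray
    ang_k: np.ndarray
    dih_ijkl: np.ndarray
    dih_phi0: np.ndarray
    dih_k1: np.ndarray
    dih_k3: np.ndarray
    con_ij: np.ndarray
    con_r0: np.ndarray
    con_eps: np.ndarray
    con_form: int
    gauss_width: float
    rep_ij: np.ndarray
    rep_sigma: np.ndarray
    eps_rep: float
    chg_ij: np.ndarray
    chg_qq: np.ndarray
    dh_pref: float
    dh_kappa: float
    dh_rcut: float
    dh_ushift: float
    masses: np.ndarray


GAUSS_WIDTH_DEFAULT = 0.6  # Å, width of the optional Gaussian contact well


def dh_params_of(topo: Topology, ion_size: float = 0.0) -> DHParams:
    return DHParams(
        dielectric=topo.params.dielectric,
        ionic_strength=topo.params.ionic_strength,
        ion_size=ion_size,
    )


def force_field(topo: Topology, dh: DHParams | None = None) -> ForceField:
    """Pack a topology into the kernel-ready array bundle."""
    if dh is None:
        dh = dh_params_of(topo)
    b = topo.bonded
    kappa = dh.kappa
    r_cut = dh.r_cut
    # per-unit-qq energy at the cutoff; the kernel multiplies by qq
    u_shift = dh.prefactor * np.exp(-kappa * r_cut) / r_cut if r_cut > 0 else 0.0
    return ForceField(
        bond_ij=np.ascontiguousarray(b.bond_ij, dtype=np.int64),
        bond_r0=np.ascontiguousarray(b.bond_r0, dtype=np.float64),
        bond_k=np.ascontiguousarray(b.bond_k, dtype=np.float64),
        ang_ijk=np.ascontiguousarray(b.angle_ijk, dtype=np.int64),
        ang_t0=np.ascontiguousarray(b.angle_t0, dtype=np.float64),
        ang_k=np.ascontiguousarray(b.angle_k, dtype=np.float64),
        dih_ijkl=np.ascontiguousarray(b.dihedral_ijkl, dtype=np.int64),
        dih_phi0=np.ascontiguousarray(b.dihedral_phi0, dtype=np.float64),
        dih_k1=np.ascontiguousarray(b.dihedral_k1, dtype=np.float64),
        dih_k3=np.ascontiguousarray(b.dihedral_k3, dtype=np.float64),
        con_ij=np.ascontiguousarray(topo.con_ij, dtype=np.int64),
        con_r0=np.ascontiguousarray(topo.con_r0, dtype=np.float64),
        con_eps=np.ascontiguousarray(topo.con_eps, dtype=np.float64),
        con_form=0 if topo.params.contact_form == "lj1206" else 1,
        gauss_width=GAUSS_WIDTH_DEFAULT,
        rep_ij=np.ascontiguousarray(topo.rep_ij, dtype=np.int64),
        rep_sigma=np.ascontiguousarray(topo.rep_sigma, dtype=np.float64),
        eps_rep=float(topo.params.eps_repulsion),
        chg_ij=np.ascontiguousarray(topo.chg_ij, dtype=np.int64),
        chg_qq=np.ascontiguousarray(topo.chg_qq, dtype=np.float64),
        dh_pref=float(dh.prefactor),
        dh_kappa=float(kappa),
        dh_rcut=float(r_cut),
        dh_ushift=float(u_shift),
        masses=np.ascontiguousarray(topo.cg.mass, dtype=np.float64),
    )


def _check_coords(topo: Topology, coords: np.ndarray) -> np.ndarray:
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (topo.n_beads, 3):
        raise ValueError(f"coords shape {coords.shape} != ({topo.n_beads}, 3)")
    if np.isnan(coords).any():
        raise ValueError("NaN coordinates")
    return coords


def bonded_energy(topo: Topology, coords: np.ndarray, ff: ForceField | None = None) -> EnergyReport:
    coords = _check_coords(topo, coords)
    if ff is None:
        ff = force_field(topo)
    forces = np.zeros_like(coords)
    e_bond = _kernels.bond_energy_forces(coords, ff.bond_ij, ff.bond_r0, ff.bond_k, forces)
    e_ang = _kernels.angle_energy_forces(coords, ff.ang_ijk, ff.ang_t0, ff.ang_k, forces)
    e_dih = _kernels.dihedral_energy_forces(
        coords, ff.dih_ijkl, ff.dih_phi0, ff.dih_k1, ff.dih_k3, forces)
    return EnergyReport(bond=e_bond, angle=e_ang, dihedral=e_dih, forces=forces)


def contact_energy(topo: Topology, coords: np.ndarray, ff: ForceField | None = None) -> EnergyReport:
    coords = _check_coords(topo, coords)
    if ff is None:
        ff = force_field(topo)
    forces = np.zeros_like(coords)
    e = _kernels.contact_energy_forces(
        coords, ff.con_ij, ff.con_r0, ff.con_eps, ff.con_form, ff.gauss_width, forces)
    return EnergyReport(contact=e, forces=forces)


def repulsion_energy(topo: Topology, coords: np.ndarray, ff: ForceField | None = None) -> EnergyReport:
    coords = _check_coords(topo, coords)
    if ff is None:
        ff = force_field(topo)
    forces = np.zeros_like(coords)
    e, min_r = _kernels.repulsion_energy_forces(coords, ff.rep_ij, ff.rep_sigma, ff.eps_rep, forces)
    if len(ff.rep_ij) and min_r < 1e-6:
        raise ValueError(f"overlapping beads: minimum non-bonded distance {min_r:.2e} Å")
    return EnergyReport(repulsion=e, forces=forces)


def dh_energy(
    coords: np.ndarray,
    charges: np.ndarray | None = None,
    params: DHParams | None = None,
    pairs: np.ndarray | None = None,
    qq: np.ndarray | None = None,
) -> EnergyReport:
    """Debye-Hückel energy over charged pairs.

    Either pass ``charges`` (all distinct pairs of nonzero charges are used)
    or explicit ``pairs``/``qq`` arrays.
    """
    if params is None:
        params = DHParams()
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if pairs is None:
        if charges is None:
            raise ValueError("need charges or explicit pairs")
        idx = np.where(np.asarray(charges) != 0)[0]
        pairs = np.array(
            [(int(idx[a]), int(idx[b])) for a in range(len(idx)) for b in range(a + 1, len(idx))],
            dtype=np.int64,
        ).reshape(-1, 2)
        qq = np.array([charges[i] * charges[j] for i, j in pairs])
    forces = np.zeros_like(coords)
    r_cut = params.r_cut
    u_shift = params.prefactor * np.exp(-params.kappa * r_cut) / r_cut if r_cut > 0 else 0.0
    e = _kernels.dh_energy_forces(
        coords, np.ascontiguousarray(pairs, dtype=np.int64),
        np.ascontiguousarray(qq, dtype=np.float64),
        float(params.prefactor), float(params.kappa), float(r_cut), float(u_shift),
        forces,
    )
    return EnergyReport(electrostatic=e, forces=forces)


def total_energy(topo: Topology, coords: np.ndarray, ff: ForceField | None = None) -> EnergyReport:
    """Full Hamiltonian; forces are exact negative gradients of the total."""
    coords = _check_coords(topo, coords)
    if ff is None:
        ff = force_field(topo)
    rep_bond = bonded_energy(topo, coords, ff)
    rep_con = contact_energy(topo, coords, ff)
    rep_rep = repulsion_energy(topo, coords, ff)
    forces = np.zeros_like(coords)
    e_el = _kernels.dh_energy_forces(
        coords, ff.chg_ij, ff.chg_qq, ff.dh_pref, ff.dh_kappa, ff.dh_rcut, ff.dh_ushift,
        forces,
    )
    forces += rep_bond.forces + rep_con.forces + rep_rep.forces
    return EnergyReport(
        bond=rep_bond.bond, angle=rep_bond.angle, dihedral=rep_bond.dihedral,
        contact=rep_con.contact, repulsion=rep_rep.repulsion, electrostatic=e_el,
        forces=forces,
    )


def numerical_forces(topo: Topology, coords: np.ndarray, h: float = 2e-6) -> np.ndarray:
    """Central finite-difference gradient (independent check of the kernels)."""
    coords = np.array(coords, dtype=float)
    ff = force_field(topo)
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            coords[i, d] += h
            ep = total_energy(topo, coords, ff).total
            coords[i, d] -= 2 * h
            em = total_energy(topo, coords, ff).total
            coords[i, d] += h
            out[i, d] = -(ep - em) / (2 * h)
    return out
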