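import numpy as np
import pytest

from tribasin import energetics
from tribasin.contacts import classify_contacts, compute_contact_map
from tribasin.energetics import (
    DHParams, bonded_energy, contact_energy, dh_energy, numerical_forces,
    repulsion_energy, total_energy,
)
from tribasin.geometry import rotation_about_axis
from tribasin.structures import coarse_grain
from tribasin.topology import ModelParams, build_topology


@pytest.fixture(scope="module")
def degenerate_topology(toy_models, toy_spec):
    """Single-basin topology (identical triple) so all r0 match the open state."""
    cg = coarse_grain(toy_models[0])
    cmap = compute_contact_map(toy_models[0], cutoff=toy_spec.contact_cutoff, cg=cg)
    mixed = classify_contacts(cmap, cmap, cmap, cg)
    return build_topology(cg, cg, cg, mixed, ModelParams())


class TestBondedEnergy:
    def test_reference_geometry_is_minimum(self, degenerate_topology):
        topo = degenerate_topology
        rep = bonded_energy(topo, topo.cg.coords)
        assert rep.bonded == pytest.approx(0.0, abs=1e-10)
        assert np.abs(rep.forces).max() < 1e-6

    def test_single_bond_closed_form(self, degenerate_topology):
        topo = degenerate_topology
        b = topo.bonded
        coords = topo.cg.coords.copy()
        i, j = b.bond_ij[0]
        # stretch bond 0 along its axis by delta
        delta = 0.3
        axis = coords[j] - coords[i]
        axis /= np.linalg.norm(axis)
        # move a terminal bead only if it participates in just this bond
        rep0 = bonded_energy(topo, coords)
        coords2 = coords.copy()
        coords2[j] = coords[i] + (np.linalg.norm(coords[j] - coords[i]) + delta) * axis
        # compute the bond term in isolation via the closed form
        from tribasin import _kernels
        f = np.zeros_like(coords2)
        e = _kernels.bond_energy_forces(
            coords2, b.bond_ij[:1].astype(np.int64), b.bond_r0[:1], b.bond_k[:1], f)
        assert e == pytest.approx(0.5 * b.bond_k[0] * delta**2, rel=1e-12)

    def test_forces_match_finite_differences(self, toy_topology, rng):
        coords = toy_topology.cg.coords + 0.05 * rng.standard_normal(
            toy_topology.cg.coords.shape)
        rep = total_energy(toy_topology, coords)
        num = numerical_forces(toy_topology, coords)
        err = np.abs(rep.forces - num) / (np.abs(num) + 1e-3)
        assert err.max() < 1e-5

    def test_nan_coordinates_rejected(self, toy_topology):
        coords = toy_topology.cg.coords.copy()
        coords[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            total_energy(toy_topology, coords)


class TestContactEnergy:
    def test_native_geometry_gives_full_well_depth(self, degenerate_topology):
        topo = degenerate_topology
        rep = contact_energy(topo, topo.cg.coords)
        assert rep.contact == pytest.approx(-topo.con_eps.sum(), rel=1e-12)

    def test_separated_pair_contributes_nothing(self, degenerate_topology):
        topo = degenerate_topology
        base = contact_energy(topo, topo.cg.coords).contact
        coords = topo.cg.coords.copy()
        # translate domain 2 far away: its cross contacts vanish
        mask = topo.cg.res_index >= 23
        coords[mask] += np.array([500.0, 0.0, 0.0])
        moved = contact_energy(topo, coords).contact
        cross = [
            k for k in range(len(topo.con_ij))
            if mask[topo.con_ij[k, 0]] != mask[topo.con_ij[k, 1]]
        ]
        expected = base + topo.con_eps[cross].sum()  # cross wells released
        assert moved == pytest.approx(expected, abs=1e-6)

    def test_pair_force_zero_at_native_distance(self, degenerate_topology):
        topo = degenerate_topology
        rep = contact_energy(topo, topo.cg.coords)
        # at the exact native geometry every contact sits at its minimum,
        # so the contact-term force reduces to numerical noise
        assert np.abs(rep.forces).max() < 1e-8


class TestRepulsion:
    def test_well_separated_beads_negligible(self, toy_topology):
        coords = toy_topology.cg.coords * 10.0  # blow up all distances
        rep = repulsion_energy(toy_topology, coords)
        assert abs(rep.repulsion) < 1e-6

    def test_contact_value_closed_form(self):
        # two beads at r = sigma contribute exactly eps_rep
        from tribasin import _kernels
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        f = np.zeros_like(coords)
        e, min_r = _kernels.repulsion_energy_forces(
            coords, np.array([[0, 1]], dtype=np.int64), np.array([4.0]), 1.0, f)
        assert e == pytest.approx(1.0, rel=1e-12)
        assert min_r == pytest.approx(4.0)

    def test_monotonic_decrease_with_separation(self):
        from tribasin import _kernels
        ij = np.array([[0, 1]], dtype=np.int64)
        sig = np.array([4.0])
        prev = np.inf
        for r in np.linspace(3.0, 8.0, 30):
            coords = np.array([[0.0, 0, 0], [r, 0, 0]])
            f = np.zeros_like(coords)
            e, _ = _kernels.repulsion_energy_forces(coords, ij, sig, 1.0, f)
            assert e < prev
            prev = e

    def test_overlapping_beads_error(self, toy_topology):
        coords = toy_topology.cg.coords.copy()
        pair = toy_topology.rep_ij[0]
        coords[pair[1]] = coords[pair[0]] + 1e-9
        with pytest.raises(ValueError, match="overlap"):
            repulsion_energy(toy_topology, coords)


class TestDebyeHuckel:
    def test_zero_charges_zero_energy(self, rng):
        coords = rng.standard_normal((5, 3)) * 10
        rep = dh_energy(coords, charges=np.zeros(5))
        assert rep.electrostatic == 0.0

    def test_closed_form_at_debye_length(self):
        p = DHParams(dielectric=80.0, ionic_strength=0.10, cutoff_lambdas=np.inf)
        lam = p.lambda_d
        coords = np.array([[0.0, 0, 0], [lam, 0, 0]])
        rep = dh_energy(coords, charges=np.array([1.0, 1.0]), params=p)
        expected = p.prefactor * np.exp(-1.0) / lam
        assert rep.electrostatic == pytest.approx(expected, rel=1e-10)

    def test_parameter_scan_endpoints_accepted(self):
        for eps_r in (40.0, 160.0):
            for ionic in (0.0, 0.20):
                p = DHParams(dielectric=eps_r, ionic_strength=ionic)
                coords = np.array([[0.0, 0, 0], [7.0, 0, 0]])
                rep = dh_energy(coords, charges=np.array([1.0, -1.0]), params=p)
                assert np.isfinite(rep.electrostatic)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError, match="ionic"):
            DHParams(ionic_strength=-0.1)

    def test_zero_salt_limit_is_coulomb(self):
        coul = DHParams(dielectric=80.0, ionic_strength=0.0)
        for r in (5.0, 10.0, 20.0):
            coords = np.array([[0.0, 0, 0], [r, 0, 0]])
            got = dh_energy(coords, charges=np.array([1.0, 1.0]), params=coul)
            assert got.electrostatic == pytest.approx(coul.prefactor / r, rel=1e-10)
        # and decreasing ionic strength converges toward it
        prev_err = np.inf
        r = 7.0
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        target = coul.prefactor / r
        for ionic in (0.1, 0.01, 0.001):
            p = DHParams(dielectric=80.0, ionic_strength=ionic, cutoff_lambdas=np.inf)
            e = dh_energy(coords, charges=np.array([1.0, 1.0]), params=p).electrostatic
            err = abs(e - target)
            assert err < prev_err
            prev_err = err

    def test_ion_size_factor_increases_prefactor(self):
        plain = DHParams(ionic_strength=0.1)
        sized = DHParams(ionic_strength=0.1, ion_size=4.0)
        assert sized.prefactor > plain.prefactor


class TestTotalEnergy:
    def test_total_is_sum_of_slices(self, toy_topology, rng):
        coords = toy_topology.cg.coords + 0.05 * rng.standard_normal(
            toy_topology.cg.coords.shape)
        ff = energetics.force_field(toy_topology)
        rep = total_energy(toy_topology, coords, ff)
        parts = (bonded_energy(toy_topology, coords, ff).bonded
                 + contact_energy(toy_topology, coords, ff).contact
                 + repulsion_energy(toy_topology, coords, ff).repulsion
                 + rep.electrostatic)
        assert rep.total == pytest.approx(parts, rel=1e-10)

    def test_rigid_motion_invariance(self, toy_topology, rng):
        coords = toy_topology.cg.coords + 0.05 * rng.standard_normal(
            toy_topology.cg.coords.shape)
        e0 = total_energy(toy_topology, coords).total
        R = rotation_about_axis(np.array([1.0, -2.0, 0.5]), 0.7)
        moved = coords @ R.T + np.array([11.0, -4.0, 3.0])
        e1 = total_energy(toy_topology, moved).total
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_net_force_and_torque_vanish(self, toy_topology, rng):
        coords = toy_topology.cg.coords + 0.08 * rng.standard_normal(
            toy_topology.cg.coords.shape)
        rep = total_energy(toy_topology, coords)
        assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8
        torque = np.cross(coords, rep.forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_zero_ligand_strength_ignores_ligand_list(self, toy_cgs, toy_mixed,
                                                      toy_ligand_contacts, rng):
        params = ModelParams(eps_ligand=0.0)
        with_list = build_topology(*toy_cgs, toy_mixed, params,
                                   ligand_contacts=toy_ligand_contacts)
        without = build_topology(*toy_cgs, toy_mixed, params, ligand_contacts=None)
        coords = with_list.cg.coords + 0.05 * rng.standard_normal(
            with_list.cg.coords.shape)
        assert total_energy(with_list, coords).total == pytest.approx(
            total_energy(without, coords).total, rel=1e-12)
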