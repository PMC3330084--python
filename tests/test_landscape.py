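import numpy as np
import pytest

from tribasin import landscape as ls
from tribasin.contacts import ContactClass
from tribasin.geometry import rotation_about_axis
from tribasin.landscape import (
    BasinDefinition, FrameCoordinates, StateSeries, assign_basins,
    contact_probability_map, cracking_scores, extract_ts_ensemble,
    fractional_flux, free_energy_surface, heat_capacity_direct,
    locate_minima_saddles, parse_transitions, phi_values, q_fraction,
    rmsd_to_state, wham_heat_capacity,
)
from tribasin.markov import make_markov_series
from tribasin.structures import superpose


# ---------------------------------------------------------------------------
# reaction coordinates

class TestQFraction:
    def test_native_frame_is_one_for_every_state(self, toy_system):
        topo, refs, _, _ = toy_system
        for name, cls in zip("OAH", (ContactClass.O_SPEC, ContactClass.A_SPEC,
                                     ContactClass.H_SPEC)):
            idx = topo.contacts_of_class(cls)
            q = q_fraction(refs[name], topo.con_ij[idx], topo.con_r0[idx])
            assert q == 1.0

    def test_extended_chain_is_zero(self, toy_system):
        topo, _, _, _ = toy_system
        n = topo.n_beads
        extended = np.column_stack([np.arange(n) * 10.0, np.zeros(n), np.zeros(n)])
        for cls in (ContactClass.O_SPEC, ContactClass.A_SPEC, ContactClass.H_SPEC):
            idx = topo.contacts_of_class(cls)
            assert q_fraction(extended, topo.con_ij[idx], topo.con_r0[idx]) == 0.0

    def test_matches_per_contact_loop_oracle(self, toy_system, rng):
        topo, refs, _, _ = toy_system
        frames = refs["O"][None] + 0.5 * rng.standard_normal((20, topo.n_beads, 3))
        idx = topo.contacts_of_class(ContactClass.H_SPEC)
        ij, r0 = topo.con_ij[idx], topo.con_r0[idx]
        got = q_fraction(frames, ij, r0)
        for f, frame in enumerate(frames):
            formed = sum(
                1 for (i, j), r in zip(ij, r0)
                if np.linalg.norm(frame[i] - frame[j]) < 1.2 * r
            )
            assert got[f] == pytest.approx(formed / len(ij))

    def test_empty_contact_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            q_fraction(np.zeros((3, 3)), np.empty((0, 2)), np.empty(0))


class TestRmsd:
    def test_reference_frame_zero(self, toy_system):
        topo, refs, _, _ = toy_system
        assert rmsd_to_state(refs["O"], refs["O"]) < 1e-10

    def test_rigid_rotation_zero_after_fit(self, toy_system):
        topo, refs, _, _ = toy_system
        R = rotation_about_axis(np.array([0.3, 1.0, -0.2]), 0.9)
        moved = refs["O"] @ R.T + np.array([4.0, 5.0, 6.0])
        assert rmsd_to_state(moved, refs["O"]) < 1e-8

    def test_consistent_with_superpose(self, toy_system, rng):
        topo, refs, _, _ = toy_system
        frames = refs["O"][None] + 0.3 * rng.standard_normal((100, topo.n_beads, 3))
        got = rmsd_to_state(frames, refs["O"])
        for f, frame in enumerate(frames):
            _, expected = superpose(frame, refs["O"])
            assert abs(got[f] - expected) < 1e-8


# ---------------------------------------------------------------------------
# basin assignment and kinetics

def synthetic_fc(labels, noise=0.02, seed=0):
    """Q series that clearly encode a label sequence."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    q = {s: np.full(n, 0.1) for s in "OAH"}
    for i, lab in enumerate(labels):
        q[lab][i] = 0.9
    for s in q:
        q[s] = np.clip(q[s] + noise * rng.standard_normal(n), 0, 1)
    return FrameCoordinates(q=q)


class TestAssignBasins:
    def test_constant_series_single_visit(self):
        fc = synthetic_fc(["O"] * 300)
        series = assign_basins(fc, dwell_filter=10)
        assert series.visit_states == ["O"]
        assert set(series.labels) == {"O"}

    def test_single_constructed_crossing(self):
        fc = synthetic_fc(["O"] * 200 + ["H"] * 200)
        series = assign_basins(fc, dwell_filter=10)
        assert series.visit_states == ["O", "H"]
        assert series.visits[1][1] == 200  # transition at the known frame

    def test_short_blips_are_dwell_filtered(self):
        labels = ["O"] * 100 + ["H"] * 3 + ["O"] * 100
        fc = synthetic_fc(labels)
        series = assign_basins(fc, dwell_filter=10)
        assert series.visit_states == ["O"]

    def test_markov_emission_recovered(self):
        q = np.array([[-0.2, 0.1, 0.1], [0.3, -0.6, 0.3], [0.1, 0.1, -0.2]])
        mseries, truth = make_markov_series(q, duration=2000.0, seed=4, frame_time=0.5)
        fc = synthetic_fc(list(mseries.labels), noise=0.02, seed=5)
        series = assign_basins(fc, dwell_filter=1)
        agree = (series.labels == mseries.labels).mean()
        assert agree >= 0.99

    def test_overlapping_basin_definitions_rejected(self):
        bad = BasinDefinition(bounds={
            "O": {"O": (0.5, 1.01)},
            "A": {"O": (0.4, 0.8)},
        })
        with pytest.raises(ValueError, match="overlap"):
            bad.validate()


def oracle_counts(states):
    """Exhaustive window-scanning transition/path counts."""
    counts = {a + b: 0 for a in "OAH" for b in "OAH" if a != b}
    for a, b in zip(states[:-1], states[1:]):
        counts[a + b] += 1
    n_oah = sum(1 for i in range(len(states) - 2)
                if states[i] == "O" and states[i + 1] == "A" and states[i + 2] == "H")
    return counts, n_oah


class TestParseTransitions:
    def test_alternating_oh(self):
        series = StateSeries(
            labels=np.array(list("O" * 10 + "H" * 10 + "O" * 10 + "H" * 10)),
            visits=[("O", 0, 9), ("H", 10, 19), ("O", 20, 29), ("H", 30, 39)],
            dwell_filter=0)
        stats = parse_transitions(series)
        assert stats.counts["OH"] == 2
        assert stats.n_oah == 0
        assert stats.f_if == 1.0

    def test_sequential_oah(self):
        series = StateSeries(
            labels=np.array(list("O" * 5 + "A" * 5 + "H" * 5)),
            visits=[("O", 0, 4), ("A", 5, 9), ("H", 10, 14)], dwell_filter=0)
        stats = parse_transitions(series)
        assert stats.counts["OH"] == 0
        assert stats.n_oah == 1
        assert stats.f_if == 0.0
        assert stats.f_ps == 1.0

    def test_thousand_random_sequences_match_oracle(self):
        rng = np.random.default_rng(99)
        states = "OAH"
        for _ in range(1000):
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
            series = StateSeries(labels=np.array(labels), visits=visits, dwell_filter=0)
            stats = parse_transitions(series)
            counts, n_oah = oracle_counts(seq)
            assert stats.counts == counts
            assert stats.n_oah == n_oah

    def test_gillespie_event_log_reproduced(self):
        q = np.array([[-0.3, 0.2, 0.1], [0.25, -0.5, 0.25], [0.15, 0.15, -0.3]])
        series, truth = make_markov_series(q, duration=5000.0, seed=11, frame_time=0.02)
        stats = parse_transitions(series, frame_time=0.02)
        # frame sampling at 0.02 time units resolves every visit in the log
        skipped = sum(1 for d in truth.durations if d < 0.02)
        if skipped == 0:
            assert stats.counts == truth.counts
            assert stats.n_oah == truth.n_oah


class TestFluxAndRates:
    def test_flux_arithmetic(self):
        series = StateSeries(labels=np.array(list("OHOAHOH")),
                             visits=[(s, i, i) for i, s in enumerate("OHOAHOH")],
                             dwell_filter=0)
        stats = parse_transitions(series)
        # direct O→H: positions 0→1, 5→6 and the O→A→H path at 3..5
        assert stats.counts["OH"] == 2
        assert stats.n_oah == 1
        f_if, f_ps = fractional_flux(stats)
        assert f_if == pytest.approx(2 / 3)
        assert f_ps == pytest.approx(1 / 3)

    def test_flux_undefined_without_arrivals(self):
        series = StateSeries(labels=np.array(list("OAOAOA")),
                             visits=[(s, i, i) for i, s in enumerate("OAOAOA")],
                             dwell_filter=0)
        stats = parse_transitions(series)
        assert stats.f_if is None and stats.f_ps is None

    def test_single_transition_rate(self):
        # O occupied 40 frames of 100 at 0.1 time/frame, one O→H transition
        labels = np.array(["O"] * 40 + ["H"] * 60)
        series = StateSeries(labels=labels, visits=[("O", 0, 39), ("H", 40, 99)],
                             dwell_filter=0)
        stats = parse_transitions(series, frame_time=0.1)
        # k = N/(P_O * T) = 1 / (0.4 * 10) = 0.25
        assert stats.rate("O", "H") == pytest.approx(0.25)

    def test_markov_generator_recovered_within_3se(self):
        q = np.array([[-0.4, 0.3, 0.1],
                      [0.2, -0.5, 0.3],
                      [0.1, 0.2, -0.3]])
        # duration chosen for ~1e4 events
        series, truth = make_markov_series(q, duration=40_000.0, seed=21,
                                           frame_time=0.05)
        stats = parse_transitions(series, frame_time=0.05)
        for a_i, a in enumerate("OAH"):
            for b_i, b in enumerate("OAH"):
                if a == b:
                    continue
                k_est = stats.rate(a, b)
                n = stats.counts[a + b]
                se = np.sqrt(max(n, 1)) / (stats.probabilities[a] * stats.total_time)
                assert abs(k_est - q[a_i, b_i]) < 3 * se + 0.01


# ---------------------------------------------------------------------------
# free-energy surfaces

class TestFES:
    def test_uniform_samples_flat_surface(self, rng):
        x = rng.uniform(0, 1, 200_000)
        y = rng.uniform(0, 1, 200_000)
        fes = free_energy_surface(x, y, temperature=1.0, bins=10)
        spread = float(fes.free_energy.max() - fes.free_energy.min())
        assert spread < 0.15  # binomial noise only

    def test_overdamped_double_well_recovered(self):
        """Brownian sampling of a known 2-D potential reproduces it in k_BT."""
        rng = np.random.default_rng(12)
        t = 1.0
        h, ky = 2.0, 4.0

        def grad(p):
            x, y = p[:, 0], p[:, 1]
            return np.column_stack([4 * h * x * (x * x - 1), ky * y])

        n_walkers, n_steps, dt = 200, 30_000, 0.002
        p = np.column_stack([rng.choice([-1.0, 1.0], n_walkers),
                             np.zeros(n_walkers)])
        samples = []
        for step in range(n_steps):
            p = p - grad(p) * dt + np.sqrt(2 * t * dt) * rng.standard_normal(p.shape)
            if step % 10 == 0 and step > 2000:
                samples.append(p.copy())
        pts = np.concatenate(samples)
        fes = free_energy_surface(pts[:, 0], pts[:, 1], temperature=t, bins=24,
                                  ranges=((-1.6, 1.6), (-1.2, 1.2)))
        xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
        yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
        vx, vy = np.meshgrid(xc, yc, indexing="ij")
        v = h * (vx**2 - 1) ** 2 + 0.5 * ky * vy**2
        well = fes.counts >= 500
        diff = (fes.free_energy - v)[well]
        diff = diff - diff.mean()   # both surfaces are defined up to a constant
        assert np.abs(diff).max() < 0.2

    def test_few_frames_warns(self):
        with pytest.warns(UserWarning, match="100 frames"):
            free_energy_surface(np.zeros(10), np.zeros(10))


class TestMinimaSaddles:
    def _two_gaussian_fes(self, bins=41):
        x = np.linspace(0, 1, bins)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        p = (np.exp(-((xx - 0.3) ** 2 + (yy - 0.3) ** 2) / 0.01)
             + np.exp(-((xx - 0.7) ** 2 + (yy - 0.7) ** 2) / 0.01))
        f = -np.log(p + 1e-12)
        f -= f.min()
        edges = np.linspace(0, 1, bins + 1)
        return ls.FES2D(x_edges=edges, y_edges=edges,
                        free_energy=np.ma.masked_greater(f, 25.0),
                        counts=p)

    def test_two_gaussian_minima_and_saddle(self):
        fes = self._two_gaussian_fes()
        minima, saddles = locate_minima_saddles(fes)
        centers = [fes.bin_center(*m) for m in minima[:2]]
        assert any(np.allclose(c, (0.3, 0.3), atol=0.05) for c in centers)
        assert any(np.allclose(c, (0.7, 0.7), atol=0.05) for c in centers)
        assert len(saddles) == 1
        (key, (i, j, barrier)), = saddles.items()
        sx, sy = fes.bin_center(i, j)
        # symmetric wells: the minimax path crosses near the midpoint
        assert abs(sx - 0.5) < 0.08 and abs(sy - 0.5) < 0.08
        assert barrier > 0

    def test_monotonic_surface_single_minimum_no_saddles(self):
        bins = 21
        x = np.linspace(0, 1, bins)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        f = xx + 2 * yy
        edges = np.linspace(0, 1, bins + 1)
        fes = ls.FES2D(x_edges=edges, y_edges=edges,
                       free_energy=np.ma.masked_invalid(f), counts=np.ones_like(f))
        minima, saddles = locate_minima_saddles(fes)
        assert len(minima) == 1
        assert minima[0] == (0, 0)
        assert saddles == {}


class TestTSEnsemble:
    def test_window_covering_plane_returns_all(self, rng):
        x, y = rng.uniform(0, 1, 500), rng.uniform(0, 1, 500)
        sel = extract_ts_ensemble(x, y, (0.5, 0.5), window=1.0, min_size=1)
        assert len(sel) == 500

    def test_constructed_inclusion(self):
        x = np.array([0.1, 0.5, 0.52, 0.9])
        y = np.array([0.1, 0.5, 0.48, 0.9])
        sel = extract_ts_ensemble(x, y, (0.5, 0.5), window=0.05, min_size=1)
        assert list(sel) == [1, 2]

    def test_matches_rectangle_oracle(self, rng):
        x, y = rng.uniform(0, 1, 2000), rng.uniform(0, 1, 2000)
        saddle, w = (0.4, 0.6), 0.07
        sel = extract_ts_ensemble(x, y, saddle, window=w, min_size=1)
        oracle = [i for i in range(2000)
                  if abs(x[i] - saddle[0]) <= w and abs(y[i] - saddle[1]) <= w]
        assert list(sel) == oracle

    def test_widening_warns_then_errors(self, rng):
        x, y = rng.uniform(0, 0.1, 300), rng.uniform(0, 0.1, 300)
        with pytest.warns(UserWarning, match="widened|fewer|frames"):
            extract_ts_ensemble(x, y, (0.5, 0.5), window=0.2, min_size=100)
        with pytest.raises(ValueError, match="saddle"):
            extract_ts_ensemble(x, y, (5.0, 5.0), window=0.01, min_size=100)


class TestContactProbability:
    def test_open_reference_forms_all_open_contacts(self, toy_system):
        topo, refs, _, _ = toy_system
        ens = np.repeat(refs["O"][None], 5, axis=0)
        rows = contact_probability_map(ens, topo, classes=(ContactClass.O_SPEC,))
        assert rows
        assert all(r["probability"] == 1.0 for r in rows)

    def test_probabilities_match_loop_oracle(self, toy_system, rng):
        topo, refs, _, _ = toy_system
        ens = refs["H"][None] + 0.4 * rng.standard_normal((30, topo.n_beads, 3))
        rows = contact_probability_map(ens, topo, classes=(ContactClass.H_SPEC,))
        for row in rows:
            i, j = row["i"], row["j"]
            k = row["contact_index"]
            r0 = topo.con_r0[k]
            formed = sum(
                1 for frame in ens if np.linalg.norm(frame[i] - frame[j]) < 1.2 * r0)
            assert row["probability"] == pytest.approx(formed / 30)
            assert 0.0 <= row["probability"] <= 1.0


class TestPhiValues:
    def test_limits(self, toy_system, rng):
        topo, refs, _, _ = toy_system
        start = refs["O"][None] + 0.15 * rng.standard_normal((40, topo.n_beads, 3))
        end = refs["H"][None] + 0.15 * rng.standard_normal((40, topo.n_beads, 3))
        as_end = phi_values(start, end, end, topo, transition="OH")
        assert as_end.phi  # some residues pass the floor
        for r, val in as_end.phi.items():
            assert val == pytest.approx(1.0, abs=1e-9)
        as_start = phi_values(start, end, start, topo, transition="OH")
        for r, val in as_start.phi.items():
            assert val == pytest.approx(0.0, abs=1e-9)

    def test_insensitive_residues_excluded(self, toy_system, rng):
        topo, refs, _, _ = toy_system
        start = refs["O"][None] + 0.15 * rng.standard_normal((30, topo.n_beads, 3))
        table = phi_values(start, start, start, topo)  # no difference anywhere
        assert table.phi == {}
        assert len(table.excluded) == topo.cg.n_residues

    def test_empty_ensemble_rejected(self, toy_system):
        topo, refs, _, _ = toy_system
        empty = np.empty((0, topo.n_beads, 3))
        with pytest.raises(ValueError, match="empty"):
            phi_values(empty, refs["H"][None], refs["H"][None], topo)


class TestCracking:
    def test_ts_equal_to_basin_gives_no_flags(self, toy_system, rng):
        topo, refs, _, _ = toy_system
        ens = refs["O"][None] + 0.05 * rng.standard_normal((20, topo.n_beads, 3))
        scores, flagged = cracking_scores(ens, ens, ens, topo)
        assert flagged == set()
        assert all(s <= 1e-12 for s in scores.values())

    def test_constructed_hinge_strain_flagged(self, toy_topology, toy_spec):
        """A TS ensemble with the mobile block rotated (bonded terms strained
        only at the hinge) flags hinge residues and no others.  Uses the
        θ_O topology, whose hinge terms carry the full open-state bias."""
        topo = toy_topology
        cg = topo.cg
        refs = {"O": cg.coords}
        pivot = cg.coords[cg.bead_index(toy_spec.pivot_residue, "CA")]
        R = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.deg2rad(55))
        strained = cg.coords.copy()
        mask = cg.res_index >= toy_spec.pivot_residue
        strained[mask] = (strained[mask] - pivot) @ R.T + pivot
        ts = strained[None]
        basin = refs["O"][None]
        scores, flagged = cracking_scores(ts, basin, basin, topo, threshold=1.0)
        assert flagged
        hinge_zone = set(range(toy_spec.pivot_residue - 2, toy_spec.pivot_residue + 3))
        assert flagged <= hinge_zone


class TestHeatCapacity:
    def test_harmonic_direct_cv_constant(self, rng):
        # quadratic system with M modes: E ~ Gamma(M/2, T); Cv = M/2
        m = 6
        energies = {t: rng.gamma(m / 2, t, size=200_000) for t in (0.4, 0.5, 0.6)}
        temps, cv, tm = heat_capacity_direct(energies)
        np.testing.assert_allclose(cv, m / 2, rtol=0.02)

    def test_schottky_peak_position(self):
        """Direct Cv of an exact two-level system peaks at the closed-form
        Schottky temperature."""
        gap = 1.0
        temps = np.linspace(0.15, 1.2, 43)
        rng = np.random.default_rng(8)
        energies = {}
        for t in temps:
            p1 = np.exp(-gap / t) / (1 + np.exp(-gap / t))
            energies[float(t)] = gap * (rng.uniform(size=400_000) < p1)
        tg, cv, tm = heat_capacity_direct(energies)
        # analytic argmax of Cv(T) = (g/T)^2 e^{g/T}/(1+e^{g/T})^2
        fine = np.linspace(0.15, 1.2, 20001)
        x = gap / fine
        cv_exact = x**2 * np.exp(x) / (1 + np.exp(x)) ** 2
        t_star = fine[np.argmax(cv_exact)]
        assert abs(tm - t_star) <= (temps[1] - temps[0]) + 1e-9

    def test_wham_recovers_harmonic_cv(self, rng):
        m = 4
        energies = {t: rng.gamma(m / 2, t, size=100_000) for t in (0.4, 0.5, 0.6)}
        tg, cv, tm = wham_heat_capacity(energies, n_bins=200)
        inner = (tg >= 0.42) & (tg <= 0.58)
        np.testing.assert_allclose(cv[inner], m / 2, rtol=0.10)

    def test_wham_rejects_nonoverlapping_histograms(self, rng):
        energies = {0.1: rng.normal(1.0, 0.001, 1000),
                    1.0: rng.normal(100.0, 0.001, 1000),
                    2.0: rng.normal(200.0, 0.001, 1000)}
        with pytest.raises(ValueError, match="overlap"):
            wham_heat_capacity(energies)

    def test_wham_needs_three_temperatures(self, rng):
        with pytest.raises(ValueError, match="3 temperatures"):
            wham_heat_capacity({0.4: rng.gamma(2, 0.4, 100),
                                0.5: rng.gamma(2, 0.5, 100)})


class TestTables:
    def test_transition_table_round_numbers(self, tmp_path):
        series = StateSeries(
            labels=np.array(list("O" * 10 + "H" * 10)),
            visits=[("O", 0, 9), ("H", 10, 19)], dwell_filter=0)
        stats = parse_transitions(series, frame_time=0.5)
        path = tmp_path / "t.tsv"
        ls.write_transition_table(stats, path, provenance="unit test")
        text = path.read_text()
        assert "N_OH\t1" in text
        assert "F_IF\t1" in text

    def test_fes_write_read_round_trip(self, tmp_path, rng):
        x, y = rng.uniform(0, 1, 5000), rng.uniform(0, 1, 5000)
        fes = free_energy_surface(x, y, bins=8)
        path = tmp_path / "fes.tsv"
        ls.write_fes(fes, path)
        back = ls.read_fes(path)
        np.testing.assert_allclose(back.x_edges, fes.x_edges)
        valid = ~np.ma.getmaskarray(fes.free_energy)
        np.testing.assert_allclose(
            np.asarray(back.free_energy)[valid],
            np.asarray(fes.free_energy)[valid], atol=1e-5)
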