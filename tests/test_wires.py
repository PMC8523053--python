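"""Hydrogen-bond detection, the wire graph and wire statistics."""

import numpy as np
import pytest

from conftest import brute_force_hbonds, brute_force_wire_exists, random_water_box
from protonflux import synthetic, wires
from protonflux.core import AtomRecord, Frame, Topology, Trajectory
from protonflux.wires import (HBondCriteria, WirePresenceSeries, WireSearchConfig,
                              detect_hbonds, find_wire, phosphate_level,
                              smooth_presence)


def two_water_frame(oo_distance, angle_deg, box=(3.0, 3.0, 3.0)):
    """Donor water at origin pointing one H at an acceptor water.

    ``angle_deg`` is the acceptor-proton-donor angle planted at the proton.
    """
    theta = np.radians(180.0 - angle_deg)
    d_o = np.zeros(3)
    h1 = np.array([0.1, 0.0, 0.0])
    h2 = np.array([-0.03, 0.095, 0.0])
    # place the acceptor at the requested distance from the donor such that
    # the angle at h1 between donor and acceptor is angle_deg
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve |d_o + t*direction_from_h1 - d_o| = oo_distance for acceptor pos
    a_o = h1 + direction * 1.0
    a_o = h1 + direction * _solve_t(h1, direction, d_o, oo_distance)
    atoms = [
        AtomRecord(0, "OW", "O", "SOL", 1, "W"),
        AtomRecord(1, "HW1", "H", "SOL", 1, "W"),
        AtomRecord(2, "HW2", "H", "SOL", 1, "W"),
        AtomRecord(3, "OW", "O", "SOL", 2, "W"),
        AtomRecord(4, "HW1", "H", "SOL", 2, "W"),
        AtomRecord(5, "HW2", "H", "SOL", 2, "W"),
    ]
    coords = np.array([d_o, h1, h2, a_o, a_o + [0.07, 0.07, 0.0],
                       a_o + [-0.07, 0.07, 0.0]])
    return Topology(atoms), Frame(coords, np.asarray(box, dtype=float))


def _solve_t(h, u, o, target):
    """Distance along u from h so that |h + t*u - o| = target."""
    b = 2 * u @ (h - o)
    c = (h - o) @ (h - o) - target ** 2
    return (-b + np.sqrt(b * b - 4 * c)) / 2


class TestDetectHbonds:
    @pytest.mark.parametrize("d,angle,expected", [
        (0.28, 180.0, 1),   # ideal linear bond
        (0.36, 180.0, 0),   # beyond the 0.35 nm distance cutoff
        (0.28, 100.0, 0),   # below the 120 deg angle cutoff
        (0.349, 121.0, 1),  # just inside both thresholds
    ])
    def test_planted_geometries(self, d, angle, expected):
        top, frame = two_water_frame(d, angle)
        bonds = detect_hbonds(top, frame, np.array([0]), np.array([3]))
        assert len(bonds) == expected
        if expected:
            (b,) = bonds
            assert (b.donor_atom, b.proton_atom, b.acceptor_atom) == (0, 1, 3)

    def test_donor_without_hydrogen_is_configuration_error(self):
        top = Topology([AtomRecord(0, "OE1", "O", "GLU", 14, "A"),
                        AtomRecord(1, "OW", "O", "SOL", 100, "W"),
                        AtomRecord(2, "HW1", "H", "SOL", 100, "W"),
                        AtomRecord(3, "HW2", "H", "SOL", 100, "W")])
        frame = Frame(np.array([[0, 0, 0], [0, 0, 0.3], [0, 0, 0.2],
                                [0.07, 0, 0.35]]), np.full(3, 3.0))
        with pytest.raises(wires.ConfigurationError, match="GLU14"):
            detect_hbonds(top, frame, np.array([0]), np.array([1]))

    def test_matches_brute_force_on_random_box(self, water_box):
        top, frame = water_box
        oxy = top.select("element O")
        crit = HBondCriteria()
        got = {(b.donor_atom, b.acceptor_atom)
               for b in detect_hbonds(top, frame, oxy, oxy, crit)}
        assert got == brute_force_hbonds(top, frame, oxy, oxy, crit)


class TestWireGraph:
    def test_isolated_waters_have_no_edges(self):
        top, frame = random_water_box(8, box=(6.0, 6.0, 6.0), seed=5)
        # pin water oxygens to a sparse grid, 1.5 nm apart, keeping O-H intact
        offsets = frame.coordinates - np.repeat(frame.coordinates[::3], 3, axis=0)
        grid = np.array([[x, y, 0.0] for x in (-2.2, -0.7, 0.8, 2.3)
                         for y in (-1.0, 1.0)])
        frame = Frame(np.repeat(grid, 3, axis=0) + offsets, frame.box)
        g = wires.build_water_graph(top, frame, HBondCriteria(),
                                    np.array([0]), lambda z: False,
                                    frame_index=0)
        water_edges = [e for e in g.edges if "SOURCE" not in e and "TARGET" not in e]
        assert water_edges == []

    def test_planted_chain_connects_source_to_target(self):
        traj, truth = synthetic.gen_wire_box(n_waters=12, wire_length=3,
                                             break_prob=0.0, n_frames=1, seed=2)
        cfg = WireSearchConfig("resid 14 and name OE1 OE2", "up")
        result = find_wire(traj.topology, traj.frames[0], cfg)
        assert result.found
        assert len(result.path) == 3

    def test_broken_link_disconnects(self):
        traj, _ = synthetic.gen_wire_box(n_waters=12, wire_length=3,
                                         break_prob=0.0, n_frames=1, seed=2)
        frame = traj.frames[0]
        top = traj.topology
        # stretch the gap between chain waters 1 and 2 beyond the cutoff
        second = top.select("resid 101")
        frame.coordinates[second] += np.array([0.0, 0.0, 0.12])
        cfg = WireSearchConfig("resid 14 and name OE1 OE2", "up")
        assert not find_wire(top, frame, cfg).found

    def test_found_flag_matches_exhaustive_enumeration(self):
        crit = HBondCriteria()
        n_found = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(5, 31))
            top, frame = random_water_box(n, box=(2.2, 2.2, 2.2),
                                          seed=2000 + seed)
            source = np.array([0])  # first water's oxygen acts as source
            z_cut = 0.6
            target = lambda z: z > z_cut
            g = wires.build_water_graph(top, frame, crit, source, target)
            import networkx as nx
            got = nx.has_path(g, "SOURCE", "TARGET")
            expected = brute_force_wire_exists(top, frame, source, target, crit)
            assert got == expected
            n_found += got
        assert 0 < n_found < 60  # both outcomes exercised

    def test_atom_permutation_leaves_found_flag_unchanged(self):
        traj, _ = synthetic.gen_wire_box(n_waters=15, wire_length=3,
                                         break_prob=0.0, n_frames=1, seed=8)
        top, frame = traj.topology, traj.frames[0]
        cfg = WireSearchConfig("resid 14 and name OE1 OE2", "up")
        base = find_wire(top, frame, cfg)
        rng = np.random.default_rng(0)
        # permute whole residues to keep proton-donor association intact
        res = top.residues()
        order = rng.permutation(len(res))
        new_atoms, new_coords = [], []
        for k in order:
            _, _, _, idx = res[k]
            for i in idx:
                a = top.atoms[i]
                new_atoms.append(AtomRecord(len(new_atoms), a.name, a.element,
                                            a.residue_name, a.residue_id,
                                            a.chain_id))
                new_coords.append(frame.coordinates[i])
        ptop = Topology(new_atoms)
        pframe = Frame(np.array(new_coords), frame.box)
        permuted = find_wire(ptop, pframe, cfg)
        assert permuted.found == base.found
        assert permuted.path == base.path  # ids are residue-based

    def test_monotone_in_criteria(self):
        # loosening thresholds can only create wires, never destroy them
        for seed in range(20):
            top, frame = random_water_box(20, box=(2.0, 2.0, 2.0),
                                          seed=3000 + seed)
            source = np.array([0])
            target = lambda z: z > 0.5
            import networkx as nx
            strict = wires.build_water_graph(
                top, frame, HBondCriteria(0.30, 140.0), source, target)
            loose = wires.build_water_graph(
                top, frame, HBondCriteria(0.35, 120.0), source, target)
            if nx.has_path(strict, "SOURCE", "TARGET"):
                assert nx.has_path(loose, "SOURCE", "TARGET")


class TestWireFraction:
    @pytest.mark.parametrize("p,expected", [(0.0, 1.0), (1.0, 0.0)])
    def test_degenerate_break_probabilities(self, p, expected):
        traj, truth = synthetic.gen_wire_box(break_prob=p, n_frames=30, seed=4)
        cfg = WireSearchConfig("resid 14 and name OE1 OE2", "up")
        assert wires.wire_fraction(traj, cfg) == expected
        assert truth.mean() == expected

    def test_grouped_fractions(self):
        traj, truth = synthetic.gen_wire_box(break_prob=0.5, n_frames=40, seed=6)
        cfg = WireSearchConfig("resid 14 and name OE1 OE2", "up")
        labels = ["w0"] * 20 + ["w1"] * 20
        frac = wires.wire_fraction(traj, cfg, group_by=labels)
        assert set(frac) == {"w0", "w1"}
        assert frac["w0"] == pytest.approx(truth[:20].mean())
        assert frac["w1"] == pytest.approx(truth[20:].mean())


class TestPhosphateLevel:
    def _bilayer(self, z_values):
        atoms = [AtomRecord(i, "P", "P", "LIP", 200 + i, "M")
                 for i in range(len(z_values))]
        coords = np.array([[0.5 * i, 0.0, z] for i, z in enumerate(z_values)])
        return Topology(atoms), Frame(coords, np.full(3, 10.0))

    def test_planted_leaflets(self):
        top, frame = self._bilayer([2.0] * 4 + [-2.0] * 4)
        assert phosphate_level(top, frame) == (2.0, -2.0)

    def test_jittered_leaflets(self):
        rng = np.random.default_rng(12)
        n = 200
        z = np.concatenate([2.0 + rng.normal(0, 0.1, n),
                            -2.0 + rng.normal(0, 0.1, n)])
        top, frame = self._bilayer(z)
        up, lo = phosphate_level(top, frame)
        bound = 3 * 0.1 / np.sqrt(n)
        assert abs(up - 2.0) < bound
        assert abs(lo + 2.0) < bound

    def test_one_sided_distribution_is_an_error(self):
        top, frame = self._bilayer([2.0] * 8)
        with pytest.raises(wires.LeafletError):
            phosphate_level(top, frame)


class TestSmoothing:
    def test_constant_series_is_preserved(self):
        s = smooth_presence(np.ones(200), kernel_sigma=5.0)
        np.testing.assert_allclose(s, 1.0)
        assert np.all((s >= 0) & (s <= 1.0 + 1e-12))

    def test_single_spike_spreads_into_unit_mass_bump(self):
        x = np.zeros(401)
        x[200] = 1.0
        s = smooth_presence(x, kernel_sigma=8.0)
        assert s.sum() == pytest.approx(1.0, rel=1e-6)  # kernel is normalized
        center = s[200]
        assert center == pytest.approx(1.0 / (np.sqrt(2 * np.pi) * 8.0), rel=1e-3)

    def test_mean_conserved_in_interior(self):
        rng = np.random.default_rng(7)
        x = (rng.random(500) < 0.4).astype(float)
        s = smooth_presence(x, kernel_sigma=4.0)
        assert s.mean() == pytest.approx(x.mean(), abs=1e-6)

    def test_time_units(self):
        times = np.arange(100) * 0.5  # ns
        x = np.zeros(100)
        x[50] = 1.0
        s = smooth_presence(x, kernel_sigma=2.0, times=times)  # 4 samples
        s_samples = smooth_presence(x, kernel_sigma=4.0)
        np.testing.assert_allclose(s, s_samples)
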