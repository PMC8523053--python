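"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own neighbour-search and
graph machinery: distances are minimized over the 27 explicit periodic
images and wire reachability is a plain depth-first search on an O(N²)
adjacency, so they can serve as independent references."""

import itertools

import numpy as np
import pytest

from protonflux import synthetic
from protonflux.core import Frame, Topology


@pytest.fixture(scope="session")
def dimer():
    """The toy two-chain dimer fixture plus its planted facts."""
    return synthetic.gen_dimer_fixture(seed=11)


@pytest.fixture()
def water_box():
    """Random 50-water box (no planted structure) for oracle comparisons."""
    return random_water_box(n_waters=50, box=(2.0, 2.0, 2.0), seed=21)


def random_water_box(n_waters, box, seed, spread=None):
    """Uniformly placed, randomly oriented mock waters in an orthorhombic box."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    spread = box if spread is None else np.asarray(spread, dtype=float)
    atoms, coords = [], []
    from protonflux.core import AtomRecord
    for i in range(n_waters):
        o = (rng.random(3) - 0.5) * spread
        coords.append(synthetic._water_coords(o, rng.normal(size=3), rng))
        atoms.extend([
            AtomRecord(3 * i, "OW", "O", "SOL", 100 + i, "W"),
            AtomRecord(3 * i + 1, "HW1", "H", "SOL", 100 + i, "W"),
            AtomRecord(3 * i + 2, "HW2", "H", "SOL", 100 + i, "W"),
        ])
    return Topology(atoms), Frame(np.concatenate(coords), box)


def image_min_distance(a, b, box):
    """Explicit minimum over the 27 neighbouring periodic images."""
    best = np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = np.linalg.norm(np.asarray(b) + np.asarray(shift) * np.asarray(box)
                           - np.asarray(a))
        best = min(best, d)
    return best


def image_min_vector(a, b, box):
    best, vec = np.inf, None
    for shift in itertools.product((-1, 0, 1), repeat=3):
        v = np.asarray(b) + np.asarray(shift) * np.asarray(box) - np.asarray(a)
        n = np.linalg.norm(v)
        if n < best:
            best, vec = n, v
    return vec


def brute_force_hbonds(topology, frame, donor_idx, acceptor_idx, criteria):
    """All-pairs H-bond detection with explicit 27-image geometry."""
    from protonflux.wires import assign_protons
    protons = assign_protons(topology, frame, donor_idx)
    x = frame.coordinates
    found = set()
    for d in donor_idx:
        for a in acceptor_idx:
            if a == d:
                continue
            if image_min_distance(x[d], x[a], frame.box) \
                    > criteria.max_donor_acceptor_distance:
                continue
            for h in protons.get(int(d), []):
                if a == h:
                    continue
                v1 = image_min_vector(x[h], x[d], frame.box)
                v2 = image_min_vector(x[h], x[a], frame.box)
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if ang >= criteria.min_acceptor_proton_donor_angle:
                    found.add((int(d), int(a)))
                    break
    return found


def brute_force_wire_exists(topology, frame, source_idx, target_test, criteria):
    """Exhaustive reachability: DFS over the brute-force water adjacency."""
    from protonflux.wires import water_molecules
    waters = water_molecules(topology)
    resids = sorted(waters)
    oxy = {r: waters[r][0] for r in resids}
    oxy_idx = np.array([oxy[r] for r in resids])
    ww = brute_force_hbonds(topology, frame, oxy_idx, oxy_idx, criteria)
    by_atom = {int(o): r for r, o in oxy.items()}
    adj = {r: set() for r in resids}
    for d, a in ww:
        r1, r2 = by_atom[d], by_atom[a]
        if r1 != r2:
            adj[r1].add(r2)
            adj[r2].add(r1)
    src_bonds = brute_force_hbonds(topology, frame, oxy_idx,
                                   np.asarray(source_idx), criteria)
    start = {by_atom[d] for d, _ in src_bonds}
    src_donating = brute_force_hbonds(topology, frame, np.asarray(source_idx),
                                      oxy_idx, criteria)
    start |= {by_atom[a] for _, a in src_donating}
    targets = {r for r in resids
               if target_test(float(frame.coordinates[oxy[r], 2]))}
    seen, stack = set(start), list(start)
    while stack:
        r = stack.pop()
        if r in targets:
            return True
        for nb in adj[r]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return bool(start & targets)
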