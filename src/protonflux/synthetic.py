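"""Seeded generators with the statistical structure each analysis stage assumes.

The study's raw trajectories are cluster-scale MD and not public, so every
stage is exercised against synthetic inputs carrying machine-readable
ground truth:

* :func:`gen_wire_box` — water boxes containing a geometrically guaranteed
  hydrogen-bonded wire from a glutamate-like source to above a synthetic
  phosphate level, broken per frame with a controllable probability;
* :func:`brownian_sampler` — overdamped Langevin sampling of analytic 1D
  free-energy surfaces under harmonic umbrella biases;
* :func:`gen_crooks_work` — Gaussian forward/reverse work distributions
  satisfying the Crooks relation exactly, with a planted ΔG;
* :func:`gen_occupancy` — frame × bond binary matrices with a planted
  two-state transition;
* :func:`gen_dimer_fixture` — a toy two-chain dimer with central acidic
  residues, a water channel open to one side, phosphate markers and a
  tetrahedral mock ligand, for end-to-end smoke tests.

Every generator takes an explicit seed and owns one RNG stream; the same
seed and parameters reproduce output bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import KB, AtomRecord, Frame, Topology, Trajectory
from .pca import BondId, OccupancyMatrix
from .alchemy import WorkSamples
from .umbrella import DEFAULT_PLAN, UmbrellaWindow, WindowPlanSegment, make_window_plan

OH_BOND = 0.1          # intramolecular O-H distance used in mock waters, nm
WIRE_SPACING = 0.28    # O-O distance along planted wires, nm (mid H-bond range)
CLEARANCE = 0.45       # minimum distractor separation, nm (> H-bond cutoff)


class GenerationError(RuntimeError):
    """Packing or stability constraints cannot be satisfied."""


# ---------------------------------------------------------------------------
# Mock-water helpers
# ---------------------------------------------------------------------------

def _water_atoms(resid: int, chain: str, start_index: int) -> list[AtomRecord]:
    return [
        AtomRecord(start_index, "OW", "O", "SOL", resid, chain),
        AtomRecord(start_index + 1, "HW1", "H", "SOL", resid, chain),
        AtomRecord(start_index + 2, "HW2", "H", "SOL", resid, chain),
    ]


def _water_coords(o: np.ndarray, h1_dir: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """O + one H along h1_dir + one H in a random transverse direction."""
    h1_dir = h1_dir / np.linalg.norm(h1_dir)
    # random unit vector not parallel to h1_dir
    while True:
        v = rng.normal(size=3)
        v -= h1_dir * (v @ h1_dir)
        n = np.linalg.norm(v)
        if n > 1e-6:
            v /= n
            break
    h2_dir = -0.35 * h1_dir + 0.94 * v  # ~110 deg from h1
    h2_dir /= np.linalg.norm(h2_dir)
    return np.array([o, o + OH_BOND * h1_dir, o + OH_BOND * h2_dir])


# ---------------------------------------------------------------------------
# Wire boxes
# ---------------------------------------------------------------------------

def gen_wire_box(n_waters: int = 40, wire_length: int = 5,
                 break_prob: float = 0.0, n_frames: int = 50,
                 box: Sequence[float] = (4.0, 4.0, 4.0),
                 seed: int = 0, jitter: float = 0.004
                 ) -> tuple[Trajectory, np.ndarray]:
    """Water box with a planted source→bulk wire; returns (trajectory, truth).

    ``truth[i]`` is 1 when frame i carries an intact wire.  The chain runs
    from a glutamate-like source at the origin straight up past the upper
    phosphate level; per frame, with probability ``break_prob``, one chain
    water is parked far from everything, which provably disconnects the
    wire (distractor waters keep a clearance larger than the H-bond cutoff
    from the chain, the source and each other).
    """
    if wire_length < 1:
        raise ValueError("wire_length must be >= 1")
    if n_waters < wire_length:
        raise ValueError("n_waters must cover the wire")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    z_phos = WIRE_SPACING * (wire_length - 0.5)
    if z_phos + 0.5 > box[2] / 2:
        raise GenerationError("box too small for the requested wire length")

    atoms: list[AtomRecord] = []
    base: list[np.ndarray] = []

    # source: glutamate-like carboxylate, OE1 at the origin
    for name, el, pos in [("CD", "C", (0.0, 0.13, -0.08)),
                          ("OE1", "O", (0.0, 0.0, 0.0)),
                          ("OE2", "O", (0.0, 0.26, 0.02))]:
        atoms.append(AtomRecord(len(atoms), name, el, "GLU", 14, "A"))
        base.append(np.asarray(pos, dtype=float))

    # phosphate markers, two leaflets of 8
    pid = 200
    for zsign in (1.0, -1.0):
        for gx in (-1.2, -0.4, 0.4, 1.2):
            for gy in (-0.8, 0.8):
                atoms.append(AtomRecord(len(atoms), "P", "P", "LIP", pid, "M"))
                base.append(np.array([gx, gy, zsign * z_phos]))
                pid += 1

    # wire chain: water i donates its first H downward to the previous node
    wire_slice = []
    resid = 100
    for i in range(1, wire_length + 1):
        o = np.array([0.0, 0.0, WIRE_SPACING * i])
        coords = _water_coords(o, np.array([0.0, 0.0, -1.0]), rng)
        wire_slice.append((len(atoms), resid))
        atoms.extend(_water_atoms(resid, "W", len(atoms)))
        base.extend(coords)
        resid += 1

    # distractors: rejection-sampled with clearance from chain, source,
    # the parking spot and each other; z confined between the leaflets
    chain_pts = [p for p in base]
    park = np.array([box[0] / 2 - 0.25, box[1] / 2 - 0.25, 0.0])
    placed: list[np.ndarray] = []
    for _ in range(n_waters - wire_length):
        for attempt in range(4000):
            p = np.array([
                rng.uniform(-box[0] / 2 + 0.3, box[0] / 2 - 0.3),
                rng.uniform(-box[1] / 2 + 0.3, box[1] / 2 - 0.3),
                rng.uniform(-z_phos + 0.15, z_phos - 0.15),
            ])
            if np.linalg.norm(p - park) < CLEARANCE + 0.05:
                continue
            near = chain_pts + placed
            if all(np.linalg.norm(p - q) >= CLEARANCE for q in near):
                placed.append(p)
                break
        else:
            raise GenerationError("could not pack distractor waters")
        coords = _water_coords(p, rng.normal(size=3), rng)
        atoms.extend(_water_atoms(resid, "W", len(atoms)))
        base.extend(coords)
        resid += 1

    base_arr = np.array(base)
    topology = Topology(atoms)

    frames: list[Frame] = []
    truth = np.ones(n_frames, dtype=int)
    for f in range(n_frames):
        coords = base_arr + rng.normal(scale=jitter, size=base_arr.shape)
        if rng.random() < break_prob:
            truth[f] = 0
            k = int(rng.integers(wire_length))
            start, _ = wire_slice[k]
            shift = park - coords[start]
            coords[start:start + 3] += shift
        frames.append(Frame(coords, box, time=f * 0.1))
    return Trajectory(topology, frames), truth


# ---------------------------------------------------------------------------
# Brownian dynamics on analytic 1D potentials
# ---------------------------------------------------------------------------

def brownian_sampler(free_energy: Callable[[np.ndarray], np.ndarray],
                     center: float | np.ndarray, force_constant: float | np.ndarray,
                     n_steps: int, dt: float | np.ndarray = 1e-4,
                     diffusion: float = 0.5,
                     temperature: float = 310.0, seed: int = 0,
                     grad: Callable[[np.ndarray], np.ndarray] | None = None,
                     burn_in: float = 0.1, z0: float | np.ndarray | None = None,
                     z_bounds: tuple[float, float] = (-50.0, 50.0)) -> np.ndarray:
    """Overdamped Langevin sampling of F(z) + ½k(z−center)².

    Update: z ← z − (D/kT)(F'(z) + k(z−c))·dt + √(2D·dt)·η.  ``center`` and
    ``force_constant`` may be arrays for several windows evolved in
    parallel (independent noise); ``dt`` may be an array too, giving each
    window its own time step (a stiff window needs a smaller one: the
    Euler–Maruyama update widens a harmonic stationary distribution by a
    factor 1/(1 − θΔt/2) with θ = D·k_total/kT, so keep θΔt small).  The
    first ``burn_in`` fraction of steps is discarded.  Units: nm, ns,
    kJ/mol; ``diffusion`` in nm²/ns.  Exceeding ``z_bounds`` aborts with a
    step-size error.
    """
    center = np.atleast_1d(np.asarray(center, dtype=float))
    k = np.broadcast_to(np.asarray(force_constant, dtype=float), center.shape).copy()
    scalar = center.size == 1 and np.isscalar(force_constant) \
        and (z0 is None or np.isscalar(z0))
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    if grad is None:
        h = 1e-5

        def grad(z, _f=free_energy):
            return (_f(z + h) - _f(z - h)) / (2 * h)

    z = center.copy() if z0 is None else \
        np.broadcast_to(np.asarray(z0, dtype=float), center.shape).copy()
    dt = np.broadcast_to(np.asarray(dt, dtype=float), center.shape)
    mobility = diffusion / kt
    noise_scale = np.sqrt(2.0 * diffusion * dt)
    out = np.empty((center.size, n_steps))
    for step in range(n_steps):
        force = grad(z) + k * (z - center)
        z = z - mobility * force * dt + noise_scale * rng.standard_normal(center.size)
        out[:, step] = z
    if np.any(out < z_bounds[0]) or np.any(out > z_bounds[1]):
        raise GenerationError(
            "Brownian trajectory left the allowed range; decrease dt")
    keep = out[:, int(np.floor(burn_in * n_steps)):]
    return keep[0] if scalar and center.size == 1 else keep


def gen_umbrella_dataset(free_energy: Callable[[np.ndarray], np.ndarray],
                         plan: Sequence[tuple[float, float]] | None = None,
                         n_steps: int = 100_000,
                         dt: float | np.ndarray | None = None,
                         diffusion: float = 0.5, temperature: float = 310.0,
                         seed: int = 0) -> list[UmbrellaWindow]:
    """Biased Brownian-dynamics samples for every window of a plan.

    Default plan: the two-segment translocation plan (36 fine + 8 coarse
    windows).  All windows are propagated in parallel from their centres.
    The default time step adapts per window to θΔt = 0.15 (θ = D·k/kT), so
    every window yields the same number of effectively independent samples
    (≈ n_steps·θΔt); at this setting the window-to-window statistical
    error, which random-walks along the profile, dominates the ~8%
    stationary-variance bias of the Euler integrator — pushing θΔt lower
    trades a small bias for much worse statistics.
    """
    if plan is None:
        plan = make_window_plan(DEFAULT_PLAN)
    centers = np.array([c for c, _ in plan])
    ks = np.array([k for _, k in plan])
    if dt is None:
        kt = KB * temperature
        dt = np.minimum(0.15 * kt / (diffusion * ks), 4e-3)
    samples = brownian_sampler(free_energy, centers, ks, n_steps, dt,
                               diffusion, temperature, seed)
    return [UmbrellaWindow(c, k, s, temperature)
            for c, k, s in zip(centers, ks, samples)]


def make_double_well(barrier: float = 10.0,
                     minima: tuple[float, float] = (0.4, 1.2),
                     width: float = 0.15) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic double well: two Gaussian basins with the requested barrier
    (kJ/mol) between them and a flat plateau far outside."""
    a, b = minima

    def shape(z):
        z = np.asarray(z, dtype=float)
        return -(np.exp(-((z - a) ** 2) / (2 * width ** 2))
                 + np.exp(-((z - b) ** 2) / (2 * width ** 2)))

    grid = np.linspace(a - 3 * width, b + 3 * width, 4001)
    g = shape(grid)
    inner = (grid > a) & (grid < b)
    amplitude = barrier / float(g[inner].max() - g.min())

    def f(z):
        return amplitude * shape(z)

    return f


def make_binding_profile(depths: tuple[float, float, float] = (12.0, 8.0, 5.0),
                         minima: tuple[float, float, float] = (0.2, 0.8, 1.5),
                         width: float = 0.14,
                         wall_z: float = -0.3, wall_k: float = 2000.0
                         ) -> Callable[[np.ndarray], np.ndarray]:
    """Multi-minimum profile qualitatively shaped like a ligand-binding PMF:
    basins near z = 0.2, 0.8 and 1.5 nm, a bulk plateau beyond ~2.2 nm and
    a soft repulsive wall below ``wall_z``.  Depths are synthetic."""

    def f(z):
        z = np.asarray(z, dtype=float)
        v = np.zeros_like(z)
        for d, m in zip(depths, minima):
            v -= d * np.exp(-((z - m) ** 2) / (2 * width ** 2))
        v = v + 0.5 * wall_k * np.minimum(z - wall_z, 0.0) ** 2
        return v

    return f


# ---------------------------------------------------------------------------
# Crooks-consistent work samples
# ---------------------------------------------------------------------------

def gen_crooks_work(delta_g: float, sigma: float, n_forward: int = 5000,
                    n_reverse: int = 5000, temperature: float = 310.0,
                    seed: int = 0) -> WorkSamples:
    """Gaussian work distributions satisfying the Crooks relation exactly:
    forward ~ N(ΔG + βσ²/2, σ²), reverse ~ N(−ΔG + βσ²/2, σ²)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    mean_shift = beta * sigma ** 2 / 2.0
    fwd = rng.normal(delta_g + mean_shift, sigma, size=n_forward)
    rev = rng.normal(-delta_g + mean_shift, sigma, size=n_reverse)
    return WorkSamples(fwd, rev, temperature)


# ---------------------------------------------------------------------------
# Occupancy matrices with a planted two-state transition
# ---------------------------------------------------------------------------

def gen_occupancy(n_frames: int = 400, n_bonds: int = 40,
                  switch_frame: int = 200,
                  flip_set: Sequence[int] | None = None,
                  noise_rate: float = 0.05, seed: int = 0
                  ) -> tuple[OccupancyMatrix, dict[BondId, str], np.ndarray]:
    """Binary occupancy with bonds in ``flip_set`` inverting at ``switch_frame``.

    Returns (matrix, truth, difference): truth maps each flipped BondId to
    its planted class ("gain" when it turns on, "lose" when it turns off);
    ``difference`` is the planted per-bond occupancy change (segment B − A),
    the vector PC1 should align with.  Each synthetic bond involves its own
    residue pair, so planted gains and losses never alias into partner swaps.
    """
    if not 0 < switch_frame < n_frames:
        raise ValueError("switch_frame must fall inside the trajectory")
    if flip_set is None:
        flip_set = list(range(min(8, n_bonds)))
    flip_set = sorted(set(int(i) for i in flip_set))
    if flip_set and (flip_set[0] < 0 or flip_set[-1] >= n_bonds):
        raise ValueError("flip_set indices out of range")
    rng = np.random.default_rng(seed)
    baseline = rng.integers(0, 2, size=n_bonds)
    values = np.tile(baseline, (n_frames, 1))
    for j in flip_set:
        values[switch_frame:, j] = 1 - baseline[j]
    noise = rng.random(values.shape) < noise_rate
    values = np.where(noise, 1 - values, values).astype(np.int8)
    bonds = [BondId(("A", 10 + j, "N"), ("B", 10 + j, "O"),
                    "backbone" if j % 2 == 0 else "sidechain")
             for j in range(n_bonds)]
    truth = {bonds[j]: ("gain" if baseline[j] == 0 else "lose") for j in flip_set}
    difference = np.zeros(n_bonds)
    for j in flip_set:
        difference[j] = 1.0 if baseline[j] == 0 else -1.0
    return OccupancyMatrix(bonds, values), truth, difference


# ---------------------------------------------------------------------------
# Toy dimer fixture
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = [("N", "N", (0.00, 0.00, 0.00)),
                     ("CA", "C", (0.12, 0.05, 0.03)),
                     ("C", "C", (0.24, 0.00, 0.06)),
                     ("O", "O", (0.24, -0.12, 0.08))]

_GLU_SIDECHAIN = [("CB", "C", (0.12, 0.18, 0.03)),
                  ("CG", "C", (0.12, 0.32, 0.08)),
                  ("CD", "C", (0.12, 0.45, 0.02)),
                  ("OE1", "O", (0.12, 0.52, 0.12)),
                  ("OE2", "O", (0.12, 0.52, -0.08))]


def gen_dimer_fixture(seed: int = 0, n_frames: int = 10, jitter: float = 0.004
                      ) -> tuple[Trajectory, dict]:
    """Two-chain mock dimer for end-to-end smoke tests.

    Chains A and B each carry residues 12–16 with a glutamate at position
    14 whose carboxyls meet at the center; a planted water wire runs from
    E14 of chain A upward past the upper phosphate leaflet (none runs
    down), 8 waters sit inside the 0.6 nm central cavity, and a tetrahedral
    mock ligand with central atom P1 floats in the upper solvent.  Returns
    the ~``n_frames``-frame jittered trajectory plus a dict of planted
    facts (phosphate level, cavity water ids, wire direction).
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    base: list[np.ndarray] = []

    def add(name, el, resname, resid, chain, pos):
        atoms.append(AtomRecord(len(atoms), name, el, resname, resid, chain))
        base.append(np.asarray(pos, dtype=float))

    # two mirror-image chains; E14 carboxyl carbons face each other near z=0
    for chain, sign in (("A", -1.0), ("B", 1.0)):
        for ires, resid in enumerate(range(12, 17)):
            resname = "GLU" if resid == 14 else "ALA"
            res_origin = np.array([sign * 0.85, -0.5 + 0.25 * ires,
                                   0.18 * (ires - 2) * sign])
            for name, el, off in _BACKBONE_OFFSETS:
                add(name, el, resname, resid, chain,
                    res_origin + np.asarray(off) * np.array([sign, 1.0, 1.0]))
            if resname == "GLU":
                # side chain reaches to the dimer center
                for name, el, off in _GLU_SIDECHAIN:
                    pos = res_origin + np.asarray(off) * np.array([sign, 1.0, 1.0])
                    add(name, el, resname, resid, chain, pos)
    # pull the two carboxyl groups to the center so their midpoint is ~origin
    names = np.array([a.name for a in atoms])
    chains = np.array([a.chain_id for a in atoms])
    resids = np.array([a.residue_id for a in atoms])
    for chain, sign in (("A", -1.0), ("B", 1.0)):
        sel = (chains == chain) & (resids == 14) & np.isin(names, ["CD", "OE1", "OE2"])
        target = {"CD": np.array([sign * 0.22, 0.0, -0.05]),
                  "OE1": np.array([sign * 0.12, 0.05, 0.10]),
                  "OE2": np.array([sign * 0.12, -0.10, -0.12])}
        for i in np.flatnonzero(sel):
            base[i] = target[atoms[i].name]

    z_phos = 1.55
    pid = 200
    for zsign in (1.0, -1.0):
        for gx in (-1.3, -0.45, 0.45, 1.3):
            for gy in (-0.9, 0.9):
                add("P", "P", "LIP", pid, "M", (gx, gy, zsign * z_phos))
                pid += 1

    # water wire from OE1 of chain A (at x=-0.12) straight up past z_phos
    wire_resids = []
    resid = 100
    oe1_a = np.array([-0.12, 0.05, 0.10])
    n_wire = 6
    for i in range(1, n_wire + 1):
        o = oe1_a + np.array([0.0, 0.0, WIRE_SPACING * i])
        prev = oe1_a + np.array([0.0, 0.0, WIRE_SPACING * (i - 1)])
        coords = _water_coords(o, prev - o, rng)
        for (name, el), pos in zip([("OW", "O"), ("HW1", "H"), ("HW2", "H")], coords):
            add(name, el, "SOL", resid, "W", pos)
        wire_resids.append(resid)
        resid += 1

    # seven cavity waters on a ring below the carboxyl midpoint; together
    # with the first wire water that is 8 waters inside the 0.6 nm cavity
    cavity_resids = [wire_resids[0]]
    for j in range(7):
        theta = 2 * np.pi * j / 7
        o = np.array([0.45 * np.cos(theta), 0.45 * np.sin(theta), -0.15])
        coords = _water_coords(o, rng.normal(size=3), rng)
        for (name, el), pos in zip([("OW", "O"), ("HW1", "H"), ("HW2", "H")], coords):
            add(name, el, "SOL", resid, "W", pos)
        cavity_resids.append(resid)
        resid += 1

    # tetrahedral mock ligand in the upper solvent
    lig_center = np.array([1.0, 1.0, 2.2])
    add("P1", "P", "PPH", 300, "L", lig_center)
    for j, d in enumerate([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]):
        add(f"C{j + 1}", "C", "PPH", 300, "L",
            lig_center + 0.18 * np.asarray(d) / np.sqrt(3.0))

    topology = Topology(atoms)
    base_arr = np.array(base)
    box = np.array([5.0, 5.0, 6.0])
    frames = [Frame(base_arr + rng.normal(scale=jitter, size=base_arr.shape),
                    box, time=0.1 * f) for f in range(n_frames)]
    facts = {
        "phosphate_z": (z_phos, -z_phos),
        "cavity_water_resids": sorted(cavity_resids),
        "wire_water_resids": wire_resids,
        "open_direction": "up",
        "ligand_central_atom": "P1",
    }
    return Trajectory(topology, frames), facts
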