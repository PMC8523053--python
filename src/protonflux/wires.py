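"""Hydrogen-bond detection and graph search for continuous Grotthuss water wires.

A Grotthuss wire is an unbroken chain of hydrogen-bonded waters linking a
proton donor/acceptor site (here: the carboxyl oxygens of a central
glutamate) to bulk solvent, i.e. to water above (or below) the bilayer
phosphate level.  H-bonds use the standard geometric criteria of a
donor–acceptor distance ≤ 0.35 nm and an acceptor–proton–donor angle
≥ 120° (the angle vertex is the proton; 180° is a perfectly linear bond).

Wire edges are undirected: the search establishes H-bond *connectivity*,
not proton-hop directionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .core import (Frame, SelectionError, Topology, Trajectory, WATER_RESNAMES,
                   min_image_distance, min_image_vector, wrap_coordinates)

#: covalent O/N–H distance bound used to assign protons to donors, nm
PROTON_COVALENT_CUTOFF = 0.125


class ConfigurationError(ValueError):
    """A donor selection has no resolvable protons, or similar setup defects."""


class LeafletError(ValueError):
    """Phosphate atoms do not split into two leaflets."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond thresholds (defaults: 0.35 nm, 120°)."""

    max_donor_acceptor_distance: float = 0.35
    min_acceptor_proton_donor_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance threshold must be positive")
        if not 0 < self.min_acceptor_proton_donor_angle <= 180:
            raise ValueError("angle threshold must lie in (0, 180]")


@dataclass(frozen=True, order=True)
class HBond:
    donor_atom: int
    proton_atom: int
    acceptor_atom: int
    frame_index: int = 0


@dataclass
class WireSearchConfig:
    """Source selection + target side for the wire search.

    ``direction="up"`` targets waters above the upper phosphate level,
    ``"down"`` waters below the lower one.
    """

    source_selection: str
    direction: str = "up"
    phosphate_selection: str = "name P"
    water_resnames: frozenset[str] = frozenset(WATER_RESNAMES)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class WireResult:
    frame_index: int
    found: bool
    path: list[int] = field(default_factory=list)  # water residue ids, source→target


@dataclass
class WirePresenceSeries:
    """Binary per-frame wire presence plus its Gaussian-smoothed version."""

    times: np.ndarray
    presence: np.ndarray
    smoothed: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Proton assignment and H-bond detection
# ---------------------------------------------------------------------------

def assign_protons(topology: Topology, frame: Frame,
                   donor_indices: np.ndarray) -> dict[int, list[int]]:
    """Map each donor heavy atom to the hydrogens covalently attached to it.

    A hydrogen belongs to a donor when it is in the same residue and within
    0.125 nm (minimum image).  Explicit hydrogens are required.
    """
    h_mask = np.char.upper(topology.elements.astype(str)) == "H"
    h_indices = np.flatnonzero(h_mask)
    out: dict[int, list[int]] = {}
    for d in np.asarray(donor_indices, dtype=int):
        same_res = (topology.residue_ids[h_indices] == topology.residue_ids[d]) & \
                   (topology.chain_ids[h_indices] == topology.chain_ids[d])
        cand = h_indices[same_res]
        if cand.size:
            dist = min_image_distance(frame.coordinates[d], frame.coordinates[cand],
                                      frame.box)
            out[int(d)] = [int(h) for h in cand[dist <= PROTON_COVALENT_CUTOFF]]
        else:
            out[int(d)] = []
    return out


def _angle_at_proton(frame: Frame, donor: int, proton: int, acceptor: int) -> float:
    """Acceptor–proton–donor angle in degrees (minimum-image vectors)."""
    x = frame.coordinates
    v1 = min_image_vector(x[proton], x[donor], frame.box)
    v2 = min_image_vector(x[proton], x[acceptor], frame.box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(topology: Topology, frame: Frame,
                  donors: np.ndarray, acceptors: np.ndarray,
                  criteria: HBondCriteria = HBondCriteria(),
                  frame_index: int = 0,
                  require_protons: bool = True) -> set[HBond]:
    """All H-bonds between donor heavy atoms and acceptors in one frame.

    A bond is reported iff the donor–acceptor minimum-image distance is
    within the cutoff and at least one donor proton makes an
    acceptor–proton–donor angle at or above the threshold.  Neighbour
    search uses a periodic k-d tree; geometry is evaluated per candidate
    pair.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return set()
    protons = assign_protons(topology, frame, donors)
    if require_protons:
        bare = [d for d, hs in protons.items() if not hs]
        if bare:
            labels = sorted({
                f"{topology.chain_ids[d]}/{topology.residue_names[d]}"
                f"{topology.residue_ids[d]}" for d in bare})
            raise ConfigurationError(
                f"donor atoms without attached hydrogens in residues: {labels}"
            )
    box = frame.box
    acc_tree = cKDTree(wrap_coordinates(frame.coordinates[acceptors], box),
                       boxsize=box)
    don_wrapped = wrap_coordinates(frame.coordinates[donors], box)
    neighbor_lists = acc_tree.query_ball_point(
        don_wrapped, criteria.max_donor_acceptor_distance)
    bonds: set[HBond] = set()
    for di, neigh in zip(donors, neighbor_lists):
        hs = protons.get(int(di), [])
        if not hs:
            continue
        for aj in neigh:
            ai = int(acceptors[aj])
            if ai == di or ai in hs:
                continue
            for h in hs:
                if _angle_at_proton(frame, di, h, ai) >= \
                        criteria.min_acceptor_proton_donor_angle:
                    bonds.add(HBond(int(di), int(h), ai, frame_index))
                    break
    return bonds


# ---------------------------------------------------------------------------
# Water identification and the wire graph
# ---------------------------------------------------------------------------

def water_molecules(topology: Topology,
                    resnames: Iterable[str] = WATER_RESNAMES
                    ) -> dict[int, tuple[int, list[int]]]:
    """Map water residue id -> (oxygen index, hydrogen indices).

    A water is any residue with a matching name containing exactly one
    oxygen; ions and malformed residues are skipped.
    """
    resnames = set(resnames)
    out: dict[int, tuple[int, list[int]]] = {}
    for chain, resid, resname, idx in topology.residues():
        if resname not in resnames:
            continue
        els = np.char.upper(topology.elements[idx].astype(str))
        ox = idx[els == "O"]
        hyd = idx[els == "H"]
        if ox.size == 1:
            out[int(resid)] = (int(ox[0]), [int(h) for h in hyd])
    return out


def phosphate_level(topology: Topology, frame: Frame,
                    phosphate_selection: str = "name P") -> tuple[float, float]:
    """Mean z of the phosphate atoms in each leaflet: (z_upper, z_lower).

    Leaflets are partitioned by the sign of z relative to the overall
    phosphate mean; an empty leaflet raises :class:`LeafletError`.
    """
    idx = topology.select(phosphate_selection)
    if idx.size == 0:
        raise SelectionError(f"phosphate selection {phosphate_selection!r} is empty")
    z = frame.coordinates[idx, 2]
    mid = z.mean()
    upper, lower = z[z > mid], z[z <= mid]
    if upper.size == 0 or lower.size == 0 or np.allclose(z, z[0]):
        raise LeafletError("phosphate atoms do not form two leaflets")
    return float(upper.mean()), float(lower.mean())


def build_water_graph(topology: Topology, frame: Frame,
                      criteria: HBondCriteria,
                      source_atoms: np.ndarray,
                      target_test: Callable[[float], bool],
                      water_resnames: Iterable[str] = WATER_RESNAMES,
                      frame_index: int = 0) -> nx.Graph:
    """Undirected wire-connectivity graph for one frame.

    Nodes are water residue ids plus the virtual ``"SOURCE"`` and
    ``"TARGET"``.  Two waters are joined iff a qualifying H-bond links them
    in either direction; SOURCE joins waters H-bonded to any source atom
    (again either direction, since a protonated source can donate and a
    carboxylate can only accept); TARGET joins waters whose oxygen passes
    the z test.
    """
    waters = water_molecules(topology, water_resnames)
    g = nx.Graph()
    g.add_nodes_from(waters)
    g.add_node("SOURCE")
    g.add_node("TARGET")
    if not waters:
        return g
    resids = np.array(sorted(waters))
    oxy = np.array([waters[r][0] for r in resids])
    o_by_atom = {int(o): int(r) for r, o in zip(resids, oxy)}

    # water–water: waters donate to water oxygens
    ww = detect_hbonds(topology, frame, oxy, oxy, criteria,
                       frame_index=frame_index)
    for b in ww:
        r1, r2 = o_by_atom[b.donor_atom], o_by_atom[b.acceptor_atom]
        if r1 != r2:
            g.add_edge(r1, r2)

    source_atoms = np.asarray(source_atoms, dtype=int)
    # waters donating to source atoms
    ws = detect_hbonds(topology, frame, oxy, source_atoms, criteria,
                       frame_index=frame_index)
    for b in ws:
        g.add_edge(o_by_atom[b.donor_atom], "SOURCE")
    # protonated source atoms donating to water oxygens (skip bare acceptors)
    sw = detect_hbonds(topology, frame, source_atoms, oxy, criteria,
                       frame_index=frame_index, require_protons=False)
    for b in sw:
        g.add_edge(o_by_atom[b.acceptor_atom], "SOURCE")

    for r, (o, _) in waters.items():
        if target_test(float(frame.coordinates[o, 2])):
            g.add_edge(r, "TARGET")
    return g


def _lexicographic_shortest_path(g: nx.Graph) -> list[int] | None:
    """Shortest SOURCE→TARGET water path, ties broken by lowest residue ids."""
    if "SOURCE" not in g or "TARGET" not in g:
        return None
    try:
        ds = nx.single_source_shortest_path_length(g, "SOURCE")
        dt = nx.single_source_shortest_path_length(g, "TARGET")
    except nx.NetworkXError:  # pragma: no cover - nodes always present
        return None
    if "TARGET" not in ds:
        return None
    total = ds["TARGET"]
    path: list[int] = []
    node: object = "SOURCE"
    for step in range(1, total):
        candidates = [n for n in g.neighbors(node)
                      if n not in ("SOURCE", "TARGET")
                      and ds.get(n) == step and dt.get(n) == total - step]
        node = min(candidates)  # residue ids are ints; deterministic tie-break
        path.append(int(node))
    return path


def find_wire(topology: Topology, frame: Frame, config: WireSearchConfig,
              criteria: HBondCriteria = HBondCriteria(),
              frame_index: int = 0) -> WireResult:
    """Search one frame for a continuous water wire from source to bulk."""
    source = topology.select(config.source_selection)
    if source.size == 0:
        raise SelectionError(f"source selection {config.source_selection!r} is empty")
    z_upper, z_lower = phosphate_level(topology, frame, config.phosphate_selection)
    if config.direction == "up":
        target_test = lambda z: z > z_upper
    else:
        target_test = lambda z: z < z_lower
    g = build_water_graph(topology, frame, criteria, source, target_test,
                          config.water_resnames, frame_index)
    path = _lexicographic_shortest_path(g)
    if path is None:
        # direct SOURCE–TARGET contact is impossible (they never share an edge)
        return WireResult(frame_index, False, [])
    return WireResult(frame_index, True, path)


def wire_fraction(trajectory: Trajectory, config: WireSearchConfig,
                  criteria: HBondCriteria = HBondCriteria(),
                  group_by: Sequence[object] | None = None):
    """Fraction of frames with a continuous wire, overall or per group label.

    With ``group_by`` (one label per frame, e.g. the umbrella window), a
    dict label -> fraction is returned; empty groups are skipped.
    """
    found = np.array([
        find_wire(trajectory.topology, f, config, criteria, i).found
        for i, f in enumerate(trajectory.frames)
    ])
    if group_by is None:
        return float(found.mean())
    group_by = list(group_by)
    if len(group_by) != trajectory.n_frames:
        raise ValueError("group_by must provide one label per frame")
    out = {}
    for label in dict.fromkeys(group_by):  # preserve first-seen order
        mask = np.array([g == label for g in group_by])
        out[label] = float(found[mask].mean())
    return out


def presence_series(trajectory: Trajectory, config: WireSearchConfig,
                    criteria: HBondCriteria = HBondCriteria(),
                    kernel_sigma: float | None = None) -> WirePresenceSeries:
    """Per-frame wire presence with optional Gaussian smoothing.

    Default kernel width: 1% of the trajectory time span.
    """
    times = trajectory.times()
    presence = np.array([
        int(find_wire(trajectory.topology, f, config, criteria, i).found)
        for i, f in enumerate(trajectory.frames)
    ])
    if kernel_sigma is None:
        span = float(times[-1] - times[0]) if len(times) > 1 else 1.0
        kernel_sigma = max(span, 1e-9) * 0.01
    smoothed = smooth_presence(presence, kernel_sigma, times)
    return WirePresenceSeries(times, presence, smoothed)


def smooth_presence(presence: np.ndarray, kernel_sigma: float,
                    times: np.ndarray | None = None) -> np.ndarray:
    """Convolve a 0/1 presence series with a normalized Gaussian kernel.

    ``kernel_sigma`` is in time units when ``times`` is given (uniform
    spacing assumed), otherwise in samples.  Boundaries are reflected, so
    values stay in [0, 1] and the kernel mass is conserved.
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    presence = np.asarray(presence, dtype=float)
    sigma_samples = kernel_sigma
    if times is not None and len(times) > 1:
        dt = float(np.mean(np.diff(times)))
        sigma_samples = kernel_sigma / dt
    return gaussian_filter1d(presence, sigma_samples, mode="reflect")
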