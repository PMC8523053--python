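"""PCA of protein–protein hydrogen-bond occupancy and gain/change/lose
classification of bonds between trajectory segments.

The featurization is a frames × bonds binary occupancy matrix (bond present
or absent under geometric criteria).  Columns are mean-centred but *not*
variance-scaled before PCA — occupancies already share the [0, 1] scale and
scaling would inflate rarely formed bonds.  Components carry a
deterministic sign convention (the largest-magnitude loading is positive)
so projections are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .core import Topology, Trajectory
from .wires import HBondCriteria, detect_hbonds

#: atom names counted as backbone for the backbone/sidechain bond flag
BACKBONE_ATOMS = {"N", "H", "HN", "CA", "HA", "C", "O", "OXT"}


class FeaturizationError(ValueError):
    """No bond columns survive the occupancy filter."""


@dataclass(frozen=True, order=True)
class BondId:
    """Canonical identity of one protein–protein hydrogen bond.

    Donor and acceptor are (chain, residue_id, atom_name) triples; the
    donor/acceptor roles are part of the identity (the same heavy-atom pair
    with swapped roles is a different bond), while the choice of proton is
    not, so a bond flickering between the two amine hydrogens keeps one id.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    kind: str  # backbone | sidechain | mixed

    def residues(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.donor[0], self.donor[1]), (self.acceptor[0], self.acceptor[1])

    def label(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{d[0]}{d[1]}:{d[2]}->{a[0]}{a[1]}:{a[2]}"


@dataclass
class OccupancyMatrix:
    bonds: list[BondId]
    values: np.ndarray  # (frames, bonds) of {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.bonds):
            raise ValueError("values must be a frames x bonds matrix")
        if len(set(self.bonds)) != len(self.bonds):
            raise ValueError("duplicate bond columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def occupancy(self) -> np.ndarray:
        """Per-bond mean occupancy over frames."""
        return self.values.mean(axis=0)


@dataclass
class PCAResult:
    bonds: list[BondId]
    components: np.ndarray               # (n_components, n_bonds), orthonormal
    projections: np.ndarray              # (frames, n_components)
    explained_variance_ratio: np.ndarray


def _bond_id(topology: Topology, donor: int, acceptor: int) -> BondId:
    d = (str(topology.chain_ids[donor]), int(topology.residue_ids[donor]),
         str(topology.names[donor]))
    a = (str(topology.chain_ids[acceptor]), int(topology.residue_ids[acceptor]),
         str(topology.names[acceptor]))
    d_bb = d[2] in BACKBONE_ATOMS
    a_bb = a[2] in BACKBONE_ATOMS
    kind = "backbone" if d_bb and a_bb else "sidechain" if not (d_bb or a_bb) else "mixed"
    return BondId(d, a, kind)


def build_occupancy(trajectory: Trajectory,
                    criteria: HBondCriteria = HBondCriteria(),
                    protein_only: bool = True,
                    min_occupancy: float = 0.01) -> OccupancyMatrix:
    """Frames × bonds occupancy of protein–protein hydrogen bonds.

    Donors are protein N/O atoms with attached hydrogens, acceptors protein
    N/O atoms; bonds within one residue are excluded, as are any involving
    water or ligand when ``protein_only``.  Bonds seen in fewer than
    ``min_occupancy`` of frames are dropped.
    """
    top = trajectory.topology
    if protein_only:
        heavy = top.select("protein and element N O")
    else:
        heavy = top.select("element N O")
    presence: dict[BondId, list[int]] = {}
    for i, frame in enumerate(trajectory.frames):
        bonds = detect_hbonds(top, frame, heavy, heavy, criteria,
                              frame_index=i, require_protons=False)
        for b in bonds:
            if top.residue_ids[b.donor_atom] == top.residue_ids[b.acceptor_atom] \
                    and top.chain_ids[b.donor_atom] == top.chain_ids[b.acceptor_atom]:
                continue
            presence.setdefault(_bond_id(top, b.donor_atom, b.acceptor_atom),
                                []).append(i)
    n = trajectory.n_frames
    kept = sorted(bid for bid, frames in presence.items()
                  if len(set(frames)) / n >= min_occupancy)
    if not kept:
        raise FeaturizationError(
            f"no hydrogen bond reaches the {min_occupancy:.0%} occupancy floor")
    values = np.zeros((n, len(kept)), dtype=np.int8)
    for j, bid in enumerate(kept):
        values[sorted(set(presence[bid])), j] = 1
    return OccupancyMatrix(kept, values)


def run_pca(matrix: OccupancyMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the mean-centred occupancy matrix (covariance eigendecomposition).

    Sign convention: each component is flipped, together with its
    projections, so that its largest-magnitude loading is positive.
    """
    x = matrix.values.astype(float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs more than one frame")
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("occupancy matrix has zero variance")
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    model = _SKPCA(n_components=n_components, svd_solver="full")
    projections = model.fit_transform(x)
    components = model.components_.copy()
    for k in range(components.shape[0]):
        peak = np.argmax(np.abs(components[k]))
        if components[k, peak] < 0:
            components[k] *= -1.0
            projections[:, k] *= -1.0
    return PCAResult(list(matrix.bonds), components, projections,
                     model.explained_variance_ratio_.copy())


def top_contributors(pca: PCAResult, component: int = 0,
                     n: int = 10) -> list[tuple[BondId, float]]:
    """Bonds ranked by |loading| on one component (full list when n is large)."""
    load = pca.components[component]
    order = np.argsort(-np.abs(load), kind="stable")
    return [(pca.bonds[i], float(load[i])) for i in order[:n]]


def residue_contributions(pca: PCAResult, component: int = 0
                          ) -> list[tuple[tuple[str, int], float]]:
    """Per-residue summed |loading| on one component, descending."""
    load = pca.components[component]
    agg: dict[tuple[str, int], float] = {}
    for bid, w in zip(pca.bonds, np.abs(load)):
        for res in bid.residues():
            agg[res] = agg.get(res, 0.0) + float(w)
    return sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))


def classify_bonds(segment_a: np.ndarray, segment_b: np.ndarray,
                   bonds: Sequence[BondId],
                   gain_threshold: float = 0.5) -> dict[BondId, str]:
    """Classify bonds between two trajectory segments.

    Per bond, Δ = mean occupancy in B − mean occupancy in A: ``gain`` when
    Δ ≥ threshold, ``lose`` when Δ ≤ −threshold, otherwise ``stable``.
    Bonds of a residue that both loses one partner and gains another above
    threshold (a partner swap) are relabelled ``change``.
    """
    a = np.asarray(segment_a, dtype=float)
    b = np.asarray(segment_b, dtype=float)
    if a.shape[1] != len(bonds) or b.shape[1] != len(bonds):
        raise ValueError("segments must share the bond columns")
    delta = b.mean(axis=0) - a.mean(axis=0)
    labels = {}
    for bid, d in zip(bonds, delta):
        labels[bid] = "gain" if d >= gain_threshold else \
                      "lose" if d <= -gain_threshold else "stable"
    # partner-swap detection at the residue level
    gained: dict[tuple[str, int], list[BondId]] = {}
    lost: dict[tuple[str, int], list[BondId]] = {}
    for bid, lab in labels.items():
        if lab in ("gain", "lose"):
            for res in bid.residues():
                (gained if lab == "gain" else lost).setdefault(res, []).append(bid)
    for res in set(gained) & set(lost):
        for bid in gained[res] + lost[res]:
            labels[bid] = "change"
    return labels


def write_loadings_tsv(path, pca: PCAResult) -> None:
    with open(path, "w") as fh:
        ncomp = pca.components.shape[0]
        cols = "\t".join(f"PC{k + 1}" for k in range(ncomp))
        fh.write(f"bond\tkind\t{cols}\n")
        for j, bid in enumerate(pca.bonds):
            vals = "\t".join(f"{pca.components[k, j]:.6f}" for k in range(ncomp))
            fh.write(f"{bid.label()}\t{bid.kind}\t{vals}\n")


def write_projections_tsv(path, pca: PCAResult) -> None:
    with open(path, "w") as fh:
        ncomp = pca.projections.shape[1]
        cols = "\t".join(f"PC{k + 1}" for k in range(ncomp))
        fh.write(f"frame\t{cols}\n")
        for i, row in enumerate(pca.projections):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
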