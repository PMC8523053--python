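"""3D ligand density maps around the protein, z-projections and per-ligand
z traces.

Frames are rigid-body superposed (least squares, Kabsch) on the alpha
carbons of the protein selection in the first frame before binning — a
spatial density is only meaningful in the protein's own frame of
reference.  Grids are written in OpenDX format for molecular viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Frame, SelectionError, Topology, Trajectory, reaction_coordinate_z


@dataclass
class DensityGrid:
    """Voxel counts on a regular grid (origin/spacing in nm).

    ``mode`` records the normalization applied by :meth:`values`:
    ``counts`` (raw), ``occupancy`` (counts per frame) or
    ``number_density`` (counts per frame per nm³).
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_frames: int
    mode: str = "occupancy"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.counts.ndim != 3 or 0 in self.counts.shape:
            raise ValueError("grid must be a non-empty 3D array")
        if self.mode not in ("counts", "occupancy", "number_density"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")

    def values(self) -> np.ndarray:
        if self.mode == "counts":
            return self.counts
        if self.mode == "occupancy":
            return self.counts / self.n_frames
        return self.counts / (self.n_frames * self.spacing ** 3)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of mobile onto reference.

    Returns (rotation, mobile_centroid, reference_centroid); apply as
    ``(x - mobile_centroid) @ rotation.T + reference_centroid``.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mc, rc


def superpose_frames(trajectory: Trajectory, align_indices: np.ndarray
                     ) -> list[np.ndarray]:
    """All-atom coordinates of every frame after superposing the alignment
    atoms onto their first-frame positions."""
    align_indices = np.asarray(align_indices, dtype=int)
    if align_indices.size == 0:
        raise SelectionError("alignment selection is empty")
    ref = trajectory.frames[0].coordinates[align_indices]
    out = []
    for frame in trajectory.frames:
        r, mc, rc = kabsch(frame.coordinates[align_indices], ref)
        out.append((frame.coordinates - mc) @ r.T + rc)
    return out


def _alignment_selection(topology: Topology, protein_selection: str) -> np.ndarray:
    """Alpha carbons of the protein selection; the full selection when the
    structure has no CA atoms (e.g. coarse mock systems)."""
    idx = topology.select(protein_selection)
    if idx.size == 0:
        raise SelectionError(f"protein selection {protein_selection!r} is empty")
    ca = idx[topology.names[idx] == "CA"]
    return ca if ca.size >= 3 else idx


def density3d(trajectory: Trajectory, atom_selection: str,
              spacing: float = 0.1, align_to: str | None = "protein",
              mode: str = "occupancy",
              bounds: tuple[np.ndarray, np.ndarray] | None = None) -> DensityGrid:
    """Accumulate the selected atoms' positions into a voxel grid.

    ``align_to`` names the protein selection used for superposition (None
    skips alignment); ``bounds`` fixes the grid extent (lower, upper
    corner), otherwise it is derived from the observations and padded to
    whole voxels.
    """
    sel = trajectory.topology.select(atom_selection)
    if sel.size == 0:
        raise SelectionError(f"selection {atom_selection!r} is empty")
    if align_to is not None:
        coords = superpose_frames(trajectory,
                                  _alignment_selection(trajectory.topology, align_to))
    else:
        coords = [f.coordinates for f in trajectory.frames]
    points = np.concatenate([c[sel] for c in coords])
    if bounds is None:
        lo = np.floor(points.min(axis=0) / spacing) * spacing
        hi = np.ceil(points.max(axis=0) / spacing + 1e-9) * spacing
        hi = np.maximum(hi, lo + spacing)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    nbins = np.maximum(np.round((hi - lo) / spacing).astype(int), 1)
    edges = [lo[d] + spacing * np.arange(nbins[d] + 1) for d in range(3)]
    counts, _ = np.histogramdd(points, bins=edges)
    return DensityGrid(origin=lo, spacing=spacing, counts=counts,
                       n_frames=trajectory.n_frames, mode=mode)


def project_z(grid: DensityGrid) -> tuple[np.ndarray, np.ndarray]:
    """Marginal z profile: (slab centers, values in the grid's mode).

    Raw counts are conserved: summing the projected counts equals the grid
    total.  ``number_density`` normalizes per slab volume (one voxel layer).
    """
    counts_z = grid.counts.sum(axis=(0, 1))
    nz = counts_z.size
    z = grid.origin[2] + grid.spacing * (np.arange(nz) + 0.5)
    if grid.mode == "counts":
        vals = counts_z
    elif grid.mode == "occupancy":
        vals = counts_z / grid.n_frames
    else:
        slab_volume = grid.counts.shape[0] * grid.counts.shape[1] * grid.spacing ** 3
        vals = counts_z / (grid.n_frames * slab_volume)
    return z, vals


def write_dx(path, grid: DensityGrid) -> None:
    """Write the grid (normalized per its mode) in OpenDX format."""
    from gridData import Grid

    g = Grid(grid.values(), origin=grid.origin,
             delta=np.full(3, grid.spacing))
    g.export(str(path), file_format="dx")


def ligand_z_traces(trajectory: Trajectory, ligand_selection: str,
                    protein_selection: str = "protein"
                    ) -> dict[int, np.ndarray]:
    """Per-ligand-atom time series of the translocation coordinate z.

    Keys are atom indices of the selected central atoms; use
    ``{k: v.min() for k, v in traces.items()}`` for entry-depth summaries.
    """
    lig = trajectory.topology.select(ligand_selection)
    if lig.size == 0:
        raise SelectionError(f"ligand selection {ligand_selection!r} is empty")
    prot = trajectory.topology.select(protein_selection)
    if prot.size == 0:
        raise SelectionError(f"protein selection {protein_selection!r} is empty")
    traces = {int(a): np.empty(trajectory.n_frames) for a in lig}
    for i, frame in enumerate(trajectory.frames):
        for a in lig:
            traces[int(a)][i] = reaction_coordinate_z(frame, trajectory.topology,
                                                      prot, int(a))
    return traces
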