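"""Binding-site water census, trapped-water detection and desolvation timing.

The "central cavity" of the transporter is operationalized as a sphere
around the midpoint of the two central-glutamate carboxyl carbons (default
radius 0.6 nm — the cavity has no sharp geometric definition, so the radius
is a parameter).  A water is *trapped* when one continuous residence
interval covers the final stretch of the trajectory; the desolvation time
of a wire-presence series is the start of its final all-zero quiescent
tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, SelectionError, Topology, Trajectory, min_image_distance
from .wires import WirePresenceSeries, water_molecules


@dataclass
class SiteDefinition:
    """Spherical binding-site probe around the midpoint of the anchor atoms."""

    anchor_selection: str
    radius: float = 0.6

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


@dataclass
class ResidenceRecord:
    water_residue_id: int
    intervals: list[tuple[int, int]] = field(default_factory=list)  # [enter, exit] frames, inclusive


def cavity_waters(topology: Topology, frame: Frame,
                  site: SiteDefinition) -> set[int]:
    """Water residue ids whose oxygen lies within the site sphere (min-image)."""
    anchors = topology.select(site.anchor_selection)
    if anchors.size == 0:
        raise SelectionError(f"site anchor selection {site.anchor_selection!r} is empty")
    center = frame.coordinates[anchors].mean(axis=0)
    waters = water_molecules(topology)
    if not waters:
        return set()
    resids = np.array(sorted(waters))
    oxy = np.array([waters[r][0] for r in resids])
    d = min_image_distance(center, frame.coordinates[oxy], frame.box)
    return {int(r) for r in resids[d <= site.radius]}


def residence_records(trajectory: Trajectory, site: SiteDefinition,
                      gap_tolerance: int = 0) -> dict[int, ResidenceRecord]:
    """Per-water residence intervals inside the site.

    Frame gaps of at most ``gap_tolerance`` frames outside the site do not
    break an interval (default 0: any exit ends the interval).
    """
    inside_per_frame = [cavity_waters(trajectory.topology, f, site)
                       for f in trajectory.frames]
    all_waters = sorted(set().union(*inside_per_frame)) if inside_per_frame else []
    out: dict[int, ResidenceRecord] = {}
    for w in all_waters:
        rec = ResidenceRecord(w)
        start = None
        last_in = None
        for i, inside in enumerate(inside_per_frame):
            if w in inside:
                if start is None:
                    start = i
                elif last_in is not None and i - last_in - 1 > gap_tolerance:
                    rec.intervals.append((start, last_in))
                    start = i
                last_in = i
        if start is not None:
            rec.intervals.append((start, last_in))
        out[w] = rec
    return out


def trapped_waters(trajectory: Trajectory, site: SiteDefinition,
                   min_residence: float, gap_tolerance: int = 0) -> set[int]:
    """Waters with one continuous stay covering the final ``min_residence`` ns."""
    times = trajectory.times()
    span = float(times[-1] - times[0])
    if min_residence > span and trajectory.n_frames > 1:
        raise ValueError(
            f"min_residence {min_residence} ns exceeds trajectory span {span} ns")
    cutoff_time = times[-1] - min_residence
    # first frame index whose time is >= cutoff
    start_frame = int(np.searchsorted(times, cutoff_time, side="left"))
    last = trajectory.n_frames - 1
    records = residence_records(trajectory, site, gap_tolerance)
    out = set()
    for w, rec in records.items():
        for a, b in rec.intervals:
            if a <= start_frame and b == last:
                out.add(w)
                break
    return out


def desolvation_time(series: WirePresenceSeries) -> float | None:
    """Earliest time from which wire presence stays zero to the end.

    Returns None when the last sample still shows a wire (no permanent
    desolvation).  Prepending additional presence=1 history does not change
    the result.
    """
    presence = np.asarray(series.presence)
    if presence.size == 0:
        raise ValueError("empty presence series")
    if presence[-1] != 0:
        return None
    nonzero = np.flatnonzero(presence)
    first_quiet = 0 if nonzero.size == 0 else int(nonzero[-1]) + 1
    return float(series.times[first_quiet])
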