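"""Umbrella-sampling window planning, WHAM unbiasing, profile consensus and
convergence batching.

The bias on a window centred at z0 with force constant k is U(z) =
½·k·(z−z0)², with k in kJ·mol⁻¹·nm⁻² (the GROMACS convention; note the ½
is part of the definition).  The default translocation plan divides the
pathway into a fine segment of 36 windows (−0.3 → 1.45 nm, 0.05 nm apart,
k = 5000) and a coarse bulk segment of 8 windows (1.6 → 3.0 nm, 0.2 nm
apart, k = 200).

WHAM solves the standard self-consistent equations on a 1D histogram

    p_b = Σ_i n_ib / Σ_i N_i exp[(f_i − U_i(z_b)) / kT]
    f_i = −kT ln Σ_b p_b exp(−U_i(z_b) / kT)

iterated in log space until the window free energies f_i move by less than
the tolerance (in kT).  The profile F(z) = −kT ln p_b is defined up to an
additive constant; empty bins stay NaN rather than being interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .core import KB, KCAL


class PlanError(ValueError):
    """Window spacing does not tile the requested range."""


class WhamError(RuntimeError):
    """WHAM cannot be estimated (e.g. disconnected histograms)."""


class AlignmentError(ValueError):
    """A profile has no finite values in the alignment reference region."""


@dataclass(frozen=True)
class WindowPlanSegment:
    z_start: float
    z_end: float
    spacing: float
    force_constant: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.z_end < self.z_start:
            raise ValueError("z_end must be >= z_start")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")


#: the two-segment translocation plan: 36 fine + 8 coarse windows
DEFAULT_PLAN = (
    WindowPlanSegment(-0.30, 1.45, 0.05, 5000.0),
    WindowPlanSegment(1.60, 3.00, 0.20, 200.0),
)


@dataclass
class UmbrellaWindow:
    center: float
    force_constant: float
    samples: np.ndarray
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class FreeEnergyProfile:
    """Binned free energy in kJ/mol, defined up to an additive constant."""

    bin_centers: np.ndarray
    values: np.ndarray
    uncertainty: np.ndarray | None = None
    converged: bool = True
    iterations: int = 0
    alignment: str = "min-zero"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must have equal length")
        if not np.any(np.isfinite(self.values)):
            raise ValueError("profile has no finite values")

    def shifted(self, delta: float) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.bin_centers, self.values - delta,
                                 self.uncertainty, self.converged,
                                 self.iterations, "custom")


def make_window_plan(segments: Sequence[WindowPlanSegment] = DEFAULT_PLAN
                     ) -> list[tuple[float, float]]:
    """Expand plan segments into (center, force_constant) pairs.

    Each segment contributes round((z_end−z_start)/spacing)+1 centres from
    z_start to z_end inclusive; a spacing that does not tile the range
    raises :class:`PlanError`.
    """
    plan: list[tuple[float, float]] = []
    for seg in segments:
        span = seg.z_end - seg.z_start
        n_steps = round(span / seg.spacing)
        if abs(n_steps * seg.spacing - span) > 1e-9 * max(1.0, abs(span)):
            raise PlanError(
                f"spacing {seg.spacing} does not tile [{seg.z_start}, {seg.z_end}]")
        for i in range(n_steps + 1):
            plan.append((seg.z_start + i * seg.spacing, seg.force_constant))
    return plan


def bias_potential(z: float | np.ndarray, center: float,
                   force_constant: float) -> float | np.ndarray:
    """Harmonic window bias ½·k·(z−center)² in kJ/mol."""
    return 0.5 * force_constant * (np.asarray(z, dtype=float) - center) ** 2


def _make_bins(windows: Sequence[UmbrellaWindow], bin_width: float,
               bin_range: tuple[float, float] | None) -> np.ndarray:
    if bin_range is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
    else:
        lo, hi = bin_range
    lo = np.floor(lo / bin_width) * bin_width
    hi = np.ceil(hi / bin_width) * bin_width
    n = max(1, int(round((hi - lo) / bin_width)))
    return lo + bin_width * np.arange(n + 1)


def _check_overlap(counts: np.ndarray, centers: Sequence[float]) -> None:
    """Warn on adjacent windows with no shared occupied bin; error if the
    occupancy graph is disconnected."""
    n_win = counts.shape[0]
    if n_win < 2:
        return
    occupied = counts > 0
    order = np.argsort(centers)
    for a, b in zip(order, order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            warnings.warn(
                f"umbrella windows at z={centers[a]:.3f} and z={centers[b]:.3f} "
                "share no occupied bin", stacklevel=3)
    # connected components of the shared-bin graph via label propagation
    labels = np.arange(n_win)
    changed = True
    while changed:
        changed = False
        for i in range(n_win):
            for j in range(i + 1, n_win):
                if np.any(occupied[i] & occupied[j]):
                    lo = min(labels[i], labels[j])
                    if labels[i] != lo or labels[j] != lo:
                        labels[labels == labels[i]] = lo
                        labels[labels == labels[j]] = lo
                        changed = True
    if len(set(labels.tolist())) > 1:
        raise WhamError("umbrella histograms form disconnected groups; "
                        "no overlap anywhere between them")


def wham(windows: Sequence[UmbrellaWindow], bin_width: float = 0.025,
         bin_range: tuple[float, float] | None = None,
         tolerance: float = 1e-6, max_iter: int = 100_000) -> FreeEnergyProfile:
    """Self-consistent WHAM over 1D harmonic umbrella windows.

    ``tolerance`` is on the window free energies f_i, in kT.  The returned
    profile is shifted so its minimum is zero; empty bins are NaN.  A
    non-converged run is returned flagged (``converged=False``) with the
    iteration count, not raised.
    """
    if not windows:
        raise ValueError("at least one window required")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError("all windows must share one temperature")
    kt = KB * windows[0].temperature
    edges = _make_bins(windows, bin_width, bin_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows],
                      dtype=float)
    _check_overlap(counts, [w.center for w in windows])
    n_i = counts.sum(axis=1)
    if np.any(n_i == 0):
        raise WhamError("a window has no samples inside the binning range")
    u = np.array([bias_potential(centers, w.center, w.force_constant)
                  for w in windows])  # (n_win, n_bins)
    total = counts.sum(axis=0)
    occupied = total > 0
    log_num = np.where(occupied, np.log(np.where(occupied, total, 1.0)), -np.inf)
    f = np.zeros(len(windows))
    log_n = np.log(n_i)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log Σ_i N_i exp[(f_i − U_ib)/kT]
        log_den = logsumexp(log_n[:, None] + (f[:, None] - u) / kt, axis=0)
        log_p = log_num - log_den
        log_p -= logsumexp(log_p[occupied])
        with np.errstate(divide="ignore"):
            f_new = -kt * logsumexp(log_p[None, occupied] - u[:, occupied] / kt,
                                    axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance * kt:
            converged = True
            break
    if not converged:
        warnings.warn(f"WHAM did not converge in {it} iterations "
                      f"(last |Δf| = {delta:.3g} kJ/mol)", stacklevel=2)
    values = np.full_like(centers, np.nan)
    values[occupied] = -kt * log_p[occupied]
    values -= np.nanmin(values)
    return FreeEnergyProfile(centers, values, converged=converged, iterations=it)


def align_profiles(profiles: Sequence[FreeEnergyProfile],
                   reference_region: tuple[float, float] = (2.5, np.inf)
                   ) -> list[FreeEnergyProfile]:
    """Shift each profile so its mean over the reference region is zero.

    The default region, z ≥ 2.5 nm, is the bulk-water plateau where all
    translocation profiles should agree.
    """
    lo, hi = reference_region
    out = []
    for ip, p in enumerate(profiles):
        mask = (p.bin_centers >= lo) & (p.bin_centers <= hi) & np.isfinite(p.values)
        if not np.any(mask):
            raise AlignmentError(
                f"profile {ip} has no finite values in reference region "
                f"[{lo}, {hi}]")
        out.append(p.shifted(float(p.values[mask].mean())))
    return out


def average_profiles(aligned: Sequence[FreeEnergyProfile],
                     require_shared_bins: bool = True) -> FreeEnergyProfile:
    """Consensus profile: per-bin mean over inputs, uncertainty = per-bin
    standard deviation across them (finite values only)."""
    if not aligned:
        raise ValueError("no profiles to average")
    ref = aligned[0].bin_centers
    for p in aligned[1:]:
        if p.bin_centers.shape != ref.shape or not np.allclose(p.bin_centers, ref):
            if require_shared_bins:
                raise ValueError("profiles must share one binning")
    stack = np.array([p.values for p in aligned])
    finite = np.isfinite(stack)
    n_fin = finite.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(n_fin > 0, np.nanmean(stack, axis=0), np.nan)
        std = np.where(n_fin > 1, np.nanstd(stack, axis=0, ddof=1), 0.0)
        std = np.where(n_fin > 0, std, np.nan)
    return FreeEnergyProfile(ref, mean, uncertainty=std, alignment="consensus")


def convergence_batches(windows: Sequence[UmbrellaWindow], n_batches: int = 6,
                        bin_width: float = 0.025,
                        tolerance: float = 1e-6,
                        max_iter: int = 100_000) -> list[FreeEnergyProfile]:
    """WHAM on cumulative chronological batches (batch 1, 1+2, ...).

    All batch profiles share the binning derived from the full data so they
    can be compared bin by bin.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    for w in windows:
        if len(w.samples) < n_batches:
            raise ValueError(
                f"window at z={w.center}: {len(w.samples)} samples cannot be "
                f"split into {n_batches} batches")
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    profiles = []
    for k in range(1, n_batches + 1):
        subset = []
        for w in windows:
            parts = np.array_split(w.samples, n_batches)
            subset.append(UmbrellaWindow(w.center, w.force_constant,
                                         np.concatenate(parts[:k]),
                                         w.temperature))
        profiles.append(wham(subset, bin_width, (lo, hi), tolerance, max_iter))
    return profiles


# ---------------------------------------------------------------------------
# Plain-text I/O (COLVAR-style samples; TSV profiles)
# ---------------------------------------------------------------------------

def read_colvar(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time, value) plain-text series; '#' lines skipped."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    return data[:, 0], data[:, 1]


def write_colvar(path: str | Path, times: np.ndarray, values: np.ndarray,
                 header: str = "time value") -> None:
    np.savetxt(path, np.column_stack([times, values]), header=header)


def write_profile_tsv(path: str | Path, profile: FreeEnergyProfile) -> None:
    """TSV columns: bin_center_nm, F_kJmol, F_kcalmol, uncertainty_kJmol."""
    unc = profile.uncertainty if profile.uncertainty is not None \
        else np.full_like(profile.values, np.nan)
    with open(path, "w") as fh:
        fh.write("bin_center_nm\tF_kJmol\tF_kcalmol\tuncertainty_kJmol\n")
        for z, v, e in zip(profile.bin_centers, profile.values, unc):
            fh.write(f"{z:.6f}\t{v:.6f}\t{v / KCAL:.6f}\t{e:.6f}\n")


def read_profile_tsv(path: str | Path) -> FreeEnergyProfile:
    data = np.loadtxt(path, skiprows=1)
    unc = data[:, 3] if data.shape[1] > 3 else None
    return FreeEnergyProfile(data[:, 0], data[:, 1], uncertainty=unc)
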