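"""Bennett-acceptance-ratio free energies and Henderson–Hasselbalch pKa shifts.

The alchemical protonation free energy ΔG of a glutamate inside the protein
is compared with the same transformation on a capped reference glutamate in
water; the difference ΔΔG converts to a pKa shift via

    ΔpKa = ΔΔG / (2.303·R·T),      pKa = 4.25 + ΔpKa

with R = 0.0083145 kJ·mol⁻¹·K⁻¹ and 4.25 the solution pKa of free glutamic
acid.  At T ≈ 300 K the slope is 0.174 pKa units per kJ/mol.  Sign
convention: a positive ΔΔG (protonation costs more in the protein than in
water) raises the pKa.

BAR solves the maximum-likelihood self-consistency

    Σ_F 1/(1+exp(β(w_F − C))) = Σ_R 1/(1+exp(β(w_R + C))),
    C = ΔG + kT·ln(n_R/n_F)

by bracketed root finding (the left-minus-right difference is strictly
monotone in C, so the root is unique); the standard error comes from
Bennett's asymptotic variance.  Here w_R is the *reverse* work (−ΔU on
state-B samples), so a perfectly reversible pair has w_R = −w_F and the
estimator is exactly antisymmetric under swapping the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .core import KB

GLU_REFERENCE_PKA = 4.25  # free glutamic acid in solution
LN10 = 2.303              # the conventional Henderson-Hasselbalch factor


class OverlapError(RuntimeError):
    """Forward and reverse work distributions do not overlap."""


@dataclass
class WorkSamples:
    """Endpoint energy differences in kJ/mol.

    ``forward``: ΔU = U_B − U_A evaluated on state-A samples.
    ``reverse``: the work for the reverse transformation, i.e. −ΔU
    evaluated on state-B samples (so a perfectly reversible process has
    forward ≈ −reverse sample by sample).
    """

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float).ravel()
        self.reverse = np.asarray(self.reverse, dtype=float).ravel()
        if self.forward.size == 0 or self.reverse.size == 0:
            raise ValueError("both work directions need at least one sample")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (np.all(np.isfinite(self.forward)) and np.all(np.isfinite(self.reverse))):
            raise ValueError("work samples must be finite")


@dataclass
class BARResult:
    delta_g: float
    std_err: float
    iterations: int
    converged: bool
    temperature: float


@dataclass
class PkaResult:
    pka: float
    delta_pka: float
    reference_pka: float
    temperature: float
    std_err: float | None = None  # pKa units, propagated from the BAR errors


def bar(samples: WorkSamples, tolerance: float = 1e-12,
        max_iter: int = 500) -> BARResult:
    """Bennett acceptance ratio ΔG (kJ/mol) from forward/reverse work samples."""
    kt = KB * samples.temperature
    beta = 1.0 / kt
    wf, wr = samples.forward, samples.reverse
    nf, nr = len(wf), len(wr)
    m = kt * np.log(nr / nf)

    def imbalance(dg: float) -> float:
        c = dg + m
        return expit(-beta * (wf - c)).sum() - expit(-beta * (wr + c)).sum()

    span = max(np.ptp(wf), np.ptp(wr), kt)
    lo = min(wf.min(), -wr.max()) - 10 * span - 50 * kt
    hi = max(wf.max(), -wr.min()) + 10 * span + 50 * kt
    flo, fhi = imbalance(lo), imbalance(hi)
    if not (flo < 0 < fhi or flo > 0 > fhi):
        raise OverlapError(
            "BAR self-consistency has no root: forward/reverse distributions "
            f"appear fully separated (f({lo:.3g})={flo:.3g}, f({hi:.3g})={fhi:.3g})")
    dg, res = brentq(imbalance, lo, hi, xtol=tolerance, maxiter=max_iter,
                     full_output=True)
    c = dg + m
    # Bennett asymptotic variance of beta*dG; underflowing Fermi weights mean
    # the two work distributions share no overlap and the estimate is void
    ff = expit(-beta * (wf - c))
    fr = expit(-beta * (wr + c))
    if np.mean(ff) ** 2 <= 0.0 or np.mean(fr) ** 2 <= 0.0:
        raise OverlapError(
            "forward/reverse work distributions do not overlap at the solution "
            f"C={c:.3g} kJ/mol (mean acceptance {np.mean(ff):.3g}/{np.mean(fr):.3g})")
    var = (np.mean(ff ** 2) / np.mean(ff) ** 2 - 1.0) / nf \
        + (np.mean(fr ** 2) / np.mean(fr) ** 2 - 1.0) / nr
    if not np.isfinite(var):
        raise OverlapError("BAR variance diverged: degenerate overlap")
    std_err = kt * np.sqrt(max(var, 0.0))
    return BARResult(float(dg), float(std_err), int(res.iterations),
                     bool(res.converged), samples.temperature)


def exponential_averaging(forward: np.ndarray, temperature: float) -> float:
    """Zwanzig one-sided estimate −kT ln⟨exp(−βw)⟩ (kJ/mol); used as an
    independent cross-check of BAR in the high-overlap limit."""
    kt = KB * temperature
    w = np.asarray(forward, dtype=float)
    shift = w.min()
    return float(shift - kt * np.log(np.mean(np.exp(-(w - shift) / kt))))


def ddg_to_dpka(delta_delta_g: float, temperature: float) -> float:
    """Convert ΔΔG (kJ/mol) to a pKa shift: ΔpKa = ΔΔG / (2.303·R·T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return delta_delta_g / (LN10 * KB * temperature)


def pka_from_legs(protein_leg: BARResult, reference_leg: BARResult | None = None,
                  temperature: float | None = None,
                  reference_pka: float = GLU_REFERENCE_PKA) -> PkaResult:
    """pKa of a protein glutamate from alchemical leg(s).

    Two entry modes:

    * two legs: ΔΔG = protein_leg.ΔG − reference_leg.ΔG;
    * combined-system construction (reference_leg=None): the protein and
      reference transformations were run together with swapped states, so
      protein_leg.ΔG *is* ΔΔG directly.
    """
    if reference_leg is not None:
        if abs(protein_leg.temperature - reference_leg.temperature) > 1e-9:
            raise ValueError("legs were computed at different temperatures")
        ddg = protein_leg.delta_g - reference_leg.delta_g
        var = protein_leg.std_err ** 2 + reference_leg.std_err ** 2
    else:
        ddg = protein_leg.delta_g
        var = protein_leg.std_err ** 2
    temp = temperature if temperature is not None else protein_leg.temperature
    dpka = ddg_to_dpka(ddg, temp)
    err = np.sqrt(var) / (LN10 * KB * temp)
    return PkaResult(pka=reference_pka + dpka, delta_pka=dpka,
                     reference_pka=reference_pka, temperature=temp,
                     std_err=float(err))


def read_work_samples(forward_path, reverse_path, temperature: float = 310.0
                      ) -> WorkSamples:
    """Load per-direction plain-text columns of energy differences (kJ/mol)."""
    fwd = np.loadtxt(forward_path, comments=("#", "@"), ndmin=1)
    rev = np.loadtxt(reverse_path, comments=("#", "@"), ndmin=1)
    if fwd.ndim > 1:
        fwd = fwd[:, -1]
    if rev.ndim > 1:
        rev = rev[:, -1]
    return WorkSamples(fwd, rev, temperature)
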