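"""Richardson extrapolation and grid-convergence-index (GCI) verification.

Implements the standard three-grid mesh-independence procedure: from
solution values (phi1, phi2, phi3) on fine/middle/coarse grids with
refinement ratios r21 = h2/h1 and r32 = h3/h2, estimate the apparent order
of convergence p, the Richardson-extrapolated grid-independent value, and
relative-error / GCI uncertainty measures.  The fixed-point equation for p
is sign-aware, so oscillatory convergence (epsilon ratios < 0) is handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class GridTriplet:
    """Fine/middle/coarse solution values and the two refinement ratios."""

    phi1: float
    phi2: float
    phi3: float
    r21: float
    r32: float

    def __post_init__(self) -> None:
        if not (self.r21 > 1.0 and self.r32 > 1.0):
            raise ValueError("refinement ratios must exceed 1")
        for name in ("phi1", "phi2", "phi3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ConvergenceReport:
    p_order: float
    phi_ext21: float
    phi_ext32: float
    ea21_pct: float
    ea32_pct: float
    eext21_pct: float
    eext32_pct: float
    gci_fine21_pct: float
    gci_middle32_pct: float


GCI_SAFETY_FACTOR = 1.25  # three-grid study convention


def apparent_order(t: GridTriplet, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Apparent order p from the sign-aware fixed-point iteration.

    Solves p = |ln|eps32/eps21| + q(p)| / ln(r21) with
    q(p) = ln((r21^p - s)/(r32^p - s)) and s = sign(eps32/eps21).
    Damped (0.5) when the iteration oscillates.
    """
    eps21 = t.phi2 - t.phi1
    eps32 = t.phi3 - t.phi2
    if eps21 == 0.0 or eps32 == 0.0:
        raise ValueError("grid-identical solutions: epsilon is zero")
    ratio = eps32 / eps21
    s = 1.0 if ratio > 0 else -1.0
    ln_r21 = math.log(t.r21)

    def step(p: float) -> float:
        q = math.log((t.r21**p - s) / (t.r32**p - s))
        return abs(abs(math.log(abs(ratio))) + q) / ln_r21

    p = abs(math.log(abs(ratio))) / ln_r21  # zeroth guess: q = 0
    p = max(p, 0.5)
    prev_delta = None
    for _ in range(max_iter):
        try:
            p_new = step(p)
        except ValueError as exc:  # log of non-positive argument
            raise ArithmeticError(f"apparent-order iteration failed at p={p}") from exc
        delta = p_new - p
        if prev_delta is not None and delta * prev_delta < 0:
            p_new = p + 0.5 * delta  # damp oscillation
            delta = p_new - p
        if abs(delta) < tol:
            return p_new
        prev_delta = delta
        p = p_new
    raise ArithmeticError(
        f"apparent-order iteration did not converge in {max_iter} steps (last p={p})"
    )


def richardson_extrapolate(t: GridTriplet, p: float) -> tuple[float, float]:
    """Extrapolated zero-spacing values for the fine and middle grid pairs."""
    r21p = t.r21**p
    r32p = t.r32**p
    if r21p == 1.0 or r32p == 1.0:
        raise ValueError("r^p equals 1: extrapolation undefined")
    phi_ext21 = (r21p * t.phi1 - t.phi2) / (r21p - 1.0)
    phi_ext32 = (r32p * t.phi2 - t.phi3) / (r32p - 1.0)
    return phi_ext21, phi_ext32


def error_measures(t: GridTriplet, p: float | None = None) -> ConvergenceReport:
    """Full convergence report: p, extrapolations, relative errors, GCI."""
    if p is None:
        p = apparent_order(t)
    if t.phi1 == 0.0 or t.phi2 == 0.0:
        raise ValueError("relative errors undefined for zero solution values")
    phi_ext21, phi_ext32 = richardson_extrapolate(t, p)
    ea21 = abs((t.phi1 - t.phi2) / t.phi1) * 100.0
    ea32 = abs((t.phi2 - t.phi3) / t.phi2) * 100.0
    eext21 = abs((phi_ext21 - t.phi1) / phi_ext21) * 100.0
    eext32 = abs((phi_ext32 - t.phi2) / phi_ext32) * 100.0
    gci21 = GCI_SAFETY_FACTOR * ea21 / (t.r21**p - 1.0)
    gci32 = GCI_SAFETY_FACTOR * ea32 / (t.r32**p - 1.0)
    return ConvergenceReport(
        p_order=p,
        phi_ext21=phi_ext21,
        phi_ext32=phi_ext32,
        ea21_pct=ea21,
        ea32_pct=ea32,
        eext21_pct=eext21,
        eext32_pct=eext32,
        gci_fine21_pct=gci21,
        gci_middle32_pct=gci32,
    )
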