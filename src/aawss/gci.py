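"""Grid-convergence-index (GCI) mesh and time-step verification.

Implements Roache's three-grid GCI procedure in the Celik et al. form
used for CFD verification reporting.  For element counts N1 > N2 > N3
(fine, medium, coarse) and a representative solution value phi on each
grid (here: mean TAWSS over the analyzed cardiac cycle):

    r21 = (N1/N2)^(1/3),   r32 = (N2/N3)^(1/3)
    eps21 = phi2 - phi1,   eps32 = phi3 - phi2,  s = sign(eps32/eps21)
    p = (1/ln r21) * | ln|eps32/eps21| + ln((r21^p - s)/(r32^p - s)) |
        (fixed point, solved iteratively)
    GCI21 = Fs * |phi1 - phi2|/|phi1| / (r21^p - 1) * 100%
    GCI32 = Fs * |phi2 - phi3|/|phi2| / (r32^p - 1) * 100%
    AR    = GCI32 / (r21^p * GCI21)    (close to 1 in the asymptotic range)

with safety factor Fs = 1.25 for a three-grid study.  The time-step check
is a plain percentage difference of the solution value at each step size
against the value at half that step size (finer-step denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GciStudy:
    """A fine/medium/coarse mesh triplet with its solution values."""
    n_elements: tuple      # (N1, N2, N3), fine > medium > coarse
    phi: tuple             # (phi1, phi2, phi3), e.g. mean TAWSS in Pa
    fs: float = 1.25

    def __post_init__(self):
        n1, n2, n3 = self.n_elements
        if not (n1 > n2 > n3 > 0):
            raise ValueError("element counts must satisfy N1 > N2 > N3 > 0")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi values must be finite")
        if self.fs <= 0:
            raise ValueError("safety factor must be positive")


@dataclass(frozen=True)
class GciResult:
    r21: float
    r32: float
    s: int
    p: float
    gci21: float     # percent
    gci32: float     # percent
    ar: float
    phi_extrapolated: float   # Richardson extrapolation (extra output)


def refinement_ratio(n_finer: float, n_coarser: float) -> float:
    """r = (N_finer / N_coarser)^(1/3) for 3-D meshes."""
    if n_finer <= 0 or n_coarser <= 0:
        raise ValueError("element counts must be positive")
    r = (n_finer / n_coarser) ** (1.0 / 3.0)
    if r <= 1.0:
        raise ValueError(f"refinement ratio {r:.4f} <= 1; "
                         "finer grid must have more elements")
    return r


def observed_order(study: GciStudy, tol: float = 1e-10,
                   max_iter: int = 200) -> tuple[float, int]:
    """Observed order of convergence p and the sign s of eps32/eps21,
    via damped fixed-point iteration."""
    p1, p2, p3 = study.phi
    e21 = p2 - p1
    e32 = p3 - p2
    if e21 == 0.0 or e32 == 0.0:
        raise ValueError("exact agreement between grids: order undefined")
    r21 = refinement_ratio(study.n_elements[0], study.n_elements[1])
    r32 = refinement_ratio(study.n_elements[1], study.n_elements[2])
    s = int(np.sign(e32 / e21))
    le = np.log(abs(e32 / e21))
    p = abs(le) / np.log(r21)   # initial guess ignoring the q-term
    for _ in range(max_iter):
        q = np.log((r21 ** p - s) / (r32 ** p - s))
        p_new = abs(le + q) / np.log(r21)
        # damping 0.5 guards against oscillation for s = -1 cases
        p_next = 0.5 * p + 0.5 * p_new
        if abs(p_next - p) < tol:
            p = p_next
            break
        p = p_next
    else:
        raise RuntimeError("observed-order fixed point did not converge")
    if not (p > 0 and np.isfinite(p)):
        raise RuntimeError(f"observed order p = {p} is not positive/finite")
    return float(p), s


def gci_pair(study: GciStudy, p: float) -> tuple[float, float]:
    """(GCI21, GCI32) in percent."""
    p1, p2, p3 = study.phi
    if p1 == 0.0 or p2 == 0.0:
        raise ValueError("phi1 and phi2 must be nonzero (relative error)")
    r21 = refinement_ratio(study.n_elements[0], study.n_elements[1])
    r32 = refinement_ratio(study.n_elements[1], study.n_elements[2])
    d21 = r21 ** p - 1.0
    d32 = r32 ** p - 1.0
    if d21 <= 0 or d32 <= 0:
        raise ValueError("r^p - 1 must be positive")
    g21 = study.fs * abs(p1 - p2) / abs(p1) / d21 * 100.0
    g32 = study.fs * abs(p2 - p3) / abs(p2) / d32 * 100.0
    return g21, g32


def asymptotic_range(gci21: float, gci32: float, r21: float, p: float) -> float:
    """AR = GCI32 / (r21^p * GCI21); values near 1 justify Fs = 1.25."""
    if gci21 == 0.0:
        raise ValueError("GCI21 = 0: asymptotic range undefined")
    return gci32 / (r21 ** p * gci21)


def analyze(study: GciStudy) -> GciResult:
    """Full pipeline: ratios, observed order, GCIs, AR and the Richardson
    extrapolate phi_ext = phi1 + (phi1 - phi2)/(r21^p - 1)."""
    r21 = refinement_ratio(study.n_elements[0], study.n_elements[1])
    r32 = refinement_ratio(study.n_elements[1], study.n_elements[2])
    p, s = observed_order(study)
    g21, g32 = gci_pair(study, p)
    ar = asymptotic_range(g21, g32, r21, p)
    phi1, phi2, _ = study.phi
    phi_ext = phi1 + (phi1 - phi2) / (r21 ** p - 1.0)
    return GciResult(r21=r21, r32=r32, s=s, p=p, gci21=g21, gci32=g32,
                     ar=ar, phi_extrapolated=phi_ext)


@dataclass(frozen=True)
class TimestepStudy:
    """Solution values at successively halved time steps."""
    dts: tuple      # strictly decreasing, each ~half the previous
    phi: tuple      # solution value (mean TAWSS, Pa) per dt

    def __post_init__(self):
        if len(self.dts) < 2:
            raise ValueError("need at least two time-step levels")
        if len(self.dts) != len(self.phi):
            raise ValueError("dts and phi must pair up")
        d = np.asarray(self.dts, dtype=float)
        if np.any(np.diff(d) >= 0):
            raise ValueError("time steps must be strictly decreasing")


def timestep_percent_diff(study: TimestepStudy,
                          halving_rtol: float = 0.05) -> dict[float, float]:
    """For each dt having a successor at dt/2:
    100 * |phi(dt) - phi(dt/2)| / phi(dt/2) (finer-step denominator).
    The smallest dt has no entry; non-halving successors are skipped."""
    out = {}
    for i, dt in enumerate(study.dts[:-1]):
        dt_next = study.dts[i + 1]
        if abs(dt_next - dt / 2.0) > halving_rtol * dt / 2.0:
            continue  # successor is not a halving; no comparison
        finer = study.phi[i + 1]
        out[dt] = 100.0 * abs(study.phi[i] - finer) / abs(finer)
    return out
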