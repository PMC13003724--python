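"""Per-node wall-shear-stress indices over one cardiac cycle.

Given the instantaneous WSS vector tau_w(t) sampled at each surface node,
the four indices are

    TAWSS = (1/T) * int_0^T |tau_w| dt                       (Pa)
    OSI   = 0.5 * (1 - |(1/T) int tau_w dt| / TAWSS)         (-)
    ECAP  = OSI / TAWSS                                      (1/Pa)
    RRT   = 1 / |(1/T) int tau_w dt|
          = 1 / ((1 - 2*OSI) * TAWSS)                        (1/Pa)

where |.| is the Euclidean norm of the 3-vector.  Time integration is
composite trapezoid on the uniform grid with both cycle endpoints; by
convention the *third* of three simulated cycles is analyzed, the first
two being discarded as transient wash-in.

OSI ranges from 0 (unidirectional shear) to 0.5 (zero-mean oscillatory
shear).  Nodes with TAWSS = 0 (no shear at all) leave OSI/ECAP undefined,
and a zero cycle-mean vector (OSI = 0.5) leaves RRT infinite; such nodes
are flagged rather than silently propagating NaN/inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import VesselMesh

#: display maxima used for contour reporting: TAWSS 5 Pa, OSI 0.5,
#: ECAP 2 Pa^-1, RRT 30.
DISPLAY_MAX = {"tawss": 5.0, "osi": 0.5, "ecap": 2.0, "rrt": 30.0}


@dataclass(frozen=True)
class CycleSpec:
    """Which cardiac cycle of a multi-cycle series to analyze."""
    period: float = 1.0
    dt: float = 0.01
    cycle_index: int = 3     # 1-based; default: third of three cycles

    def __post_init__(self):
        n = self.period / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("period/dt must be an integer")
        if self.cycle_index < 1:
            raise ValueError("cycle_index is 1-based and must be >= 1")

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period / self.dt))


@dataclass(frozen=True)
class WssSeries:
    """Per-node, per-time WSS 3-vectors tau (n_times, n_nodes, 3), Pa."""
    mesh: VesselMesh
    times: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if t.ndim != 1:
            raise ValueError("times must be 1-D")
        if tau.shape != (len(t), self.mesh.n_nodes, 3):
            raise ValueError(
                f"tau shape {tau.shape} != (n_times={len(t)}, "
                f"n_nodes={self.mesh.n_nodes}, 3)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(tau)):
            raise ValueError("tau contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "tau", tau)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class HemodynamicFields:
    """Per-node TAWSS/OSI/ECAP/RRT with degenerate-value flags."""
    mesh: VesselMesh
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray
    rrt: np.ndarray
    undefined_osi: np.ndarray   # TAWSS == 0: OSI/ECAP meaningless
    infinite_rrt: np.ndarray    # zero cycle-mean vector


def extract_cycle(series: WssSeries, spec: CycleSpec) -> WssSeries:
    """Slice out one cardiac cycle, returned with *both* endpoints
    (samples_per_cycle + 1 samples) for closed trapezoidal integration.

    If the series ends exactly at the last cycle's open end (n_cycles *
    samples_per_cycle samples, the usual periodic-sampling convention) the
    closing endpoint is supplied by periodicity: the cycle's first sample
    is repeated at t_end.
    """
    n = spec.samples_per_cycle
    i0 = (spec.cycle_index - 1) * n
    i1 = i0 + n
    if len(series.times) < i1:
        raise ValueError(
            f"series has {len(series.times)} samples; cycle "
            f"{spec.cycle_index} needs samples up to index {i1}")
    if abs(series.dt - spec.dt) > 1e-9:
        raise ValueError(f"series dt {series.dt} != spec dt {spec.dt}")
    if len(series.times) >= i1 + 1:
        times = series.times[i0:i1 + 1]
        tau = series.tau[i0:i1 + 1]
    else:  # close periodically
        times = np.r_[series.times[i0:i1], series.times[i0] + spec.period]
        tau = np.concatenate([series.tau[i0:i1], series.tau[i0:i0 + 1]])
    return WssSeries(mesh=series.mesh, times=times, tau=tau)


def _check_one_cycle(cycle: WssSeries) -> float:
    T = float(cycle.times[-1] - cycle.times[0])
    if T <= 0:
        raise ValueError("cycle must span positive duration")
    return T


def compute_tawss(cycle: WssSeries) -> np.ndarray:
    """(1/T) * trapezoid of the instantaneous WSS vector magnitude, Pa."""
    T = _check_one_cycle(cycle)
    mag = np.linalg.norm(cycle.tau, axis=2)
    return np.trapezoid(mag, cycle.times, axis=0) / T


def mean_wss_vector(cycle: WssSeries) -> np.ndarray:
    """(1/T) * trapezoid of the WSS vector, per node, (n_nodes, 3) Pa."""
    T = _check_one_cycle(cycle)
    return np.trapezoid(cycle.tau, cycle.times, axis=0) / T


def compute_osi(cycle: WssSeries, tawss: np.ndarray | None = None):
    """OSI per node plus an undefined-flag for TAWSS == 0 nodes."""
    if tawss is None:
        tawss = compute_tawss(cycle)
    mean_mag = np.linalg.norm(mean_wss_vector(cycle), axis=1)
    undefined = tawss == 0.0
    osi = np.zeros_like(tawss)
    np.divide(mean_mag, tawss, out=osi, where=~undefined)
    osi = np.where(undefined, 0.0, 0.5 * (1.0 - osi))
    # numerical guard: the ratio cannot exceed 1 analytically
    osi = np.clip(osi, 0.0, 0.5)
    return osi, undefined


def compute_ecap(tawss: np.ndarray, osi: np.ndarray):
    """ECAP = OSI / TAWSS (1/Pa); TAWSS == 0 nodes flagged undefined."""
    tawss = np.asarray(tawss, dtype=float)
    osi = np.asarray(osi, dtype=float)
    if tawss.shape != osi.shape:
        raise ValueError("tawss and osi shapes differ")
    undefined = tawss == 0.0
    ecap = np.zeros_like(tawss)
    np.divide(osi, tawss, out=ecap, where=~undefined)
    return ecap, undefined


def compute_rrt(cycle: WssSeries, tawss: np.ndarray | None = None,
                osi: np.ndarray | None = None, rtol: float = 1e-9):
    """RRT = 1 / |cycle-mean WSS vector| (1/Pa), cross-checked against the
    equivalent 1 / ((1 - 2*OSI) * TAWSS); zero-mean nodes flagged infinite."""
    if tawss is None:
        tawss = compute_tawss(cycle)
    if osi is None:
        osi, _ = compute_osi(cycle, tawss)
    mean_mag = np.linalg.norm(mean_wss_vector(cycle), axis=1)
    # a mean vector at rounding-noise level relative to TAWSS is zero
    # (OSI = 0.5): flag RRT infinite rather than returning 1/noise
    infinite = mean_mag <= 1e-12 * np.maximum(tawss, 1e-300)
    rrt = np.full_like(tawss, np.inf)
    np.divide(1.0, mean_mag, out=rrt, where=~infinite)

    alt = (1.0 - 2.0 * osi) * tawss       # must equal mean_mag
    ok = ~infinite & (tawss > 0)
    err = np.abs(alt[ok] - mean_mag[ok])
    tol = rtol * mean_mag[ok] + 1e-12 * tawss[ok]
    if np.any(err > tol):
        raise ValueError(
            "internal inconsistency between the direct and the "
            "(1-2*OSI)*TAWSS forms of RRT beyond tolerance")
    return rrt, infinite


def compute_fields(series: WssSeries,
                   spec: CycleSpec = CycleSpec()) -> HemodynamicFields:
    """All four indices on the requested cycle of a multi-cycle series."""
    cycle = extract_cycle(series, spec)
    tawss = compute_tawss(cycle)
    osi, undef = compute_osi(cycle, tawss)
    ecap, _ = compute_ecap(tawss, osi)
    rrt, inf_rrt = compute_rrt(cycle, tawss, osi)
    return HemodynamicFields(mesh=series.mesh, tawss=tawss, osi=osi,
                             ecap=ecap, rrt=rrt, undefined_osi=undef,
                             infinite_rrt=inf_rrt)


def clamp_for_report(fields: HemodynamicFields) -> HemodynamicFields:
    """Display copy with values clipped at the contour maxima
    (TAWSS 5 Pa, OSI 0.5, ECAP 2 Pa^-1, RRT 30); raw fields untouched."""
    return HemodynamicFields(
        mesh=fields.mesh,
        tawss=np.minimum(fields.tawss, DISPLAY_MAX["tawss"]),
        osi=np.minimum(fields.osi, DISPLAY_MAX["osi"]),
        ecap=np.minimum(fields.ecap, DISPLAY_MAX["ecap"]),
        rrt=np.minimum(fields.rrt, DISPLAY_MAX["rrt"]),
        undefined_osi=fields.undefined_osi,
        infinite_rrt=fields.infinite_rrt,
    )
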