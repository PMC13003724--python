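"""Synthetic pulsatile WSS fields with planted ground-truth risk lesions.

Stands in for a CFD solve: every node carries an axially aligned WSS
vector time series.  Outside lesions the shear is unidirectional (the
driving waveform scaled to a prescribed TAWSS, hence OSI = 0).  Inside a
lesion the node's signal is a sinusoidal carrier with a reversing
component,

    tau(t) = (c + d * sin(2 pi t / T)) * a_hat,

whose offset c and amplitude d are solved *per node* so that the discrete
trapezoid TAWSS and OSI of the emitted samples equal targets drawn from
the lesion's requested bins: c = (1 - 2*OSI*) * TAWSS* makes the cycle
mean exact, and d is found by root-finding the discrete mean-|.|
functional at TAWSS*.  Downstream metric computation therefore recovers
the planted values to solver precision rather than statistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mesh import VesselMesh
from .metrics import WssSeries
from .waveform import Waveform


def derived_ecap(tawss: float, osi: float) -> float:
    return osi / tawss


def derived_rrt(tawss: float, osi: float) -> float:
    return 1.0 / ((1.0 - 2.0 * osi) * tawss)


@dataclass(frozen=True)
class LesionSpec:
    """A circular geodesic patch with target index bins.

    ``target_bins`` maps each parameter to its (lo, hi) interval, e.g. the
    joint rupture criterion TAWSS (0, 0.5) Pa, OSI (0.35, 0.5),
    ECAP (1.6, 2.0) 1/Pa, RRT (24, 30).  The four bins must be mutually
    consistent under ECAP = OSI/TAWSS and RRT = 1/((1-2*OSI)*TAWSS);
    this is checked at construction.
    """
    center: tuple
    geodesic_radius: float
    tawss_bin: tuple = (0.0, 0.5)
    osi_bin: tuple = (0.35, 0.5)
    ecap_bin: tuple = (1.6, 2.0)
    rrt_bin: tuple = (24.0, 30.0)

    def __post_init__(self):
        if self.geodesic_radius <= 0:
            raise ValueError("geodesic_radius must be positive")
        if not self._feasible_grid().any():
            raise ValueError(
                "target bins admit no (TAWSS, OSI) satisfying "
                "ECAP = OSI/TAWSS and RRT = 1/((1-2*OSI)*TAWSS) "
                "within the requested ECAP/RRT bins")

    def _grid(self, n: int = 201):
        lo, hi = self.tawss_bin
        t = np.linspace(max(lo, 1e-6), hi, n)
        o = np.linspace(self.osi_bin[0], min(self.osi_bin[1], 0.5 - 1e-9), n)
        return np.meshgrid(t, o, indexing="ij")

    def _feasible_grid(self, n: int = 201):
        tt, oo = self._grid(n)
        ec = oo / tt
        rr = 1.0 / ((1.0 - 2.0 * oo) * tt)
        return ((ec >= self.ecap_bin[0]) & (ec <= self.ecap_bin[1]) &
                (rr >= self.rrt_bin[0]) & (rr <= self.rrt_bin[1]))

    def sample_targets(self, n: int, rng: np.random.Generator):
        """Draw n consistent (TAWSS*, OSI*) pairs uniformly from the
        feasible region of the bins (rejection sampling)."""
        out_t = np.empty(n)
        out_o = np.empty(n)
        got = 0
        tries = 0
        while got < n:
            tries += 1
            if tries > 10000:
                raise RuntimeError("rejection sampling failed to converge")
            m = max(4 * (n - got), 64)
            t = rng.uniform(max(self.tawss_bin[0], 1e-6), self.tawss_bin[1], m)
            o = rng.uniform(self.osi_bin[0], min(self.osi_bin[1], 0.5 - 1e-9), m)
            ec = o / t
            rr = 1.0 / ((1.0 - 2.0 * o) * t)
            ok = ((ec >= self.ecap_bin[0]) & (ec <= self.ecap_bin[1]) &
                  (rr >= self.rrt_bin[0]) & (rr <= self.rrt_bin[1]))
            k = min(int(ok.sum()), n - got)
            out_t[got:got + k] = t[ok][:k]
            out_o[got:got + k] = o[ok][:k]
            got += k
        return out_t, out_o


def _closed_cycle_phases(waveform: Waveform) -> np.ndarray:
    """Sample phases of one closed cycle (n+1 points incl. both endpoints),
    matching the discrete grid downstream metrics integrate over."""
    n = waveform.samples_per_cycle
    return 2.0 * np.pi * np.arange(n + 1) / n


def _trapmean_abs(c: float, d: float, sin_ph: np.ndarray) -> float:
    """Discrete trapezoid cycle-average of |c + d*sin| on the closed grid."""
    f = np.abs(c + d * sin_ph)
    return (0.5 * f[0] + f[1:-1].sum() + 0.5 * f[-1]) / (len(sin_ph) - 1)


def solve_carrier(tawss: float, osi: float, sin_ph: np.ndarray):
    """Offset c and reversing amplitude d such that the discrete metrics of
    c + d*sin reproduce (tawss, osi) exactly."""
    if not (0.0 <= osi < 0.5):
        raise ValueError("need 0 <= OSI < 0.5 for a finite-RRT carrier")
    if tawss <= 0:
        raise ValueError("TAWSS target must be positive")
    c = (1.0 - 2.0 * osi) * tawss
    if osi == 0.0:
        return c, 0.0
    lo, hi = c, max(2.0 * tawss, 2.0 * c)
    while _trapmean_abs(c, hi, sin_ph) < tawss:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("carrier amplitude bracket blew up")
    d = brentq(lambda d: _trapmean_abs(c, d, sin_ph) - tawss, lo, hi,
               xtol=1e-15, rtol=8.9e-16)
    return c, float(d)


def synth_wss_series(mesh: VesselMesh, waveform: Waveform,
                     base_tawss: float = 1.5,
                     lesions: list[LesionSpec] = (),
                     seed: int = 0,
                     base_variation: float = 0.05) -> WssSeries:
    """Three-cycle (or however many the waveform carries) per-node WSS
    vector series: unidirectional waveform-scaled shear at ``base_tawss``
    outside lesions, exact planted (TAWSS*, OSI*) carriers inside.

    Deterministic for a fixed seed.  Returns the planted ground truth in
    ``series.ground_truth`` — a dict with per-lesion node indices and
    per-node planted targets.
    """
    if base_tawss <= 0:
        raise ValueError("base_tawss must be positive")
    rng = np.random.default_rng(seed)
    axial = mesh.axial_directions()
    n_nodes = mesh.n_nodes
    nt = len(waveform.times)

    # background: waveform normalized to unit discrete cycle-mean |.|
    wabs = waveform.cycle_mean_abs()
    if wabs == 0:
        raise ValueError("waveform has zero mean magnitude")
    carrier = waveform.values / wabs
    base = base_tawss * (1.0 + base_variation * rng.uniform(-1, 1, n_nodes))

    scal = np.empty((nt, n_nodes))
    scal[:] = carrier[:, None] * base[None, :]

    sin_closed = np.sin(_closed_cycle_phases(waveform))
    n_cyc = waveform.samples_per_cycle
    phase_idx = np.arange(nt) % n_cyc   # exact cycle-periodic phases
    sin_open = np.sin(2.0 * np.pi * phase_idx / n_cyc)

    truth = {"lesions": []}
    claimed = np.zeros(n_nodes, dtype=bool)
    for spec in lesions:
        center_idx = int(np.argmin(np.linalg.norm(
            mesh.vertices - np.asarray(spec.center, dtype=float), axis=1)))
        nodes = mesh.geodesic_ball(center_idx, spec.geodesic_radius)
        nodes = nodes[~claimed[nodes]]
        if len(nodes) == 0:
            raise ValueError("lesion contains no mesh nodes")
        claimed[nodes] = True
        t_star, o_star = spec.sample_targets(len(nodes), rng)
        for j, node in enumerate(nodes):
            c, d = solve_carrier(t_star[j], o_star[j], sin_closed)
            scal[:, node] = c + d * sin_open
        truth["lesions"].append({
            "spec": spec, "center_node": center_idx,
            "nodes": nodes, "tawss": t_star, "osi": o_star,
            "ecap": derived_ecap(t_star, o_star),
            "rrt": derived_rrt(t_star, o_star)})

    tau = scal[:, :, None] * axial[None, :, :]
    series = WssSeries(mesh=mesh, times=waveform.times, tau=tau)
    object.__setattr__(series, "ground_truth", truth)
    return series
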