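"""Cardiac-cycle driving waveforms.

A :class:`Waveform` is a uniformly sampled periodic signal (velocity scale
or pressure-gradient scale) over an integer number of cardiac cycles.  The
default timing matches transient aortic CFD practice: period T = 1.0 s
sampled at dt = 0.01 s, three concatenated cycles (samples at
t = 0 ... 3 - dt; the closing endpoint is implied by periodicity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Waveform:
    period: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-15):
            raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    def cycle_mean(self) -> float:
        """Trapezoid average over one period, closed periodically."""
        n = self.samples_per_cycle
        closed = np.r_[self.values[:n], self.values[0]]
        return float(np.trapezoid(closed, dx=self.dt) / self.period)

    def cycle_mean_abs(self) -> float:
        n = self.samples_per_cycle
        closed = np.r_[np.abs(self.values[:n]), abs(self.values[0])]
        return float(np.trapezoid(closed, dx=self.dt) / self.period)


def make_waveform(kind: str = "generic_aortic", period: float = 1.0,
                  cycles: int = 3, dt: float = 0.01,
                  peak: float = 0.45, trough: float = 0.05,
                  systole_fraction: float = 0.35,
                  mean: float = 0.0, amplitude: float = 1.0,
                  value: float = 1.0) -> Waveform:
    """Build a periodic driving waveform.

    kind
        ``generic_aortic`` — parametric two-phase pulse: a single systolic
        half-sine peak occupying ``systole_fraction`` of the cycle over a
        diastolic low plateau at ``trough``; a stand-in for literature
        aortic velocity profiles whose numeric samples are not tabulated.
        The default 0.45 m/s peak puts a 2-cm-diameter vessel at a peak
        Reynolds number inside the transitional 2000-3000 band.
        ``sinusoid`` — ``mean + amplitude * sin(2 pi t / T)``.
        ``steady`` — constant ``value``.
    """
    if period <= 0 or dt <= 0:
        raise ValueError("period and dt must be positive")
    n = period / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"period/dt = {n} is not an integer sample count")
    n = int(round(n))
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    t = np.arange(n * cycles) * dt
    tc = np.arange(n) * dt     # one cycle, tiled: exact periodicity
    if kind == "steady":
        one = np.full(n, float(value))
    elif kind == "sinusoid":
        one = mean + amplitude * np.sin(2 * np.pi * tc / period)
    elif kind == "generic_aortic":
        ts = systole_fraction * period
        one = np.where(tc < ts,
                       trough + (peak - trough) * np.sin(np.pi * tc / ts),
                       trough)
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    return Waveform(period=period, times=t, values=np.tile(one, cycles))


def reynolds_number(mean_velocity: float, diameter: float,
                    density: float = 1047.0, viscosity: float = 0.0035) -> float:
    """Re = rho * U * D / mu, with blood density 1047 kg/m^3 and the
    Newtonian high-shear viscosity by default."""
    return density * mean_velocity * diameter / viscosity
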