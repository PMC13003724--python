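"""Womersley pulsatile pipe-flow wall shear stress.

Analytic oracle for pulsatile wall shear in a rigid straight tube of
radius R driven by an axial pressure gradient
G(t) = -dp/dz = Re{ sum_k A_k * exp(i * omega_k * t) }  (Pa/m),
with a Newtonian fluid (density rho, viscosity mu).  The velocity profile
for one harmonic is

    u(r, t) = Re{ (A / (i rho omega)) * (1 - J0(beta r)/J0(beta R)) e^{i omega t} },
    beta^2 = -i omega rho / mu,

and the wall shear stress exerted by the fluid on the wall along +z is

    tau_w(t) = Re{ (A / beta) * (J1(beta R)/J0(beta R)) * e^{i omega t} }.

A zero-frequency harmonic contributes the steady Poiseuille wall shear
A*R/2 (equivalently 4*mu*U/R for mean velocity U).  The Womersley number
alpha = R * sqrt(rho*omega/mu) controls the phase lag and the plug-like
flattening of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

BLOOD_DENSITY = 1047.0       # kg/m^3
BLOOD_VISCOSITY = 0.0035     # Pa*s, Newtonian high-shear limit


@dataclass(frozen=True)
class WomersleyConfig:
    """Harmonic decomposition of the driving pressure gradient.

    ``amplitudes`` are complex amplitudes A_k (Pa/m) paired with angular
    frequencies ``omegas`` (rad/s); omega = 0 denotes the steady component.
    """
    radius: float
    amplitudes: tuple = ()
    omegas: tuple = ()
    density: float = BLOOD_DENSITY
    viscosity: float = BLOOD_VISCOSITY

    def __post_init__(self):
        if self.radius <= 0 or self.density <= 0 or self.viscosity <= 0:
            raise ValueError("radius, density and viscosity must be positive")
        if len(self.amplitudes) != len(self.omegas):
            raise ValueError("amplitudes and omegas must pair up")
        if len(self.amplitudes) == 0:
            raise ValueError("at least one harmonic is required")

    def alpha(self, omega: float) -> float:
        """Womersley number for angular frequency omega."""
        return self.radius * np.sqrt(self.density * abs(omega) / self.viscosity)


def poiseuille_gradient(mean_velocity: float, radius: float,
                        viscosity: float = BLOOD_VISCOSITY) -> float:
    """Steady pressure gradient -dp/dz giving cross-section mean velocity U:
    G = 8 mu U / R^2 (then tau_w = G R / 2 = 4 mu U / R)."""
    return 8.0 * viscosity * mean_velocity / radius ** 2


def _beta(omega: float, rho: float, mu: float) -> complex:
    # principal square root of -i*omega*rho/mu
    return np.sqrt(complex(0.0, -omega) * rho / mu)


def womersley_wss(config: WomersleyConfig, times: np.ndarray) -> np.ndarray:
    """Wall shear stress time series (Pa, signed along +z) at the tube wall."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("times must be a 1-D array of at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
        raise ValueError("times must be uniform")
    tau = np.zeros_like(t)
    R = config.radius
    for k, (A, om) in enumerate(zip(config.amplitudes, config.omegas)):
        if om == 0:
            tau += np.real(A) * R / 2.0
            continue
        alpha = config.alpha(om)
        if alpha > 1e3:
            raise ValueError(
                f"harmonic {k}: Womersley number {alpha:.3g} too large for "
                "stable Bessel evaluation")
        b = _beta(om, config.density, config.viscosity)
        ratio = jv(1, b * R) / jv(0, b * R)
        tau += np.real((A / b) * ratio * np.exp(1j * om * t))
    return tau


def womersley_velocity(config: WomersleyConfig, r: np.ndarray,
                       t: float) -> np.ndarray:
    """Axial velocity profile u(r) at time t (for cross-checking the wall
    gradient by finite differences)."""
    r = np.asarray(r, dtype=float)
    R = config.radius
    u = np.zeros_like(r)
    for A, om in zip(config.amplitudes, config.omegas):
        if om == 0:
            G = np.real(A)
            u += G / (4.0 * config.viscosity) * (R ** 2 - r ** 2)
            continue
        b = _beta(om, config.density, config.viscosity)
        prof = 1.0 - jv(0, b * r) / jv(0, b * R)
        u += np.real(A / (1j * config.density * om) * prof * np.exp(1j * om * t))
    return u
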