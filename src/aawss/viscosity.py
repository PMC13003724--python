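"""Bird-Carreau shear-thinning blood viscosity.

mu(gdot) = mu_inf + (mu_0 - mu_inf) * [1 + (lambda*gdot)^2]^((n-1)/2)

The two plateaus are the physiological values for whole blood
(mu_0 = 0.056 Pa*s at vanishing shear, mu_inf = 0.0035 Pa*s at high shear);
the relaxation time ``lam`` and power index ``n`` default to the common
literature convention for blood (Cho & Kensey-type fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ViscosityModel:
    mu0: float = 0.056       # Pa*s, low-shear plateau
    mu_inf: float = 0.0035   # Pa*s, high-shear plateau
    lam: float = 3.313       # s
    n: float = 0.3568        # dimensionless, < 1 => shear thinning

    def __post_init__(self):
        if not (self.mu0 > self.mu_inf > 0):
            raise ValueError("require mu0 > mu_inf > 0")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def bird_carreau_viscosity(shear_rate, model: ViscosityModel = ViscosityModel()):
    """Apparent viscosity (Pa*s) at shear rate(s) gdot (1/s), gdot >= 0."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = model.mu_inf + (model.mu0 - model.mu_inf) * (
        1.0 + (model.lam * g) ** 2) ** ((model.n - 1.0) / 2.0)
    return mu if mu.ndim else float(mu)
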