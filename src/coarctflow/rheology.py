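"""Blood rheology: Carreau–Yasuda shear-thinning viscosity.

mu(gdot) = mu_inf + (mu_0 - mu_inf) * [1 + (lambda gdot)^a]^((n-1)/a)

interpolates between the zero-shear plateau mu_0 and the infinite-shear
plateau mu_inf; lambda sets the shear rate where thinning begins, a the
sharpness of the transition and n the power-law slope. The defaults are
the whole-blood constants commonly used in aortic CFD. A fixed-viscosity
Newtonian model is provided for verification against analytic solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CarreauYasudaParams:
    mu0: float = 0.16        # zero-shear viscosity, Pa s
    mu_inf: float = 0.0035   # infinite-shear viscosity, Pa s
    lam: float = 8.2         # relaxation time, s
    a: float = 0.64          # transition exponent
    n: float = 0.2128        # power index

    def __post_init__(self) -> None:
        if not (self.mu0 > self.mu_inf > 0):
            raise ValueError("need mu0 > mu_inf > 0")
        if self.lam <= 0 or self.a <= 0 or not 0 < self.n < 1:
            raise ValueError("need lambda > 0, a > 0 and 0 < n < 1")

    def viscosity(self, shear_rate) -> np.ndarray:
        return carreau_yasuda_viscosity(shear_rate, self)


@dataclass(frozen=True)
class NewtonianParams:
    mu: float = 0.0035  # Pa s

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")

    def viscosity(self, shear_rate) -> np.ndarray:
        return np.full_like(np.asarray(shear_rate, dtype=float), self.mu)


def carreau_yasuda_viscosity(shear_rate, params: CarreauYasudaParams) -> np.ndarray:
    """Effective viscosity (Pa s) at shear rate gdot (1/s), vectorized.

    Monotone non-increasing in gdot and bounded by [mu_inf, mu0]; raises on
    negative shear rates (the scalar shear rate is a tensor magnitude).
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * gdot) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    return mu if mu.ndim else float(mu)
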