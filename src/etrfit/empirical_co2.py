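"""Ye empirical model of the CO2 response of electron transport.

J(Ci) = alpha (1 - beta Ci) Ci / (1 + gamma Ci) + J0

rises from J0 at Ci = 0, peaks at the saturation CO2 concentration Cisat,
and declines beyond it (beta captures high-CO2 suppression of electron
transport, gamma the curvature of the initial rise).  Both the maximizer
and the maximum have closed forms:

    Cisat  = (sqrt((beta + gamma)/beta) - 1) / gamma
    Jf-max = alpha (sqrt(beta + gamma) - sqrt(beta))^2 / gamma^2 + J0

so the maximum fluorescence-observable electron transport rate J_f-max is
read directly off a fitted J-Ci curve without any electron-partitioning
assumption.  With beta = 0 the curve is monotone saturating and has no
interior maximum; that degenerate case raises :class:`NoMaximumError`.

The model is empirical: alpha, beta, gamma carry no agreed mechanistic
interpretation.  Its domain of validity is Ci in [0, 1/beta] (J falls back
to J0 at Ci = 1/beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NoMaximumError

__all__ = ["EmpiricalCO2Params", "jf_rate", "cisat", "jfmax"]


@dataclass(frozen=True)
class EmpiricalCO2Params:
    """Coefficients of the empirical J-Ci model.

    alpha: initial-slope coefficient, umol m-2 s-1 per (umol mol-1);
    beta, gamma_coef: (umol mol-1)^-1; j0: electron transport rate at
    Ci = 0, umol m-2 s-1.
    """

    alpha: float
    beta: float
    gamma_coef: float
    j0: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DomainError("alpha must be strictly positive")
        if self.beta < 0:
            raise DomainError("beta must be non-negative")
        if self.gamma_coef <= 0:
            raise DomainError("gamma_coef must be strictly positive")
        if self.j0 < 0:
            raise DomainError("j0 must be non-negative")

    @property
    def ci_validity_limit(self) -> float:
        """Upper end of the model's validity domain, 1/beta (inf if beta=0)."""
        return np.inf if self.beta == 0 else 1.0 / self.beta


def jf_rate(params: EmpiricalCO2Params, ci):
    """Electron transport rate alpha (1 - beta Ci) Ci / (1 + gamma Ci) + J0."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise DomainError("ci must be non-negative")
    out = (
        params.alpha * (1.0 - params.beta * ci) * ci / (1.0 + params.gamma_coef * ci)
        + params.j0
    )
    return out if out.ndim else float(out)


def cisat(params: EmpiricalCO2Params) -> float:
    """Saturation CO2 concentration: the unique interior maximizer of jf_rate."""
    if params.beta == 0:
        raise NoMaximumError("beta = 0: J-Ci curve is monotone, no Cisat")
    g = params.gamma_coef
    return (np.sqrt((params.beta + g) / params.beta) - 1.0) / g


def jfmax(params: EmpiricalCO2Params) -> float:
    """Maximum electron transport rate J_f-max = jf_rate(cisat)."""
    if params.beta == 0:
        raise NoMaximumError("beta = 0: J-Ci curve is monotone, no Jf-max")
    g = params.gamma_coef
    return (
        params.alpha * (np.sqrt(params.beta + g) - np.sqrt(params.beta)) ** 2 / g**2
        + params.j0
    )
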