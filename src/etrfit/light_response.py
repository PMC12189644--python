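"""Ye light-response model of net assimilation and the saturating irradiance.

An(I) = alpha_i (1 - beta_i I) I / (1 + gamma_i I) - Rd

is the irradiance analogue of the empirical J-Ci family: it rises from -Rd
in darkness, peaks at the saturating irradiance Isat, and declines beyond it
when photoinhibition (beta_i > 0) operates.  Isat is the irradiance at which
CO2-response curves are subsequently measured, and has the same closed form
as the CO2 maximizer:

    Isat = (sqrt((beta_i + gamma_i)/beta_i) - 1) / gamma_i

Rd is treated as a fitted parameter of the light curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NoMaximumError

__all__ = ["LightResponseParams", "an_light", "isat", "an_light_max"]


@dataclass(frozen=True)
class LightResponseParams:
    """alpha_i: apparent quantum yield (umol CO2 per umol photons);
    beta_i: photoinhibition coefficient, (umol m-2 s-1)^-1;
    gamma_i: curvature coefficient, (umol m-2 s-1)^-1;
    rd: day respiration, umol m-2 s-1."""

    alpha_i: float
    beta_i: float
    gamma_i: float
    rd: float

    def __post_init__(self) -> None:
        if self.alpha_i <= 0:
            raise DomainError("alpha_i must be strictly positive")
        if self.beta_i < 0:
            raise DomainError("beta_i must be non-negative")
        if self.gamma_i <= 0:
            raise DomainError("gamma_i must be strictly positive")


def an_light(params: LightResponseParams, i):
    """Net assimilation alpha_i (1 - beta_i I) I / (1 + gamma_i I) - Rd."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise DomainError("irradiance must be non-negative")
    out = (
        params.alpha_i * (1.0 - params.beta_i * i) * i / (1.0 + params.gamma_i * i)
        - params.rd
    )
    return out if out.ndim else float(out)


def isat(params: LightResponseParams) -> float:
    """Saturating irradiance: the interior maximizer of an_light."""
    if params.beta_i == 0:
        raise NoMaximumError("beta_i = 0: light curve is monotone, no Isat")
    g = params.gamma_i
    return (np.sqrt((params.beta_i + g) / params.beta_i) - 1.0) / g


def an_light_max(params: LightResponseParams) -> float:
    """Maximum net assimilation, an_light evaluated at Isat."""
    if params.beta_i == 0:
        raise NoMaximumError("beta_i = 0: light curve is monotone")
    g = params.gamma_i
    return (
        params.alpha_i
        * (np.sqrt(params.beta_i + g) - np.sqrt(params.beta_i)) ** 2
        / g**2
        - params.rd
    )
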