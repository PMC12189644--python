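"""Forward equations of the FvCB model of C3 net assimilation versus Ci.

The model takes net assimilation as the minimum of three candidate rates:

* ``ac_rate`` -- Rubisco (carboxylation) limited:
  ``Ac = Vcmax (Ci - Gamma*) / (Ci + Kc (1 + O/Ko)) - Rd``
* ``aj_rate`` -- RuBP-regeneration (electron transport) limited:
  ``Aj = J (Ci - Gamma*) / (a Ci + b Gamma*) - Rd``
* ``ap_rate`` -- triose-phosphate-utilization limited plateau:
  ``Ap = 3 TPU - Rd``

The pair ``(a, b)`` of electron-requirement coefficients selects the
sub-model: ``(4, 8)`` when RuBP regeneration is limited by NADPH alone,
``(4.5, 10.5)`` when NADPH and ATP co-limit, and ``(3, 7)`` when the
cytochrome b6f Q cycle raises the proton yield to H+/e- = 3.  Because the
denominator ``a Ci + b Gamma*`` differs between sub-models while the data do
not, the electron transport rate J fitted to the same A-Ci curve is larger
under (4.5, 10.5) than under (4, 8); at saturating irradiance that fitted J
is the maximum electron transport rate for assimilation, J_A-max.

The ratio a/b has a stoichiometric reading: writing the denominator as
``a (Ci + Gamma*/f)`` identifies ``f = a/b`` as the mol CO2 released in the
photorespiratory pathway per mol RuBP oxygenated (0.5 for the canonical
(4, 8) pair).  ``implied_f`` exposes that identity.

All concentrations are on an intercellular (Ci) basis; mesophyll conductance
is not modelled (infinite-gm convention).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "ElectronVariant",
    "SUBMODEL_I",
    "SUBMODEL_II",
    "QCYCLE",
    "variant_from_label",
    "FvCBParams",
    "LimitationState",
    "aj_rate",
    "invert_aj",
    "ac_rate",
    "ap_rate",
    "an_fvcb",
    "transition_ci",
    "implied_f",
]


@dataclass(frozen=True)
class ElectronVariant:
    """Electron-requirement coefficients (a, b) of the Aj denominator.

    ``a`` multiplies Ci (electrons per carboxylation), ``b`` multiplies
    Gamma* (electrons per oxygenation-driven CO2 release).  ``b > a`` is
    required so that Aj stays below its asymptote J/a - Rd.
    """

    a: float
    b: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise DomainError(
                f"electron-requirement coefficients must be positive, got "
                f"a={self.a}, b={self.b}"
            )
        if not self.b > self.a:
            raise DomainError(
                f"coefficient of Gamma* must exceed coefficient of Ci "
                f"(got a={self.a}, b={self.b})"
            )


#: NADPH-limited RuBP regeneration.
SUBMODEL_I = ElectronVariant(4.0, 8.0, "I")
#: NADPH and ATP co-limited RuBP regeneration.
SUBMODEL_II = ElectronVariant(4.5, 10.5, "II")
#: Q-cycle operating, H+/e- = 3.
QCYCLE = ElectronVariant(3.0, 7.0, "qcycle")

_BUILTIN_VARIANTS = {"I": SUBMODEL_I, "II": SUBMODEL_II, "qcycle": QCYCLE}


def variant_from_label(label: str) -> ElectronVariant:
    """Resolve ``"I" | "II" | "qcycle" | "custom:a,b"`` to an ElectronVariant."""
    if label in _BUILTIN_VARIANTS:
        return _BUILTIN_VARIANTS[label]
    if label.startswith("custom:"):
        try:
            a_str, b_str = label[len("custom:"):].split(",")
            return ElectronVariant(float(a_str), float(b_str), label)
        except (ValueError, TypeError) as exc:  # split or float failure
            raise DomainError(f"cannot parse variant label {label!r}") from exc
    raise DomainError(
        f"unknown variant label {label!r}; expected I, II, qcycle or custom:a,b"
    )


@dataclass(frozen=True)
class FvCBParams:
    """FvCB parameter set.

    Units: rates (vcmax, j, tpu, rd) in umol m-2 s-1; gamma_star and kc in
    umol mol-1; ko and o in mmol mol-1.  The Rubisco kinetic constants
    default to widely used 25 C values (kc = 404.9, ko = 278.4) with an
    ambient O2 mole fraction of 210 mmol mol-1.
    """

    vcmax: float
    j: float
    tpu: float
    rd: float
    gamma_star: float
    kc: float = 404.9
    ko: float = 278.4
    o: float = 210.0

    def __post_init__(self) -> None:
        for name in ("vcmax", "j", "tpu", "rd", "gamma_star", "kc", "ko", "o"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc (1 + O/Ko), umol mol-1."""
        return self.kc * (1.0 + self.o / self.ko)

    def with_(self, **kwargs) -> "FvCBParams":
        return replace(self, **kwargs)


class LimitationState(str, enum.Enum):
    """Which candidate rate is binding at a given Ci."""

    RUBISCO = "rubisco"
    RUBP = "rubp"
    TPU = "tpu"


def _check_variant(variant: ElectronVariant) -> None:
    if variant.a <= 0 or variant.b <= 0:
        raise DomainError("variant coefficients must be positive")


def aj_rate(j, ci, gamma_star, rd, variant: ElectronVariant = SUBMODEL_I):
    """Electron-transport-limited assimilation J(Ci-G*)/(a Ci + b G*) - Rd.

    Strictly increasing in Ci with horizontal asymptote J/a - Rd.
    Accepts scalars or numpy arrays for ``ci``.
    """
    _check_variant(variant)
    ci = np.asarray(ci, dtype=float)
    out = j * (ci - gamma_star) / (variant.a * ci + variant.b * gamma_star) - rd
    return out if out.ndim else float(out)


def invert_aj(a_obs, ci, gamma_star, rd, variant: ElectronVariant = SUBMODEL_I):
    """Exact algebraic inverse of :func:`aj_rate` for J.

    ``j = (a_obs + rd) (a Ci + b G*) / (Ci - G*)``; requires Ci > Gamma*.
    """
    _check_variant(variant)
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= gamma_star):
        raise DomainError("invert_aj requires ci > gamma_star")
    out = (a_obs + rd) * (variant.a * ci + variant.b * gamma_star) / (ci - gamma_star)
    return out if out.ndim else float(out)


def ac_rate(vcmax, ci, gamma_star, kc=404.9, ko=278.4, o=210.0, rd=0.0):
    """Rubisco-limited assimilation Vcmax (Ci-G*)/(Ci + Kc(1+O/Ko)) - Rd."""
    if min(vcmax, gamma_star, kc, ko, o) <= 0:
        raise DomainError("ac_rate parameters must be strictly positive")
    ci = np.asarray(ci, dtype=float)
    km = kc * (1.0 + o / ko)
    out = vcmax * (ci - gamma_star) / (ci + km) - rd
    return out if out.ndim else float(out)


def ap_rate(tpu, rd=0.0):
    """TPU-limited plateau 3 TPU - Rd, independent of Ci."""
    if tpu <= 0:
        raise DomainError("tpu must be strictly positive")
    return 3.0 * tpu - rd


def candidate_rates(params: FvCBParams, ci, variant: ElectronVariant = SUBMODEL_I):
    """The three candidate rates stacked as rows (rubisco, rubp, tpu)."""
    ci = np.atleast_1d(np.asarray(ci, dtype=float))
    ac = params.vcmax * (ci - params.gamma_star) / (ci + params.km) - params.rd
    aj = (
        params.j
        * (ci - params.gamma_star)
        / (variant.a * ci + variant.b * params.gamma_star)
        - params.rd
    )
    ap = np.full_like(ci, 3.0 * params.tpu - params.rd)
    return np.vstack([ac, aj, ap])


_STATE_ORDER = (LimitationState.RUBISCO, LimitationState.RUBP, LimitationState.TPU)


def an_fvcb(params: FvCBParams, ci, variant: ElectronVariant = SUBMODEL_I):
    """Net assimilation min(Ac, Aj, Ap) and the binding limitation state.

    Ties resolve with precedence RUBISCO < RUBP < TPU (argmin takes the
    first minimal row).  Returns ``(float, LimitationState)`` for scalar
    ``ci`` and ``(ndarray, list[LimitationState])`` for array input.
    """
    scalar = np.isscalar(ci) or np.ndim(ci) == 0
    rates = candidate_rates(params, ci, variant)
    idx = np.argmin(rates, axis=0)
    an = rates[idx, np.arange(rates.shape[1])]
    states = [_STATE_ORDER[i] for i in idx]
    if scalar:
        return float(an[0]), states[0]
    return an, states


def transition_ci(
    params: FvCBParams,
    variant: ElectronVariant,
    pair: str,
    ci_max: float = 2000.0,
    method: str = "bisect",
) -> Optional[float]:
    """Ci at which two adjacent candidate rates intersect.

    ``pair`` is ``"rubisco-rubp"`` (Ac = Aj) or ``"rubp-tpu"`` (Aj = Ap,
    the Ci,TPU transit point).  The crossing is located on
    ``(gamma_star, ci_max]`` by dense sign scan + Brent bisection to
    |delta A| < 1e-9; returns ``None`` when the rates do not cross in range
    (e.g. the electron-transport plateau never reaches 3 TPU).

    ``method="closed"`` is available for ``"rubp-tpu"``, where
    Aj = Ap has the closed form
    ``ci = gamma_star (3 TPU b + J) / (J - 3 TPU a)``.
    """
    g = params.gamma_star
    if pair == "rubp-tpu":
        if method == "closed":
            denom = params.j - 3.0 * params.tpu * variant.a
            if denom <= 0:
                return None
            ci = g * (3.0 * params.tpu * variant.b + params.j) / denom
            return ci if g < ci <= ci_max else None

        def diff(ci):
            return aj_rate(params.j, ci, g, params.rd, variant) - ap_rate(
                params.tpu, params.rd
            )

    elif pair == "rubisco-rubp":
        if method == "closed":
            raise DomainError("no closed form for the rubisco-rubp transition")

        def diff(ci):
            return ac_rate(
                params.vcmax, ci, g, params.kc, params.ko, params.o, params.rd
            ) - aj_rate(params.j, ci, g, params.rd, variant)

    else:
        raise DomainError(f"unknown transition pair {pair!r}")

    lo = g * (1.0 + 1e-9)
    grid = np.linspace(lo, ci_max, 4096)
    vals = np.array([diff(c) for c in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    root = brentq(diff, grid[i], grid[i + 1], xtol=1e-12)
    assert abs(diff(root)) < 1e-9
    return float(root)


def implied_f(b_coeff: float, a_coeff: float = 4.0) -> float:
    """Mol CO2 released per mol RuBP oxygenated implied by (a, b).

    Writing the Aj denominator as ``a (Ci + Gamma*/f)`` gives ``f = a/b``:
    0.5 for the canonical (4, 8) pair, and ~0.57 when b is tightened to
    about 7.02 so that the fitted J_A-max stays below the fluorescence
    J_f-max.
    """
    if b_coeff <= 0 or a_coeff <= 0:
        raise DomainError("coefficients must be strictly positive")
    return a_coeff / b_coeff
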