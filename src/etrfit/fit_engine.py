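"""Bounded least-squares fitting by simulated annealing with Metropolis
acceptance, followed by a deterministic derivative-free polish.

Any forward model above (FvCB A-Ci composition, empirical J-Ci, light
response) is wrapped as a :class:`ForwardModel` -- a named parameter vector
plus a vectorized predict function -- and handed to :func:`fit` together
with a :class:`FitConfig`.  The annealer proposes Gaussian steps (scale =
``step_frac`` of each bound width), reflects them back into the bounds, and
accepts with the Metropolis rule: a proposal that lowers the SSE is always
taken, one that raises it by dSSE is taken with probability
exp(-dSSE / T).  The temperature starts at the initial SSE (unless given)
and cools geometrically per sweep.  A Nelder-Mead polish (scipy) from the
best annealed point then makes the result a local SSE minimum, so repeated
runs with the same seed are bit-identical and results are robust to the
choice of seed.

Goodness of fit is reported as R^2 = 1 - SSE/SST.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.optimize import minimize

from . import empirical_co2, fvcb_model, light_response
from .errors import (
    DomainError,
    UndefinedRSquaredError,
    UnderdeterminedError,
    ValidationError,
)
from .gasx_io import CurveKind, ResponseCurve

__all__ = [
    "ForwardModel",
    "FitConfig",
    "FitResult",
    "fit",
    "r_squared",
    "metropolis_accept",
    "fvcb_aci_model",
    "empirical_jci_model",
    "light_response_model",
    "fit_fvcb",
    "fit_empirical",
    "fit_light",
]

# Generous physiological bounds (umol m-2 s-1 and umol mol-1 scales).
FVCB_BOUNDS = {
    "vcmax": (5.0, 500.0),
    "j": (10.0, 600.0),
    "tpu": (1.0, 60.0),
    "rd": (0.05, 10.0),
    "gamma_star": (20.0, 80.0),
}
EMPIRICAL_BOUNDS = {
    "alpha": (0.01, 10.0),
    "beta": (1e-5, 0.01),
    "gamma_coef": (1e-4, 0.05),
    "j0": (0.0, 200.0),
}
LIGHT_BOUNDS = {
    "alpha_i": (0.005, 0.2),
    "beta_i": (1e-6, 0.005),
    "gamma_i": (1e-4, 0.05),
    "rd": (0.05, 10.0),
}


@dataclass(frozen=True)
class ForwardModel:
    """A fittable forward model: named free parameters + predict(theta, x)."""

    name: str
    param_names: tuple[str, ...]
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray]
    default_bounds: dict[str, tuple[float, float]]
    kind: Optional[CurveKind] = None
    variant_label: Optional[str] = None
    # optional per-point limitation labels, called on the fitted theta
    states: Optional[Callable[[np.ndarray, np.ndarray], list[str]]] = None
    # optional derived quantities (e.g. Cisat / Jf-max), from the fitted theta
    derived: Optional[Callable[[np.ndarray], dict[str, float]]] = None
    # optional data-driven initial point: init(x, y) -> theta0 (clipped to bounds)
    init: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    # parameters held fixed by the factory, reported alongside the fitted ones
    fixed_params: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FitConfig:
    """Annealing schedule and options.

    ``t0`` is in squared objective units; ``None`` starts at the SSE of the
    mid-bounds initial point.  ``bounds`` overrides the model defaults per
    parameter.
    """

    t0: Optional[float] = None
    cooling: float = 0.95
    sweeps: int = 200
    proposals_per_sweep: int = 50
    seed: int = 0
    polish: bool = True
    step_frac: float = 0.02
    bounds: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise DomainError("cooling must lie in (0, 1)")
        if self.sweeps < 1 or self.proposals_per_sweep < 1:
            raise DomainError("sweeps and proposals_per_sweep must be >= 1")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                    raise DomainError(f"bounds for {name!r} must be finite and non-degenerate")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus fit diagnostics.

    ``trace`` is the best-so-far SSE at the end of each sweep (monotone
    non-increasing); ``derived`` carries model-specific quantities such as
    Cisat and Jf-max for the empirical J-Ci model.
    """

    params: dict[str, float]
    sse: float
    r2: float
    n_obs: int
    seed: int
    converged: bool
    model: str
    variant: Optional[str] = None
    limitation_states: Optional[tuple[str, ...]] = None
    derived: dict[str, float] = field(default_factory=dict)
    trace: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "params": self.params,
            "sse": self.sse,
            "r2": self.r2,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "converged": self.converged,
            "model": self.model,
            "variant": self.variant,
            "limitation_states": (
                None if self.limitation_states is None else list(self.limitation_states)
            ),
            "derived": self.derived,
            "trace": list(self.trace),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=dict(d["params"]),
            sse=d["sse"],
            r2=d["r2"],
            n_obs=d["n_obs"],
            seed=d["seed"],
            converged=d["converged"],
            model=d["model"],
            variant=d.get("variant"),
            limitation_states=(
                None
                if d.get("limitation_states") is None
                else tuple(d["limitation_states"])
            ),
            derived=dict(d.get("derived", {})),
            trace=tuple(d.get("trace", ())),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination R^2 = 1 - SSE/SST."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValidationError("observed and predicted must have equal length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedRSquaredError("all observed values identical: SST = 0")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def metropolis_accept(delta_sse: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept iff dSSE <= 0, else with prob exp(-dSSE/T)."""
    if delta_sse <= 0.0:
        return True
    if temperature <= 0.0:
        return False
    return rng.random() < math.exp(-delta_sse / temperature)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold points back into [lo, hi] by reflection at the bounds."""
    width = hi - lo
    r = np.mod(x - lo, 2.0 * width)
    return lo + np.minimum(r, 2.0 * width - r)


def _extract_xy(curve: Union[ResponseCurve, tuple], model: ForwardModel):
    if isinstance(curve, ResponseCurve):
        if model.kind is not None and curve.kind is not model.kind:
            raise ValidationError(
                f"curve kind {curve.kind.value} does not match model {model.name!r}"
            )
        return curve.independent_values, curve.dependent_values
    x, y = curve
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit(model: ForwardModel, curve, config: FitConfig = FitConfig()) -> FitResult:
    """Fit ``model`` to a curve (ResponseCurve or ``(x, y)`` pair).

    Deterministic in ``(curve, config)``: the annealer draws from a
    Generator seeded with ``config.seed`` and the polish is deterministic,
    so identical inputs give bit-identical results.
    """
    x, y = _extract_xy(curve, model)
    k = len(model.param_names)
    if x.size < k + 1:
        raise UnderdeterminedError(
            f"{x.size} observations cannot constrain {k} free parameters"
        )
    if np.unique(x).size < 2:
        raise ValidationError("independent-variable values are all identical")

    bounds = dict(model.default_bounds)
    if config.bounds:
        bounds.update(config.bounds)
    lo = np.array([bounds[p][0] for p in model.param_names])
    hi = np.array([bounds[p][1] for p in model.param_names])

    def sse(theta: np.ndarray) -> float:
        resid = y - model.predict(theta, x)
        return float(resid @ resid)

    rng = np.random.default_rng(config.seed)
    if model.init is not None:
        theta = np.clip(np.asarray(model.init(x, y), dtype=float), lo, hi)
    else:
        theta = 0.5 * (lo + hi)
    current = sse(theta)
    best, best_sse = theta.copy(), current
    temperature = config.t0 if config.t0 is not None else max(current, 1e-12)
    scale = config.step_frac * (hi - lo)

    trace = []
    for _ in range(config.sweeps):
        for _ in range(config.proposals_per_sweep):
            proposal = _reflect(theta + rng.normal(0.0, 1.0, k) * scale, lo, hi)
            val = sse(proposal)
            if metropolis_accept(val - current, temperature, rng):
                theta, current = proposal, val
                if val < best_sse:
                    best, best_sse = proposal, val
        temperature *= config.cooling
        trace.append(best_sse)

    converged = True
    if config.polish:
        # restart once: a fresh simplex escapes flat valleys (e.g. a TPU
        # plateau that stops binding) where a single Nelder-Mead run stalls
        for _ in range(2):
            res = minimize(
                sse,
                best,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 20000},
            )
            if res.fun <= best_sse:
                best, best_sse = np.asarray(res.x), float(res.fun)
            converged = bool(res.success)

    params = {p: float(v) for p, v in zip(model.param_names, best)}
    params.update({p: float(v) for p, v in model.fixed_params.items()})
    try:
        r2 = r_squared(y, model.predict(best, x))
    except UndefinedRSquaredError:
        raise ValidationError("dependent values are all identical: R^2 undefined")
    states = tuple(model.states(best, x)) if model.states is not None else None
    derived = model.derived(best) if model.derived is not None else {}
    return FitResult(
        params=params,
        sse=best_sse,
        r2=r2,
        n_obs=int(x.size),
        seed=config.seed,
        converged=converged,
        model=model.name,
        variant=model.variant_label,
        limitation_states=states,
        derived=derived,
        trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# model factories


def fvcb_aci_model(
    variant: fvcb_model.ElectronVariant = fvcb_model.SUBMODEL_I,
    fixed: Optional[dict[str, float]] = None,
    kc: float = 404.9,
    ko: float = 278.4,
    o: float = 210.0,
) -> ForwardModel:
    """FvCB A-Ci composition with free set (vcmax, j, tpu, rd, gamma_star).

    ``fixed`` removes parameters from the free set and pins them (e.g.
    ``{"rd": 1.5, "gamma_star": 40.0}`` to share Rd and Gamma* between
    sub-model fits).  Rubisco kinetics (kc, ko, o) are always fixed.
    """
    fixed = dict(fixed or {})
    all_names = ("vcmax", "j", "tpu", "rd", "gamma_star")
    unknown = set(fixed) - set(all_names)
    if unknown:
        raise DomainError(f"cannot fix unknown parameters {sorted(unknown)}")
    free = tuple(n for n in all_names if n not in fixed)
    if not free:
        raise DomainError("at least one parameter must remain free")
    km = kc * (1.0 + o / ko)
    idx = {n: i for i, n in enumerate(free)}

    def assemble(theta):
        get = lambda n: theta[idx[n]] if n in idx else fixed[n]
        return get("vcmax"), get("j"), get("tpu"), get("rd"), get("gamma_star")

    def stacked(theta, ci):
        vcmax, j, tpu, rd, g = assemble(theta)
        ac = vcmax * (ci - g) / (ci + km) - rd
        aj = j * (ci - g) / (variant.a * ci + variant.b * g) - rd
        ap = np.full_like(ci, 3.0 * tpu - rd)
        return np.vstack([ac, aj, ap])

    def predict(theta, ci):
        return np.min(stacked(theta, ci), axis=0)

    def states(theta, ci):
        idx_min = np.argmin(stacked(theta, ci), axis=0)
        order = (
            fvcb_model.LimitationState.RUBISCO,
            fvcb_model.LimitationState.RUBP,
            fvcb_model.LimitationState.TPU,
        )
        return [order[i].value for i in idx_min]

    def derived(theta):
        _, j, _, _, _ = assemble(theta)
        return {"j_a_max": float(j)}

    def init(ci, y):
        # heuristic start: TPU from the high-Ci plateau, Vcmax/J by
        # inverting Ac/Aj at representative Ci.  Rd starts at a typical
        # 1.5 umol m-2 s-1: the lowest-Ci point cannot separate Rd because
        # An(0) = -J/b - Rd under the electron-transport-limited phase.
        g0 = fixed.get("gamma_star", 40.0)
        rd0 = fixed.get("rd", 1.5)
        tpu0 = (float(y.max()) + rd0) / 3.0
        low = (ci > 1.2 * g0) & (ci < 360.0)
        if low.any():
            c = float(ci[low].max())
            a = float(y[low][np.argmax(ci[low])])
            vc0 = (a + rd0) * (c + km) / (c - g0)
        else:
            vc0 = 100.0
        mid = ci > 1.5 * g0
        c = float(ci[mid][np.argmin(np.abs(ci[mid] - 600.0))]) if mid.any() else 600.0
        a = float(y[mid][np.argmin(np.abs(ci[mid] - 600.0))]) if mid.any() else y.max()
        j0 = (a + rd0) * (variant.a * c + variant.b * g0) / (c - g0)
        j0 = max(j0, variant.a * 3.0 * tpu0)  # keep the Aj asymptote above the plateau
        full = {"vcmax": vc0, "j": j0, "tpu": tpu0, "rd": rd0, "gamma_star": g0}
        return np.array([full[n] for n in free])

    return ForwardModel(
        name="fvcb_aci",
        param_names=free,
        predict=predict,
        default_bounds={n: FVCB_BOUNDS[n] for n in free},
        kind=CurveKind.A_VS_CI,
        variant_label=variant.label,
        states=states,
        derived=derived,
        init=init,
        fixed_params=fixed,
    )


def empirical_jci_model() -> ForwardModel:
    """Empirical J-Ci model with free (alpha, beta, gamma_coef, j0)."""

    def predict(theta, ci):
        alpha, beta, gamma_coef, j0 = theta
        return alpha * (1.0 - beta * ci) * ci / (1.0 + gamma_coef * ci) + j0

    def derived(theta):
        p = empirical_co2.EmpiricalCO2Params(*map(float, theta))
        return {
            "cisat": float(empirical_co2.cisat(p)),
            "jfmax": float(empirical_co2.jfmax(p)),
        }

    def init(ci, y):
        # typical curvature/suppression scales; alpha from the peak height
        # via Jf-max - J0 = 125 alpha at (beta, gamma) = (5e-4, 4e-3)
        j0_init = float(y[np.argmin(ci)])
        alpha0 = max(0.02, (float(y.max()) - j0_init) / 125.0)
        return np.array([alpha0, 5e-4, 4e-3, max(0.0, j0_init)])

    return ForwardModel(
        name="empirical_jci",
        param_names=("alpha", "beta", "gamma_coef", "j0"),
        predict=predict,
        default_bounds=dict(EMPIRICAL_BOUNDS),
        kind=CurveKind.J_VS_CI,
        derived=derived,
        init=init,
    )


def light_response_model() -> ForwardModel:
    """Light-response model with free (alpha_i, beta_i, gamma_i, rd)."""

    def predict(theta, i):
        alpha_i, beta_i, gamma_i, rd = theta
        return alpha_i * (1.0 - beta_i * i) * i / (1.0 + gamma_i * i) - rd

    def derived(theta):
        p = light_response.LightResponseParams(*map(float, theta))
        return {
            "isat": float(light_response.isat(p)),
            "an_max": float(light_response.an_light_max(p)),
        }

    def init(i, y):
        rd0 = max(0.05, -float(y[np.argmin(i)]))
        # peak height via An_max + Rd = 200 alpha_i at (beta, gamma) = (5e-5, 4e-3)
        alpha0 = max(0.01, (float(y.max()) + rd0) / 200.0)
        return np.array([alpha0, 5e-5, 4e-3, rd0])

    return ForwardModel(
        name="light_response",
        param_names=("alpha_i", "beta_i", "gamma_i", "rd"),
        predict=predict,
        default_bounds=dict(LIGHT_BOUNDS),
        kind=CurveKind.A_VS_I,
        derived=derived,
        init=init,
    )


# ---------------------------------------------------------------------------
# convenience wrappers


def fit_fvcb(
    curve,
    variant: fvcb_model.ElectronVariant = fvcb_model.SUBMODEL_I,
    config: FitConfig = FitConfig(),
    fixed: Optional[dict[str, float]] = None,
) -> FitResult:
    return fit(fvcb_aci_model(variant, fixed=fixed), curve, config)


def fit_empirical(curve, config: FitConfig = FitConfig()) -> FitResult:
    return fit(empirical_jci_model(), curve, config)


def refit_j_shared(
    curve,
    base: FitResult,
    variant: fvcb_model.ElectronVariant,
    kc: float = 404.9,
    ko: float = 278.4,
    o: float = 210.0,
) -> FitResult:
    """Re-estimate J under another electron-requirement variant, sharing the
    leaf biochemistry (Vcmax, TPU, Rd, Gamma*) of a base FvCB fit.

    The sub-models differ only in the stoichiometry of the RuBP-
    regeneration-limited phase, so the variant's J is re-estimated on the
    RuBP-limited segment identified by the base fit (segment-wise phase
    fitting, the convention of spreadsheet A-Ci fitting tools).  Aj is
    linear in J, so the segment least-squares solution is closed-form:

        J* = sum(phi_i (y_i + Rd)) / sum(phi_i^2),
        phi_i = (Ci_i - Gamma*) / (a Ci_i + b Gamma*)

    SSE/R^2 and the limitation states are then reported over the full curve
    under the shared-parameter composition with the new J.
    """
    model = fvcb_aci_model(variant, kc=kc, ko=ko, o=o)
    x, y = _extract_xy(curve, model)
    if base.limitation_states is None or len(base.limitation_states) != x.size:
        raise ValidationError("base fit lacks per-point limitation states")
    p = base.params
    for name in ("vcmax", "tpu", "rd", "gamma_star"):
        if name not in p:
            raise ValidationError(f"base fit does not provide {name!r}")
    mask = np.array(
        [s == fvcb_model.LimitationState.RUBP.value for s in base.limitation_states]
    )
    if not mask.any():
        raise ValidationError("base fit identifies no RuBP-limited segment")
    g = p["gamma_star"]
    phi = (x[mask] - g) / (variant.a * x[mask] + variant.b * g)
    j_star = float(np.sum(phi * (y[mask] + p["rd"])) / np.sum(phi**2))

    theta = np.array([p["vcmax"], j_star, p["tpu"], p["rd"], g])
    pred = model.predict(theta, x)
    sse = float(np.sum((y - pred) ** 2))
    return FitResult(
        params={
            "vcmax": p["vcmax"],
            "j": j_star,
            "tpu": p["tpu"],
            "rd": p["rd"],
            "gamma_star": g,
        },
        sse=sse,
        r2=r_squared(y, pred),
        n_obs=int(x.size),
        seed=base.seed,
        converged=base.converged,
        model="fvcb_aci_shared",
        variant=variant.label,
        limitation_states=tuple(model.states(theta, x)),
        derived={"j_a_max": j_star},
        trace=(),
    )


def fit_light(curve, config: FitConfig = FitConfig()) -> FitResult:
    return fit(light_response_model(), curve, config)
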