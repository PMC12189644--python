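"""Synthetic gas-exchange / fluorescence curves from known ground truth.

The generators emulate the measurement protocol the analysis assumes:
12 CO2 levels stepped 1600 -> 0 umol mol-1 for A-Ci and J-Ci curves,
15/13/12-level light grids stepped 2000 -> 0 umol m-2 s-1 for A-I curves,
n = 3 replicates, additive homoscedastic Gaussian noise on the dependent
variable (instrument noise; biological replicate-to-replicate parameter
spread is not simulated).

Every generator is deterministic under a fixed seed and returns the ground
truth alongside the curves so that parameter-recovery tests can close the
loop.  :func:`gen_paper_like_study` bundles a four-species study -- each
species with A-Ci, J-Ci and A-I curves -- whose truths put fitted J_A-max
and observed J_f-max in the 215-365 umol m-2 s-1 range, with at least one
species built to violate the electron-budget credibility criterion
(FvCB J_A-max above the fluorescence J_f-max) and one to satisfy it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .empirical_co2 import EmpiricalCO2Params, jf_rate
from .errors import DomainError, ValidationError
from .fvcb_model import SUBMODEL_I, ElectronVariant, FvCBParams, an_fvcb
from .gasx_io import CurveKind, ObservationRecord, ResponseCurve
from .light_response import LightResponseParams, an_light

__all__ = [
    "CI_LEVELS_12",
    "LIGHT_LEVELS_15",
    "LIGHT_LEVELS_13",
    "LIGHT_LEVELS_12",
    "ScenarioConfig",
    "SyntheticDataset",
    "SpeciesTruth",
    "StudyBundle",
    "gen_aci",
    "gen_jci",
    "gen_ani",
    "gen_paper_like_study",
    "DEFAULT_FVCB_TRUTH",
    "DEFAULT_EMPIRICAL_TRUTH",
    "DEFAULT_LIGHT_TRUTH",
]

#: Measurement-order CO2 levels (umol mol-1), high to low.
CI_LEVELS_12 = (1600.0, 1400.0, 1200.0, 1000.0, 800.0, 600.0, 420.0, 300.0, 200.0, 100.0, 60.0, 0.0)
#: Measurement-order light levels (umol m-2 s-1); 13/12-level grids drop the top steps.
LIGHT_LEVELS_15 = (2000.0, 1800.0, 1600.0, 1400.0, 1200.0, 1000.0, 800.0, 600.0, 400.0, 200.0, 150.0, 100.0, 80.0, 50.0, 0.0)
LIGHT_LEVELS_13 = LIGHT_LEVELS_15[2:]
LIGHT_LEVELS_12 = LIGHT_LEVELS_15[3:]

#: Ambient CO2 (umol mol-1) held during light-response measurements.
AMBIENT_CO2 = 420.0

# Default ground truths: a generic healthy C3 leaf at 25 C.  tpu = 14 keeps
# a real RuBP-regeneration-limited window (Ci ~ 370-670, grid points 420 and
# 600) between the Rubisco phase and the TPU plateau, so every FvCB
# parameter is identifiable from the 12-level grid.
DEFAULT_FVCB_TRUTH = FvCBParams(vcmax=120.0, j=200.0, tpu=14.0, rd=1.5, gamma_star=40.0)
DEFAULT_EMPIRICAL_TRUTH = EmpiricalCO2Params(alpha=0.9, beta=0.0005, gamma_coef=0.004, j0=20.0)
DEFAULT_LIGHT_TRUTH = LightResponseParams(alpha_i=0.06, beta_i=0.00005, gamma_i=0.004, rd=1.5)

#: Default instrument noise on An (umol m-2 s-1), matching the 1-3 percent
#: SE/mean scale of replicated gas-exchange measurements.
DEFAULT_NOISE_SD = 0.3
#: Default instrument noise on fluorescence-derived J (umol m-2 s-1).
DEFAULT_J_NOISE_SD = 1.0

Truth = Union[FvCBParams, EmpiricalCO2Params, LightResponseParams]


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic measurement scenario.

    ``levels`` defaults to the protocol grid matching the truth type;
    ``held`` is the controlled variable's value (saturating irradiance for
    CO2-response curves, ambient CO2 for light curves).
    """

    truth: Truth
    variant: ElectronVariant = SUBMODEL_I
    levels: Optional[tuple[float, ...]] = None
    n_reps: int = 3
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    species: str = "synthetic"
    held: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_reps < 1:
            raise DomainError("n_reps must be >= 1")
        if self.levels is not None:
            arr = np.asarray(self.levels, dtype=float)
            if arr.size == 0 or np.unique(arr).size != arr.size:
                raise ValidationError("levels must be non-empty and distinct")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated curves plus the ground truth that produced them."""

    curves: tuple[ResponseCurve, ...]
    truth: Truth
    config: ScenarioConfig


def _levels(config: ScenarioConfig, default: tuple[float, ...]) -> np.ndarray:
    levels = config.levels if config.levels is not None else default
    return np.asarray(levels, dtype=float)


def gen_aci(config: ScenarioConfig) -> SyntheticDataset:
    """A-Ci curves: An = an_fvcb(truth, Ci) + Gaussian(0, noise_sd)."""
    if not isinstance(config.truth, FvCBParams):
        raise ValidationError("gen_aci needs an FvCBParams truth")
    ci = _levels(config, CI_LEVELS_12)
    held = config.held if config.held is not None else 1500.0
    rng = np.random.default_rng(config.seed)
    clean, _ = an_fvcb(config.truth, ci, config.variant)
    curves = []
    for rep in range(1, config.n_reps + 1):
        an = clean + rng.normal(0.0, config.noise_sd, ci.size)
        records = tuple(
            ObservationRecord(
                species=config.species, replicate=rep,
                ci=float(c), an=float(a), ppfd=held,
            )
            for c, a in zip(ci, an)
        )
        curves.append(
            ResponseCurve(
                kind=CurveKind.A_VS_CI, species=config.species, replicate=rep,
                records=records, held_constant=("ppfd", held),
            )
        )
    return SyntheticDataset(tuple(curves), config.truth, config)


def gen_jci(config: ScenarioConfig) -> SyntheticDataset:
    """J-Ci curves: J = jf_rate(truth, Ci) + Gaussian(0, noise_sd)."""
    if not isinstance(config.truth, EmpiricalCO2Params):
        raise ValidationError("gen_jci needs an EmpiricalCO2Params truth")
    ci = _levels(config, CI_LEVELS_12)
    held = config.held if config.held is not None else 1500.0
    rng = np.random.default_rng(config.seed)
    clean = jf_rate(config.truth, ci)
    curves = []
    for rep in range(1, config.n_reps + 1):
        j = clean + rng.normal(0.0, config.noise_sd, ci.size)
        records = tuple(
            ObservationRecord(
                species=config.species, replicate=rep,
                ci=float(c), an=None, ppfd=held, j=float(v),
            )
            for c, v in zip(ci, j)
        )
        curves.append(
            ResponseCurve(
                kind=CurveKind.J_VS_CI, species=config.species, replicate=rep,
                records=records, held_constant=("ppfd", held),
            )
        )
    return SyntheticDataset(tuple(curves), config.truth, config)


def gen_ani(config: ScenarioConfig) -> SyntheticDataset:
    """A-I curves: An = an_light(truth, I) + Gaussian(0, noise_sd)."""
    if not isinstance(config.truth, LightResponseParams):
        raise ValidationError("gen_ani needs a LightResponseParams truth")
    i_levels = _levels(config, LIGHT_LEVELS_15)
    held = config.held if config.held is not None else AMBIENT_CO2
    rng = np.random.default_rng(config.seed)
    clean = an_light(config.truth, i_levels)
    curves = []
    for rep in range(1, config.n_reps + 1):
        an = clean + rng.normal(0.0, config.noise_sd, i_levels.size)
        records = tuple(
            ObservationRecord(
                species=config.species, replicate=rep,
                ci=held, an=float(a), ppfd=float(i),
            )
            for i, a in zip(i_levels, an)
        )
        curves.append(
            ResponseCurve(
                kind=CurveKind.A_VS_I, species=config.species, replicate=rep,
                records=records, held_constant=("ci", held),
            )
        )
    return SyntheticDataset(tuple(curves), config.truth, config)


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth parameter sets for one synthetic species."""

    fvcb: FvCBParams
    empirical: EmpiricalCO2Params
    light: LightResponseParams
    light_levels: tuple[float, ...]
    isat: float


@dataclass(frozen=True)
class StudyBundle:
    """Four-species synthetic study: curves and truths keyed by species."""

    truths: dict[str, SpeciesTruth]
    aci: dict[str, tuple[ResponseCurve, ...]]
    jci: dict[str, tuple[ResponseCurve, ...]]
    ani: dict[str, tuple[ResponseCurve, ...]]
    seed: int

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.truths)


def _study_truths() -> dict[str, SpeciesTruth]:
    # Species A is built to violate the electron-budget criterion
    # (FvCB j = 320 above the J-Ci maximum ~ 295); species B and D satisfy
    # it under sub-model I.  Empirical truths share beta/gamma (Cisat = 500)
    # and set Jf-max = 125 alpha + j0.
    return {
        "species_A": SpeciesTruth(
            fvcb=FvCBParams(vcmax=160.0, j=320.0, tpu=24.0, rd=1.6, gamma_star=42.0),
            empirical=EmpiricalCO2Params(alpha=1.88, beta=0.0005, gamma_coef=0.004, j0=60.0),
            light=LightResponseParams(alpha_i=0.065, beta_i=1.2255e-4, gamma_i=0.004, rd=1.6),
            light_levels=LIGHT_LEVELS_15,
            isat=1200.0,
        ),
        "species_B": SpeciesTruth(
            fvcb=FvCBParams(vcmax=115.0, j=225.0, tpu=17.0, rd=1.4, gamma_star=40.0),
            empirical=EmpiricalCO2Params(alpha=1.6, beta=0.0005, gamma_coef=0.004, j0=50.0),
            light=LightResponseParams(alpha_i=0.055, beta_i=1.984e-4, gamma_i=0.004, rd=1.4),
            light_levels=LIGHT_LEVELS_12,
            isat=900.0,
        ),
        "species_C": SpeciesTruth(
            fvcb=FvCBParams(vcmax=140.0, j=270.0, tpu=20.0, rd=1.5, gamma_star=41.0),
            empirical=EmpiricalCO2Params(alpha=1.84, beta=0.0005, gamma_coef=0.004, j0=55.0),
            light=LightResponseParams(alpha_i=0.06, beta_i=5e-5, gamma_i=0.004, rd=1.5),
            light_levels=LIGHT_LEVELS_15,
            isat=2000.0,
        ),
        "species_D": SpeciesTruth(
            fvcb=FvCBParams(vcmax=110.0, j=215.0, tpu=16.5, rd=1.3, gamma_star=39.0),
            empirical=EmpiricalCO2Params(alpha=1.616, beta=0.0005, gamma_coef=0.004, j0=48.0),
            light=LightResponseParams(alpha_i=0.05, beta_i=5e-5, gamma_i=0.004, rd=1.3),
            light_levels=LIGHT_LEVELS_13,
            isat=2000.0,
        ),
    }


def gen_paper_like_study(
    seed: int = 0,
    n_reps: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD,
    j_noise_sd: float = DEFAULT_J_NOISE_SD,
) -> StudyBundle:
    """Generate the four-species study bundle (A-Ci, J-Ci, A-I x 3 reps).

    Per-curve seeds are derived deterministically from ``seed`` so the
    bundle is reproducible and sub-streams are independent.
    """
    truths = _study_truths()
    ss = np.random.SeedSequence(seed)
    aci, jci, ani = {}, {}, {}
    for k, (name, truth) in enumerate(truths.items()):
        s_aci, s_jci, s_ani = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
        aci[name] = gen_aci(
            ScenarioConfig(
                truth=truth.fvcb, n_reps=n_reps, noise_sd=noise_sd,
                seed=s_aci, species=name, held=truth.isat,
            )
        ).curves
        jci[name] = gen_jci(
            ScenarioConfig(
                truth=truth.empirical, n_reps=n_reps, noise_sd=j_noise_sd,
                seed=s_jci, species=name, held=truth.isat,
            )
        ).curves
        ani[name] = gen_ani(
            ScenarioConfig(
                truth=truth.light, levels=truth.light_levels, n_reps=n_reps,
                noise_sd=noise_sd, seed=s_ani, species=name,
            )
        ).curves
    return StudyBundle(truths=truths, aci=aci, jci=jci, ani=ani, seed=seed)
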