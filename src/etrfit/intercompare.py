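"""Observation-modelling intercomparison of maximum electron transport rates.

The scientific question: a fluorescence-derived J-Ci curve measures the
total PSII electron flux J_f, which feeds carbon assimilation *and*
photorespiration, nitrate reduction and Mehler-reaction oxygen uptake
(J_f = J_A + J_O + J_Nit + J_MAP).  An FvCB fit of the A-Ci curve estimates
only the assimilatory part, so a credible fitted J_A-max must lie *below*
the observed fluorescence maximum J_f-max.  This module assembles the two
quantities per species, runs the significance tests, applies that
electron-budget credibility criterion, and -- where an estimate breaks it --
solves for the Gamma*-coefficient b* that would restore it, together with
the photorespiratory stoichiometry f = a/b* it implies.

All tests operate on summary statistics (mean, SE, n) because replicate
fits, not raw points, are the experimental unit.  The compact letter
display supports two conventions: the standard insert-and-absorb display
built from all pairwise tests, and an observed-anchored convention
(``reference=``) in which each estimate is compared against the observed
group by Student's t-test, the convention gas-exchange tables typically
follow.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError
from .fit_engine import FitConfig, FitResult, fit_empirical, fit_fvcb
from .fvcb_model import SUBMODEL_I, SUBMODEL_II, ElectronVariant, implied_f
from .gasx_io import CurveKind, ResponseCurve
from .synthetic_data import StudyBundle

__all__ = [
    "GroupSummary",
    "TTestOutcome",
    "AnovaOutcome",
    "CredibilityVerdict",
    "ThresholdResult",
    "SpeciesComparison",
    "ComparisonReport",
    "observed_jfmax",
    "ttest_summary",
    "anova_letters",
    "credibility_check",
    "threshold_b_coefficient",
    "run_study",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SE of a group of replicate values (umol m-2 s-1)."""

    label: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be non-negative")
        if self.n < 1:
            raise ValidationError("n must be >= 1")

    @property
    def variance(self) -> float:
        """Sample variance s^2 = se^2 * n."""
        return self.se**2 * self.n

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size == 1:
            warnings.warn(f"group {label!r} has a single replicate: SE set to 0")
            return cls(label, float(arr[0]), 0.0, 1)
        se = float(arr.std(ddof=1) / math.sqrt(arr.size))
        return cls(label, float(arr.mean()), se, int(arr.size))


@dataclass(frozen=True)
class TTestOutcome:
    t: float
    df: float
    p: float
    significant: bool


@dataclass(frozen=True)
class AnovaOutcome:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class CredibilityVerdict:
    """Outcome of the electron-budget criterion J_A-max < J_f-max.

    ``overestimate`` requires both the mean inequality (estimate >=
    observation) and one-sided significance, so sampling noise alone cannot
    flag an overestimate.
    """

    status: str  # "consistent" | "overestimate"
    mean_diff: float  # ja_max mean - jf_max mean
    t: float
    p_one_sided: float

    @property
    def is_overestimate(self) -> bool:
        return self.status == "overestimate"


@dataclass(frozen=True)
class ThresholdResult:
    found: bool
    b_star: Optional[float]
    implied_f: Optional[float]
    mean_j_at_b: Optional[float]
    iterations: int
    message: str = ""


def observed_jfmax(curves: Sequence[ResponseCurve], label: str = "observed") -> GroupSummary:
    """Observed J_f-max: per-replicate maximum J over the Ci levels, then
    mean +/- SE over replicates."""
    if not curves:
        raise ValidationError("need at least one J-Ci curve")
    maxima = []
    for curve in curves:
        if curve.kind is not CurveKind.J_VS_CI:
            raise ValidationError("observed_jfmax needs J-Ci curves")
        maxima.append(float(np.max(curve.dependent_values)))
    return GroupSummary.from_values(label, maxima)


def ttest_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    alpha: float = 0.05,
    welch: bool = False,
    alternative: str = "two-sided",
) -> TTestOutcome:
    """Two-sample t-test from summary statistics.

    Default is Student's pooled-variance test with df = n1 + n2 - 2; the
    Welch-Satterthwaite correction is available via ``welch=True``.
    ``alternative`` in {"two-sided", "greater"} ("greater": H1 is
    mean(g1) > mean(g2)).
    """
    if g1.n < 2 or g2.n < 2:
        raise ValidationError("both groups need n >= 2 for a t-test")
    v1, v2 = g1.variance, g2.variance
    diff = g1.mean - g2.mean
    if welch:
        se2 = v1 / g1.n + v2 / g2.n
        df = se2**2 / (
            (v1 / g1.n) ** 2 / (g1.n - 1) + (v2 / g2.n) ** 2 / (g2.n - 1)
        )
    else:
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se2 = sp2 * (1.0 / g1.n + 1.0 / g2.n)
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / math.sqrt(se2)
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df) if math.isfinite(t) else 0.0
        if t == 0.0:
            p = 1.0
    elif alternative == "greater":
        p = stats.t.sf(t, df) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    else:
        raise DomainError(f"unknown alternative {alternative!r}")
    return TTestOutcome(t=float(t), df=float(df), p=float(p), significant=bool(p < alpha))


def _pairwise_significance(
    groups: Sequence[GroupSummary], alpha: float, welch: bool
) -> dict[tuple[str, str], TTestOutcome]:
    out = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            res = ttest_summary(g1, g2, alpha=alpha, welch=welch)
            out[(g1.label, g2.label)] = res
    return out


def _insert_absorb_letters(
    ordered: list[GroupSummary],
    sig: dict[tuple[str, str], TTestOutcome],
) -> dict[str, str]:
    """Standard compact letter display (insert-and-absorb).

    Starts from one column holding every group; each significant pair
    splits every column containing both; subset columns are absorbed.
    Columns are lettered in descending order of their best member's mean,
    so 'a' marks the highest-mean grouping.
    """
    labels = [g.label for g in ordered]
    columns: list[set[str]] = [set(labels)]
    for (l1, l2), res in sig.items():
        if not res.significant:
            continue
        for col in [c for c in columns if l1 in c and l2 in c]:
            columns.remove(col)
            columns.extend([col - {l1}, col - {l2}])
        # absorb: drop any column that is a subset of another
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(c < other or (c == other and i > j)
                             for j, other in enumerate(columns))
        ]
    rank = {label: i for i, label in enumerate(labels)}
    columns.sort(key=lambda c: min(rank[l] for l in c))
    letters = {label: "" for label in labels}
    for letter, col in zip(string.ascii_lowercase, columns):
        for label in col:
            letters[label] += letter
    return {label: "".join(sorted(v)) for label, v in letters.items()}


def _reference_letters(
    ordered: list[GroupSummary],
    reference: str,
    alpha: float,
    welch: bool,
) -> dict[str, str]:
    """Observed-anchored letters: groups not significantly different from
    the reference share its letter; the remaining groups are lettered among
    themselves by the standard display."""
    by_label = {g.label: g for g in ordered}
    ref = by_label[reference]
    ref_cluster = {reference}
    others = []
    for g in ordered:
        if g.label == reference:
            continue
        if ttest_summary(g, ref, alpha=alpha, welch=welch).significant:
            others.append(g)
        else:
            ref_cluster.add(g.label)
    if others:
        sig = _pairwise_significance(others, alpha, welch)
        other_letters = _insert_absorb_letters(others, sig)
        other_columns: dict[str, set[str]] = {}
        for label, ls in other_letters.items():
            for letter in ls:
                other_columns.setdefault(letter, set()).add(label)
        clusters = list(other_columns.values())
    else:
        clusters = []
    clusters.append(ref_cluster)
    rank = {g.label: i for i, g in enumerate(ordered)}
    clusters.sort(key=lambda c: min(rank[l] for l in c))
    letters = {g.label: "" for g in ordered}
    for letter, cluster in zip(string.ascii_lowercase, clusters):
        for label in cluster:
            letters[label] += letter
    return {label: "".join(sorted(v)) for label, v in letters.items()}


def anova_letters(
    groups: Sequence[GroupSummary],
    alpha: float = 0.05,
    reference: Optional[str] = None,
    welch: bool = False,
) -> tuple[AnovaOutcome, dict[str, str], dict[tuple[str, str], TTestOutcome]]:
    """One-way ANOVA from summary statistics plus a compact letter display.

    Returns ``(anova, letters, pairwise)``.  Letters are assigned in
    descending order of group mean ('a' = highest).  With ``reference``
    set to a group label, the observed-anchored convention is used (see
    module docstring); otherwise the standard insert-and-absorb display.
    If the ANOVA itself is not significant at ``alpha``, all groups share
    the letter 'a'.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValidationError("every group needs n >= 2")
    if all(g.se == 0 for g in groups) and len({g.mean for g in groups}) == 1:
        # fully degenerate: identical groups with no variance
        return (
            AnovaOutcome(f=0.0, df_between=len(groups) - 1,
                         df_within=sum(g.n for g in groups) - len(groups), p=1.0),
            {g.label: "a" for g in groups},
            _pairwise_significance(list(groups), alpha, welch),
        )
    if all(g.se == 0 for g in groups):
        raise ValidationError("all groups have zero variance: ANOVA undefined")

    n_total = sum(g.n for g in groups)
    k = len(groups)
    grand = sum(g.mean * g.n for g in groups) / n_total
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ssw = sum((g.n - 1) * g.variance for g in groups)
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw if msw > 0 else math.inf
    p = float(stats.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    anova = AnovaOutcome(f=float(f), df_between=df_b, df_within=df_w, p=p)

    ordered = sorted(groups, key=lambda g: -g.mean)
    pairwise = _pairwise_significance(ordered, alpha, welch)
    if p >= alpha:
        letters = {g.label: "a" for g in groups}
    elif reference is not None:
        if reference not in {g.label for g in groups}:
            raise ValidationError(f"reference {reference!r} is not a group label")
        letters = _reference_letters(ordered, reference, alpha, welch)
    else:
        letters = _insert_absorb_letters(ordered, pairwise)
    return anova, letters, pairwise


def credibility_check(
    ja_max: GroupSummary, jf_max_observed: GroupSummary, alpha: float = 0.05
) -> CredibilityVerdict:
    """Electron-budget criterion: is the fitted J_A-max credibly below the
    observed J_f-max?

    Verdict is ``overestimate`` iff the estimate's mean is at or above the
    observation *and* the one-sided test rejects J_A-max < J_f-max at
    ``alpha``; otherwise ``consistent``.
    """
    res = ttest_summary(ja_max, jf_max_observed, alpha=alpha, alternative="greater")
    diff = ja_max.mean - jf_max_observed.mean
    over = diff >= 0 and res.p < alpha
    return CredibilityVerdict(
        status="overestimate" if over else "consistent",
        mean_diff=float(diff),
        t=res.t,
        p_one_sided=res.p,
    )


def ja_max_at_b(
    curves: Sequence[ResponseCurve],
    b: float,
    config: FitConfig = FitConfig(),
    fixed: Optional[dict[str, float]] = None,
    a_coeff: float = 4.0,
    base_fits: Optional[Sequence[FitResult]] = None,
) -> float:
    """Mean fitted J_A-max over replicates under the variant (a_coeff, b).

    Each replicate is fit once under the reference variant (a_coeff, 8)
    (or the supplied ``base_fits`` are reused), then J is re-estimated on
    the RuBP-limited segment under (a_coeff, b) with shared biochemistry
    via :func:`etrfit.fit_engine.refit_j_shared`.  Continuous and strictly
    increasing in b: a larger denominator needs a larger J to carry the
    same assimilation.
    """
    from .fit_engine import refit_j_shared

    if base_fits is None:
        base_variant = ElectronVariant(a_coeff, 8.0, f"custom:{a_coeff},8")
        base_fits = [fit_fvcb(c, base_variant, config, fixed=fixed) for c in curves]
    variant = ElectronVariant(a_coeff, b, f"custom:{a_coeff},{b:.6g}")
    js = [
        refit_j_shared(curve, base, variant).params["j"]
        for curve, base in zip(curves, base_fits)
    ]
    return float(np.mean(js))


def threshold_b_coefficient(
    curves: Sequence[ResponseCurve],
    jf_target: float,
    config: FitConfig = FitConfig(),
    fixed: Optional[dict[str, float]] = None,
    a_coeff: float = 4.0,
    bracket: tuple[float, float] = (4.01, 12.0),
    tol: float = 0.01,
    max_iter: int = 60,
) -> ThresholdResult:
    """Solve for the Gamma*-coefficient b* at which the mean fitted J_A-max
    equals ``jf_target``.

    Re-estimates J on the A-Ci replicates under the variant (a_coeff, b)
    along a bisection on b in ``bracket`` until |mean J(b) - jf_target| <
    ``tol`` (see :func:`ja_max_at_b` for the refit).  ``fixed`` optionally
    pins parameters (e.g. rd, gamma_star) in the base fits.  Returns a
    no-solution result (found=False) when the bracket shows no sign change.
    """
    base_variant = ElectronVariant(a_coeff, 8.0, f"custom:{a_coeff},8")
    base_fits = [fit_fvcb(c, base_variant, config, fixed=fixed) for c in curves]

    def mean_j(b: float) -> float:
        return ja_max_at_b(curves, b, config, fixed, a_coeff, base_fits=base_fits)

    lo, hi = bracket
    g_lo = mean_j(lo) - jf_target
    g_hi = mean_j(hi) - jf_target
    iterations = 2
    if g_lo == 0.0:
        return ThresholdResult(True, lo, implied_f(lo, a_coeff), jf_target, iterations)
    if g_hi == 0.0:
        return ThresholdResult(True, hi, implied_f(hi, a_coeff), jf_target, iterations)
    if g_lo * g_hi > 0:
        return ThresholdResult(
            False, None, None, None, iterations,
            message=(
                f"no sign change on b in [{lo}, {hi}]: mean J spans "
                f"[{g_lo + jf_target:.2f}, {g_hi + jf_target:.2f}] vs target {jf_target:.2f}"
            ),
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = mean_j(mid) - jf_target
        iterations += 1
        if abs(g_mid) < tol:
            return ThresholdResult(
                True, float(mid), implied_f(mid, a_coeff), g_mid + jf_target, iterations
            )
        if g_lo * g_mid < 0:
            hi, g_hi = mid, g_mid
        else:
            lo, g_lo = mid, g_mid
    mid = 0.5 * (lo + hi)
    return ThresholdResult(
        True, float(mid), implied_f(mid, a_coeff), mean_j(mid), iterations,
        message="bisection hit max_iter before |dJ| < tol",
    )


# ---------------------------------------------------------------------------
# report assembly

GROUP_KEYS = ("submodel_I", "submodel_II", "empirical", "observed")


@dataclass(frozen=True)
class SpeciesComparison:
    species: str
    summaries: dict[str, GroupSummary]
    letters: dict[str, str]
    anova_p: float
    pairwise_p: dict[str, float]
    credibility: dict[str, str]
    threshold_b: Optional[float] = None
    implied_f: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "summaries": {
                k: {"label": g.label, "mean": g.mean, "se": g.se, "n": g.n}
                for k, g in self.summaries.items()
            },
            "letters": dict(self.letters),
            "anova_p": self.anova_p,
            "pairwise_p": dict(self.pairwise_p),
            "credibility": dict(self.credibility),
            "threshold_b": self.threshold_b,
            "implied_f": self.implied_f,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesComparison":
        return cls(
            species=d["species"],
            summaries={k: GroupSummary(**g) for k, g in d["summaries"].items()},
            letters=dict(d["letters"]),
            anova_p=d["anova_p"],
            pairwise_p=dict(d["pairwise_p"]),
            credibility=dict(d["credibility"]),
            threshold_b=d.get("threshold_b"),
            implied_f=d.get("implied_f"),
        )


@dataclass(frozen=True)
class ComparisonReport:
    species: tuple[SpeciesComparison, ...]
    alpha: float

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "species": [s.to_dict() for s in self.species]}

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            species=tuple(SpeciesComparison.from_dict(s) for s in d["species"]),
            alpha=d["alpha"],
        )


def compare_species(
    species: str,
    aci_curves: Sequence[ResponseCurve],
    jci_curves: Sequence[ResponseCurve],
    config: FitConfig = FitConfig(),
    alpha: float = 0.05,
    solve_threshold: bool = False,
) -> SpeciesComparison:
    """Fit both FvCB sub-models and the empirical model, compare with the
    observed J_f-max, and assemble one species' comparison row.

    The leaf biochemistry (Vcmax, TPU, Rd, Gamma*) is fitted once per
    replicate (sub-model I) and shared with the sub-model II estimate,
    whose J is re-estimated on the RuBP-limited segment (the sub-models
    differ only in that phase's stoichiometry).  When ``solve_threshold``
    is set and sub-model I overestimates, the Gamma*-coefficient b* at
    which the mean J_A-max would equal the observed mean is solved as well.
    """
    from .fit_engine import refit_j_shared

    j_i, j_ii, j_emp = [], [], []
    for rep, curve in enumerate(aci_curves):
        cfg = FitConfig(**{**config.__dict__, "seed": config.seed + 1000 * rep})
        res_i = fit_fvcb(curve, SUBMODEL_I, cfg)
        res_ii = refit_j_shared(curve, res_i, SUBMODEL_II)
        j_i.append(res_i.params["j"])
        j_ii.append(res_ii.params["j"])
    for rep, curve in enumerate(jci_curves):
        cfg = FitConfig(**{**config.__dict__, "seed": config.seed + 1000 * rep + 7})
        j_emp.append(fit_empirical(curve, cfg).derived["jfmax"])

    summaries = {
        "submodel_I": GroupSummary.from_values("submodel_I", j_i),
        "submodel_II": GroupSummary.from_values("submodel_II", j_ii),
        "empirical": GroupSummary.from_values("empirical", j_emp),
        "observed": observed_jfmax(jci_curves),
    }
    anova, letters, pairwise = anova_letters(
        list(summaries.values()), alpha=alpha, reference="observed"
    )
    credibility = {
        key: credibility_check(summaries[key], summaries["observed"], alpha).status
        for key in ("submodel_I", "submodel_II")
    }
    threshold_b = f_star = None
    if solve_threshold and credibility["submodel_I"] == "overestimate":
        first = fit_fvcb(aci_curves[0], SUBMODEL_I, config)
        res = threshold_b_coefficient(
            aci_curves,
            summaries["observed"].mean,
            config,
            fixed={
                "rd": first.params["rd"],
                "gamma_star": first.params["gamma_star"],
            },
        )
        if res.found:
            threshold_b, f_star = res.b_star, res.implied_f
    return SpeciesComparison(
        species=species,
        summaries=summaries,
        letters=letters,
        anova_p=anova.p,
        pairwise_p={f"{a}|{b}": r.p for (a, b), r in pairwise.items()},
        credibility=credibility,
        threshold_b=threshold_b,
        implied_f=f_star,
    )


def run_study(
    bundle: StudyBundle,
    config: FitConfig = FitConfig(),
    alpha: float = 0.05,
    solve_threshold: bool = False,
) -> ComparisonReport:
    """Full pipeline over a study bundle: fit, test, letter, verdict."""
    rows = []
    for k, name in enumerate(bundle.species):
        cfg = FitConfig(**{**config.__dict__, "seed": config.seed + 100_000 * k})
        rows.append(
            compare_species(
                name, bundle.aci[name], bundle.jci[name], cfg, alpha, solve_threshold
            )
        )
    return ComparisonReport(species=tuple(rows), alpha=alpha)
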