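"""Reading and writing gas-exchange / fluorescence response curves.

The on-disk format is a plain comma-separated table, UTF-8, one observation
per row, with a header.  Column names are configurable through a
:class:`Dialect` so that instrument exports (e.g. LI-6400 headers ``Ci``,
``Photo``, ``PARi``, ``PhiPS2``, ``ETR``) can be read without renaming.

Fluorescence gives either the electron transport rate J directly or the
PSII operating efficiency PhiPSII; :func:`compute_etr` applies the standard
fluorometer convention J = PhiPSII x PPFD x absorptance x PSII fraction.
A J column, when present, takes precedence over recomputation from PhiPSII.

Curves are stored in measurement order (independent variable descending,
the order in which levels are stepped on the instrument); fitting operates
on values, not order.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, FormatError, ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .intercompare import ComparisonReport

__all__ = [
    "ObservationRecord",
    "CurveKind",
    "ResponseCurve",
    "Dialect",
    "DEFAULT_DIALECT",
    "LI6400_DIALECT",
    "EtrConstants",
    "compute_etr",
    "read_curves",
    "write_curves",
    "write_report",
    "read_report",
    "load_config",
]

#: Default leaf absorptance (dimensionless) of the fluorometer convention.
DEFAULT_LEAF_ABSORPTANCE = 0.84
#: Default fraction of absorbed quanta reaching PSII.
DEFAULT_PSII_FRACTION = 0.5


@dataclass(frozen=True)
class ObservationRecord:
    """One logged observation: gas exchange plus optional fluorescence.

    ``an`` may be None on pure fluorescence (J-Ci) curves; at least one of
    ``j`` / ``phi_psii`` must be present when fluorescence is used.
    """

    species: str
    replicate: int
    ci: float
    an: Optional[float]
    ppfd: float
    j: Optional[float] = None
    phi_psii: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if self.ci < 0:
            raise ValidationError("ci must be non-negative")
        if self.ppfd < 0:
            raise ValidationError("ppfd must be non-negative")
        if self.phi_psii is not None and not (0.0 <= self.phi_psii <= 1.0):
            raise ValidationError("phi_psii must lie in [0, 1]")


class CurveKind(str, enum.Enum):
    A_VS_CI = "A_vs_Ci"
    J_VS_CI = "J_vs_Ci"
    A_VS_I = "A_vs_I"


@dataclass(frozen=True)
class ResponseCurve:
    """One replicate's ordered response curve.

    ``held_constant`` names the controlled variable and its value:
    irradiance for CO2-response curves, ambient CO2 for light-response
    curves.
    """

    kind: CurveKind
    species: str
    replicate: int
    records: tuple[ObservationRecord, ...]
    held_constant: Optional[tuple[str, float]] = None

    def __post_init__(self) -> None:
        if len(self.records) < 5:
            raise ValidationError(
                f"a response curve needs at least 5 records, got {len(self.records)}"
            )
        x = self.independent_values
        if len(np.unique(x)) != len(x):
            raise ValidationError(
                f"duplicate independent-variable values in curve "
                f"({self.species!r}, rep {self.replicate}, {self.kind.value})"
            )

    @property
    def independent_values(self) -> np.ndarray:
        if self.kind is CurveKind.A_VS_I:
            return np.array([r.ppfd for r in self.records], dtype=float)
        return np.array([r.ci for r in self.records], dtype=float)

    @property
    def dependent_values(self) -> np.ndarray:
        if self.kind is CurveKind.J_VS_CI:
            if any(r.j is None for r in self.records):
                raise ValidationError(
                    f"J-Ci curve ({self.species!r}, rep {self.replicate}) "
                    "is missing J values"
                )
            return np.array([r.j for r in self.records], dtype=float)
        if any(r.an is None for r in self.records):
            raise ValidationError(
                f"curve ({self.species!r}, rep {self.replicate}) is missing An values"
            )
        return np.array([r.an for r in self.records], dtype=float)


@dataclass(frozen=True)
class Dialect:
    """Column-name map of the CSV dialect."""

    species: str = "species"
    replicate: str = "replicate"
    ci: str = "ci"
    an: str = "an"
    ppfd: str = "ppfd"
    j: str = "j"
    phi_psii: str = "phi_psii"


DEFAULT_DIALECT = Dialect()
#: Aliases matching LI-6400 export headers.
LI6400_DIALECT = Dialect(
    species="Species",
    replicate="Rep",
    ci="Ci",
    an="Photo",
    ppfd="PARi",
    j="ETR",
    phi_psii="PhiPS2",
)


@dataclass(frozen=True)
class EtrConstants:
    leaf_absorptance: float = DEFAULT_LEAF_ABSORPTANCE
    psii_fraction: float = DEFAULT_PSII_FRACTION


def compute_etr(
    phi_psii,
    ppfd,
    leaf_absorptance: float = DEFAULT_LEAF_ABSORPTANCE,
    psii_fraction: float = DEFAULT_PSII_FRACTION,
):
    """PSII electron transport rate from fluorescence yield.

    J = PhiPSII x PPFD x absorptance x PSII fraction, umol m-2 s-1.
    Linear in both PhiPSII and PPFD.
    """
    phi = np.asarray(phi_psii, dtype=float)
    q = np.asarray(ppfd, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise DomainError("phi_psii must lie in [0, 1]")
    if np.any(q < 0):
        raise DomainError("ppfd must be non-negative")
    if not (0 < leaf_absorptance <= 1):
        raise DomainError("leaf_absorptance must lie in (0, 1]")
    if not (0 < psii_fraction < 1):
        raise DomainError("psii_fraction must lie in (0, 1)")
    out = phi * q * leaf_absorptance * psii_fraction
    return out if out.ndim else float(out)


def _numeric_column(df: pd.DataFrame, col: str, path, required: bool):
    """Convert a column to float, reporting the first offending row."""
    if col not in df.columns:
        if required:
            raise FormatError(f"{path}: missing required column {col!r}")
        return None
    raw = df[col]
    converted = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = converted.isna() & ~blank
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, "
            f"data row {row + 1}"
        )
    if required and blank.any():
        row = int(np.nonzero(blank.to_numpy())[0][0])
        raise ParseError(f"{path}: empty cell in required column {col!r}, data row {row + 1}")
    return converted.to_numpy(dtype=float), blank.to_numpy()


def read_curves(
    path,
    kind: CurveKind | str,
    dialect: Dialect = DEFAULT_DIALECT,
    etr_constants: EtrConstants = EtrConstants(),
) -> list[ResponseCurve]:
    """Read one ResponseCurve per (species, replicate) group from a CSV file.

    Records are sorted by the independent variable descending (measurement
    order).  When the J column is absent but PhiPSII is present, J is
    derived via :func:`compute_etr`.

    Raises :class:`FormatError` for a missing required column,
    :class:`ParseError` (with the row number) for a non-numeric cell, and
    :class:`ValidationError` for duplicated independent-variable values
    within a curve.
    """
    kind = CurveKind(kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)

    for col in (dialect.species, dialect.replicate):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    need_an = kind in (CurveKind.A_VS_CI, CurveKind.A_VS_I)
    ci_vals, _ = _numeric_column(df, dialect.ci, path, required=True)
    ppfd_required = kind is CurveKind.A_VS_I
    ppfd_res = _numeric_column(df, dialect.ppfd, path, required=ppfd_required)
    an_res = _numeric_column(df, dialect.an, path, required=need_an)
    j_res = _numeric_column(df, dialect.j, path, required=False)
    phi_res = _numeric_column(df, dialect.phi_psii, path, required=False)
    if kind is CurveKind.J_VS_CI and j_res is None and phi_res is None:
        raise FormatError(
            f"{path}: a J-Ci file needs a {dialect.j!r} or {dialect.phi_psii!r} column"
        )

    n = len(df)
    rep_raw = pd.to_numeric(df[dialect.replicate], errors="coerce")
    if rep_raw.isna().any():
        row = int(np.nonzero(rep_raw.isna().to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric replicate id in data row {row + 1}"
        )
    reps = rep_raw.to_numpy(dtype=int)
    species = df[dialect.species].to_numpy()

    def cell(res, i):
        if res is None:
            return None
        vals, blank = res
        return None if blank[i] else float(vals[i])

    records = []
    for i in range(n):
        ppfd = cell(ppfd_res, i)
        j = cell(j_res, i)
        phi = cell(phi_res, i)
        if j is None and phi is not None and ppfd is not None:
            j = compute_etr(
                phi, ppfd, etr_constants.leaf_absorptance, etr_constants.psii_fraction
            )
        records.append(
            ObservationRecord(
                species=str(species[i]),
                replicate=int(reps[i]),
                ci=float(ci_vals[i]),
                an=cell(an_res, i),
                ppfd=0.0 if ppfd is None else ppfd,
                j=j,
                phi_psii=phi,
            )
        )

    groups: dict[tuple[str, int], list[ObservationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species, rec.replicate), []).append(rec)

    curves = []
    for (sp, rep), recs in groups.items():
        key = (lambda r: r.ppfd) if kind is CurveKind.A_VS_I else (lambda r: r.ci)
        recs = sorted(recs, key=key, reverse=True)
        if kind is CurveKind.A_VS_I:
            held = ("ci", recs[0].ci)
        else:
            held = ("ppfd", recs[0].ppfd)
        curves.append(
            ResponseCurve(
                kind=kind,
                species=sp,
                replicate=rep,
                records=tuple(recs),
                held_constant=held,
            )
        )
    curves.sort(key=lambda c: (c.species, c.replicate))
    return curves


def write_curves(curves: Sequence[ResponseCurve], path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    """Write curves to CSV in the given dialect (lossless for numeric fields)."""
    rows = []
    for curve in curves:
        for r in curve.records:
            rows.append(
                {
                    dialect.species: r.species,
                    dialect.replicate: r.replicate,
                    dialect.ci: r.ci,
                    dialect.an: r.an,
                    dialect.ppfd: r.ppfd,
                    dialect.j: r.j,
                    dialect.phi_psii: r.phi_psii,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _fmt_group(mean: float, se: float, letter: str) -> str:
    s = f"{mean:.2f} +/- {se:.2f}"
    return f"{s} {letter}" if letter else s


def write_report(report: "ComparisonReport", path) -> None:
    """Write a comparison report as a table-shaped CSV plus a JSON twin.

    The CSV has one row per species with ``mean +/- SE letter`` cells for
    the two FvCB sub-models, the empirical fit and the observed maximum;
    the JSON twin (same stem, ``.json`` suffix) round-trips bit-exactly via
    :func:`read_report`.
    """
    path = Path(path)
    rows = []
    for sp in report.species:
        row = {"species": sp.species}
        for key in ("submodel_I", "submodel_II", "empirical", "observed"):
            g = sp.summaries.get(key)
            letter = sp.letters.get(key, "")
            row[key] = "" if g is None else _fmt_group(g.mean, g.se, letter)
        row["credibility_I"] = sp.credibility.get("submodel_I", "")
        row["credibility_II"] = sp.credibility.get("submodel_II", "")
        if sp.threshold_b is not None:
            row["threshold_b"] = f"{sp.threshold_b:.3f}"
            row["implied_f"] = f"{sp.implied_f:.3f}"
        rows.append(row)
    columns = [
        "species", "submodel_I", "submodel_II", "empirical", "observed",
        "credibility_I", "credibility_II",
    ]
    if any("threshold_b" in r for r in rows):
        columns += ["threshold_b", "implied_f"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_report(path) -> "ComparisonReport":
    """Read back the JSON twin written by :func:`write_report`."""
    from .intercompare import ComparisonReport

    with open(path) as fh:
        return ComparisonReport.from_dict(json.load(fh))


def load_config(path) -> dict:
    """Load a YAML config holding a column map and ETR constants.

    Recognised keys: ``columns`` (mapping of Dialect field names to CSV
    headers), ``leaf_absorptance``, ``psii_fraction``.  Returns a dict with
    ``dialect`` (:class:`Dialect`) and ``etr_constants``
    (:class:`EtrConstants`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    columns = raw.get("columns", {})
    valid = {f.name for f in fields(Dialect)}
    unknown = set(columns) - valid
    if unknown:
        raise FormatError(f"unknown column-map keys: {sorted(unknown)}")
    dialect = Dialect(**columns)
    etr = EtrConstants(
        leaf_absorptance=float(raw.get("leaf_absorptance", DEFAULT_LEAF_ABSORPTANCE)),
        psii_fraction=float(raw.get("psii_fraction", DEFAULT_PSII_FRACTION)),
    )
    if not (0 < etr.leaf_absorptance <= 1) or not (0 < etr.psii_fraction < 1):
        raise DomainError("ETR constants out of range in config")
    return {"dialect": dialect, "etr_constants": etr}
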