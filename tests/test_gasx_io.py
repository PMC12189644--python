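"""CSV dialects, fluorometer ETR conversion, report round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from etrfit.errors import DomainError, FormatError, ParseError, ValidationError
from etrfit.fit_engine import FitConfig
from etrfit.gasx_io import (
    LI6400_DIALECT,
    CurveKind,
    EtrConstants,
    ObservationRecord,
    ResponseCurve,
    compute_etr,
    load_config,
    read_curves,
    read_report,
    write_curves,
    write_report,
)
from etrfit.intercompare import ComparisonReport, run_study
from etrfit.synthetic_data import (
    DEFAULT_EMPIRICAL_TRUTH,
    DEFAULT_FVCB_TRUTH,
    ScenarioConfig,
    gen_aci,
    gen_jci,
    gen_paper_like_study,
)


def _write_csv(path, header, rows):
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")


class TestComputeEtr:
    def test_standard_convention_value(self):
        assert compute_etr(0.25, 1000, 0.84, 0.5) == pytest.approx(105.0)

    def test_zero_yield(self):
        assert compute_etr(0.0, 1234, 0.84, 0.5) == 0.0

    def test_limiting_case(self):
        assert compute_etr(1.0, 100, 1.0, 0.5) == pytest.approx(50.0)

    @given(
        phi=st.floats(0.01, 1.0),
        ppfd=st.floats(0.0, 2500.0),
        c=st.floats(0.1, 3.0),
    )
    def test_linear_in_each_argument(self, phi, ppfd, c):
        base = compute_etr(phi, ppfd)
        assert compute_etr(phi, c * ppfd) == pytest.approx(c * base, rel=1e-12)
        if c * phi <= 1.0:
            assert compute_etr(c * phi, ppfd) == pytest.approx(c * base, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phi_psii": -0.1, "ppfd": 100},
            {"phi_psii": 1.2, "ppfd": 100},
            {"phi_psii": 0.5, "ppfd": -5},
            {"phi_psii": 0.5, "ppfd": 100, "leaf_absorptance": 0.0},
            {"phi_psii": 0.5, "ppfd": 100, "psii_fraction": 1.0},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(DomainError):
            compute_etr(**kwargs)


class TestReadCurves:
    def test_single_replicate_twelve_levels(self, tmp_path):
        ci = [1600, 1400, 1200, 1000, 800, 600, 420, 300, 200, 100, 60, 0]
        rows = [["wheat", 1, c, 10.0, 1200, 0.3] for c in ci]
        p = tmp_path / "one.csv"
        _write_csv(p, "species,replicate,ci,an,ppfd,phi_psii", rows)
        curves = read_curves(p, CurveKind.A_VS_CI)
        assert len(curves) == 1
        assert len(curves[0].records) == 12
        # measurement order high -> low
        assert list(curves[0].independent_values) == sorted(ci, reverse=True)

    def test_three_replicates_grouped(self, tmp_path):
        ci = [1600, 1400, 1200, 1000, 800, 600, 420, 300, 200, 100, 60, 0]
        rows = [["w", r, c, 10.0, 1200, ""] for r in (1, 2, 3) for c in ci]
        p = tmp_path / "three.csv"
        _write_csv(p, "species,replicate,ci,an,ppfd,phi_psii", rows)
        curves = read_curves(p, "A_vs_Ci")
        assert len(curves) == 3
        assert all(len(c.records) == 12 for c in curves)

    def test_missing_ci_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        _write_csv(p, "species,replicate,an,ppfd", [["w", 1, 10.0, 1200]])
        with pytest.raises(FormatError, match="ci"):
            read_curves(p, CurveKind.A_VS_CI)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        rows = [["w", 1, c, 10.0, 1200] for c in (1600, 1400, 1200, 1000, 800)]
        rows[3][3] = "oops"
        p = tmp_path / "nan.csv"
        _write_csv(p, "species,replicate,ci,an,ppfd", rows)
        with pytest.raises(ParseError, match="row 4"):
            read_curves(p, CurveKind.A_VS_CI)

    def test_duplicate_ci_within_curve_rejected(self, tmp_path):
        rows = [["w", 1, c, 10.0, 1200] for c in (1600, 1400, 1400, 1000, 800)]
        p = tmp_path / "dup.csv"
        _write_csv(p, "species,replicate,ci,an,ppfd", rows)
        with pytest.raises(ValidationError, match="duplicate"):
            read_curves(p, CurveKind.A_VS_CI)

    def test_li6400_dialect_aliases(self, tmp_path):
        rows = [["w", 1, c, 10.0, 1200, 150.0] for c in (1600, 1200, 800, 400, 100)]
        p = tmp_path / "li.csv"
        _write_csv(p, "Species,Rep,Ci,Photo,PARi,ETR", rows)
        curves = read_curves(p, CurveKind.J_VS_CI, LI6400_DIALECT)
        assert curves[0].records[0].j == 150.0

    def test_j_derived_from_phi_when_absent(self, tmp_path):
        rows = [["w", 1, c, 10.0, 1000, 0.25] for c in (1600, 1200, 800, 400, 100)]
        p = tmp_path / "phi.csv"
        _write_csv(p, "species,replicate,ci,an,ppfd,phi_psii", rows)
        curves = read_curves(p, CurveKind.J_VS_CI)
        assert curves[0].records[0].j == pytest.approx(105.0)

    def test_j_column_takes_precedence_over_phi(self, tmp_path):
        rows = [["w", 1, c, 10.0, 1000, 0.25, 90.0] for c in (1600, 1200, 800, 400, 100)]
        p = tmp_path / "both.csv"
        _write_csv(p, "species,replicate,ci,an,ppfd,phi_psii,j", rows)
        curves = read_curves(p, CurveKind.J_VS_CI)
        assert curves[0].records[0].j == 90.0


class TestRoundTrip:
    @pytest.mark.parametrize("gen,cfg_kw", [
        (gen_aci, {"truth": DEFAULT_FVCB_TRUTH}),
        (gen_jci, {"truth": DEFAULT_EMPIRICAL_TRUTH}),
    ])
    def test_write_read_lossless(self, tmp_path, gen, cfg_kw):
        ds = gen(ScenarioConfig(n_reps=2, noise_sd=0.3, seed=9, **cfg_kw))
        p = tmp_path / "rt.csv"
        write_curves(ds.curves, p)
        kind = ds.curves[0].kind
        back = read_curves(p, kind)
        assert len(back) == len(ds.curves)
        for a, b in zip(ds.curves, back):
            np.testing.assert_allclose(a.independent_values, b.independent_values, rtol=1e-6)
            np.testing.assert_allclose(a.dependent_values, b.dependent_values, rtol=1e-6)


class TestCurveValidation:
    def _rec(self, ci):
        return ObservationRecord("w", 1, ci, 5.0, 1200.0)

    def test_minimum_five_records(self):
        with pytest.raises(ValidationError):
            ResponseCurve(CurveKind.A_VS_CI, "w", 1, tuple(self._rec(c) for c in (1, 2, 3, 4)))

    def test_phi_psii_range_enforced(self):
        with pytest.raises(ValidationError):
            ObservationRecord("w", 1, 100.0, 5.0, 1200.0, phi_psii=1.2)

    def test_j_curve_without_j_rejected_on_access(self):
        curve = ResponseCurve(
            CurveKind.J_VS_CI, "w", 1, tuple(self._rec(c) for c in (1, 2, 3, 4, 5))
        )
        with pytest.raises(ValidationError, match="missing J"):
            curve.dependent_values


@pytest.fixture(scope="module")
def report():
    bundle = gen_paper_like_study(seed=2)
    cfg = FitConfig(seed=2, sweeps=60, proposals_per_sweep=25)
    return run_study(bundle, cfg)


class TestReport:
    def test_csv_has_one_row_per_species(self, tmp_path, report):
        p = tmp_path / "report.csv"
        write_report(report, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 + len(report.species) == 5

    def test_json_round_trips_bit_exactly(self, tmp_path, report):
        p = tmp_path / "report.csv"
        write_report(report, p)
        assert read_report(p.with_suffix(".json")) == report

    def test_empty_report_header_only(self, tmp_path):
        empty = ComparisonReport(species=(), alpha=0.05)
        p = tmp_path / "empty.csv"
        write_report(empty, p)
        assert len(p.read_text().strip().splitlines()) == 1


class TestConfig:
    def test_yaml_column_map_and_constants(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "columns:\n  ci: Ci\n  an: Photo\nleaf_absorptance: 0.85\npsii_fraction: 0.45\n"
        )
        cfg = load_config(p)
        assert cfg["dialect"].ci == "Ci"
        assert cfg["dialect"].species == "species"  # default preserved
        assert cfg["etr_constants"] == EtrConstants(0.85, 0.45)

    def test_unknown_column_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("columns:\n  bogus: X\n")
        with pytest.raises(FormatError):
            load_config(p)
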