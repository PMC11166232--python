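"""Rendering companions, category alignment, report bundles, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from patternshift import (
    ComplexityParams,
    PTDAConfig,
    TransitionEstimate,
    align_categories,
    build_crd,
    dc_series,
    export_report,
    instability_periods,
    locf_impute,
    render_crd,
    render_transition_band,
    run_ptda,
    simulate_categories,
    simulate_process,
    surrogate_null,
    SyntheticSpec,
)
from patternshift.cli import main as cli_main
from patternshift.complexity import InstabilityPeriod
from patternshift.reporting import CATEGORY_BAND_ORDER, transition_band


def estimate_from(day_weights, points=None):
    return TransitionEstimate(
        transition_day=max(day_weights, key=day_weights.get),
        probability=0.5,
        surrogate_p=None,
        contributing_points=points or [],
        pooled_histogram=day_weights,
        per_channel={"F": points or []},
    )


@pytest.fixture(scope="module")
def small_pipeline():
    spec = SyntheticSpec(seed=21)
    series, truth = simulate_process(spec)
    imputed = locf_impute(series)
    from patternshift import factor_scores

    fac = factor_scores(imputed)
    params = ComplexityParams(n_surrogates=100, seed=21)
    null = surrogate_null(fac, params)
    field = build_crd(dc_series(fac, params), null)
    periods = instability_periods(field, null)
    est = run_ptda(imputed, PTDAConfig(seed=21), compute_surrogate_p=False)
    est.surrogate_p = 0.0099  # stand-in for the full surrogate run
    timeline = simulate_categories(truth, spec)
    return imputed, fac, field, null, periods, est, timeline


class TestRenderCrd:
    def test_companion_csv_matches_field(self, small_pipeline, tmp_path):
        _, fac, field, _, _, est, timeline = small_pipeline
        out = render_crd(field, timeline, est, tmp_path / "crd.png")
        assert out.exists()
        comp = pd.read_csv(tmp_path / "crd.csv")
        hist = comp[comp.channel == "__histogram__"]
        assert len(hist) == fac.n_days
        assert np.array_equal(hist.dc.to_numpy(), field.column_histogram)
        cells = comp[comp.channel != "__histogram__"]
        assert len(cells) == int(field.defined.sum())

    def test_zero_significance_histogram_all_zero(self, series_factory, tmp_path):
        s = series_factory(np.full((2, 40), 60.0))
        p = ComplexityParams(n_surrogates=100, seed=0)
        field = build_crd(dc_series(s, p), surrogate_null(s, p))
        render_crd(field, out=tmp_path / "flat.png")
        comp = pd.read_csv(tmp_path / "flat.csv")
        assert (comp[comp.channel == "__histogram__"].dc == 0).all()

    def test_band_rows_are_the_eight_subcategories(self):
        assert len(CATEGORY_BAND_ORDER) == 8
        assert "no_entry" not in CATEGORY_BAND_ORDER


class TestTransitionBand:
    def test_pooling_example_peaks_at_65(self, tmp_path):
        est = estimate_from({65: 2.0, 64: 1.0, 66: 1.0, 63: 1.0, 20: 1.0})
        est.transition_day = 65
        band = transition_band(est, 90)
        assert int(np.argmax(band)) + 1 == 65
        render_transition_band(est, 90, tmp_path / "band.png")
        comp = pd.read_csv(tmp_path / "band.csv")
        assert comp.intensity.max() == pytest.approx(1.0)
        assert (comp.intensity >= 0).all()
        assert int(comp.loc[comp.intensity.idxmax(), "day"]) == 65

    def test_single_point_single_peak(self):
        band = transition_band(estimate_from({40: 1.0}), 90)
        assert int(np.argmax(band)) + 1 == 40
        assert band[39] == 1.0


class TestAlignment:
    def test_counts_sum_to_n_days(self, small_pipeline):
        *_, periods, est, timeline = small_pipeline
        results = align_categories(timeline, periods, est, seed=0, n_perm=200)
        for r in results:
            assert sum(r.counts.values()) == r.n_days
            assert 0 < r.permutation_p <= 1

    def test_coupled_instability_detected(self):
        hits = 0
        for seed in range(15):
            spec = SyntheticSpec(
                seed=seed, transition_day=None, instability_window=(25, 45)
            )
            series, truth = simulate_process(spec)
            timeline = simulate_categories(truth, spec)
            periods = [
                InstabilityPeriod("case_mean", 25, 45, mean_dc=0.2, p_value=0.01)
            ]
            res = {
                r.group: r
                for r in align_categories(
                    timeline, periods, None, n_perm=300, seed=seed
                )
            }
            hits += res["critical_instability"].permutation_p < 0.05
        assert hits >= 11  # strong built-in coupling found most of the time

    def test_requires_an_indicator(self, small_pipeline):
        *_, timeline = small_pipeline
        with pytest.raises(Exception):
            align_categories(timeline, None, None)


class TestExportReport:
    def test_bundle_contract_and_determinism(self, small_pipeline, tmp_path):
        imputed, fac, field, null, periods, est, timeline = small_pipeline
        out1 = export_report(
            imputed, field, est, periods, None, timeline,
            tmp_path / "r1", manifest={"seed": 21},
        )
        summary = json.loads((out1 / "summary.json").read_text())
        assert set(summary) >= {"transition_day", "probability", "surrogate_p", "periods"}
        assert (out1 / "crd.png").exists()
        assert (out1 / "transition_band.csv").exists()
        assert (out1 / "change_points.csv").exists()
        export_report(
            imputed, field, est, periods, None, timeline,
            tmp_path / "r2", manifest={"seed": 21},
        )
        assert (out1 / "summary.json").read_text() == (
            tmp_path / "r2" / "summary.json"
        ).read_text()

    def test_missing_mandatory_artifact_errors(self, small_pipeline, tmp_path):
        imputed, _, field, _, periods, est, _ = small_pipeline
        with pytest.raises(Exception):
            export_report(imputed, None, est, periods, out_dir=tmp_path / "x")


class TestCli:
    def test_simulate_then_dc_roundtrip(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--out", str(tmp_path / "sim")],
        )
        assert r.exit_code == 0, r.output
        for name in ("case.csv", "schema.json", "categories.csv", "truth.json"):
            assert (tmp_path / "sim" / name).exists()
        r = runner.invoke(
            cli_main,
            [
                "dc", "--in", str(tmp_path / "sim" / "case.csv"),
                "--schema", str(tmp_path / "sim" / "schema.json"),
                "--surrogates", "100", "--seed", "3",
                "--out", str(tmp_path / "dcout"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "dcout" / "crd.csv").exists()
        assert (tmp_path / "dcout" / "instability_periods.json").exists()

    def test_validation_failure_exits_2(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("case_id,day,item_id,value\nc,1,WPE01,140\nc,2,WPE01,20\n")
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["dc", "--in", str(bad), "--surrogates", "100", "--seed", "1",
             "--out", str(tmp_path / "o")],
        )
        assert r.exit_code == 2
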