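"""Stress-test metric arithmetic, plateau estimation and the exact
bioenergetic identities (reserve, spare capacity, ATP + leak = basal)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboswitch.flux import (
    FluxValidationError,
    GLYCOLYSIS_STRESS,
    MITO_STRESS,
    GlycolysisMetrics,
    InjectionSchedule,
    MitoMetrics,
    SegmentLevels,
    compare_conditions,
    glycolysis_stress_metrics,
    mito_stress_metrics,
    normalize_per_cells,
    ocr_ecar_ratio,
    read_plate_tsv,
    segment_trace,
    write_plate_tsv,
)
from metaboswitch.synthetic import FluxSimSpec, generate_flux_trace

MITO_PLATEAUS = (("baseline", 30.0), ("oligomycin", 10.0), ("FCCP", 62.0),
                 ("rotenone/antimycin A", 2.0))
GLYCO_PLATEAUS = (("baseline", 10.0), ("glucose", 40.0), ("oligomycin", 60.0),
                  ("2DG", 4.0))


def glyco_levels(baseline, glucose, oligo, dg):
    return SegmentLevels(GLYCOLYSIS_STRESS,
                         {"baseline": baseline, "glucose": glucose,
                          "oligomycin": oligo, "2DG": dg},
                         {}, {})


def mito_levels(baseline, oligo, fccp, rot):
    return SegmentLevels(MITO_STRESS,
                         {"baseline": baseline, "oligomycin": oligo,
                          "FCCP": fccp, "rotenone/antimycin A": rot},
                         {}, {})


class TestSegmentTrace:
    def test_noise_free_levels_equal_plateaus(self):
        spec = FluxSimSpec(GLYCO_PLATEAUS, kind="ECAR", noise_sd=0.0, seed=0)
        levels = segment_trace(generate_flux_trace(spec))
        assert [levels[lbl] for lbl, _ in GLYCO_PLATEAUS] == [10.0, 40.0, 60.0, 4.0]

    def test_single_cycle_per_segment_uses_that_measurement(self):
        spec = FluxSimSpec(MITO_PLATEAUS, cycles_per_segment=1, noise_sd=0.3, seed=8)
        trace = generate_flux_trace(spec)
        levels = segment_trace(trace)
        for i, (lbl, _) in enumerate(MITO_PLATEAUS):
            assert levels[lbl] == trace.rates[i]
            assert levels.n_points[lbl] == 1

    def test_first_post_injection_cycle_dropped_in_long_segments(self):
        # 5 cycles/segment: injection transient at the segment start must not
        # leak into the plateau estimate of later segments
        spec = FluxSimSpec(MITO_PLATEAUS, cycles_per_segment=5, noise_sd=0.0, seed=0)
        trace = generate_flux_trace(spec)
        rates = trace.rates.copy()
        rates[5] = 999.0  # corrupt the first post-oligomycin cycle
        corrupted = type(trace)(trace.well, trace.kind, trace.time_min, rates,
                                trace.schedule, trace.cell_count)
        levels = segment_trace(corrupted, k=3)
        assert levels["oligomycin"] == 10.0

    def test_empty_segment_error_names_segment(self):
        schedule = InjectionSchedule(MITO_STRESS, (("oligomycin", 3), ("FCCP", 6),
                                                   ("rotenone/antimycin A", 9)))
        spec = FluxSimSpec(MITO_PLATEAUS, cycles_per_segment=3, noise_sd=0.0, seed=0)
        trace = generate_flux_trace(spec)
        short = type(trace)(trace.well, trace.kind, trace.time_min[:9],
                            trace.rates[:9], schedule, trace.cell_count)
        with pytest.raises(FluxValidationError, match="rotenone"):
            segment_trace(short)

    def test_monte_carlo_level_error_within_noise_budget(self):
        spec = FluxSimSpec(MITO_PLATEAUS, noise_sd=0.5, seed=21)
        errs = []
        for i in range(100):
            levels = segment_trace(generate_flux_trace(spec, well=f"W{i}"))
            errs.extend(abs(levels[lbl] - val) for lbl, val in MITO_PLATEAUS)
        assert np.mean(errs) < 3 * (0.5 / np.sqrt(3))


class TestGlycolysisMetrics:
    def test_worked_example(self):
        m = glycolysis_stress_metrics(glyco_levels(10, 40, 60, 11))
        assert (m.non_glycolytic_acidification, m.basal_glycolysis,
                m.glycolytic_capacity, m.glycolytic_reserve) == (10, 30, 50, 20)
        assert m.utilization_fraction == pytest.approx(0.6)

    def test_saturated_glycolysis_boundary(self):
        m = glycolysis_stress_metrics(glyco_levels(10, 40, 40, 11))
        assert m.glycolytic_reserve == 0
        assert m.utilization_fraction == pytest.approx(1.0)

    def test_negative_values_reported_with_warning(self):
        m = glycolysis_stress_metrics(glyco_levels(10, 5, 60, 11))
        assert m.basal_glycolysis == -5
        assert any("negative basal_glycolysis" in w for w in m.warnings)

    def test_wrong_assay_kind_rejected(self):
        with pytest.raises(FluxValidationError, match="glycolysis"):
            glycolysis_stress_metrics(mito_levels(30, 10, 62, 2))


class TestMitoMetrics:
    def test_worked_example_with_saturation_fraction(self):
        m = mito_stress_metrics(mito_levels(30, 10, 62, 2))
        assert (m.non_mitochondrial_ocr, m.basal_respiration,
                m.atp_linked_respiration, m.proton_leak,
                m.maximal_respiration, m.spare_capacity) == (2, 28, 20, 8, 60, 32)
        assert m.utilization_fraction == pytest.approx(28 / 60)
        assert round(m.utilization_fraction, 3) == 0.467

    def test_no_spare_capacity_when_basal_equals_maximal(self):
        m = mito_stress_metrics(mito_levels(30, 10, 30, 2))
        assert m.spare_capacity == 0
        assert m.utilization_fraction == pytest.approx(1.0)

    def test_degenerate_equal_plateaus_flagged(self):
        m = mito_stress_metrics(mito_levels(5, 5, 5, 5))
        assert m.basal_respiration == m.maximal_respiration == m.proton_leak == 0
        assert math.isnan(m.utilization_fraction)
        assert any("undefined" in w for w in m.warnings)


class TestIdentitiesAndNormalization:
    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=4, max_size=4))
    @settings(deadline=None)
    def test_mito_identities_exact(self, vals):
        m = mito_stress_metrics(mito_levels(*vals))
        assert m.spare_capacity == m.maximal_respiration - m.basal_respiration
        assert (m.atp_linked_respiration + m.proton_leak) == pytest.approx(
            m.basal_respiration, abs=1e-12)

    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=4, max_size=4))
    @settings(deadline=None)
    def test_glyco_reserve_identity_exact(self, vals):
        m = glycolysis_stress_metrics(glyco_levels(*vals))
        assert m.glycolytic_reserve == m.glycolytic_capacity - m.basal_glycolysis

    def test_normalization_scales_rates_only(self):
        m = mito_stress_metrics(mito_levels(30, 10, 62, 2))
        n = normalize_per_cells(m, cell_count=50_000, unit_cells=10_000)
        assert n.basal_respiration == pytest.approx(28 / 5)
        assert n.utilization_fraction == m.utilization_fraction
        ident = normalize_per_cells(m, cell_count=10_000, unit_cells=10_000)
        assert ident.basal_respiration == m.basal_respiration

    @given(st.floats(0.01, 100))
    @settings(deadline=None)
    def test_utilization_invariant_under_uniform_rescaling(self, c):
        a = mito_stress_metrics(mito_levels(30, 10, 62, 2))
        b = mito_stress_metrics(mito_levels(30 * c, 10 * c, 62 * c, 2 * c))
        assert b.utilization_fraction == pytest.approx(a.utilization_fraction)

    def test_non_positive_cell_count_rejected(self):
        m = mito_stress_metrics(mito_levels(30, 10, 62, 2))
        with pytest.raises(FluxValidationError):
            normalize_per_cells(m, cell_count=0)


class TestOcrEcarRatio:
    def test_worked_values(self):
        mito = MitoMetrics(2, 28, 20, 8, 60, 32, 28 / 60)
        glyco = GlycolysisMetrics(10, 14, 50, 36, 0.28)
        assert ocr_ecar_ratio(mito, glyco) == pytest.approx(2.0)
        glyco_eq = GlycolysisMetrics(10, 28, 50, 22, 0.56)
        assert ocr_ecar_ratio(mito, glyco_eq) == pytest.approx(1.0)

    def test_non_positive_basal_glycolysis_flagged(self):
        mito = MitoMetrics(2, 28, 20, 8, 60, 32, 28 / 60)
        glyco = GlycolysisMetrics(10, 0.0, 50, 50, 0.0)
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(ocr_ecar_ratio(mito, glyco))


class TestCompareConditions:
    def test_equal_condition_means_give_fold_one_p_one(self):
        df = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3,
                           "basal": [10.0, 11.0, 12.0, 12.0, 10.0, 11.0]})
        out = compare_conditions(df, reference="a")
        b = out[(out.condition == "b") & (out.metric == "basal")].iloc[0]
        assert b["fold_vs_reference"] == pytest.approx(1.0)
        assert b["p_value"] == pytest.approx(1.0)

    def test_single_well_condition_reports_fold_without_p(self):
        df = pd.DataFrame({"condition": ["a", "a", "b"], "basal": [10.0, 12.0, 22.0]})
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_conditions(df, reference="a")
        b = out[(out.condition == "b")].iloc[0]
        assert b["fold_vs_reference"] == pytest.approx(2.0)
        assert math.isnan(b["p_value"])

    def test_unknown_reference_rejected(self):
        df = pd.DataFrame({"condition": ["a"], "basal": [1.0]})
        with pytest.raises(FluxValidationError):
            compare_conditions(df, reference="zz")


class TestPlateIO:
    def test_round_trip(self, tmp_path):
        spec = FluxSimSpec(MITO_PLATEAUS, noise_sd=0.4, seed=13)
        traces = [generate_flux_trace(spec, well=f"W{i}") for i in range(3)]
        paths = [tmp_path / n for n in ("plate.tsv", "sched.tsv", "cells.tsv")]
        write_plate_tsv(traces, *paths)
        back = read_plate_tsv(*paths)
        assert [t.well for t in back] == [t.well for t in traces]
        for a, b in zip(traces, back):
            assert np.allclose(a.rates, b.rates)
            assert a.schedule == b.schedule
            assert a.cell_count == b.cell_count
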