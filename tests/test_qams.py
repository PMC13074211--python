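"""Single-marker core: correction factors, RRT assignment, durability, content."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pepperqams import (
    AnalyteDef,
    NoiseSpec,
    REFERENCE_CONDITION,
    assess_rcf_durability,
    assign_peaks,
    compute_content,
    compute_rcf,
    compute_rrt,
    quantify_qams,
)
from pepperqams.peaks import Peak
from pepperqams.presets import (
    RCF_HASS_IR,
    RETENTION_MIN,
    RRT_VS_NONIVAMIDE,
    hass_method,
    nonivamide_method,
    table_calibration_curves,
)
from pepperqams.simulate import simulate_condition_grid
from pepperqams.pipeline import DEFAULT_RCF_MIX_UG_ML

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


def _peak(t_r, height=100.0, area=1000.0, name="unassigned"):
    return Peak(
        t_r=t_r,
        area=area,
        height=height,
        left_bound=t_r - 1.0,
        right_bound=t_r + 1.0,
        snr=100.0,
        analyte_name=name,
    )


class TestCorrectionFactor:
    def test_identical_analyte_gives_unity(self):
        assert compute_rcf(2.0, 10.0, 2.0, 10.0) == 1.0

    def test_slope_ratio_reproduces_published_factor(self):
        curves = table_calibration_curves()
        f = compute_rcf(1.0, curves["HaSS"].slope, 1.0, curves["HbSS"].slope)
        assert f == pytest.approx(RCF_HASS_IR["HbSS"], rel=0.01)

    def test_direct_arithmetic(self):
        assert compute_rcf(2.0, 10.0, 1.0, 10.0) == 0.5

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_rcf(1.0, 0.0, 1.0, 1.0)

    @given(c_s=positive, a_s=positive, c_i=positive, a_i=positive)
    def test_quantify_inverts_rcf_exactly(self, c_s, a_s, c_i, a_i):
        f = compute_rcf(c_s, a_s, c_i, a_i)
        assert quantify_qams(a_i, a_s, c_s, f) == pytest.approx(c_i, rel=1e-12)

    @given(gain=st.floats(0.01, 100.0))
    def test_common_area_gain_cancels(self, gain):
        f0 = compute_rcf(2.0, 300.0, 5.0, 700.0)
        f1 = compute_rcf(2.0, 300.0 * gain, 5.0, 700.0 * gain)
        assert f1 == pytest.approx(f0, rel=1e-12)


class TestQuantify:
    def test_self_quantitation(self):
        assert quantify_qams(50.0, 50.0, 7.0, 1.0) == pytest.approx(7.0)

    def test_published_factor_arithmetic(self):
        # f = 0.0513, C_s = 10 µg/mL, area ratio 2 -> 1.026 µg/mL
        assert quantify_qams(20.0, 10.0, 10.0, 0.0513) == pytest.approx(1.026)

    def test_invalid_marker_area_rejected(self):
        with pytest.raises(ValueError):
            quantify_qams(1.0, 0.0, 1.0, 1.0)


class TestRrt:
    def test_marker_rrt_is_unity(self):
        assert compute_rrt(38.0, 38.0) == 1.0

    def test_nominal_time_ratio(self):
        assert compute_rrt(26.0, 38.0) == pytest.approx(0.6842, abs=1e-4)

    @given(scale=st.floats(0.1, 10.0))
    def test_invariant_under_common_time_scaling(self, scale):
        assert compute_rrt(26.0 * scale, 38.0 * scale) == pytest.approx(
            compute_rrt(26.0, 38.0), rel=1e-12
        )

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            compute_rrt(-1.0, 38.0)


class TestAssignment:
    def _standard_peaks(self, scale=1.0):
        heights = {"HeSS": 40, "HaSS": 90, "HbSS": 50, "Nonivamide": 70, "HgSS": 45}
        return [
            _peak(RETENTION_MIN[name] * scale, height=heights[name]) for name in heights
        ]

    def test_all_four_sanshools_assigned_vs_nonivamide(self):
        method = nonivamide_method()
        result = assign_peaks(
            self._standard_peaks(),
            method.analytes,
            rrt_tolerance=0.05,
            ir_locator=("nearest-time", 38.0),
        )
        assert result.missing == []
        for name in RRT_VS_NONIVAMIDE:
            assert result.assigned[name].t_r == pytest.approx(RETENTION_MIN[name])

    def test_missing_analyte_reported_not_fatal(self):
        method = nonivamide_method()
        peaks = [p for p in self._standard_peaks() if p.t_r != RETENTION_MIN["HgSS"]]
        result = assign_peaks(
            peaks, method.analytes, ir_locator=("nearest-time", 38.0)
        )
        assert result.missing == ["HgSS"]
        assert set(result.assigned) == {"Nonivamide", "HaSS", "HbSS", "HeSS"}

    def test_assignment_invariant_under_flow_rescaling(self):
        method = nonivamide_method()
        scale = 1.0 / 0.7  # flow 1.0 -> 0.7 mL/min stretches all times
        result = assign_peaks(
            self._standard_peaks(scale),
            method.analytes,
            ir_locator=("nearest-time", 38.0 * scale),
        )
        assert result.missing == []
        assert result.assigned["HgSS"].t_r == pytest.approx(42.0 * scale)

    def test_tallest_locator_finds_dominant_marker(self):
        method = hass_method()
        result = assign_peaks(
            [p for p in self._standard_peaks() if p.t_r != 38.0],
            method.analytes,
            ir_locator=("tallest", None),
        )
        assert result.assigned["HaSS"].t_r == pytest.approx(26.0)
        assert result.missing == []

    def test_empty_peak_list_rejected(self):
        with pytest.raises(ValueError):
            assign_peaks([], nonivamide_method().analytes)


class TestDurability:
    def test_shared_gain_gives_zero_rsd(self, responses):
        runs = simulate_condition_grid(
            responses,
            DEFAULT_RCF_MIX_UG_ML,
            noise=NoiseSpec(area_rsd=0.0, seed=1),
            run_gain_rsd=0.05,
        )
        for est in assess_rcf_durability(runs, "Nonivamide"):
            assert est.rsd_percent == pytest.approx(0.0, abs=1e-9)
            assert est.durable

    def test_independent_one_percent_noise_propagates_as_root_two(self, responses):
        # f is a ratio of two noisy areas: RSD ≈ √2 · 1% ≈ 1.4%
        rsds = []
        for seed in range(8):
            runs = simulate_condition_grid(
                responses,
                DEFAULT_RCF_MIX_UG_ML,
                grid=[
                    dataclasses.replace(REFERENCE_CONDITION, column_temp=t)
                    for t in np.linspace(25, 40, 20)
                ],
                noise=NoiseSpec(area_rsd=0.01, seed=seed),
            )
            ests = assess_rcf_durability(runs, "Nonivamide")
            rsds.extend(e.rsd_percent for e in ests)
        assert np.mean(rsds) == pytest.approx(np.sqrt(2.0), abs=0.5)

    def test_single_condition_reports_zero_rsd(self, responses):
        runs = simulate_condition_grid(
            responses, DEFAULT_RCF_MIX_UG_ML, grid=[REFERENCE_CONDITION]
        )
        for est in assess_rcf_durability(runs, "Nonivamide"):
            assert est.rsd_percent == 0.0
            assert len(est.per_condition_f) == 1

    def test_missing_marker_names_the_run(self, responses):
        runs = simulate_condition_grid(
            responses, {"HaSS": 10.0, "HbSS": 2.0}, grid=[REFERENCE_CONDITION]
        )
        with pytest.raises(ValueError, match="Nonivamide"):
            assess_rcf_durability(runs, "Nonivamide")


class TestContent:
    def test_hand_inverted_example(self):
        # C=0.045 mg/mL, V=25 mL, K=1, M=0.025 g -> 45 mg/g
        assert compute_content(0.045, 25.0, 1.0, 0.025) == pytest.approx(45.0)

    def test_zero_concentration_gives_zero_content(self):
        assert compute_content(0.0, 25.0, 1.0, 0.025) == 0.0

    def test_dilution_scales_linearly(self):
        assert compute_content(0.01, 25.0, 2.0, 0.025) == pytest.approx(
            2.0 * compute_content(0.01, 25.0, 1.0, 0.025)
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_content(0.01, 25.0, 1.0, 0.0)


def test_method_config_yaml_round_trip(tmp_path):
    method = nonivamide_method()
    path = tmp_path / "method.yaml"
    method.to_yaml(path)
    loaded = type(method).from_yaml(path)
    assert loaded == method
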