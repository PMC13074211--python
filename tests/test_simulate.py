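"""Simulator contracts: area conservation, determinism, condition transforms."""

import dataclasses

import numpy as np
import pytest

from pepperqams import (
    ConditionSet,
    NoiseSpec,
    PeakShapeSpec,
    REFERENCE_CONDITION,
    ResolutionWarning,
    ResponseModel,
    apply_condition_perturbation,
    content_to_concentration,
    simulate_chromatogram,
    simulate_sample_batch,
    simulate_standard_series,
)
from pepperqams.simulate import SECONDS_PER_MINUTE, default_durability_grid, simulate_condition_grid
from pepperqams.presets import RETENTION_MIN


def _trapezoid_area(chrom, lo, hi):
    m = (chrom.time >= lo) & (chrom.time <= hi)
    return np.trapezoid(chrom.intensity[m], chrom.time[m]) * SECONDS_PER_MINUTE


class TestSimulateChromatogram:
    def test_noiseless_peak_conserves_area(self):
        p = PeakShapeSpec("X", 10.0, 100.0, sigma=0.25)
        chrom = simulate_chromatogram(
            [p], duration=20, sampling_rate=20, noise=NoiseSpec(baseline_sigma=0)
        )
        area = _trapezoid_area(chrom, 10 - 5 * 0.25, 10 + 5 * 0.25)
        assert area == pytest.approx(100.0, rel=5e-3)

    def test_five_peaks_produce_maxima_at_nominal_times(self, five_peak_specs):
        chrom = simulate_chromatogram(
            five_peak_specs, duration=50, sampling_rate=20, noise=NoiseSpec(baseline_sigma=0)
        )
        y = chrom.intensity
        local_max = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
        times = chrom.time[local_max]
        step = 1 / 20
        for expected in RETENTION_MIN.values():
            assert np.min(np.abs(times - expected)) <= step + 1e-9

    def test_same_seed_is_bit_identical(self, five_peak_specs):
        kwargs = dict(duration=50, sampling_rate=20, noise=NoiseSpec(seed=123))
        a = simulate_chromatogram(five_peak_specs, **kwargs)
        b = simulate_chromatogram(five_peak_specs, **kwargs)
        assert np.array_equal(a.intensity, b.intensity)

    def test_overlapping_peaks_warn(self):
        peaks = [PeakShapeSpec("A", 10.0, 1.0, sigma=0.3), PeakShapeSpec("B", 10.5, 1.0, sigma=0.3)]
        with pytest.warns(ResolutionWarning):
            simulate_chromatogram(peaks, duration=20, noise=NoiseSpec(baseline_sigma=0))

    @pytest.mark.parametrize(
        "kwargs", [dict(duration=-5.0), dict(sampling_rate=5.0)]
    )
    def test_invalid_run_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            simulate_chromatogram([PeakShapeSpec("A", 1.0, 1.0)], **kwargs)

    def test_peak_outside_window_raises(self):
        with pytest.raises(ValueError):
            simulate_chromatogram([PeakShapeSpec("A", 30.0, 1.0)], duration=20)


class TestStandardSeries:
    def test_true_area_follows_response_line(self, responses):
        chroms, manifest = simulate_standard_series(
            responses,
            [{"HaSS": 1.0}],
            condition=dataclasses.replace(REFERENCE_CONDITION, wavelength=270.0),
            noise=NoiseSpec(baseline_sigma=0),
        )
        model = responses["HaSS"]
        expected = model.slope * 1.0 + model.intercept
        area = _trapezoid_area(chroms[0], 24.5, 27.5)
        assert area == pytest.approx(expected, rel=5e-3)
        assert manifest.records["std-00"]["HaSS"].mass == 1.0

    def test_zero_mass_omits_peak(self, responses):
        chroms, _ = simulate_standard_series(
            responses, [{"HaSS": 0.0}], noise=NoiseSpec(baseline_sigma=0)
        )
        assert np.allclose(chroms[0].intensity, 0.0)

    def test_out_of_range_level_is_flagged_not_fatal(self, responses):
        _, manifest = simulate_standard_series(
            responses, [{"HbSS": 50.0}], noise=NoiseSpec(baseline_sigma=0)
        )
        assert manifest.records["std-00"]["HbSS"].out_of_range
        assert manifest.warnings


class TestSampleBatch:
    def test_content_to_concentration_inverts_content_equation(self):
        # W=45 mg/g, M=0.025 g, V=25 mL, K=1 -> C = 0.045 mg/mL = 45 µg/mL
        assert content_to_concentration(45.0, 0.025, 25.0, 1.0) == pytest.approx(45.0)

    def test_blank_sample_gives_noise_only_trace(self, responses):
        chroms, _ = simulate_sample_batch(
            {"HaSS": 0.0, "HbSS": 0.0},
            responses,
            n_replicates=1,
            noise=NoiseSpec(baseline_sigma=0),
        )
        assert np.allclose(chroms[0].intensity, 0.0)

    def test_replicates_are_distinct_with_identical_truth(self, responses):
        chroms, manifest = simulate_sample_batch(
            {"HaSS": 30.0},
            responses,
            n_replicates=3,
            noise=NoiseSpec(baseline_sigma=0.5, area_rsd=0.01, seed=5),
        )
        assert len(chroms) == 3
        assert not np.array_equal(chroms[0].intensity, chroms[1].intensity)
        truths = [manifest.records[c.run_id]["HaSS"] for c in chroms]
        assert len({t.content for t in truths}) == 1 == len({t.mass for t in truths})

    def test_unknown_analyte_raises(self, responses):
        with pytest.raises(ValueError, match="ResponseModel"):
            simulate_sample_batch({"Ghost": 1.0}, responses)


class TestConditionPerturbation:
    def test_halving_flow_doubles_retention(self):
        peaks = [PeakShapeSpec("A", 10.0, 100.0)]
        new = dataclasses.replace(REFERENCE_CONDITION, flow_rate=0.5)
        out = apply_condition_perturbation(peaks, REFERENCE_CONDITION, new)
        assert out[0].t_r == pytest.approx(20.0)

    def test_doubling_injection_doubles_area_but_not_ratio(self):
        peaks = [PeakShapeSpec("A", 10.0, 100.0), PeakShapeSpec("S", 20.0, 400.0)]
        new = dataclasses.replace(REFERENCE_CONDITION, injection_volume=20.0)
        out = apply_condition_perturbation(peaks, REFERENCE_CONDITION, new)
        # hand recomputation: areas double, the area ratio is unchanged
        assert out[0].area == pytest.approx(200.0)
        assert out[1].area == pytest.approx(800.0)
        assert out[1].area / out[0].area == pytest.approx(400.0 / 100.0)

    def test_identity_transformation(self):
        peaks = [PeakShapeSpec("A", 10.0, 100.0, sigma=0.2)]
        out = apply_condition_perturbation(peaks, REFERENCE_CONDITION, REFERENCE_CONDITION)
        assert out == peaks

    def test_temperature_shift_is_linear(self):
        peaks = [PeakShapeSpec("A", 10.0, 100.0)]
        new = dataclasses.replace(REFERENCE_CONDITION, column_temp=25.0)
        out = apply_condition_perturbation(peaks, REFERENCE_CONDITION, new)
        assert out[0].t_r == pytest.approx(10.0 - 0.05 * (25.0 - 35.0))

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            ConditionSet(flow_rate=-1.0)


class TestConditionGrid:
    def test_default_grid_has_16_points(self):
        assert len(default_durability_grid()) == 16

    def test_area_ratios_preserved_under_shared_gain(self, responses):
        runs = simulate_condition_grid(
            responses,
            {"HaSS": 10.0, "Nonivamide": 20.0},
            noise=NoiseSpec(area_rsd=0.0, seed=3),
            run_gain_rsd=0.05,
        )
        ratios = [
            float(
                r.peak_table.set_index("analyte").loc["HaSS", "area"]
                / r.peak_table.set_index("analyte").loc["Nonivamide", "area"]
            )
            for r in runs
        ]
        assert np.ptp(ratios) / np.mean(ratios) < 1e-9
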