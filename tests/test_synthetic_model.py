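"""Generative threshold-suppression model: determinism, nulls, recovery."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import xsuppress as xs


def germline(**kw):
    defaults = dict(dosage_compensation=False, seed=0)
    defaults.update(kw)
    return xs.SuppressionModelParams(**defaults)


class TestParams:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_genes", 0),
            ("x_fraction", 0.0),
            ("x_fraction", 1.0),
            ("log_sd", 0.0),
            ("buffering_b", 0.4),
            ("buffering_b", 1.1),
            ("suppression_threshold_tau", 0.0),
            ("suppression_exponent_gamma", -0.1),
            ("n_replicates", 0),
            ("replicate_noise_sd", -1.0),
        ],
    )
    def test_invalid_ranges_rejected(self, field, value):
        with pytest.raises(xs.ValidationError):
            xs.SuppressionModelParams(**{field: value})


class TestSuppressionFactor:
    def test_gamma_zero_is_identity(self):
        assert xs.suppression_factor(1e6, tau=10.0, gamma=0.0) == 1.0

    def test_infinite_tau_is_identity(self):
        assert xs.suppression_factor(1e6, tau=math.inf, gamma=2.0) == 1.0

    def test_power_law_above_threshold(self):
        assert xs.suppression_factor(20.0, tau=10.0, gamma=1.0) == pytest.approx(0.5)
        assert xs.suppression_factor(20.0, tau=10.0, gamma=2.0) == pytest.approx(0.25)

    @given(
        st.floats(0.01, 1e4),
        st.floats(0.1, 1e3),
        st.floats(0, 5),
    )
    def test_bounded_and_one_below_threshold(self, e, tau, gamma):
        f = xs.suppression_factor(e, tau, gamma)
        assert 0 < f <= 1
        if e <= tau:
            assert f == 1.0

    @given(st.floats(0.1, 100))
    def test_nonincreasing_in_expression(self, tau):
        e = np.linspace(0.01, 10 * tau, 300)
        f = xs.suppression_factor(e, tau, 1.5)
        assert np.all(np.diff(f) <= 1e-12)


class TestGenerator:
    def test_seed_reproducibility(self):
        a = xs.generate_expression_dataset(germline(n_genes=300, seed=42))
        b = xs.generate_expression_dataset(germline(n_genes=300, seed=42))
        assert a == b

    def test_seeds_differ(self):
        a = xs.generate_expression_dataset(germline(n_genes=300, seed=1))
        b = xs.generate_expression_dataset(germline(n_genes=300, seed=2))
        assert a != b

    def test_records_conform_to_data_io(self):
        recs = xs.generate_expression_dataset(
            germline(n_genes=500, seed=7), tissue="head", sex="male"
        )
        table = xs.build_tissue_table(recs, "head", "male", min_fpkm=0.0)
        assert len(table) + sum(table.excluded.values()) == 500
        assert set(table.data.chromosome_class) == {"X", "A"}

    def test_replicate_count_respected(self):
        recs = xs.generate_expression_dataset(germline(n_genes=10, n_replicates=5))
        assert all(len(r.replicate_fpkm) == 5 for r in recs)

    def test_zero_noise_replicates_identical(self):
        recs = xs.generate_expression_dataset(
            germline(n_genes=10, replicate_noise_sd=0.0)
        )
        for r in recs:
            assert len(set(r.replicate_fpkm)) == 1

    def test_compensated_null_ratio_near_one(self):
        params = xs.SuppressionModelParams(
            n_genes=20_000, dosage_compensation=True, seed=101
        )
        recs = xs.generate_expression_dataset(params)
        table = xs.build_tissue_table(recs, "testis", "male", min_fpkm=0.0)
        assert xs.median_xa_ratio(table).xa_ratio == pytest.approx(1.0, abs=0.15)


class TestRecoverBuffering:
    @pytest.mark.parametrize("b", [0.5, 0.65, 1.0])
    def test_estimates_track_truth(self, b):
        # mean over a small fixed seed panel to tame the median's MC noise
        estimates = [
            xs.recover_buffering(germline(buffering_b=b, seed=s))
            for s in range(5)
        ]
        assert np.mean(estimates) == pytest.approx(b, abs=0.03)

    def test_requires_germline_conditions(self):
        with pytest.raises(xs.ValidationError):
            xs.recover_buffering(
                xs.SuppressionModelParams(dosage_compensation=True)
            )
        with pytest.raises(xs.ValidationError):
            xs.recover_buffering(
                germline(suppression_threshold_tau=10.0, suppression_exponent_gamma=1.0)
            )


class TestRecoverSuppressionSignal:
    TAU = 32.5  # ~80th percentile of the default baseline distribution

    def test_under_flags_above_threshold(self):
        params = germline(
            suppression_threshold_tau=self.TAU,
            suppression_exponent_gamma=1.0,
            seed=11,
        )
        results = xs.recover_suppression_signal(params)
        assert xs.suppression_detected(results, self.TAU)
        below = [r for r in results if r.threshold <= self.TAU and r.tested]
        assert all(r.direction != "over" for r in below)

    def test_gamma_monotonically_depletes_top_category(self):
        # same seed couples the baseline, assignment and noise draws
        counts = []
        for gamma in (0.0, 0.5, 1.0, 2.0):
            params = germline(
                suppression_threshold_tau=self.TAU,
                suppression_exponent_gamma=gamma,
                seed=21,
            )
            recs = xs.generate_expression_dataset(params)
            table = xs.build_tissue_table(recs, "testis", "male")
            corrected = xs.dosage_correction(table, 1 / params.buffering_b)
            counts.append(xs.categorize_cumulative(corrected, [100.0])[0][1])
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]


class TestReporterGenerator:
    def test_zero_noise_no_suppression_classes_identical(self):
        params = xs.ReporterModelParams(
            line_noise_sd=0, bio_noise_sd=0, tech_noise_sd=0,
            suppression_exponent_gamma=0.0, seed=1,
        )
        points = xs.suppression_points(xs.generate_reporter_dataset(params))
        assert all(ratio == pytest.approx(1.0) for _, ratio in points.values())

    def test_zero_noise_ratio_two_at_twice_threshold(self):
        params = xs.ReporterModelParams(
            construct_activities={"c": 1.0},
            suppression_threshold_tau=0.5,
            suppression_exponent_gamma=1.0,
            line_noise_sd=0, bio_noise_sd=0, tech_noise_sd=0, seed=1,
        )
        points = xs.suppression_points(xs.generate_reporter_dataset(params))
        assert points["c"][1] == pytest.approx(2.0)

    def test_positive_slope_recovered_with_noise(self):
        params = xs.ReporterModelParams(seed=8)
        points = xs.suppression_points(xs.generate_reporter_dataset(params))
        fit = xs.suppression_vs_expression(list(points.values()))
        assert fit.slope > 0
        assert fit.p_value < 0.05

    def test_fly_count_normalization_roundtrip(self):
        noisy = xs.ReporterModelParams(
            construct_activities={"c": 2.0},
            line_noise_sd=0, bio_noise_sd=0, tech_noise_sd=0,
            suppression_exponent_gamma=0.0,
            flies_per_assay=6, seed=2,
        )
        ms = [m for m in xs.generate_reporter_dataset(noisy)
              if m.chromosome_class == "A"]
        # raw readings scale with fly count; normalization restores the truth
        assert ms[0].activity == pytest.approx(2.0 * 6 / 5)
        assert xs.summarize_line(
            [m for m in ms if m.line_id == ms[0].line_id], normalize_to=5
        ).mean_activity == pytest.approx(2.0)

    def test_seed_reproducibility(self):
        a = xs.generate_reporter_dataset(xs.ReporterModelParams(seed=9))
        b = xs.generate_reporter_dataset(xs.ReporterModelParams(seed=9))
        assert a == b

    def test_control_near_detection_floor(self):
        params = xs.ReporterModelParams(n_control_lines=30, seed=13)
        controls = [
            m.activity
            for m in xs.generate_reporter_dataset(params)
            if m.chromosome_class == "control"
        ]
        assert np.mean(controls) == pytest.approx(-0.05, abs=0.03)


def test_end_to_end_composition_without_external_inputs(tmp_path):
    """generate -> write -> read -> stats -> representation, all in-process."""
    params = germline(n_genes=4000, seed=33)
    recs = xs.generate_expression_dataset(params)
    path = tmp_path / "synthetic.tsv"
    xs.write_expression_table(recs, path)
    back = xs.read_expression_table(path)
    expected = xs.expected_x_proportion(back)
    table = xs.build_tissue_table(back, "testis", "male")
    ratio = xs.median_xa_ratio(table)
    profile = xs.representation_profile(
        table, expected_proportion=expected,
        correction_factor=xs.correction_factor(ratio),
    )
    assert 0.4 < ratio.xa_ratio < 1.0
    assert len(profile) == len(xs.DEFAULT_THRESHOLDS)
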