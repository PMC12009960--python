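import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synspread.geometry import DeviceGeometry
from synspread.quantify import (
    FieldMetrics,
    aggregate_chamber,
    grubbs_outliers,
    linear_trend,
    mann_whitney_u,
    mean_difference,
    propagation_ratio,
    summarize_field,
)
from synspread.segment import Fragment
from synspread.synth import SynthConfig, default_study_schedule, generate_study

from _oracles import grubbs_exclusions_direct, mann_whitney_exact_enumeration

GEO1 = DeviceGeometry(pixel_size=1.0)


def _frag(area, row, col):
    return Fragment(
        pixels=np.array([[row, col]]), area_um2=area, length_um=None,
        centroid_um=(0.0, 0.0), centroid_px=(float(row), float(col)),
        chamber="forward", distance_um=500.0, on_neurite=True, pixel_size=1.0,
    )


class TestSummarizeField:
    def test_scaling_to_quarter_mm2(self):
        # ROI of 0.5 mm² at 1 µm/px; 100 µm² raw -> 50 per 0.25 mm²
        roi = np.ones((500, 1000), dtype=bool)
        tub = np.zeros_like(roi)
        m = summarize_field([_frag(100.0, 5, 5)], roi, tub, GEO1)
        assert m.roi_area_mm2 == pytest.approx(0.5)
        assert m.area_per_qmm2 == pytest.approx(50.0)

    def test_count_normalisation(self):
        roi = np.ones((500, 500), dtype=bool)  # 0.25 mm²
        frags = [_frag(10.0, r, r) for r in range(10)]
        m = summarize_field(frags, roi, np.zeros_like(roi), GEO1)
        assert m.frags_per_qmm2 == pytest.approx(10.0)

    def test_percent_of_neurite_area(self):
        roi = np.ones((100, 100), dtype=bool)
        tub = np.zeros_like(roi)
        tub[:50, :] = True  # 5000 µm² neurite within ROI
        m = summarize_field([_frag(50.0, 2, 2)], roi, tub, GEO1)
        assert m.pct_neurite == pytest.approx(1.0)

    def test_zero_neurite_area_flagged_not_fatal(self):
        roi = np.ones((10, 10), dtype=bool)
        m = summarize_field([_frag(5.0, 2, 2)], roi, np.zeros_like(roi), GEO1)
        assert np.isnan(m.pct_neurite)
        assert m.area_per_qmm2 > 0

    def test_empty_roi_is_error(self):
        with pytest.raises(ValueError):
            summarize_field([], np.zeros((5, 5), bool), np.zeros((5, 5), bool), GEO1)


class TestGrubbs:
    def test_flags_single_extreme_in_ten(self):
        values = [8.0, 7.9, 8.1, 8.05, 7.95, 8.2, 7.8, 8.0, 8.1, 15.0]
        assert grubbs_outliers(values, 0.05) == [9]
        assert grubbs_exclusions_direct(values, 0.05) == [9]

    def test_constant_sample_has_no_outliers(self):
        assert grubbs_outliers([4.0] * 8) == []

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            grubbs_outliers([1.0, 2.0])

    def test_matches_direct_oracle_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            vals = rng.normal(10, 2, n)
            if rng.random() < 0.5:  # plant an outlier sometimes
                vals[rng.integers(n)] += rng.choice([-1, 1]) * rng.uniform(5, 20)
            assert grubbs_outliers(vals, 0.05) == grubbs_exclusions_direct(vals, 0.05)

    def test_single_pass_mode_removes_at_most_one(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 8), [30.0, -30.0]])
        out = grubbs_outliers(vals, 0.05, iterative=False)
        assert len(out) <= 1


class TestAggregateChamber:
    def _metrics(self, areas, counts=None):
        counts = counts or [1.0] * len(areas)
        return [
            FieldMetrics(
                image_id=f"f{i}", roi_area_mm2=0.25, area_per_qmm2=a,
                frags_per_qmm2=c, pct_neurite=a / 100, neurite_area_um2=1.0,
                n_fragments=int(c),
            )
            for i, (a, c) in enumerate(zip(areas, counts))
        ]

    def test_simple_median(self):
        s = aggregate_chamber(self._metrics([3.0, 1.0, 2.0]))
        assert s.medians["area_per_qmm2"] == 2.0

    def test_outlier_removed_before_median(self):
        areas = [8.0, 7.9, 8.1, 8.05, 7.95, 8.2, 7.8, 8.0, 8.1, 15.0]
        s = aggregate_chamber(self._metrics(areas))
        assert s.excluded["area_per_qmm2"] == ["f9"]
        assert s.medians["area_per_qmm2"] == pytest.approx(np.median(areas[:9]))
        assert s.n_used["area_per_qmm2"] == 9

    def test_even_count_median_is_central_mean(self):
        s = aggregate_chamber(self._metrics([1.0, 2.0, 3.0, 4.0]))
        assert s.medians["area_per_qmm2"] == 2.5

    def test_permutation_invariance_and_bounds(self, rng):
        areas = list(rng.uniform(0, 50, 10))
        s1 = aggregate_chamber(self._metrics(areas))
        s2 = aggregate_chamber(self._metrics(areas[::-1]))
        assert s1.medians == s2.medians
        assert min(areas) <= s1.medians["area_per_qmm2"] <= max(areas)

    def test_outliers_independent_per_metric(self):
        # field f9 extreme in area only: still contributes to counts
        areas = [8.0] * 9 + [15.0]
        counts = [2.0] * 10
        s = aggregate_chamber(self._metrics(areas, counts))
        assert s.excluded["area_per_qmm2"] == ["f9"]
        assert s.excluded["frags_per_qmm2"] == []
        assert s.n_used["frags_per_qmm2"] == 10

    def test_fewer_than_three_fields_errors(self):
        with pytest.raises(ValueError):
            aggregate_chamber(self._metrics([1.0, 2.0]))


class TestMeanDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (145.9, 29.3, 116.6),  # forward vs reverse pathology area
            (11.745, 5.557, 6.188),  # CFSE-negative vs control area
            (4.399, 1.792, 2.607),  # CFSE-negative vs control fragment count
        ],
    )
    def test_reported_group_differences(self, a, b, expected):
        assert mean_difference([a], [b]) == pytest.approx(expected, abs=5e-4)

    def test_identical_groups(self):
        assert mean_difference([1, 2, 3], [3, 2, 1]) == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mean_difference([], [1.0])


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_stat == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_symmetric_u(self):
        res = mann_whitney_u([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.u_stat == pytest.approx(8.0)  # n1*n2/2

    def test_interleaved_matches_enumeration(self):
        res = mann_whitney_u([1, 3], [2, 4])
        u, p = mann_whitney_exact_enumeration([1, 3], [2, 4])
        assert res.u_stat == pytest.approx(u)
        assert res.p_value == pytest.approx(p)

    def test_constant_groups_warn_p_one(self):
        with pytest.warns(RuntimeWarning):
            res = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.lists(st.integers(0, 50), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 50), min_size=1, max_size=5),
    )
    def test_u_complementarity(self, a, b):
        if len(set(a) | set(b)) == 1:
            return
        ua = mann_whitney_u(a, b).u_stat
        ub = mann_whitney_u(b, a).u_stat
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_exact_p_matches_enumeration_random_untied(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            pooled = rng.choice(np.arange(100), size=n1 + n2, replace=False)
            a, b = pooled[:n1].tolist(), pooled[n1:].tolist()
            res = mann_whitney_u(a, b)
            u, p = mann_whitney_exact_enumeration(a, b)
            assert res.u_stat == pytest.approx(u)
            assert res.p_value == pytest.approx(p)


class TestLinearTrend:
    def test_exact_line(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        fit = linear_trend(t, 2 * t + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value == 0.0

    def test_constant_response(self):
        fit = linear_trend([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_f_statistic_relation(self, rng):
        t = rng.uniform(0, 10, 20)
        y = 3 * t + rng.normal(0, 2, 20)
        fit = linear_trend(t, y)
        expect_f = fit.r_squared / (1 - fit.r_squared) * (len(t) - 2)
        assert fit.f_stat == pytest.approx(expect_f)
        assert fit.df == (1, 18)

    def test_degenerate_time_errors(self):
        with pytest.raises(ValueError):
            linear_trend([2, 2, 2], [1, 2, 3])

    def test_zero_noise_study_truth_recovers_slope_exactly(self, geometry):
        cfg = SynthConfig(
            seed=1, field_size_um=(166.4, 166.4), pixel_size_um=0.65, device_cv=0.0
        )
        sched = default_study_schedule(10)
        study = generate_study(cfg, sched, fields_per_chamber=3, geometry=geometry)
        tt = study.truth_table()
        fit = linear_trend(tt["t_weeks"], tt["expected_area_per_qmm2"])
        assert fit.slope == pytest.approx(53.828, rel=1e-9)
        assert fit.intercept == pytest.approx(-137.706, rel=1e-9)


class TestPropagationRatio:
    def test_reported_chamber_means(self):
        assert propagation_ratio(29.3, 145.9) == pytest.approx(0.2008, abs=1e-4)

    def test_equal_chambers(self):
        assert propagation_ratio(10.0, 10.0) == 1.0

    def test_zero_seeded_flagged_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(propagation_ratio(5.0, 0.0))
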