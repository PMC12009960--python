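import numpy as np
import pytest

from synspread.geometry import DeviceGeometry, distance_to_barrier
from synspread.synth import (
    NoiseModel,
    PunctumSpec,
    SynthConfig,
    generate_channel_timelapse,
    generate_cfse_channel,
    generate_neurite_field,
    generate_pathology_image,
    generate_study,
    load_config,
    save_config,
)

PX = 0.65


class TestNeuriteField:
    def test_zero_neurites_gives_noise_only_field(self, small_cfg, geometry):
        import dataclasses

        cfg = dataclasses.replace(
            small_cfg,
            neurites=dataclasses.replace(small_cfg.neurites, count=0),
            soma_density_per_mm2=0.0,
        )
        img, truth = generate_neurite_field(cfg, geometry)
        assert truth.neurites == []
        assert not truth.skeleton_mask.any()

    def test_same_seed_identical_output(self, small_cfg, geometry):
        img1, t1 = generate_neurite_field(small_cfg, geometry)
        img2, t2 = generate_neurite_field(small_cfg, geometry)
        assert (img1.data == img2.data).all()
        assert len(t1.neurites) == len(t2.neurites)
        for a, b in zip(t1.neurites, t2.neurites):
            assert (a.path_px == b.path_px).all()

    def test_skeleton_length_within_configured_bounds(self, geometry):
        cfg = SynthConfig(seed=7, field_size_um=(665.6, 665.6), pixel_size_um=PX)
        import dataclasses

        cfg = dataclasses.replace(
            cfg, neurites=dataclasses.replace(cfg.neurites, count=50)
        )
        _, truth = generate_neurite_field(cfg, geometry)
        total = truth.total_skeleton_length_um()
        lo, hi = cfg.neurites.length_range_um
        # paths are clipped at the field boundary, so only the upper bound
        # is sharp; rasterisation ties the polyline within ~un pixel per step
        assert 0 < total <= 50 * hi * 1.05
        per = [
            np.sqrt((np.diff(n.path_px.astype(float), axis=0) ** 2).sum(1)).sum() * PX
            for n in truth.neurites
        ]
        assert max(per) <= hi * 1.05


class TestPathologyImage:
    def test_negative_time_rejected(self, small_cfg, geometry):
        _, truth = generate_neurite_field(small_cfg, geometry)
        with pytest.raises(ValueError):
            generate_pathology_image(small_cfg, truth, -1.0)

    def test_expected_area_truncates_at_zero(self, small_cfg):
        assert small_cfg.expected_area_per_qmm2(0.0) == 0.0

    def test_expected_area_matches_growth_line(self, small_cfg):
        # 53.828 * 4.4 - 137.706
        assert small_cfg.expected_area_per_qmm2(4.4) == pytest.approx(99.137, abs=0.001)

    def test_time_zero_places_no_countable_pathology(self, small_cfg, geometry):
        _, truth = generate_neurite_field(small_cfg, geometry)
        _, frags = generate_pathology_image(small_cfg, truth, 0.0)
        assert [f for f in frags if not f.sub_threshold] == []

    def test_truth_area_equals_pixel_count(self, small_cfg, geometry):
        _, truth = generate_neurite_field(small_cfg, geometry)
        _, frags = generate_pathology_image(small_cfg, truth, 9.0)
        assert frags
        for f in frags:
            assert f.area_um2 == pytest.approx(len(f.pixels) * PX**2)
            assert (f.pixels[:, 0] < truth.shape[0]).all()
            assert (f.pixels[:, 1] < truth.shape[1]).all()

    def test_determinism_and_monotonic_expectation(self, small_cfg, geometry):
        _, truth = generate_neurite_field(small_cfg, geometry)
        _, f1 = generate_pathology_image(small_cfg, truth, 6.0)
        _, truth_b = generate_neurite_field(small_cfg, geometry)
        _, f2 = generate_pathology_image(small_cfg, truth_b, 6.0)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert (a.pixels == b.pixels).all()
        ts = np.linspace(0, 12, 13)
        exp = [small_cfg.expected_area_per_qmm2(t) for t in ts]
        assert (np.diff(exp) >= 0).all()


class TestCfseChannel:
    def test_linear_decay_profile_endpoints(self, small_cfg):
        prof = small_cfg.cfse.profile(np.array([0.0, 200.0, 400.0, 600.0]))
        assert prof[0] == small_cfg.cfse.max_intensity
        assert prof[1] == pytest.approx(small_cfg.cfse.max_intensity / 2)
        assert prof[2] == 0.0
        assert prof[3] == 0.0

    def test_signal_only_on_forward_originating_neurites(self, geometry):
        cfg = SynthConfig(
            seed=3,
            field_size_um=(166.4, 166.4),
            pixel_size_um=PX,
            noise=NoiseModel.noise_free(),
        )
        # reverse-chamber field right at the barrier
        _, truth = generate_neurite_field(cfg, geometry, offset=(1000.0, 0.0))
        img = generate_cfse_channel(cfg, truth, geometry)
        fwd = np.zeros(truth.shape, bool)
        nat = np.zeros(truth.shape, bool)
        for n in truth.neurites:
            tgt = fwd if n.forward_originating else nat
            tgt[n.path_px[:, 0], n.path_px[:, 1]] = True
        assert img.data[fwd & ~nat].mean() > 50
        # reverse-native pixels well away from any forward neurite stay dark
        from scipy import ndimage

        far_native = nat & ~ndimage.binary_dilation(fwd, iterations=6)
        assert img.data[far_native].max() <= 5  # blur tail only

    def test_mean_intensity_non_increasing_with_distance(self, geometry):
        cfg = SynthConfig(
            seed=3,
            field_size_um=(332.8, 332.8),
            pixel_size_um=PX,
            noise=NoiseModel.noise_free(),
        )
        _, truth = generate_neurite_field(cfg, geometry, offset=(1000.0, 0.0))
        img = generate_cfse_channel(cfg, truth, geometry)
        fwd = np.zeros(truth.shape, bool)
        for n in truth.neurites:
            if n.forward_originating:
                fwd[n.path_px[:, 0], n.path_px[:, 1]] = True
        rr, cc = np.nonzero(fwd)
        x = truth.offset[0] + (cc + 0.5) * PX
        d = distance_to_barrier(x, geometry)
        vals = img.data[rr, cc].astype(float)
        bins = np.digitize(d, [50, 100, 150, 200, 250, 300])
        means = [vals[bins == b].mean() for b in range(7) if (bins == b).any()]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestTimelapse:
    def test_frame_count(self, geometry):
        cfg = SynthConfig(seed=0, duration_s=600.0, frame_interval_s=5.0)
        movie, _ = generate_channel_timelapse(cfg, geometry)
        assert movie.shape[0] == 121

    def test_exit_time_kinematics(self, geometry):
        cfg = SynthConfig(
            seed=0, puncta=[PunctumSpec(x0_um=500.0, speed_um_s=-1.0)]
        )
        _, truths = generate_channel_timelapse(cfg, geometry)
        assert truths[0].exit_time_s == pytest.approx(500.0)
        assert truths[0].direction == "retrograde"

    def test_empty_puncta_noise_only(self, geometry):
        cfg = SynthConfig(seed=0, duration_s=50.0)
        movie, truths = generate_channel_timelapse(cfg, geometry)
        assert truths == []
        assert movie.max() < 200  # baseline + noise only

    def test_punctum_outside_field_rejected(self, geometry):
        cfg = SynthConfig(seed=0, puncta=[PunctumSpec(x0_um=-5.0, speed_um_s=1.0)])
        with pytest.raises(ValueError):
            generate_channel_timelapse(cfg, geometry)

    def test_stationary_punctum_supported(self, geometry):
        cfg = SynthConfig(
            seed=0, duration_s=100.0, puncta=[PunctumSpec(500.0, 0.0)]
        )
        _, truths = generate_channel_timelapse(cfg, geometry)
        assert truths[0].direction == "stationary"
        assert truths[0].exit_time_s is None


class TestStudy:
    def test_duplicate_device_ids_rejected(self, small_cfg, geometry):
        with pytest.raises(ValueError):
            generate_study(
                small_cfg,
                [("d0", 5.0, True), ("d0", 6.0, True)],
                fields_per_chamber=3,
                geometry=geometry,
            )

    def test_same_master_seed_identical_dataset(self, small_cfg, geometry):
        sched = [(f"d{i}", 4.0 + i, True) for i in range(3)]
        s1 = generate_study(small_cfg, sched, fields_per_chamber=3, geometry=geometry)
        s2 = generate_study(small_cfg, sched, fields_per_chamber=3, geometry=geometry)
        for d1, d2 in zip(s1.devices, s2.devices):
            assert d1.device_factor == d2.device_factor
            for f1, f2 in zip(d1.fields, d2.fields):
                assert (f1.psyn.data == f2.psyn.data).all()
                assert (f1.tubulin.data == f2.tubulin.data).all()

    def test_zero_slope_constant_truth(self, geometry):
        import dataclasses

        cfg = SynthConfig(seed=2, field_size_um=(166.4, 166.4), pixel_size_um=PX)
        cfg = dataclasses.replace(
            cfg, growth_slope=0.0, growth_intercept=120.0, device_cv=0.0
        )
        sched = [(f"d{i}", float(t), True) for i, t in enumerate([3, 6, 9])]
        study = generate_study(cfg, sched, fields_per_chamber=3, geometry=geometry)
        exp = study.truth_table()["expected_area_per_qmm2"]
        assert exp.nunique() == 1


def test_config_yaml_roundtrip(tmp_path, small_cfg):
    path = tmp_path / "cfg.yaml"
    save_config(small_cfg, path)
    loaded = load_config(path)
    assert loaded == small_cfg
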