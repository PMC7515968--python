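"""Simulator: vessel placement, diffusion field, ring envelope, noise, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from periquant.simulate import (
    ImageFrame,
    PlacementError,
    SimulationConfig,
    VesselRecord,
    add_noise,
    generate_dataset,
    read_frame_tiff,
    render_frame,
    ring_amplitude_at,
    sample_vessels,
    tracer_field,
)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_positive=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(image_px=32)
        with pytest.raises(ValueError):
            SimulationConfig(frame_interval_min=7.0, total_min=40.0)
        with pytest.raises(ValueError):
            SimulationConfig(decay_min=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(read_noise_sd=-0.5)

    def test_frame_grid_defaults(self):
        cfg = SimulationConfig()
        assert list(cfg.frame_times_min) == [0, 5, 10, 15, 20, 25, 30, 35, 40]
        assert cfg.pixel_size_um == pytest.approx(425.10 / 512)


class TestSampleVessels:
    @pytest.mark.parametrize("p,expect", [(0.0, False), (1.0, True)])
    def test_degenerate_probability(self, p, expect):
        cfg = SimulationConfig(n_vessels=10, p_positive=p, seed=3)
        assert all(v.is_positive_truth is expect for v in sample_vessels(cfg))

    def test_seeded_positive_count_and_determinism(self):
        cfg = SimulationConfig(n_vessels=50, p_positive=0.30, seed=1)
        vs = sample_vessels(cfg)
        k = sum(v.is_positive_truth for v in vs)
        assert 4 <= k <= 27  # binomial(50, 0.3) 99% interval
        assert k == 18  # frozen regression of the seeded draw
        vs2 = sample_vessels(cfg)
        assert [v.center_xy_um for v in vs2] == [v.center_xy_um for v in vs]

    def test_geometry_constraints(self):
        cfg = SimulationConfig(n_vessels=50, seed=7)
        vs = sample_vessels(cfg)
        lo, hi = cfg.vessel_diameter_range_um
        for v in vs:
            assert lo <= v.diameter_um <= hi
            x, y = v.center_xy_um
            assert v.radius_um < x < cfg.field_size_um - v.radius_um
            assert v.radius_um < y < cfg.field_size_um - v.radius_um
        for i, a in enumerate(vs):
            for b in vs[i + 1:]:
                gap = math.dist(a.center_xy_um, b.center_xy_um) - a.radius_um - b.radius_um
                assert gap >= cfg.clearance_um - 1e-9

    def test_crowded_field_fails_clearly(self):
        cfg = SimulationConfig(n_vessels=2000, seed=0)
        with pytest.raises(PlacementError, match="crowded"):
            sample_vessels(cfg)


class TestTracerField:
    def test_closed_forms(self):
        cfg = SimulationConfig(
            field_size_um=128.0, image_px=512, diffusion_coeff_um2_per_min=10.0,
            injected_mass=1.0, source_xy_um=(64.125, 64.125),
        )
        # source placed on a pixel centre; 20 um = 80 px exactly
        c = tracer_field(cfg, 10.0)
        i0 = j0 = int(64.125 / cfg.pixel_size_um - 0.5)
        assert c[i0, j0] == pytest.approx(1.0 / (4 * math.pi * 10.0 * 10.0), rel=1e-12)
        ratio = c[i0, j0 + 80] / c[i0, j0]
        assert ratio == pytest.approx(math.exp(-1.0), abs=1e-6)

    def test_mass_conservation(self):
        # grid extends ~212 um from the source >> 6*sqrt(2*D*t) = 85 um
        cfg = SimulationConfig(injected_mass=5000.0)
        c = tracer_field(cfg, 10.0)
        total = c.sum() * cfg.pixel_size_um**2
        assert total == pytest.approx(5000.0, rel=0.01)

    def test_rejects_nonpositive_time(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            tracer_field(cfg, 0.0)


class TestRingEnvelope:
    def test_trapezoid_anchors(self):
        cfg = SimulationConfig(ring_amplitude=10.0)
        assert ring_amplitude_at(cfg, 0.0) == 0.0
        assert ring_amplitude_at(cfg, 15.0 + 5.0) == 10.0  # plateau midpoint
        assert ring_amplitude_at(cfg, 32.5) == pytest.approx(5.0)  # decay leg
        assert ring_amplitude_at(cfg, 60.0) == 0.0
        with pytest.raises(ValueError):
            ring_amplitude_at(cfg, -1.0)

    @given(st.floats(0.0, 60.0), st.floats(0.0, 60.0))
    def test_monotone_rise_and_decay(self, t1, t2):
        cfg = SimulationConfig()
        lo, hi = sorted((t1, t2))
        if hi <= cfg.rise_min:
            assert ring_amplitude_at(cfg, lo) <= ring_amplitude_at(cfg, hi) + 1e-12
        if lo >= cfg.rise_min + cfg.plateau_min:
            assert ring_amplitude_at(cfg, lo) >= ring_amplitude_at(cfg, hi) - 1e-12


class TestRenderFrame:
    def test_all_negative_no_tracer_is_dark(self, noiseless_cfg):
        v = VesselRecord(0, (212.0, 210.0), 0.1, 8.0, False, 0.0)
        frame = render_frame(noiseless_cfg, [v], 20.0)
        assert np.all(frame.green == 0.0)
        assert frame.red.max() == pytest.approx(noiseless_cfg.lumen_intensity, rel=1e-6)

    def test_ring_annulus_pixel_average(self, noiseless_cfg):
        cfg = noiseless_cfg
        v = VesselRecord(0, (212.0, 210.0), 0.1, 8.0, True, 0.0)
        frame = render_frame(cfg, [v], 20.0)  # plateau amplitude
        xs = (np.arange(cfg.image_px) + 0.5) * cfg.pixel_size_um
        r = np.hypot(xs[:, None] - 210.0, xs[None, :] - 212.0)
        # interior of each annulus, clear of the one-pixel edge ramps
        m = cfg.pixel_size_um * 0.75
        ring = (r > 4.0 + m) & (r <= 7.0 - m)
        shifted = (r > 14.0 + m) & (r <= 17.0 - m)
        diff = frame.green[ring].mean() - frame.green[shifted].mean()
        assert diff == pytest.approx(cfg.ring_amplitude, rel=0.05)
        assert np.all(frame.green[r < 4.0 - m] == 0.0)  # lumen excluded
        assert np.all(frame.green[r > 7.0 + m] == 0.0)  # beyond ring

    def test_lumen_excludes_tracer(self):
        cfg = SimulationConfig(n_vessels=0, noise_gain=0.0, read_noise_sd=0.0)
        v = VesselRecord(0, (212.0, 210.0), 0.0, 10.0, False, 0.0)
        frame = render_frame(cfg, [v], 10.0)
        xs = (np.arange(cfg.image_px) + 0.5) * cfg.pixel_size_um
        r = np.hypot(xs[:, None] - 210.0, xs[None, :] - 212.0)
        assert np.all(frame.green[r <= 5.0] == 0.0)
        assert frame.green[r > 6.0].max() > 0.0


class TestAddNoise:
    def test_zero_noise_is_identity(self, noiseless_cfg):
        v = VesselRecord(0, (212.0, 210.0), 0.1, 8.0, True, 0.0)
        frame = render_frame(noiseless_cfg, [v], 20.0)
        out = add_noise(frame, noiseless_cfg, 0)
        np.testing.assert_array_equal(out.green, frame.green)
        np.testing.assert_array_equal(out.red, frame.red)

    def test_constant_plane_mean_preserved(self):
        cfg = SimulationConfig(noise_gain=0.2, read_noise_sd=2.0, seed=11)
        plane = np.full((256, 256), 50.0)
        frame = ImageFrame(green=plane, red=plane, pixel_size_um=1.0, t_min=0.0)
        out = add_noise(frame, cfg, 0)
        n = plane.size
        sd = math.sqrt(0.2 * 50.0 + 4.0)  # Poisson*gain variance + read variance
        assert abs(out.green.mean() - 50.0) < 3 * sd / math.sqrt(n)

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=5)
        plane = np.full((64, 64), 10.0)
        frame = ImageFrame(green=plane, red=plane, pixel_size_um=1.0, t_min=0.0)
        a = add_noise(frame, cfg, 3)
        b = add_noise(frame, cfg, 3)
        np.testing.assert_array_equal(a.green, b.green)
        c = add_noise(frame, cfg, 4)
        assert not np.array_equal(a.green, c.green)

    def test_pure_photon_noise_of_dark_field_is_dark(self):
        # channel separation: no tracer, no positives, no read noise -> the
        # green channel is exactly zero (Poisson of zero intensity)
        cfg = SimulationConfig(n_vessels=5, p_positive=0.0, injected_mass=0.0,
                               read_noise_sd=0.0, seed=2)
        vs = sample_vessels(cfg)
        frame = add_noise(render_frame(cfg, vs, 20.0), cfg, 0)
        assert np.all(frame.green == 0.0)


class TestDatasetIO:
    def test_default_grid_writes_nine_frames(self, tmp_path):
        cfg = SimulationConfig(n_vessels=3, image_px=128, field_size_um=425.10, seed=4)
        ds = generate_dataset(cfg, tmp_path)
        names = sorted(p.name for p in ds["frames"])
        assert len(names) == 9
        assert names[0] == "frame_t00.tif" and names[-1] == "frame_t40.tif"
        assert (tmp_path / "annotations.csv").exists()
        assert (tmp_path / "config.yaml").exists()

    def test_empty_field_valid(self, tmp_path):
        cfg = SimulationConfig(n_vessels=0, image_px=64, field_size_um=53.0, seed=0)
        ds = generate_dataset(cfg, tmp_path)
        import pandas as pd

        ann = pd.read_csv(ds["annotations"])
        assert len(ann) == 0
        assert len(ds["frames"]) == 9

    def test_tiff_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_vessels=2, image_px=128, seed=9)
        vs = sample_vessels(cfg)
        frame = add_noise(render_frame(cfg, vs, 20.0), cfg, 4)
        from periquant.simulate import write_frame_tiff

        p = tmp_path / "f.tif"
        write_frame_tiff(p, frame)
        back = read_frame_tiff(p)
        np.testing.assert_allclose(back.green, frame.green.astype(np.float32))
        np.testing.assert_allclose(back.red, frame.red.astype(np.float32))
        assert back.pixel_size_um == pytest.approx(frame.pixel_size_um)
        assert back.t_min == 20.0
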