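"""Forward-model generator: geometry, emission models, noise, truth."""

import math

import numpy as np
import pytest

from polegrow import synthetic as sy


def numeric_emission_integral(geom, optics, channel, cap=None, oversample=8,
                              shape=(80, 120), label_amplitude=300.0,
                              cap_pole="A", band_width_px=2.0):
    """Independent fine-grid integral of the continuous emission model."""
    ps = optics.pixel_size / oversample
    h, w = shape[0] * oversample, shape[1] * oversample
    y = (np.arange(h) + 0.5) * ps
    x = (np.arange(w) + 0.5) * ps
    X, Y = np.meshgrid(x, y)
    u = geom.axis
    dx, dy = X - geom.center[0], Y - geom.center[1]
    t = dx * u[0] + dy * u[1]
    perp = -dx * u[1] + dy * u[0]
    hl = (geom.length - geom.width) / 2
    tc = np.clip(t, -hl, hl)
    dist = np.hypot(t - tc, perp)
    s = np.clip(t + geom.length / 2, 0.0, geom.length)
    body = dist <= geom.width / 2
    if channel == "label":
        band = np.abs(dist - geom.width / 2) <= band_width_px * optics.pixel_size / 2
        e = label_amplitude * band
        for f in geom.septa_positions:
            e = np.where(
                body & (np.abs(s - f * geom.length) <= sy.SEPTUM_HALFWIDTH_UM),
                label_amplitude,
                e,
            )
        e = np.where(band | body, e, 0.0)
    else:  # cap
        s_cap = s if cap_pole == "A" else geom.length - s
        e = np.where(body, cap.amplitude * np.exp(-(s_cap**2) / (2 * cap.sigma**2)), 0.0)
    return float(e.sum() * ps * ps)


class TestRenderPopulation:
    def test_empty_population_gives_blank_frame_and_empty_truth(self, noiseless_optics):
        frames, truth = sy.render_population([], None, noiseless_optics)
        assert frames["phase"].min() == frames["phase"].max() == noiseless_optics.background
        assert truth.cells == []

    def test_body_raster_matches_analytic_spherocylinder(self, rod, noiseless_optics):
        ps = noiseless_optics.pixel_size
        shape = (80, 120)
        mask = sy.rasterize_cell(rod, shape, ps, supersample=1)
        # analytic raster: pixel centres inside the spherocylinder
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        X, Y = (xx + 0.5) * ps, (yy + 0.5) * ps
        u = rod.axis
        t = (X - rod.center[0]) * u[0] + (Y - rod.center[1]) * u[1]
        perp = -(X - rod.center[0]) * u[1] + (Y - rod.center[1]) * u[0]
        hl = (rod.length - rod.width) / 2
        dist = np.hypot(t - np.clip(t, -hl, hl), perp)
        analytic_raster = dist <= rod.width / 2
        # at supersample=1 the raster is exactly the pixel-centre rule
        assert np.array_equal(mask, analytic_raster)
        analytic_px = sy.spherocylinder_area(rod.length, rod.width) / ps**2
        assert abs(mask.sum() - analytic_px) <= rod.length / ps  # one pixel row
        # the default antialiased raster stays within the same area bound
        mask4 = sy.rasterize_cell(rod, shape, ps, supersample=4)
        assert abs(mask4.sum() - analytic_px) <= rod.length / ps

    def test_tip_cap_concentrates_intensity_at_pole(self, rod):
        optics = sy.OpticsParams(
            psf_sigma=0.0, poisson_gain=0.0, read_noise_sd=0.0, background=0.0
        )
        cap = sy.CapModel(kind="tip", sigma=0.2, amplitude=70.0)
        frames, _ = sy.render_population(
            [rod], cap, optics, channels=("cap",), shape=(80, 120), supersample=3
        )
        img = frames["cap"]
        ps = optics.pixel_size
        yy, xx = np.mgrid[0:80, 0:120]
        d_tip = np.hypot((xx + 0.5) * ps - rod.tip_a[0], (yy + 0.5) * ps - rod.tip_a[1])
        frac = img[d_tip <= 0.4].sum() / img.sum()
        assert frac >= 0.60
        # numeric oracle on the continuous kernel agrees with the raster
        ps8 = ps / 8
        y = (np.arange(80 * 8) + 0.5) * ps8
        x = (np.arange(120 * 8) + 0.5) * ps8
        X, Y = np.meshgrid(x, y)
        u = rod.axis
        t = (X - rod.center[0]) * u[0] + (Y - rod.center[1]) * u[1]
        perp = -(X - rod.center[0]) * u[1] + (Y - rod.center[1]) * u[0]
        hl = (rod.length - rod.width) / 2
        dist = np.hypot(t - np.clip(t, -hl, hl), perp)
        s = np.clip(t + rod.length / 2, 0, rod.length)
        e = np.where(dist <= rod.width / 2, np.exp(-(s**2) / (2 * 0.2**2)), 0.0)
        d = np.hypot(X - rod.tip_a[0], Y - rod.tip_a[1])
        oracle_frac = e[d <= 0.4].sum() / e.sum()
        assert frac == pytest.approx(oracle_frac, abs=0.03)

    @pytest.mark.parametrize("channel", ["label", "cap"])
    def test_integrated_fluorescence_conserved(self, channel, noiseless_optics):
        geom = sy.CellGeometry((3.0, 2.5), 0.4, 3.2, 1.0, (0.4,))
        cap = sy.CapModel(kind="broad", sigma=0.5, amplitude=50.0)
        optics = sy.OpticsParams(
            psf_sigma=0.0, poisson_gain=0.0, read_noise_sd=0.0, background=0.0
        )
        frames, _ = sy.render_population(
            [geom], cap, optics, channels=(channel,), shape=(90, 110), supersample=4
        )
        total = float(frames[channel].sum()) * optics.pixel_size**2
        oracle = numeric_emission_integral(
            geom, optics, channel, cap=cap, shape=(90, 110)
        )
        assert total == pytest.approx(oracle, rel=0.005)

    def test_overlapping_cells_rejected_with_identities(self, noiseless_optics):
        a = sy.CellGeometry((3.0, 2.0), 0.0, 3.0, 1.0)
        b = sy.CellGeometry((3.5, 2.2), 0.0, 3.0, 1.0)
        c = sy.CellGeometry((3.0, 6.0), 0.0, 3.0, 1.0)
        with pytest.raises(sy.OverlapError) as err:
            sy.render_population([a, b, c], None, noiseless_optics, shape=(150, 150))
        assert err.value.pairs == [(0, 1)]

    def test_cell_outside_bounds_rejected(self, noiseless_optics):
        g = sy.CellGeometry((0.5, 0.5), 0.0, 3.0, 1.0)
        with pytest.raises(ValueError, match="bounds"):
            sy.render_population([g], None, noiseless_optics, shape=(64, 64))

    def test_identical_seed_reproduces_images_exactly(self):
        spec = sy.make_strain_scenario("d", 6, (0.5, 0.3, 0.2), seed=11)
        for _ in range(2):
            opt = sy.OpticsParams(seed=11)
            f, t = sy.render_population(spec.geometries, sy.CapModel(), opt)
        f2, t2 = sy.render_population(spec.geometries, sy.CapModel(), sy.OpticsParams(seed=11))
        assert all(np.array_equal(f[ch], f2[ch]) for ch in f)
        assert t.to_json() == t2.to_json()


class TestPulseChase:
    def test_zero_rates_give_zero_unlabeled_everywhere(self, rod, noiseless_optics):
        growth = sy.GrowthParams(rate_pole_a=0.0, rate_pole_b=0.0, pulse_end=6.0)
        tl, truth = sy.simulate_pulse_chase(
            [rod], growth, noiseless_optics, times=(0.0, 60.0, 120.0), shape=(80, 120)
        )
        assert all(c.unlabeled_length == 0.0 for c in truth.cells)

    def test_unlabeled_total_follows_rate_times_chase(self, noiseless_optics):
        g = sy.CellGeometry((5.0, 5.0), 0.0, 3.0, 1.0)
        growth = sy.GrowthParams(rate_pole_a=0.01, rate_pole_b=0.01, pulse_end=0.0)
        _, truth = sy.simulate_pulse_chase(
            [g], growth, noiseless_optics, times=(100.0,), shape=(160, 160)
        )
        assert truth.cells[0].unlabeled_length == pytest.approx(2.0)

    def test_unlabeled_length_monotone_in_time(self, noiseless_optics):
        spec = sy.make_strain_scenario("m", 4, (1.0, 0, 0), seed=2, extra_spacing_um=2.0)
        growth = sy.GrowthParams(rate_pole_a=0.004, rate_pole_b=0.007, pulse_end=6.0)
        _, truth = sy.simulate_pulse_chase(
            spec.geometries, growth, noiseless_optics, times=(0.0, 10.0, 40.0, 80.0, 120.0)
        )
        for idx in range(4):
            series = [c.unlabeled_length for c in truth.cells if c.cell_index == idx]
            assert all(b >= a for a, b in zip(series, series[1:]))

    def test_growth_beyond_frame_names_frame_index(self, noiseless_optics):
        g = sy.CellGeometry((2.5, 2.5), 0.0, 3.0, 1.0)
        growth = sy.GrowthParams(rate_pole_a=0.02, rate_pole_b=0.02, pulse_end=6.0)
        with pytest.raises(ValueError, match="frame 1"):
            sy.simulate_pulse_chase(g and [g], growth, noiseless_optics,
                                    times=(0.0, 120.0), shape=(80, 80))

    def test_pulse_must_end_before_duration(self, rod, noiseless_optics):
        growth = sy.GrowthParams(pulse_end=200.0, duration=120.0)
        with pytest.raises(ValueError, match="pulse_end"):
            sy.simulate_pulse_chase([rod], growth, noiseless_optics)


class TestStrainScenario:
    def test_all_none_fractions_give_zero_septa(self):
        spec = sy.make_strain_scenario("w", 50, (1.0, 0.0, 0.0), seed=1)
        assert all(g.n_septa == 0 for g in spec.geometries)

    def test_sampled_fractions_match_request_within_binomial_error(self):
        n = 10000
        fr = (0.75, 0.20, 0.05)
        spec = sy.make_strain_scenario("w", n, fr, seed=2)
        counts = np.bincount([min(c, 2) for c in spec.septa_counts], minlength=3)
        for k, p in enumerate(fr):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) <= 3 * se

    def test_same_seed_is_byte_identical(self):
        a = sy.make_strain_scenario("w", 200, (0.75, 0.2, 0.05), seed=5)
        b = sy.make_strain_scenario("w", 200, (0.75, 0.2, 0.05), seed=5)
        assert a.geometries == b.geometries
        assert a.septa_counts == b.septa_counts

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sy.make_strain_scenario("w", 10, (0.5, 0.2, 0.2), seed=0)

    def test_septa_positions_respect_geometry_invariant(self):
        spec = sy.make_strain_scenario("w", 300, (0.0, 0.2, 0.8), seed=3)
        for g in spec.geometries:
            for f in g.septa_positions:
                assert 0.15 < f < 0.85


class TestTypeInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(center=(1, 1), orientation=0.0, length=0.5, width=1.0),
            dict(center=(1, 1), orientation=-0.1, length=3.0, width=1.0),
            dict(center=(1, 1), orientation=0.0, length=3.0, width=1.0,
                 septa_positions=(0.05,)),
        ],
    )
    def test_bad_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sy.CellGeometry(**kwargs)

    def test_bad_growth_and_optics_rejected(self):
        with pytest.raises(ValueError):
            sy.GrowthParams(rate_pole_a=-0.1)
        with pytest.raises(ValueError):
            sy.GrowthParams(frame_interval=0.0)
        with pytest.raises(ValueError):
            sy.OpticsParams(pixel_size=0.0)
        with pytest.raises(ValueError):
            sy.CapModel(sigma=0.0)
        with pytest.raises(ValueError):
            sy.CapModel(kind="ring")
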