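"""Unlabeled-wall measurement, elongation rate and septum counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polegrow import synthetic as sy
from polegrow import pipeline as pl
from polegrow.pulsechase import (
    SeptaRecord,
    count_septa,
    polar_elongation_rate,
    septa_fractions,
    unlabeled_length,
)
from conftest import make_profile


def brute_force_unlabeled(values, positions, frac):
    """Independent per-sample scan implementing the threshold rule."""
    values = np.asarray(values, float)
    thr = frac * values.max()
    step = positions[1] - positions[0]
    n_below = 0
    segments = 0
    in_run = False
    for v in values:
        if v < thr:
            n_below += 1
            if not in_run:
                segments += 1
                in_run = True
        else:
            in_run = False
    return min(n_below * step, positions[-1]), segments


class TestUnlabeledLength:
    def test_constant_profile_is_fully_labeled(self):
        m = unlabeled_length(make_profile([5.0] * 20))
        assert m.unlabeled_length == 0.0
        assert m.n_segments == 0

    def test_worked_stepwise_profile(self):
        # 4.0 µm at 0.1 µm: value 0.1 on [0, 1.0) µm, 1.0 elsewhere
        values = np.where(np.linspace(0, 4.0, 41) < 1.0, 0.1, 1.0)
        m = unlabeled_length(make_profile(values, length=4.0))
        assert m.threshold_used == pytest.approx(0.2)
        assert m.unlabeled_length == pytest.approx(1.0)
        assert m.n_segments == 1

    def test_all_zero_profile_flagged_no_signal(self):
        m = unlabeled_length(make_profile([0.0] * 30, length=2.9))
        assert m.no_signal
        assert m.unlabeled_length == pytest.approx(2.9)

    def test_too_short_profile_and_bad_frac_rejected(self):
        with pytest.raises(ValueError):
            unlabeled_length(make_profile([1, 2, 3]))
        with pytest.raises(ValueError):
            unlabeled_length(make_profile([1.0] * 10), frac=1.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_scan_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        values = rng.uniform(0, 50, n)
        prof = make_profile(values)
        m = unlabeled_length(prof, frac=0.2)
        expect, segs = brute_force_unlabeled(values, prof.positions, 0.2)
        assert m.unlabeled_length == expect
        assert m.n_segments == segs

    @pytest.mark.parametrize("k", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 30, 40)
        a = unlabeled_length(make_profile(values))
        b = unlabeled_length(make_profile(k * values))
        assert a.unlabeled_length == b.unlabeled_length
        assert a.n_segments == b.n_segments

    def test_monotone_nondecreasing_in_threshold_fraction(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            values = rng.uniform(0, 20, int(rng.integers(8, 60)))
            prof = make_profile(values)
            lengths = [
                unlabeled_length(prof, frac=f).unlabeled_length
                for f in (0.1, 0.2, 0.3, 0.5)
            ]
            assert all(b >= a for a, b in zip(lengths, lengths[1:]))


class TestElongationRate:
    def _measures(self, lengths, t):
        return [
            unlabeled_length(
                make_profile(np.where(np.linspace(0, 4, 41) < u, 0.0, 1.0), length=4.0),
                time=t,
            )
            for u in lengths
        ]

    def test_equal_means_give_zero_rate(self):
        est = polar_elongation_rate(self._measures([1.0, 2.0], 20.0),
                                    self._measures([2.0, 1.0], 120.0))
        assert est.mean_rate == pytest.approx(0.0)

    def test_worked_mean_difference(self):
        # mean 1.0 µm at t=20, mean 2.0 µm at t=120 -> 0.01 µm/min
        est = polar_elongation_rate(self._measures([1.0], 20.0),
                                    self._measures([2.0], 120.0))
        assert est.mean_rate == pytest.approx(0.01, rel=0.05)
        assert est.t_initial == 20.0 and est.t_final == 120.0

    def test_reversed_time_order_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            polar_elongation_rate(self._measures([1.0], 120.0),
                                  self._measures([2.0], 20.0))

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            polar_elongation_rate([], self._measures([1.0], 120.0))

    def test_no_signal_cells_excluded_by_default(self):
        good = self._measures([1.0, 1.0], 20.0)
        bad = unlabeled_length(make_profile([0.0] * 30, length=4.0), time=20.0)
        est = polar_elongation_rate(good + [bad], self._measures([2.0], 120.0))
        assert est.n_initial == 2


class TestCountSepta:
    def test_profile_without_interior_maximum(self):
        values = np.exp(-np.linspace(0, 4, 41))  # monotone decay
        rec = count_septa(make_profile(values, length=4.0))
        assert rec.count == 0 and rec.category == "none"

    def test_two_rendered_bands_counted_as_multiple(self):
        geom = sy.CellGeometry((3.5, 2.5), 0.2, 4.0, 1.0, (0.33, 0.66))
        optics = sy.OpticsParams(psf_sigma=0.08, poisson_gain=0.0, read_noise_sd=0.0)
        frames, _ = sy.render_population(
            [geom], None, optics, channels=("phase", "label"), shape=(110, 130)
        )
        records, _ = pl.septa_survey(
            frames["phase"], frames["label"], optics.pixel_size
        )
        assert records[0].count == 2
        assert records[0].category == "multiple"

    def test_band_inside_pole_exclusion_not_counted(self):
        positions = np.linspace(0, 4.0, 81)
        values = np.ones(81)
        values[np.abs(positions - 0.2) < 0.1] = 10.0  # polar label, not a septum
        rec = count_septa(make_profile(values, length=4.0), pole_exclusion=0.4)
        assert rec.count == 0

    def test_pole_exclusion_must_leave_an_interior(self):
        with pytest.raises(ValueError):
            count_septa(make_profile([1.0] * 11, length=1.0), pole_exclusion=0.6)

    def test_close_peaks_merged_by_separation_rule(self):
        positions = np.linspace(0, 4.0, 201)
        values = np.ones(201)
        for c in (2.0, 2.1):  # two peaks 0.1 µm apart
            values[np.abs(positions - c) < 0.02] = 10.0
        rec = count_septa(make_profile(values, length=4.0))
        assert rec.count == 1


class TestSeptaFractions:
    def test_percentages_are_plain_arithmetic(self):
        records = (
            [SeptaRecord(i, 0) for i in range(70)]
            + [SeptaRecord(i, 1) for i in range(70, 90)]
            + [SeptaRecord(i, 2) for i in range(90, 100)]
        )
        fr = septa_fractions(records)
        assert (fr["none"], fr["one"], fr["multiple"]) == (70.0, 20.0, 10.0)
        assert fr["n"] == 100

    def test_all_zero_counts(self):
        fr = septa_fractions([SeptaRecord(i, 0) for i in range(5)])
        assert (fr["none"], fr["one"], fr["multiple"]) == (100.0, 0.0, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            septa_fractions([])

    def test_categories_partition_population(self):
        rng = np.random.default_rng(1)
        records = [SeptaRecord(i, int(c)) for i, c in enumerate(rng.integers(0, 5, 333))]
        fr = septa_fractions(records)
        assert fr["none"] + fr["one"] + fr["multiple"] == pytest.approx(100.0, abs=0.01)


def test_noiseless_pulse_chase_cell_measures_close_to_truth():
    g = sy.CellGeometry((5.0, 5.0), 0.0, 3.0, 1.0)
    growth = sy.GrowthParams(rate_pole_a=0.01, rate_pole_b=0.01, pulse_end=0.0)
    optics = sy.OpticsParams(poisson_gain=0.0, read_noise_sd=0.0)
    tl, truth = sy.simulate_pulse_chase([g], growth, optics, times=(100.0,),
                                        shape=(170, 170))
    ms = pl.unlabeled_measures_frame(
        tl.frames[0]["phase"], tl.frames[0]["label"], optics.pixel_size, time=100.0
    )
    assert len(ms) == 1
    assert ms[0].unlabeled_length == pytest.approx(2.0, abs=0.2)
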