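"""Classification tests: scores, shuffles, fields, grid score and geometry."""

import numpy as np
import pytest

from mini2p_tuning.classify import (CellVerdict, GridGeometry, SessionContext,
                                    TuningCurve, classify_grid_cell,
                                    classify_hd_cell, classify_place_cell,
                                    conjunctive_flag, detect_place_fields,
                                    draw_circular_shifts, escape_active,
                                    grid_geometry, grid_score,
                                    grid_score_batch, mean_vector_length,
                                    population_ratio_null, rolled,
                                    spatial_information)
from mini2p_tuning.maps import TuningMap, spatial_autocorrelogram
from mini2p_tuning.synthetic import TuningModel, grid_pattern, rate_from_tuning

from conftest import events_from_rate


def _map_from(p, lam):
    """TuningMap with prescribed occupancy probabilities and rates."""
    p = np.asarray(p, dtype=float).reshape(1, -1)
    lam = np.asarray(lam, dtype=float).reshape(1, -1)
    return TuningMap(rate=lam, rate_raw=lam, occupancy_s=p,
                     visit_mask=np.ones_like(p, dtype=bool),
                     bin_size_cm=2.5, smoothing_sd_cm=3.0)


class TestSpatialInformation:
    def test_uniform_zero(self):
        assert spatial_information(_map_from([0.25] * 4, [1.0] * 4)) == 0.0

    def test_half_half_one_bit(self):
        assert spatial_information(_map_from([0.5, 0.5], [2.0, 0.0])) \
            == pytest.approx(1.0)

    def test_quarter_two_bits(self):
        assert spatial_information(_map_from([0.25, 0.75], [4.0, 0.0])) \
            == pytest.approx(2.0)

    def test_zero_map_flagged_zero(self):
        assert spatial_information(_map_from([0.5, 0.5], [0.0, 0.0])) == 0.0


class TestMVL:
    def _curve(self, values):
        nb = len(values)
        centers = (np.arange(nb) + 0.5) * (360.0 / nb)
        return TuningCurve(values=np.asarray(values, float),
                           values_raw=np.asarray(values, float),
                           occupancy_s=np.ones(nb), bin_centers=centers,
                           bin_width=360.0 / nb, smoothing_sd=6.0, circular=True)

    def test_single_bin_unity(self):
        v = np.zeros(120)
        v[17] = 3.0
        assert mean_vector_length(self._curve(v)) == pytest.approx(1.0)

    def test_uniform_zero(self):
        assert mean_vector_length(self._curve(np.ones(120))) \
            == pytest.approx(0.0, abs=1e-12)

    def test_one_plus_cosine_half(self):
        centers = (np.arange(120) + 0.5) * 3.0
        v = 1.0 + np.cos(np.radians(centers))
        assert mean_vector_length(self._curve(v)) == pytest.approx(0.5, abs=0.01)

    def test_all_zero_flagged(self):
        assert mean_vector_length(self._curve(np.zeros(120))) == 0.0


class TestShuffles:
    def test_full_length_shift_identity(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(size=100)
        out = rolled(e, np.array([100]), np.arange(100))
        assert np.allclose(out[0], e)

    def test_mass_conserved(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(size=1000) * (rng.uniform(size=1000) < 0.1)
        shifts = draw_circular_shifts(1000, 15.0, 20, rng, margin_s=10.0)
        out = rolled(e, shifts, np.arange(1000))
        assert np.allclose(out.sum(axis=1), e.sum())

    def test_seed_determinism_and_bounds(self):
        a = draw_circular_shifts(27000, 15.0, 50, np.random.default_rng(7))
        b = draw_circular_shifts(27000, 15.0, 50, np.random.default_rng(7))
        c = draw_circular_shifts(27000, 15.0, 50, np.random.default_rng(8))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert a.min() >= 30 * 15 and a.max() <= 27000 - 30 * 15

    def test_session_too_short(self):
        with pytest.raises(ValueError):
            draw_circular_shifts(100, 15.0, 5, np.random.default_rng(0))


class TestPlaceFields:
    def _bump_map(self, sigma_bins=2.0, peak=1.0, shape=(32, 32), center=(16, 16)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        rate = peak * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                             / (2 * sigma_bins ** 2))
        occ = np.full(shape, 1.0)
        return TuningMap(rate=rate, rate_raw=rate, occupancy_s=occ,
                         visit_mask=np.ones(shape, bool), bin_size_cm=2.5,
                         smoothing_sd_cm=3.0)

    def test_single_bump_one_field(self):
        fields = detect_place_fields(self._bump_map(), min_mean_rate=0.1)
        assert len(fields) == 1
        assert any((b == [16, 16]).all() for b in fields[0].bins)

    def test_small_bump_rejected(self):
        tm = self._bump_map(sigma_bins=0.7)
        # threshold at 20% of peak spans ~3 bins across: under the 9-bin floor
        fields = detect_place_fields(tm, min_mean_rate=0.0)
        assert fields == []

    def test_flat_zero_map_no_fields(self):
        tm = self._bump_map(peak=0.0)
        assert detect_place_fields(tm) == []

    def test_low_rate_field_rejected(self):
        fields = detect_place_fields(self._bump_map(peak=0.01), min_mean_rate=0.1)
        assert fields == []


class TestStability:
    def test_identical_halves_unity(self, context_30min, tracking_30min):
        rate = rate_from_tuning(
            TuningModel("place", {"center_cm": (40.0, 40.0), "width_cm": 10.0,
                                  "peak_rate_hz": 4.0}, baseline_rate_hz=0.5),
            tracking_30min)
        ev = events_from_rate(rate, 15.0, seed=12)
        stab = context_30min.stability_batch(ev, np.array([0]))[0]
        assert stab > 0.5  # same generating field in both halves

    def test_anticorrelated_checkerboard_negative(self):
        from mini2p_tuning.maps import map_correlation
        m = (np.indices((10, 10)).sum(axis=0) % 2).astype(float)
        assert map_correlation(m, 1.0 - m) < 0


class TestGridScoreOracle:
    def test_matches_brute_force_on_random_maps(self):
        # 20 random 30x30 maps: library scorer vs explicit-loop oracle
        from oracle_gridscore import grid_score_brute
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = gaussian_filter(rng.normal(size=(30, 30)), 1.5)
            ac = spatial_autocorrelogram(m).values
            a = grid_score(ac)
            b = grid_score_brute(ac)
            if np.isnan(a) and np.isnan(b):
                continue
            assert a == pytest.approx(b, abs=1e-9)

    def test_ideal_grid_scores_high(self):
        xs = (np.arange(63) - 31) * 2.5
        X, Y = np.meshgrid(xs, xs)
        field = grid_pattern(X, Y, 40.0)
        s = grid_score(field)
        assert s > 1.0

    def test_square_lattice_negative(self):
        xs = (np.arange(63) - 31) * 2.5
        X, Y = np.meshgrid(xs, xs)
        k = 2 * np.pi / 40.0
        field = np.clip(np.cos(k * X) + np.cos(k * Y), 0, None)
        assert grid_score(field) < 0

    def test_white_noise_scores_stay_low(self):
        # the max-over-annuli selection gives unstructured maps a small
        # positive offset; the distribution must stay far below real grid
        # scores (> 1 for an ideal lattice) and straddle zero
        rng = np.random.default_rng(9)
        stack = rng.normal(size=(100, 51, 51))
        acs = np.stack([spatial_autocorrelogram(m).values for m in stack])
        scores = grid_score_batch(acs)
        assert abs(np.nanmean(scores)) < 0.3
        assert np.nanpercentile(scores, 95) < 0.7
        assert np.nanmin(scores) < 0.0


class TestGridGeometry:
    def _hex_field(self, spacing_cm=40.0, orientation_deg=0.0, bin_cm=2.5, n=63):
        xs = (np.arange(n) - n // 2) * bin_cm
        X, Y = np.meshgrid(xs, xs)
        return grid_pattern(X, Y, spacing_cm, orientation_deg)

    def test_ideal_hexagon_spacing_and_axes(self):
        g = grid_geometry(self._hex_field(), 2.5)
        assert g.valid
        assert g.spacing_cm == pytest.approx(40.0, abs=2.5)
        got = sorted(round(a) for a in g.axis_angles_deg)
        assert got == pytest.approx([-60, 0, 60], abs=3)

    def test_rotation_equivariance(self):
        for phi in (10.0, 25.0, 47.0):
            g = grid_geometry(self._hex_field(orientation_deg=phi), 2.5)
            assert g.valid
            d = (g.orientation_deg - phi) % 60.0
            assert min(d, 60.0 - d) < 3.0

    def test_square_lattice_fails_interaxis(self):
        xs = (np.arange(63) - 31) * 2.5
        X, Y = np.meshgrid(xs, xs)
        k = 2 * np.pi / 40.0
        field = np.clip(np.cos(k * X) + np.cos(k * Y), 0, None)
        g = grid_geometry(field, 2.5)
        assert not g.valid

    def test_too_few_fields(self):
        g = grid_geometry(np.zeros((21, 21)), 2.5)
        assert not g.valid and "six" in g.reason


class TestClassifiers:
    def test_ineligible_cell_no_flags(self, context_30min):
        v = classify_place_cell(np.zeros(context_30min.n_frames), context_30min,
                                np.random.default_rng(0), eligible=False)
        assert not v.flags and not v.eligible

    def test_place_cell_recovered(self, context_30min, tracking_30min):
        rate = rate_from_tuning(
            TuningModel("place", {"center_cm": (30.0, 50.0), "width_cm": 8.0,
                                  "peak_rate_hz": 5.0}, baseline_rate_hz=1.0),
            tracking_30min)
        ev = events_from_rate(rate, 15.0, seed=21)
        v = classify_place_cell(ev, context_30min, np.random.default_rng(1),
                                n_perm=200)
        assert v.flags["place"] and v.n_fields >= 1

    def test_hd_cell_recovered_with_direction(self, context_30min, tracking_30min):
        rate = rate_from_tuning(
            TuningModel("head_direction", {"preferred_deg": 120.0,
                                           "concentration": 4.0,
                                           "peak_rate_hz": 3.0},
                        baseline_rate_hz=0.2), tracking_30min)
        ev = events_from_rate(rate, 15.0, seed=22)
        v = classify_hd_cell(ev, context_30min, np.random.default_rng(2),
                             n_perm=200)
        assert v.flags["head_direction"]
        pref = v.criteria["preferred_direction_deg"].statistic
        d = abs((pref - 120.0 + 180.0) % 360.0 - 180.0)
        assert d <= 6.0  # within two 3-degree bins

    def test_uniform_curve_not_flagged(self, context_30min):
        # untuned cell: MVL of its curve stays at chance
        rng = np.random.default_rng(3)
        ev = (rng.uniform(size=context_30min.n_frames) < 0.03).astype(float)
        v = classify_hd_cell(ev, context_30min, rng, n_perm=100)
        assert v.criteria["mvl"].statistic < 0.2

    def test_grid_cell_recovered(self, context_30min, tracking_30min):
        rate = rate_from_tuning(
            TuningModel("grid", {"spacing_cm": 40.0, "orientation_deg": 15.0,
                                 "phase_cm": (5.0, 12.0), "peak_rate_hz": 5.0},
                        baseline_rate_hz=0.05), tracking_30min)
        ev = events_from_rate(rate, 15.0, seed=23)
        v = classify_grid_cell(ev, context_30min, np.random.default_rng(4),
                               n_perm=200)
        assert v.flags["grid"]
        assert v.geometry.spacing_cm == pytest.approx(40.0, abs=2.5)

    def test_conjunctive_requires_both(self):
        g = CellVerdict(cell_id=0, eligible=True, flags={"grid": True})
        h = CellVerdict(cell_id=0, eligible=True, flags={"head_direction": False})
        assert not conjunctive_flag(g, h)
        h.flags["head_direction"] = True
        assert conjunctive_flag(g, h)

    def test_detection_monotone_in_peak_rate(self, context_30min, tracking_30min):
        # raising the place-field peak rate never lowers the detection rate
        rates = []
        for peak in (0.3, 1.0, 3.0, 6.0):
            hits = 0
            for s in range(6):
                rate = rate_from_tuning(
                    TuningModel("place", {"center_cm": (30.0, 50.0),
                                          "width_cm": 8.0,
                                          "peak_rate_hz": peak},
                                baseline_rate_hz=1.0), tracking_30min)
                ev = events_from_rate(rate, 15.0, seed=100 + s)
                v = classify_place_cell(ev, context_30min,
                                        np.random.default_rng(200 + s),
                                        n_perm=100)
                hits += v.flags["place"]
            rates.append(hits / 6)
        assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 1.0


class TestEscape:
    def test_score_arithmetic(self):
        n = 3000
        rng = np.random.default_rng(5)
        mask = np.zeros(n, bool)
        mask[::10] = True
        # equal means: score 0
        dff = np.ones(n)
        s, _, _ = escape_active(dff, mask, 15.0, rng, n_perm=10)
        assert s == pytest.approx(0.0)
        # all activity inside the mask: score 1
        dff = np.where(mask, 2.0, 0.0)
        s, _, _ = escape_active(dff, mask, 15.0, np.random.default_rng(6),
                                n_perm=10)
        assert s == pytest.approx(1.0)
        # F_escape = 1, F_other = 3 -> -0.5
        dff = np.where(mask, 1.0, 3.0)
        s, _, _ = escape_active(dff, mask, 15.0, np.random.default_rng(7),
                                n_perm=10)
        assert s == pytest.approx(-0.5)

    def test_escape_cell_flagged(self):
        rng = np.random.default_rng(8)
        n = 27000
        mask = np.zeros(n, bool)
        for start in range(2000, n - 200, 3000):
            mask[start:start + 30] = True
        dff = rng.normal(0.1, 0.05, n) + np.where(mask, 1.0, 0.0)
        score, thr, flagged = escape_active(dff, mask, 15.0, rng)
        assert flagged and score > thr

    def test_bad_mask_rejected(self):
        with pytest.raises(ValueError):
            escape_active(np.ones(100), np.ones(100, bool), 15.0,
                          np.random.default_rng(0))


class TestPopulationRatioNull:
    def test_deterministic_and_calibrated(self):
        rng = np.random.default_rng(11)
        n = 9000
        flagged = [(np.random.default_rng(k).uniform(size=n) < 0.05).astype(float)
                   for k in range(3)]
        # criterion passing ~10% of shuffles by construction
        thresholds = {}
        for i, ev in enumerate(flagged):
            nulls = [np.roll(ev, s)[:100].sum() for s in
                     draw_circular_shifts(n, 15.0, 200, np.random.default_rng(i))]
            thresholds[i] = np.percentile(nulls, 90)

        calls = {"i": 0}

        def criterion(ev):
            i = calls["i"] % 3
            calls["i"] += 1
            return ev[:100].sum() > thresholds[i]

        fr_a = population_ratio_null(flagged, total_n=30, n_rounds=4,
                                     criterion=criterion, frame_rate_hz=15.0,
                                     rng=np.random.default_rng(99))
        calls["i"] = 0
        fr_b = population_ratio_null(flagged, total_n=30, n_rounds=4,
                                     criterion=criterion, frame_rate_hz=15.0,
                                     rng=np.random.default_rng(99))
        assert np.array_equal(fr_a, fr_b)
        assert 0.0 <= fr_a.mean() <= 0.5
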