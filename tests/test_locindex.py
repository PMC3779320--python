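"""Localization index: closed forms, affine invariance, Monte-Carlo null
calibration against independent oracles, and behavior on synthetic cells.

Frozen oracle values (brute-force order-statistics Monte Carlo, 2e5 reps):
null index mean 2.514 at n=100 (k=1) and 2.663 at n=10,000 (k=100); the
analytic large-n limit is phi(z_0.99)/0.01 = 2.6652.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meltkit import locindex as li
from meltkit import scenes


class TestClosedForms:
    @pytest.mark.parametrize("c", [1.0, 5.0, 1000.0])
    def test_one_hot_sample_gives_exact_index(self, c):
        """n=100 with one bright pixel: index = (1 - 1/n) sqrt(n) = 9.9,
        independent of the bright value."""
        x = np.zeros(100)
        x[37] = c
        assert li.localization_index(x) == pytest.approx(9.9, abs=1e-9)

    @pytest.mark.parametrize("n", [64, 81, 100])
    def test_one_hot_general_formula(self, n):
        x = np.zeros(n)
        x[0] = 3.0
        expected = (1 - 1 / n) * np.sqrt(n)
        assert li.localization_index(x) == pytest.approx(expected, abs=1e-9)

    def test_top_k_rule(self):
        assert li.top_k(100) == 1
        assert li.top_k(101) == 2
        assert li.top_k(10_000) == 100
        assert li.top_k(50, 0.5) == 25
        assert li.top_k(3, 0.01) == 1

    @given(st.lists(st.floats(-100, 100), min_size=50, max_size=300),
           st.floats(0.1, 50), st.floats(-1000, 1000))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_affine_invariance(self, values, a, b):
        x = np.asarray(values)
        if x.std(ddof=1) < 1e-6:
            return
        ref = li.localization_index(x)
        mapped = li.localization_index(a * x + b)
        assert mapped == pytest.approx(ref, abs=1e-9)

    def test_error_conditions(self):
        with pytest.raises(li.InsufficientPixelsError):
            li.localization_index(np.arange(10))
        with pytest.raises(li.DegenerateSampleError):
            li.localization_index(np.full(100, 7.0))
        with pytest.raises(ValueError):
            li.localization_index(np.r_[np.ones(99), np.nan])


class TestNullCalibration:
    def test_null_mean_matches_analytic_tail_mean_at_large_n(self):
        """Monte-Carlo null mean at n=10,000, f=0.01 within 0.05 of the
        standardized upper-tail conditional mean phi(z_0.99)/0.01."""
        entry = li.calibrate_null(10_000, reps=1500, seed=3)
        assert entry.mean == pytest.approx(li.analytic_null_mean(), abs=0.05)
        assert li.analytic_null_mean() == pytest.approx(2.6652, abs=1e-3)

    def test_null_mean_at_n100_matches_max_oracle(self):
        """At n=100 the top set is the single maximum; the frozen
        order-statistics oracle value is 2.514."""
        entry = li.calibrate_null(100, reps=20_000, seed=5)
        assert entry.mean == pytest.approx(2.514, abs=0.05)

    def test_null_sd_decreases_with_sample_size(self):
        sds = [li.calibrate_null(n, reps=800, seed=7).sd
               for n in (500, 5000, 50_000)]
        assert sds[0] > sds[1] > sds[2]

    def test_calibration_is_deterministic_and_monotone(self):
        e1 = li.calibrate_null(2000, reps=500, seed=11)
        e2 = li.calibrate_null(2000, reps=500, seed=11)
        assert e1 == e2
        qs = [e1.quantiles[q] for q in sorted(e1.quantiles)]
        assert qs == sorted(qs)
        assert list(e1.tail_values) == sorted(e1.tail_values)

    def test_tail_interpolation_brackets_calibrated_points(self):
        entry = li.calibrate_null(1000, reps=4000, seed=2)
        assert entry.quantile_at(0.99) == pytest.approx(entry.quantiles[0.99],
                                                        abs=1e-9)
        assert (entry.quantiles[0.99] < entry.quantile_at(0.997)
                < entry.quantiles[0.999])

    def test_camera_null_sits_above_gaussian_null(self):
        """Shot noise at finite counts is right-skewed, so the camera-model
        null mean exceeds the ideal Gaussian one."""
        g = li.calibrate_null(2000, reps=1500, seed=4)
        cam = li.calibrate_null_camera(2000, mean_counts=500.0,
                                       read_noise_sd=3.0, reps=1500, seed=4)
        assert cam.mean > g.mean
        assert cam.mean - g.mean < 0.15

    def test_nearest_n_lookup_and_json_round_trip(self, tmp_path):
        calib = li.NullCalibration.calibrate([500, 1500], reps=300, seed=9)
        assert calib.entry_for(700).n == 500
        assert calib.entry_for(1101).n == 1500
        calib.to_json(tmp_path / "null.json")
        back = li.NullCalibration.from_json(tmp_path / "null.json")
        assert back.entries == calib.entries
        assert back.empirical_baseline == li.EMPIRICAL_BASELINE == 3.7


class TestIndexOnSyntheticCells:
    def test_expected_index_increases_with_focus_amplitude(self,
                                                           small_scene_config):
        """Mean index over frames is strictly increasing in the focus
        amplitude (Spearman rho = 1 over the amplitude grid)."""
        from dataclasses import replace
        means = []
        for amp in (0.0, 200.0, 400.0, 800.0, 1600.0):
            cfg = replace(small_scene_config, channels=(
                replace(small_scene_config.channels[0], focus_amplitude=amp),))
            stack, truth = scenes.generate_scene(cfg, 21)
            vals = []
            for f in range(cfg.n_frames):
                pix = stack[f, 0][truth.label_masks[f] == 1]
                vals.append(li.localization_index(pix))
            means.append(np.mean(vals))
        assert means == sorted(means)
        assert means[-1] > means[0] + 3.0

    def test_wildtype_focus_frames_exceed_null_quantile(self, wildtype_scene):
        """Inside the localized window the median index clears the 0.99
        null quantile by a wide margin."""
        cfg, stack, truth = wildtype_scene
        vals, ns = [], []
        for cid in range(cfg.n_cells):
            for f in range(cfg.n_frames):
                if truth.localized_flags[cid, f]:
                    pix = stack[f, 0][truth.label_masks[f] == cid + 1]
                    vals.append(li.localization_index(pix))
                    ns.append(pix.size)
        entry = li.calibrate_null(int(np.median(ns)), reps=1500, seed=1)
        assert np.median(vals) > entry.quantiles[0.99]

    def test_mutant_series_stays_in_camera_null_band(self, mutant_scene,
                                                     mutant_masks,
                                                     mutant_tracks):
        """Delocalized (mutant) index values are distributed like the
        camera-noise null: the fraction of frames above the 0.999 null
        quantile stays at the per-mille level, far below the wild-type
        localized fraction."""
        cfg, stack, truth = mutant_scene
        tracks, events = mutant_tracks
        mothers = {e.mother_track_id for e in events}
        vals, ns = [], []
        for t in tracks:
            if t.track_id not in mothers:
                continue
            s = li.index_series(stack, mutant_masks, t, channel=0)
            vals.extend(s.values[s.valid()])
            ns.extend(s.n_pixels[s.valid()])
        lam = float(np.mean([stack[f, 0][mutant_masks[f] > 0].mean()
                             for f in range(0, stack.shape[0], 12)]))
        cam = cfg.channels[0]
        entry = li.calibrate_null_camera(int(np.median(ns)), lam,
                                         cam.photon_gain, cam.read_noise_sd,
                                         reps=4000, seed=1)
        exceed = np.mean(np.asarray(vals) > entry.quantiles[0.999])
        assert len(vals) > 300
        assert exceed <= 0.01

    def test_degenerate_cell_recorded_as_gap(self):
        stack = np.full((2, 1, 50, 50), 300, dtype=np.uint16)
        masks = np.zeros((2, 50, 50), dtype=np.int32)
        masks[:, 10:30, 10:30] = 1
        from meltkit.tracking import CellTrack
        tr = CellTrack(track_id=1)
        tr.add(0, 1, (20, 20), 400)
        tr.add(1, 1, (20, 20), 400)
        s = li.index_series(stack, masks, tr, channel=0)
        assert np.isnan(s.values).all()
        assert (s.n_pixels == 400).all()

    def test_empty_track_gives_empty_series(self):
        from meltkit.tracking import CellTrack
        s = li.index_series(np.zeros((1, 1, 8, 8), dtype=np.uint16),
                            np.zeros((1, 8, 8), dtype=np.int32),
                            CellTrack(track_id=5), channel=0)
        assert s.frames.size == 0 and s.values.size == 0
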