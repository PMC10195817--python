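"""AFM grain masking, filtering, bounding sizes and contour morphometrics."""

import numpy as np
import pytest
from scipy import ndimage

from oracles import brute_caliper_bounds, brute_threshold_mask
from smquant.afm import (
    Grain,
    GrainParams,
    compaction_stats,
    dna_binding_position,
    filter_grains,
    grain_bounds,
    kde_mode,
    mask_grains,
)
from smquant.io import HeightMap, ParameterError
from smquant.simulate import simulate_afm_scene


def _blob_map(centres, amp=5.0, size=64, sd=2.0, pixel_size=1.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    h = rng.normal(0, 0.05, (size, size))
    for cy, cx in centres:
        h += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sd ** 2))
    return HeightMap(heights=h, pixel_size=pixel_size)


class TestMaskGrains:
    def test_single_blob_single_grain(self):
        hmap = _blob_map([(32, 32)])
        gs = mask_grains(hmap, GrainParams(k_sigma=0.7))
        assert len(gs) == 1

    def test_grain_count_monotone_in_k_sigma(self):
        hmap = _blob_map([(16, 16), (48, 48)], amp=3.0)
        counts = [len(mask_grains(hmap, GrainParams(k_sigma=k)))
                  for k in (0.5, 1.0, 2.0, 50.0)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_mask_matches_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(0, 0.1, (48, 48))
        for _ in range(rng.integers(1, 4)):
            cy, cx = rng.integers(8, 40, 2)
            yy, xx = np.mgrid[0:48, 0:48]
            h += rng.uniform(1, 4) * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0)
        hmap = HeightMap(heights=h, pixel_size=2.0)
        k = float(rng.uniform(0.5, 1.5))
        gs = mask_grains(hmap, GrainParams(k_sigma=k))
        combined = np.zeros((48, 48), dtype=bool)
        for g in gs.grains:
            combined |= g.mask
        smoothed = ndimage.gaussian_filter(h, 1.5)
        np.testing.assert_array_equal(combined,
                                      brute_threshold_mask(h, smoothed, k))

    def test_empty_mask_ok(self):
        hmap = HeightMap(heights=np.zeros((16, 16)), pixel_size=1.0)
        assert len(mask_grains(hmap, GrainParams(k_sigma=5.0))) == 0


class TestFilterGrains:
    @staticmethod
    def _grain(area_px, pixel_size=1.0, touch=False, offset=2):
        mask = np.zeros((32, 32), dtype=bool)
        side = int(np.sqrt(area_px))
        r0 = 0 if touch else offset
        mask[r0:r0 + side, offset:offset + max(1, area_px // side)] = True
        rows, cols = np.nonzero(mask)
        return Grain(mask=mask, area=float(mask.sum()) * pixel_size ** 2,
                     max_height=1.0, centroid=(0.0, 0.0),
                     touches_border=touch)

    def test_small_grain_dropped_by_area_rule(self):
        from smquant.afm import GrainSet
        gs = GrainSet(grains=[self._grain(40), self._grain(64)], pixel_size=1.0)
        out = filter_grains(gs, GrainParams(min_area=50.0))
        assert len(out) == 1
        assert out.drop_counts["min_area"] == 1

    def test_border_grain_dropped(self):
        from smquant.afm import GrainSet
        gs = GrainSet(grains=[self._grain(64, touch=True)], pixel_size=1.0)
        out = filter_grains(gs, GrainParams(min_area=0.0))
        assert len(out) == 0 and out.drop_counts["border"] == 1

    def test_identical_areas_survive_median_window(self):
        from smquant.afm import GrainSet
        gs = GrainSet(grains=[self._grain(64) for _ in range(5)],
                      pixel_size=1.0)
        out = filter_grains(gs, GrainParams(min_area=0.0,
                                            median_window=(0.5, 2.0)))
        assert len(out) == 5 and out.drop_counts["median_window"] == 0


class TestGrainBounds:
    def test_rectangle_caliper_widths(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:9, 4:14] = True   # 10 x 4 pixels
        g = Grain(mask=mask, area=40.0, max_height=1.0, centroid=(0, 0),
                  touches_border=False)
        mn, mx = grain_bounds(g, pixel_size=1.0)
        assert mn == pytest.approx(4.0, abs=1e-9)
        assert mx == pytest.approx(np.hypot(10, 4), abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_rotation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24), dtype=bool)
        n_px = int(rng.integers(2, 40))
        rows = rng.integers(4, 20, n_px)
        cols = rng.integers(4, 20, n_px)
        mask[rows, cols] = True
        g = Grain(mask=mask, area=float(mask.sum()), max_height=1.0,
                  centroid=(0, 0), touches_border=False)
        px = float(rng.uniform(0.5, 3.0))
        mn, mx = grain_bounds(g, pixel_size=px)
        rr, cc = np.nonzero(mask)
        corners = np.concatenate([
            np.column_stack([cc + dx, rr + dy])
            for dx in (0, 1) for dy in (0, 1)]).astype(float) * px
        omn, omx = brute_caliper_bounds(corners)
        # the grid oracle overestimates the minimum by up to O(dtheta^2)
        assert mn == pytest.approx(omn, rel=5e-4)
        assert mx == pytest.approx(omx, rel=5e-4)

    def test_disc_bounds_near_diameter(self):
        yy, xx = np.mgrid[0:40, 0:40]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2
        g = Grain(mask=mask, area=float(mask.sum()), max_height=1.0,
                  centroid=(0, 0), touches_border=False)
        mn, mx = grain_bounds(g, pixel_size=1.0)
        assert mn == pytest.approx(31.0, rel=0.05)
        assert mx == pytest.approx(31.0, rel=0.07)

    def test_single_pixel_both_bounds_equal_pixel_size(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        g = Grain(mask=mask, area=4.0, max_height=1.0, centroid=(0, 0),
                  touches_border=False)
        assert grain_bounds(g, pixel_size=2.0) == (2.0, 2.0)

    def test_rotation_by_90_degrees_invariant(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:9, 4:14] = True
        rot = np.rot90(mask)
        for m in (mask, rot):
            g = Grain(mask=m, area=float(m.sum()), max_height=1.0,
                      centroid=(0, 0), touches_border=False)
            mn, mx = grain_bounds(g, pixel_size=1.0)
            assert mn == pytest.approx(4.0)
            assert mx == pytest.approx(np.hypot(10, 4))


class TestKDEMode:
    def test_unimodal_gaussian_mode(self):
        rng = np.random.default_rng(0)
        mode, sd = kde_mode(rng.normal(20.0, 2.0, 1000))
        assert abs(mode - 20.0) < 0.5
        assert abs(sd - 2.0) < 0.3

    def test_bimodal_taller_wins_tie_toward_lower(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(10, 1, 700), rng.normal(30, 1, 300)])
        mode, _ = kde_mode(vals)
        assert abs(mode - 10.0) < 1.0

    def test_constant_sample(self):
        assert kde_mode(np.full(20, 7.0)) == (7.0, 0.0)

    def test_min_count_enforced(self):
        with pytest.raises(ParameterError):
            kde_mode(np.arange(5))


class TestDNABindingPosition:
    @staticmethod
    def _line(length=100.0, n=51):
        return np.column_stack([np.linspace(0, length, n), np.zeros(n)])

    def test_endpoint_zero_percent(self):
        out = dna_binding_position(self._line(), np.array([0.0, 0.0]))
        assert out["assigned"] and out["pct_from_end"] == 0.0
        assert out["label"] == "edge"

    def test_midpoint_fifty_percent_middle(self):
        out = dna_binding_position(self._line(), np.array([50.0, 0.0]))
        assert out["pct_from_end"] == pytest.approx(50.0)
        assert out["label"] == "middle"

    def test_orientation_symmetry(self):
        line = self._line()
        site = np.array([19.0, 1.0])
        a = dna_binding_position(line, site)
        b = dna_binding_position(line[::-1], site)
        assert a["pct_from_end"] == pytest.approx(b["pct_from_end"], abs=1e-9)

    def test_far_site_unassigned(self):
        out = dna_binding_position(self._line(), np.array([50.0, 500.0]))
        assert not out["assigned"]

    def test_synthetic_scene_blob_recovery(self):
        hits = []
        for s in range(10):
            _, truth = simulate_afm_scene(blob_positions=[0.19], noise_sd=0.0,
                                          seed=s)
            out = dna_binding_position(truth.polyline, truth.blob_xy[0])
            assert out["assigned"]
            hits.append(out["pct_from_end"])
        assert abs(np.mean(hits) - 19.0) < 1.5


class TestCompactionStats:
    def test_identical_samples(self, rng):
        v = rng.normal(100, 10, 200)
        out = compaction_stats(v, v)
        assert out["overlap"] == pytest.approx(1.0)
        assert out["shift_sign"] == 0

    def test_translated_sample_negative_shift(self, rng):
        v = rng.normal(100, 10, 200)
        out = compaction_stats(v, v - 20.0)
        assert out["shift_sign"] == -1
        assert out["overlap"] < 1.0

    def test_wlc_compaction_sign_across_seeds(self):
        correct = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            relaxed = rng.normal(40.0, 8.0, 50)    # max bounds, nm
            compact = rng.normal(28.0, 8.0, 50)
            out = compaction_stats(relaxed, compact)
            correct += out["shift_sign"] == -1
        assert correct >= 19
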