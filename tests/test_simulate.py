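"""Generator contracts: determinism, statistical structure, ground truth."""

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import box

from smquant.io import ParameterError
from smquant.simulate import (
    ClusterSceneParams,
    MobilityMixture,
    simulate_afm_scene,
    simulate_clustered_channels,
    simulate_csr,
    simulate_frap,
    simulate_titration,
    simulate_tracks,
    mst_dilution_series,
)
from smquant.tracking import track_msd


class TestCSR:
    def test_empty_and_determinism(self, square_roi):
        assert len(simulate_csr(square_roi, 0, seed=1)) == 0
        a = simulate_csr(square_roi, 100, seed=9)
        b = simulate_csr(square_roi, 100, seed=9)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_quadrant_intensity_binomial(self, square_roi):
        # 5000 pts in a 5x5 µm square: each quadrant ~ Binomial(5000, 1/4)
        table = simulate_csr(square_roi, 5000, precision=20.0, seed=2)
        x, y = table.xy[:, 0], table.xy[:, 1]
        sd = np.sqrt(5000 * 0.25 * 0.75)
        for qx in (0, 1):
            for qy in (0, 1):
                n_q = np.sum((x >= 2500 * qx) & (x < 2500 * (qx + 1))
                             & (y >= 2500 * qy) & (y < 2500 * (qy + 1)))
                assert abs(n_q - 1250) < 3 * sd

    def test_degenerate_roi_rejected(self):
        from shapely.geometry import Polygon
        line = Polygon([(0, 0), (10, 0), (10, 0)])
        with pytest.raises(ParameterError):
            simulate_csr(line, 10)


class TestClusteredChannels:
    def test_full_coloc_copies_centres(self, square_roi):
        p = ClusterSceneParams(roi=square_roi, n_clusters=10,
                               background_fraction=0.0, coloc_fraction=1.0,
                               seed=5)
        _, _, truth = simulate_clustered_channels(p)
        assert truth.shared_centre_b.all()
        # every B centre equals some A centre
        for c in truth.centres_b:
            assert np.min(np.linalg.norm(truth.centres_a - c, axis=1)) == 0.0

    def test_coloc_fraction_zero_overlap_matches_csr_oracle(self, square_roi):
        """B points near A centres should be no more common than chance."""
        p = ClusterSceneParams(roi=square_roi, n_clusters=20,
                               molecules_per_cluster=30, cluster_sd=25.0,
                               background_fraction=0.0, coloc_fraction=0.0,
                               seed=11)
        _, chb, truth = simulate_clustered_channels(p)
        r = p.cluster_sd
        d = np.sqrt(((chb.xy[:, None, :] - truth.centres_a[None, :, :]) ** 2
                     ).sum(-1)).min(axis=1)
        frac = np.mean(d <= r)
        # Monte-Carlo oracle: CSR points against the same centres
        rng = np.random.default_rng(0)
        mc = []
        for _ in range(40):
            pts = rng.uniform(0, 5000, (len(chb), 2))
            dd = np.sqrt(((pts[:, None, :] - truth.centres_a[None, :, :]) ** 2
                          ).sum(-1)).min(axis=1)
            mc.append(np.mean(dd <= r))
        # B is itself clustered, so allow generous Monte-Carlo spread
        assert frac < np.mean(mc) + 6 * np.std(mc) + 0.05

    def test_truth_labels_align_with_tables(self, clustered_scene):
        cha, chb, truth = clustered_scene
        assert len(truth.labels_a) == len(cha)
        assert len(truth.labels_b) == len(chb)
        assert np.all(cha.precision > 0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            simulate_clustered_channels(ClusterSceneParams(coloc_fraction=1.5))


class TestTracks:
    def test_brownian_ensemble_msd_closed_form(self):
        mix = MobilityMixture(components=[(1.0, 0.5, 1.0)], n_tracks=300,
                              track_length=30, dt=0.032, loc_noise=0.0, seed=3)
        ts, _ = simulate_tracks(mix)
        curves = [track_msd(t) for t in ts.tracks]
        ens = np.mean([c.msd for c in curves], axis=0)
        lags = curves[0].lags
        expected = 6 * 0.5 * lags
        np.testing.assert_allclose(ens[:5], expected[:5], rtol=0.12)

    def test_subdiffusive_loglog_slope(self):
        mix = MobilityMixture(components=[(1.0, 0.24, 0.7)], n_tracks=200,
                              track_length=30, dt=0.032, loc_noise=0.0, seed=4)
        ts, _ = simulate_tracks(mix)
        ens = np.mean([track_msd(t).msd for t in ts.tracks], axis=0)
        lags = track_msd(ts.tracks[0]).lags
        slope = np.polyfit(np.log(lags), np.log(ens), 1)[0]
        assert abs(slope - 0.7) < 0.07

    def test_component_assignment_fractions(self):
        mix = MobilityMixture(n_tracks=2000, seed=6)
        _, comp = simulate_tracks(mix)
        fr = np.bincount(comp, minlength=3) / 2000
        np.testing.assert_allclose(fr, [0.55, 0.43, 0.02], atol=0.04)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            MobilityMixture(components=[(1.0, 0.1, 2.5)]).validate()


class TestFRAP:
    def test_half_time_definition_noiseless(self):
        tr = simulate_frap(t_half=7.5, mobile_fraction=0.65, noise_sd=0.0,
                           dt=0.5, seed=0)
        post = tr.bleach_roi[tr.bleach_index:]
        t_post = tr.t[tr.bleach_index:] - tr.t[tr.bleach_index]
        # normalized signal at t_half equals mobile_fraction / 2
        norm = (post - 50.0) / 1000.0
        idx = np.argmin(np.abs(t_post - 7.5))
        assert abs(norm[idx] - 0.325) < 1e-9

    def test_full_recovery_plateau(self):
        tr = simulate_frap(t_half=1.0, mobile_fraction=1.0, duration=100.0,
                           noise_sd=0.0)
        norm = (tr.bleach_roi[-1] - 50.0) / 1000.0
        assert abs(norm - 1.0) < 1e-9

    def test_prebleach_plateau_is_one(self):
        tr = simulate_frap(noise_sd=0.0)
        norm = (tr.bleach_roi[:tr.bleach_index] - 50.0) / 1000.0
        np.testing.assert_allclose(norm, 1.0)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ParameterError):
            simulate_frap(dt=0.0)


class TestTitration:
    def test_stoichiometric_limit(self):
        c = simulate_titration(kd=1e-9, design=np.array([10.0]),
                               fixed_partner=0.05, f_free=1.0, f_bound=2.0)
        assert abs(c.signal[0] - 2.0) < 1e-6

    def test_half_saturation_at_kd_trace_partner(self):
        c = simulate_titration(kd=0.5, design=np.array([0.5]),
                               fixed_partner=1e-6, f_free=0.0, f_bound=1.0)
        assert abs(c.signal[0] - 0.5) < 1e-3

    def test_mst_design_shape(self):
        d = mst_dilution_series()
        assert len(d) == 16
        assert d[-1] == 10.0
        np.testing.assert_allclose(d[1:] / d[:-1], 2.0)

    def test_eq2_requires_baseline_terms(self):
        with pytest.raises(ParameterError):
            simulate_titration(kd=0.2, model="eq2")


class TestAFMScene:
    def test_straight_chain_end_to_end(self):
        hmap, truth = simulate_afm_scene(
            map_size=128, pixel_size=2.0, dna_length=115.0,
            persistence_length=1e9, noise_sd=0.0, seed=1)
        e2e = np.linalg.norm(truth.polyline[-1] - truth.polyline[0])
        assert abs(e2e - 115.0) / 115.0 < 0.02
        assert abs(truth.contour_length - 115.0) / 115.0 < 0.02

    def test_blob_ground_truth_position(self):
        _, truth = simulate_afm_scene(blob_positions=[0.10], noise_sd=0.0,
                                      seed=2)
        pct = 100.0 * min(truth.blob_positions[0], 1 - truth.blob_positions[0])
        assert pct == 10.0

    def test_max_height_equals_ridge_height_noiseless(self):
        hmap, _ = simulate_afm_scene(noise_sd=0.0, dna_height=2.0, seed=3)
        assert np.isclose(hmap.heights.max(), 2.0)

    def test_determinism(self):
        a, _ = simulate_afm_scene(seed=7)
        b, _ = simulate_afm_scene(seed=7)
        np.testing.assert_array_equal(a.heights, b.heights)
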