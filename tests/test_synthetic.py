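"""Generators: determinism, planted-statistics recovery, coupling, geometry truth."""

import numpy as np
import pandas as pd
import pytest

from isletca import synthetic as syn
from isletca.contacts import MaskPair, classify_mitochondria, find_contact_sites


def _spec(**kw):
    base = dict(n_cells=2, duration_s=120.0, seed=1)
    base.update(kw)
    return syn.TracePopulationSpec(**base)


class TestSimulateTraces:
    def test_shapes_and_determinism(self):
        spec = _spec(n_cells=3, duration_s=60)
        tr1, gt1 = syn.simulate_traces(spec)
        tr2, gt2 = syn.simulate_traces(_spec(n_cells=3, duration_s=60))
        assert tr1.shape == (3, 1200)
        np.testing.assert_array_equal(tr1, tr2)
        pd.testing.assert_frame_equal(gt1.events, gt2.events)

    def test_zero_amplitude_gives_baseline_plus_noise(self):
        spec = _spec(amplitude_snr=0.0, noise_sd=0.5, bleach_tau_s=200.0)
        traces, gt = syn.simulate_traces(spec)
        t = np.arange(traces.shape[1]) / spec.rate_hz
        expected = spec.baseline * np.exp(-t / 200.0)
        # traces deviate from the bleached baseline only by the noise
        assert np.abs(traces - expected).max() < 5 * 0.5
        assert len(gt.events) > 0
        assert (gt.events.amplitude == 0).all()

    def test_midtimes_strictly_increasing_per_cell(self):
        _, gt = syn.simulate_traces(_spec(n_cells=4, duration_s=300, seed=3))
        for _, grp in gt.events.groupby("cell_id"):
            assert (np.diff(grp.midtime_s.to_numpy()) > 0).all()

    def test_validation_errors_name_the_field(self):
        with pytest.raises(ValueError, match="n_cells"):
            _spec(n_cells=0)
        with pytest.raises(ValueError, match="duration_s"):
            _spec(duration_s=-1)
        with pytest.raises(ValueError, match="iei_dist"):
            _spec(iei_dist=(-5.0, 0.3))
        with pytest.raises(ValueError, match="shared_prob"):
            syn.Coupling(np.zeros((2, 2), bool), shared_prob=1.5)

    def test_planted_statistics_recover_distribution_medians(self):
        # noiseless, unbleached population: empirical medians of the planted
        # events match the log-normal medians within 5% at n >= 500
        spec = _spec(
            n_cells=20,
            duration_s=1000,
            noise_sd=0.0,
            halfwidth_dist=(3.0, 0.3),
            iei_dist=(15.0, 0.3),
            seed=11,
        )
        _, gt = syn.simulate_traces(spec)
        assert len(gt.events) >= 500
        assert np.median(gt.events.fwhm_s) == pytest.approx(3.0, rel=0.05)
        ieis = np.concatenate(
            [np.diff(np.sort(g.midtime_s.to_numpy())) for _, g in gt.events.groupby("cell_id")]
        )
        assert np.median(ieis) == pytest.approx(15.0, rel=0.05)


class TestCoupling:
    def test_full_coupling_zero_noise_correlates(self):
        adj = np.array([[0, 1], [1, 0]], bool)
        spec = _spec(
            n_cells=2, duration_s=300, noise_sd=0.0, coupling=syn.Coupling(adj, 1.0), seed=3
        )
        traces, _ = syn.simulate_traces(spec)
        assert np.corrcoef(traces)[0, 1] > 0.99

    def test_correlation_monotone_in_shared_probability(self):
        adj = np.array([[0, 1], [1, 0]], bool)
        corrs = []
        for p in (0.0, 0.5, 1.0):
            spec = _spec(
                n_cells=2,
                duration_s=600,
                noise_sd=1.0,
                coupling=syn.Coupling(adj, p),
                seed=5,
            )
            traces, _ = syn.simulate_traces(spec)
            corrs.append(np.corrcoef(traces)[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]

    def test_adjacency_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            syn.Coupling(np.array([[0, 1], [0, 0]], bool))
        with pytest.raises(ValueError, match="self-edges"):
            syn.Coupling(np.eye(2, dtype=bool))


class TestSimulateMovie:
    def test_two_cells_two_bright_components(self):
        spec = _spec(n_cells=2, duration_s=30, noise_sd=0.0)
        layout = syn.CellLayout((40, 40), [(10.0, 10.0), (28.0, 28.0)], [5.0, 5.0])
        movie, labels, _ = syn.simulate_movie(spec, layout)
        from scipy import ndimage

        mean_img = movie.stack.mean(axis=0)
        _, n = ndimage.label(mean_img > 1.0)
        assert n == 2
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_determinism(self):
        spec = _spec(n_cells=2, duration_s=20, noise_sd=1.0)
        layout = syn.disk_layout(2, (40, 40), seed=2)
        m1, l1, _ = syn.simulate_movie(spec, layout)
        m2, l2, _ = syn.simulate_movie(spec, layout)
        np.testing.assert_array_equal(m1.stack, m2.stack)
        np.testing.assert_array_equal(l1, l2)

    def test_extracted_trace_matches_planted_within_noise(self):
        spec = _spec(n_cells=1, duration_s=60, noise_sd=2.0, seed=4)
        layout = syn.CellLayout((32, 32), [(16.0, 16.0)], [6.0])
        movie, labels, gt = syn.simulate_movie(spec, layout)
        mask = labels == 1
        n_px = mask.sum()
        extracted = movie.stack[:, mask].mean(axis=1)
        events = [(r.midtime_s, r.fwhm_s, r.amplitude) for _, r in gt.events.iterrows()]
        planted = syn.make_trace(events, 60, 20, baseline=spec.baseline)
        tol = 6 * spec.noise_sd / np.sqrt(n_px)
        assert np.abs(extracted - planted).max() < tol

    def test_overlapping_cells_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            syn.CellLayout((40, 40), [(10.0, 10.0), (12.0, 12.0)], [5.0, 5.0])


class TestSimulateDoseResponse:
    def test_midpoint_at_ec50(self):
        tab = syn.simulate_dose_response(1.0, 3.0, 10.0, 2.0, [10.0])
        assert tab.response.iloc[0] == pytest.approx(2.0)

    def test_low_concentration_limit(self):
        tab = syn.simulate_dose_response(0.2, 1.2, 5.0, 1.0, [5.0 / 1e6])
        assert abs(tab.response.iloc[0] - 0.2) < 1e-4 * 1.0

    def test_seed_reproducibility(self):
        conc = [0.1, 1.0, 10.0]
        a = syn.simulate_dose_response(0, 1, 1.0, 1, conc, noise_sd=0.1, seed=9)
        b = syn.simulate_dose_response(0, 1, 1.0, 1, conc, noise_sd=0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.simulate_dose_response(0, 1, 1.0, 1, [0.0, 1.0])


class TestOrganelleMasks:
    def test_one_pixel_gap_is_a_contact_site(self):
        # 4x4 squares, 1 px gap at 5 nm/px: centre distance 10 nm (inclusive),
        # facing run 4 px = 20 nm -> one qualifying site
        spec = syn.MaskLayoutSpec(
            shape=(20, 20), mito=[syn.Rect(5, 5, 4, 4)], er=[syn.Rect(5, 10, 4, 4)]
        )
        _, _, truth = syn.simulate_organelle_masks(spec)
        row = truth.iloc[0]
        assert row.perimeter_px == 12
        assert row.contact_px == 4
        assert row.coupled

    def test_three_pixel_gap_no_contact(self):
        spec = syn.MaskLayoutSpec(
            shape=(20, 20), mito=[syn.Rect(5, 5, 4, 4)], er=[syn.Rect(5, 12, 4, 4)]
        )
        _, _, truth = syn.simulate_organelle_masks(spec)
        assert truth.contact_px.iloc[0] == 0
        assert not truth.coupled.iloc[0]

    def test_empty_er_all_uncoupled(self):
        spec = syn.MaskLayoutSpec(shape=(20, 20), mito=[syn.Rect(5, 5, 4, 4)], er=[])
        _, er_mask, truth = syn.simulate_organelle_masks(spec)
        assert not er_mask.any()
        assert not truth.coupled.any()

    def test_overlapping_rectangles_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            syn.MaskLayoutSpec(
                shape=(20, 20), mito=[syn.Rect(5, 5, 4, 4)], er=[syn.Rect(6, 6, 4, 4)]
            )

    def test_truth_table_matches_image_route(self):
        # analytic truth vs the image-based pipeline on one random layout
        layout = syn.random_mask_layout(n_mito=5, seed=2)
        mito, er, truth = syn.simulate_organelle_masks(layout)
        pair = MaskPair(mito, er, layout.nm_per_px)
        report = classify_mitochondria(pair, find_contact_sites(pair))
        assert report.per_mito.coupled.tolist() == truth.coupled.tolist()
        assert report.per_mito.contact_px.tolist() == truth.contact_px.tolist()
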