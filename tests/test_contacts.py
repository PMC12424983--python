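"""Contact-site rules, distance landscapes, and ER surface-to-volume."""

import numpy as np
import pandas as pd
import pytest

from isletca import contacts as ct
from isletca import synthetic as syn


def _pair_from_rects(mito_rects, er_rects, shape=(40, 40), nm=5.0):
    spec = syn.MaskLayoutSpec(shape=shape, nm_per_px=nm, mito=mito_rects, er=er_rects)
    mito, er, truth = syn.simulate_organelle_masks(spec)
    return ct.MaskPair(mito, er, nm), truth


class TestContactSites:
    def test_one_pixel_gap_single_site_of_four_pixels(self):
        pair, _ = _pair_from_rects([syn.Rect(5, 5, 4, 4)], [syn.Rect(5, 10, 4, 4)])
        sites = ct.find_contact_sites(pair)
        assert len(sites) == 1
        assert len(sites[0].pixels) == 4
        assert sites[0].length_nm == 20.0

    def test_three_pixel_gap_no_sites(self):
        pair, _ = _pair_from_rects([syn.Rect(5, 5, 4, 4)], [syn.Rect(5, 12, 4, 4)])
        assert ct.find_contact_sites(pair) == []

    def test_gap_exactly_ten_nm_counts(self):
        # 1 px edge gap at 5 nm/px: centre-to-centre distance 2 px = 10 nm,
        # the proximity criterion is inclusive
        pair, _ = _pair_from_rects([syn.Rect(5, 5, 4, 4)], [syn.Rect(5, 10, 4, 2)])
        assert len(ct.find_contact_sites(pair)) == 1

    def test_single_pixel_run_is_not_a_site(self):
        # an ER sliver 1 px tall faces exactly one perimeter pixel: 5 nm < 10 nm
        pair, _ = _pair_from_rects([syn.Rect(5, 5, 4, 4)], [syn.Rect(6, 10, 1, 3)])
        assert ct.find_contact_sites(pair) == []

    def test_empty_mito_mask_empty_list(self):
        pair = ct.MaskPair(np.zeros((10, 10), bool), np.zeros((10, 10), bool), 5.0)
        assert ct.find_contact_sites(pair) == []

    def test_masks_must_be_disjoint(self):
        m = np.zeros((10, 10), bool)
        m[2:4, 2:4] = True
        with pytest.raises(ValueError, match="disjoint"):
            ct.MaskPair(m, m, 5.0)


class TestClassification:
    def test_hand_counted_fraction(self):
        pair, _ = _pair_from_rects([syn.Rect(5, 5, 4, 4)], [syn.Rect(5, 10, 4, 4)])
        report = ct.classify_mitochondria(pair, ct.find_contact_sites(pair))
        row = report.per_mito.iloc[0]
        assert row.perimeter_px == 12
        assert row.contact_px == 4
        assert row.contact_fraction == pytest.approx(1 / 3)
        assert row.coupled

    def test_fraction_exactly_five_percent_uncoupled(self):
        # 11x11 square: perimeter 40 px; a 2 px ER run gives exactly 2/40 = 5%,
        # which is not strictly greater than 5%
        pair, truth = _pair_from_rects(
            [syn.Rect(10, 10, 11, 11)], [syn.Rect(14, 22, 2, 3)], shape=(40, 40)
        )
        report = ct.classify_mitochondria(pair, ct.find_contact_sites(pair))
        row = report.per_mito.iloc[0]
        assert row.perimeter_px == 40
        assert row.contact_px == 2
        assert row.contact_fraction == pytest.approx(0.05)
        assert not row.coupled
        assert not truth.coupled.iloc[0]

    def test_no_er_population_fraction_zero(self):
        pair, _ = _pair_from_rects([syn.Rect(5, 5, 4, 4), syn.Rect(20, 20, 5, 5)], [])
        report = ct.classify_mitochondria(pair, ct.find_contact_sites(pair))
        assert (report.per_mito.contact_fraction == 0).all()
        assert report.fraction_coupled == 0.0

    def test_population_fraction_is_mean_of_flags(self):
        layout = syn.random_mask_layout(n_mito=8, seed=5)
        mito, er, _ = syn.simulate_organelle_masks(layout)
        pair = ct.MaskPair(mito, er, layout.nm_per_px)
        report = ct.classify_mitochondria(pair, ct.find_contact_sites(pair))
        assert report.fraction_coupled == pytest.approx(report.per_mito.coupled.mean())

    def test_rotation_and_mirror_invariance(self):
        layout = syn.random_mask_layout(n_mito=6, seed=3)
        mito, er, _ = syn.simulate_organelle_masks(layout)

        def summary(m, e):
            pair = ct.MaskPair(m, e, layout.nm_per_px)
            rep = ct.classify_mitochondria(pair, ct.find_contact_sites(pair))
            return sorted(
                zip(rep.per_mito.perimeter_px, rep.per_mito.contact_px, rep.per_mito.coupled)
            )

        base = summary(mito, er)
        assert summary(np.rot90(mito), np.rot90(er)) == base
        assert summary(np.fliplr(mito), np.fliplr(er)) == base
        assert summary(np.flipud(mito), np.flipud(er)) == base

    def test_contact_fraction_monotone_in_gap(self):
        layout = syn.random_mask_layout(n_mito=6, seed=4)
        mito, er, _ = syn.simulate_organelle_masks(layout)
        pair = ct.MaskPair(mito, er, layout.nm_per_px)
        prev = None
        for gap in (5.0, 10.0, 15.0, 25.0):
            rep = ct.classify_mitochondria(pair, ct.find_contact_sites(pair, max_gap_nm=gap))
            frac = rep.per_mito.contact_fraction.to_numpy()
            if prev is not None:
                assert (frac >= prev - 1e-12).all()
            prev = frac


class TestDistanceProfile:
    def test_three_four_five_triangle(self):
        mito = np.zeros((30, 30), bool)
        mito[10, 10] = True
        er = np.zeros((30, 30), bool)
        er[13, 14] = True
        d, _, _ = ct.nearest_distance_profile(ct.MaskPair(mito, er, 5.0))
        np.testing.assert_allclose(d, [25.0])

    def test_planted_gaps_binned(self):
        # three mitochondria at edge gaps 1, 5 and 12 px (5 nm/px): nearest
        # centre distances 10, 30 and 65 nm -> bins [0,20), [20,50), [50,inf)
        rects = [syn.Rect(5, 5, 4, 4), syn.Rect(20, 5, 4, 4), syn.Rect(35, 5, 4, 4)]
        ers = [syn.Rect(5, 10, 4, 3), syn.Rect(20, 14, 4, 3), syn.Rect(35, 21, 4, 3)]
        pair, _ = _pair_from_rects(rects, ers, shape=(50, 50))
        d, counts, _ = ct.nearest_distance_profile(pair, bins_nm=(0, 20, 50, np.inf))
        np.testing.assert_allclose(sorted(d), [10.0, 30.0, 65.0])
        np.testing.assert_array_equal(counts, [1, 1, 1])

    def test_empty_er_censored(self):
        mito = np.zeros((10, 10), bool)
        mito[2:5, 2:5] = True
        d, counts, _ = ct.nearest_distance_profile(
            ct.MaskPair(mito, np.zeros((10, 10), bool), 5.0), bins_nm=(0, 50, np.inf)
        )
        assert np.isinf(d).all()
        assert counts[-1] == 1


class TestSurfaceToVolume:
    def test_single_voxel_cube(self):
        vol = np.zeros((3, 3, 3), bool)
        vol[1, 1, 1] = True
        df = ct.er_surface_to_volume(vol, 10.0)
        row = df.iloc[0]
        assert row.surface_nm2 == 600.0
        assert row.volume_nm3 == 1000.0
        assert row.sav_per_nm == pytest.approx(0.6)

    def test_two_voxel_bar(self):
        vol = np.zeros((3, 3, 4), bool)
        vol[1, 1, 1:3] = True
        row = ct.er_surface_to_volume(vol, 10.0).iloc[0]
        assert row.surface_nm2 == 1000.0
        assert row.volume_nm3 == 2000.0
        assert row.sav_per_nm == pytest.approx(0.5)

    def test_digitized_ball_marching_cubes(self):
        r = 20
        g = np.mgrid[0:2 * r + 9, 0:2 * r + 9, 0:2 * r + 9]
        c = r + 4
        ball = ((g[0] - c) ** 2 + (g[1] - c) ** 2 + (g[2] - c) ** 2) <= r**2
        row = ct.er_surface_to_volume(ball, 1.0, method="marching").iloc[0]
        assert row.sav_per_nm == pytest.approx(3.0 / r, rel=0.10)

    def test_anisotropic_voxels(self):
        vol = np.zeros((3, 3, 3), bool)
        vol[1, 1, 1] = True
        row = ct.er_surface_to_volume(vol, (10.0, 10.0, 20.0)).iloc[0]
        # faces: 2 of 10x10 plus 4 of 10x20
        assert row.surface_nm2 == 2 * 100 + 4 * 200
        assert row.volume_nm3 == 2000.0

    def test_empty_mask_empty_table(self):
        df = ct.er_surface_to_volume(np.zeros((4, 4, 4), bool), 10.0)
        assert isinstance(df, pd.DataFrame) and df.empty
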