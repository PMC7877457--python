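"""Measurement battery vs brute-force pixel-loop oracles, plus table rules."""

import numpy as np
import pandas as pd
import pytest
from skimage.morphology import disk

from conftest import random_region
from oracles import intensity_features_loop, shape_features_loop
from synaptomap.feature_extraction import (
    PAPER_FEATURE_COLUMNS,
    FeatureTable,
    build_feature_table,
    NormalizationError,
    intensity_features,
    normalize_to_untreated,
    relational_features,
    shape_features,
)
from synaptomap.synapse_assembly import Punctum, Synapse


def punctum(rows, cols, shape=(64, 64), target="Synapsin1", pid=1):
    return Punctum(pid, target, np.asarray(rows), np.asarray(cols), shape)


def punctum_from_mask(mask, pad=2, **kw):
    padded = np.pad(mask, pad)
    rr, cc = np.nonzero(padded)
    return Punctum(1, kw.get("target", "Synapsin1"), rr, cc, padded.shape)


class TestShapeOracle:
    def test_battery_matches_pixel_loop_oracle(self, rng):
        """Every shape feature agrees with an independent loop
        implementation to 1e-9 on a large batch of random regions."""
        n_checked = 0
        for _ in range(500):
            rows, cols = random_region(rng)
            got = shape_features(punctum(rows, cols))
            want = shape_features_loop(rows, cols)
            for name, expected in want.items():
                assert getattr(got, name) == pytest.approx(expected, abs=1e-9), name
                n_checked += 1
        assert n_checked >= 1000

    def test_line_geometry(self):
        line = np.zeros((1, 10), bool)
        line[:] = True
        sf = shape_features(punctum_from_mask(line))
        assert sf.extent == 1.0
        assert sf.euler_number == 1
        assert sf.minor_axis_length < sf.major_axis_length / 5
        assert 0 <= sf.eccentricity < 1

    def test_digital_disk(self):
        sf = shape_features(punctum_from_mask(disk(5).astype(bool)))
        assert sf.area == 81
        assert sf.solidity == 1.0
        assert sf.eccentricity <= 0.2
        assert sf.form_factor == pytest.approx(1.0, abs=0.15)
        assert sf.compactness == pytest.approx(1.0, abs=0.05)

    def test_hollow_square_has_euler_zero(self):
        sq = np.ones((3, 3), bool)
        sq[1, 1] = False
        assert shape_features(punctum_from_mask(sq)).euler_number == 0

    def test_form_factor_of_disks_approaches_one(self):
        errors = []
        for radius in (5, 10, 20):
            sf = shape_features(punctum_from_mask(disk(radius).astype(bool)))
            errors.append(abs(1.0 - sf.form_factor))
        assert errors[0] > errors[1] > errors[2]
        assert errors[0] < 0.15


class TestIntensityOracle:
    def test_battery_matches_pixel_loop_oracle(self, rng):
        image = rng.random((24, 24)) * 100
        for _ in range(500):
            rows, cols = random_region(rng, max_extent=8)
            got = intensity_features(rows, cols, image)
            want = intensity_features_loop(rows.tolist(), cols.tolist(), image)
            for name, expected in want.items():
                assert getattr(got, name) == pytest.approx(expected, abs=1e-9), name

    def test_uniform_region_degenerate_statistics(self):
        img = np.full((16, 16), 4.0)
        rows, cols = np.meshgrid(np.arange(3, 8), np.arange(3, 8), indexing="ij")
        f = intensity_features(rows.ravel(), cols.ravel(), img)
        assert f.mass_displacement == 0.0
        assert f.std_intensity == 0.0
        assert f.mad_intensity == 0.0

    def test_two_pixel_region_hand_computed(self):
        img = np.zeros((4, 4))
        img[1, 1], img[1, 2] = 1.0, 3.0
        f = intensity_features(np.array([1, 1]), np.array([1, 2]), img)
        assert f.integrated_intensity == 4.0
        assert f.mad_intensity == 1.0
        assert f.lower_quartile_intensity == pytest.approx(1.5)
        assert f.upper_quartile_intensity == pytest.approx(2.5)
        assert f.min_intensity == 1.0
        assert f.max_intensity == 3.0

    def test_corner_mass_displacement_closed_form(self):
        img = np.zeros((10, 10))
        img[2, 2] = 50.0  # all intensity in the region's corner pixel
        rows, cols = np.meshgrid(np.arange(2, 5), np.arange(2, 5), indexing="ij")
        f = intensity_features(rows.ravel(), cols.ravel(), img)
        assert f.mass_displacement == pytest.approx(np.hypot(1.0, 1.0))

    def test_integrated_intensity_additive_under_partition(self, rng):
        img = rng.random((20, 20)) * 10
        rows, cols = np.meshgrid(np.arange(4, 12), np.arange(5, 15), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        whole = intensity_features(rows, cols, img).integrated_intensity
        half = len(rows) // 2
        a = intensity_features(rows[:half], cols[:half], img).integrated_intensity
        b = intensity_features(rows[half:], cols[half:], img).integrated_intensity
        assert whole == pytest.approx(a + b, abs=1e-9)

    def test_region_outside_image_rejected(self):
        with pytest.raises(ValueError):
            intensity_features(np.array([5]), np.array([99]), np.zeros((10, 10)))


class TestRelationalFeatures:
    def _synapse(self, child_rows, child_cols, target="PSD95"):
        anchor = punctum(
            *np.meshgrid(np.arange(10, 16), np.arange(10, 16), indexing="ij")
        )
        anchor = Punctum(1, "Synapsin1", anchor.rows.ravel(), anchor.cols.ravel(),
                         (64, 64))
        syn = Synapse(anchor=anchor)
        syn.children[target] = [
            Punctum(1, target, np.asarray(child_rows), np.asarray(child_cols), (64, 64))
        ]
        return syn

    def test_coincident_centroids_zero_distance(self):
        rr, cc = np.meshgrid(np.arange(11, 15), np.arange(11, 15), indexing="ij")
        syn = self._synapse(rr.ravel(), cc.ravel())
        feats = relational_features(syn)
        assert feats["DistanceCentroid__PSD95__PSD95"] == pytest.approx(0.0)
        assert feats["DistanceMinimum__PSD95__PSD95"] == 0.0

    def test_three_four_five_distance(self):
        syn = self._synapse([15 + 4], [12 + 3])  # offset (4, 3) from (12.5, 12.5)?
        anchor_r, anchor_c = syn.anchor.centroid
        child_r, child_c = syn.children["PSD95"][0].centroid
        expected = np.hypot(child_r - anchor_r, child_c - anchor_c)
        feats = relational_features(syn)
        assert feats["DistanceCentroid__PSD95__PSD95"] == pytest.approx(expected)

    def test_absent_target_gives_zero_count_na_distance(self):
        syn = self._synapse([12], [12])
        feats = relational_features(syn)
        assert feats["PunctaNumber__Synapsin1__vGAT"] == 0.0
        assert np.isnan(feats["DistanceCentroid__vGAT__vGAT"])
        assert feats["PunctaNumber__Synapsin1__PSD95"] == 1.0


class TestFeatureTable:
    def test_paper_mode_column_count_matches_published_list(self):
        assert len(PAPER_FEATURE_COLUMNS) == 107
        assert len(set(PAPER_FEATURE_COLUMNS)) == 107

    def test_all_na_columns_dropped_and_recorded(self):
        rows = [
            {"replicate": 0, "treatment": "untreated",
             "A__Synapsin1__X": 1.0, "B__Y__Y": np.nan},
            {"replicate": 1, "treatment": "untreated",
             "A__Synapsin1__X": 2.0, "B__Y__Y": np.nan},
        ]
        table = build_feature_table(rows, mode="full")
        assert "B__Y__Y" not in table.data.columns
        assert table.dropped_columns == ("B__Y__Y",)

    def test_duplicate_columns_rejected(self):
        df = pd.DataFrame([[1, 2]], columns=["A__S__T", "A__S__T"])
        with pytest.raises(ValueError):
            build_feature_table(df, mode="full")

    def test_zero_synapses_gives_full_header(self):
        table = build_feature_table(pd.DataFrame(), mode="paper")
        assert list(table.data.columns[-107:]) == list(PAPER_FEATURE_COLUMNS)
        assert len(table.data) == 0


class TestNormalization:
    def _table(self):
        return build_feature_table(
            [
                {"replicate": 0, "treatment": "untreated", "class": "excitatory",
                 "IntegratedIntensity__Synapsin1__vGlut1": 10.0,
                 "DistanceCentroid__PSD95__PSD95": 3.0},
                {"replicate": 1, "treatment": "untreated", "class": "excitatory",
                 "IntegratedIntensity__Synapsin1__vGlut1": 30.0,
                 "DistanceCentroid__PSD95__PSD95": 5.0},
                {"replicate": 6, "treatment": "treated", "class": "excitatory",
                 "IntegratedIntensity__Synapsin1__vGlut1": 40.0,
                 "DistanceCentroid__PSD95__PSD95": 4.0},
            ],
            mode="full",
        )

    def test_untreated_mean_becomes_one_and_distances_untouched(self):
        out = normalize_to_untreated(self._table())
        col = "IntegratedIntensity__Synapsin1__vGlut1"
        ut = out.data[out.data["treatment"] == "untreated"]
        assert ut[col].mean() == pytest.approx(1.0)
        assert out.data[col].iloc[2] == pytest.approx(2.0)  # 40 / 20
        assert list(out.data["DistanceCentroid__PSD95__PSD95"]) == [3.0, 5.0, 4.0]

    def test_idempotent(self):
        once = normalize_to_untreated(self._table())
        twice = normalize_to_untreated(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_zero_untreated_mean_is_an_error_naming_the_column(self):
        table = self._table()
        table.data.loc[
            table.data["treatment"] == "untreated",
            "IntegratedIntensity__Synapsin1__vGlut1",
        ] = 0.0
        with pytest.raises(NormalizationError, match="vGlut1"):
            normalize_to_untreated(table)
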