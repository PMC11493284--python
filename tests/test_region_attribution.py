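"""Affine coordinate transport, relative frequencies, selection and tallies."""

import numpy as np
import pandas as pd
import pytest

from nativecam.attribution import AttentionMask
from nativecam.io_core import LabelVolume, RegionInfo
from nativecam.model import PredictionRecord
from nativecam.region_attribution import (RFTable, RegionSet, aggregate_rf,
                                          background_audit,
                                          hemisphere_breakdown,
                                          map_voxel_coordinates,
                                          relative_frequencies,
                                          select_top_regions, stratify,
                                          tally_consistency)


class TestMapCoordinates:
    def test_identity_mapping(self, toy_labels):
        coords = np.array([[1, 1, 1], [4, 4, 4]])
        out = map_voxel_coordinates(np.eye(4), toy_labels, coords)
        np.testing.assert_array_equal(out, toy_labels.labels[1, 1, 1:2].tolist()
                                      + toy_labels.labels[4, 4, 4:5].tolist())

    def test_affine_inverse_round_trip(self, rng):
        """B.A = I within 1e-9 for random invertible affines."""
        for _ in range(100):
            a = np.eye(4)
            a[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            a[:3, 3] = rng.normal(size=3) * 10
            b = np.linalg.inv(a)
            np.testing.assert_allclose(b @ a, np.eye(4), atol=1e-9)

    def test_spacing_ratio_mapping(self):
        """Aligned 1.5 mm grid onto a 1 mm grid: index 10 maps to 15."""
        labels = np.arange(32**3, dtype=np.int64).reshape(32, 32, 32) % 2
        src = LabelVolume(labels.astype(np.int32), np.eye(4), {1: RegionInfo("a")})
        target_affine = np.diag([1.5, 1.5, 1.5, 1.0])
        out = map_voxel_coordinates(target_affine, src, np.array([[10, 10, 10]]))
        assert out[0] == labels[15, 15, 15]

    def test_out_of_bounds_background(self, toy_labels):
        out = map_voxel_coordinates(np.eye(4), toy_labels, np.array([[99, 0, 0]]))
        assert out[0] == 0


def _mask(arr, affine=None):
    return AttentionMask(np.asarray(arr, dtype=np.uint8),
                         np.eye(4) if affine is None else affine, 0.5)


class TestRelativeFrequencies:
    def test_full_coverage_rf_one(self, toy_labels):
        t = relative_frequencies(_mask(np.ones((6, 6, 6))), toy_labels)
        assert t.rf_of(1) == 1.0 and t.rf_of(2) == 1.0

    def test_partial_coverage_counted(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[0, 0, :] = 1  # region of 5 voxels... make it 10
        labels[0, 1, :] = 1  # now 10 voxels
        lv = LabelVolume(labels, np.eye(4), {1: RegionInfo("a")})
        mask = np.zeros((5, 5, 5))
        mask[0, 0, :3] = 1  # 3 of the 10
        t = relative_frequencies(_mask(mask), lv)
        assert t.rf_of(1) == pytest.approx(0.3)

    def test_conservation_over_random_pairs(self, rng):
        """Sum of per-region important counts equals the total mask size."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 5, size=(7, 7, 7)).astype(np.int32)
            table = {i: RegionInfo(f"r{i}") for i in range(1, 5)}
            lv = LabelVolume(labels, np.eye(4), table)
            mask = r.integers(0, 2, size=(7, 7, 7))
            t = relative_frequencies(_mask(mask), lv)
            assert t.table["n_voxels_important"].sum() == mask.sum()
            assert ((t.table["rf"] >= 0) & (t.table["rf"] <= 1)).all()

    def test_grid_mismatch_rejected(self, toy_labels):
        with pytest.raises(ValueError, match="mismatch"):
            relative_frequencies(_mask(np.ones((4, 4, 4))), toy_labels)

    def test_rf_monotone_under_mask_growth(self, rng, toy_labels):
        base = rng.integers(0, 2, size=(6, 6, 6))
        grown = np.clip(base + (rng.random((6, 6, 6)) > 0.7), 0, 1)
        t0 = relative_frequencies(_mask(base), toy_labels)
        t1 = relative_frequencies(_mask(grown), toy_labels)
        for rid in (0, 1, 2):
            assert t1.rf_of(rid) >= t0.rf_of(rid)


def _rf_table(rfs, scope="g"):
    rows = [{"region_id": i, "region_name": f"r{i}", "hemisphere": "none",
             "n_voxels_region": 10, "n_voxels_important": int(10 * rf), "rf": rf}
            for i, rf in enumerate(rfs)]
    return RFTable(pd.DataFrame(rows), scope=scope)


class TestAggregate:
    def test_single_table_identity(self):
        t = _rf_table([0.0, 0.5, 1.0])
        agg = aggregate_rf([t])
        np.testing.assert_allclose(agg.table["rf"], [0.0, 0.5, 1.0])

    def test_mean_of_two(self):
        agg = aggregate_rf([_rf_table([0.0, 0.2]), _rf_table([0.0, 0.4])])
        assert agg.table.set_index("region_id").loc[1, "rf"] == pytest.approx(0.3)

    def test_missing_region_counts_as_zero(self):
        a = _rf_table([0.0, 0.6])
        b = RFTable(a.table[a.table["region_id"] == 0].copy(), scope="b")
        agg = aggregate_rf([a, b])
        assert agg.table.set_index("region_id").loc[1, "rf"] == pytest.approx(0.3)

    def test_order_invariant(self, rng):
        tables = [_rf_table(rng.random(4)) for _ in range(5)]
        f = aggregate_rf(tables).table["rf"].to_numpy()
        b = aggregate_rf(tables[::-1]).table["rf"].to_numpy()
        np.testing.assert_allclose(f, b)


class TestSelect:
    def test_160_distinct_values_give_16(self, rng):
        rfs = rng.permutation(np.linspace(0.001, 0.999, 160))
        top = select_top_regions(_rf_table(rfs), 90)
        assert len(top.members) == 16

    def test_ramp_of_ten(self):
        top = select_top_regions(_rf_table([0.1, 0.2, 0.3, 0.4, 0.5,
                                            0.6, 0.7, 0.8, 0.9, 1.0]), 90)
        assert top.members == {9}  # only the 1.0 row exceeds P90 = 0.91
        assert top.threshold == pytest.approx(0.91)

    def test_constant_rf_empty(self):
        top = select_top_regions(_rf_table([0.4] * 12), 90)
        assert top.members == frozenset()

    def test_decile_count_property(self, rng):
        for n in (20, 50, 100):
            rfs = rng.permutation(np.arange(1, n + 1) / (n + 1))
            top = select_top_regions(_rf_table(rfs), 90)
            assert len(top.members) == n // 10

    def test_background_excludable(self):
        rfs = [0.99, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.85]  # region 0 = background
        with_bg = select_top_regions(_rf_table(rfs), 90, include_background=True)
        without = select_top_regions(_rf_table(rfs), 90, include_background=False)
        assert 0 in with_bg.members
        assert 0 not in without.members


def _pred(i, outcome, gender="male", age=12.0):
    predicted = 1 if outcome in ("TP", "FP") else 0
    true = 1 if outcome in ("TP", "FN") else 0
    return PredictionRecord(id=f"s{i}", probability=0.8 if predicted else 0.2,
                            predicted=predicted, true_label=true,
                            gender=gender, age=age)


class TestStratify:
    def test_outcome_partition(self):
        preds = [_pred(0, "TP"), _pred(1, "TN"), _pred(2, "FP"), _pred(3, "FN")]
        cells = stratify(preds, "outcome")
        assert set(cells) == {"TP", "TN", "FP", "FN"}

    def test_age_boundary(self):
        cells = stratify([_pred(0, "TP", age=10.0)], "age")
        assert list(cells) == ["10-15"]

    def test_under_five_flagged(self):
        cells = stratify([_pred(0, "TP", age=2.0)], "age")
        assert list(cells) == ["under-5"]

    def test_crossed_scheme_partitions(self):
        preds = [_pred(i, "TP", gender=g, age=a)
                 for i, (g, a) in enumerate([("male", 6), ("female", 6),
                                             ("male", 12), ("male", 30)])]
        cells = stratify(preds, "outcome,gender,age")
        assert sum(len(v) for v in cells.values()) == len(preds)
        assert "TP/male/5-10" in cells


class TestConsistency:
    def test_counts_across_datasets(self):
        sets = [RegionSet(frozenset({1, 2}), "m", d) for d in
                ("train", "validation", "test", "test2")]
        sets.append(RegionSet(frozenset({2}), "m2", "train"))
        sets.append(RegionSet(frozenset({2}), "m2", "validation"))
        ct = tally_consistency(sets)
        s = ct.summary.set_index(["region_id", "model"])
        assert s.loc[(1, "m"), "n_present"] == 4
        assert s.loc[(1, "m2"), "n_present"] == 0
        assert s.loc[(2, "m2"), "n_present"] == 2

    def test_everywhere_region_in_all_models(self):
        sets = [RegionSet(frozenset({5, m * 10 + d}), f"m{m}", f"d{d}")
                for m in range(3) for d in range(4)]
        ct = tally_consistency(sets)
        always = ct.summary[ct.summary["in_all_models"]]["region_id"].unique()
        assert list(always) == [5]

    def test_hemisphere_breakdown(self):
        table = {1: RegionInfo("a", "left"), 2: RegionInfo("b", "right"),
                 3: RegionInfo("c", "bilateral")}
        counts = hemisphere_breakdown([1, 2, 3], table)
        assert counts == {"left": 1, "right": 1, "bilateral": 1, "none": 0}


class TestBackgroundAudit:
    def test_mask_inside_brain_background_last(self, toy_labels):
        mask = (toy_labels.labels > 0).astype(np.uint8)
        t = relative_frequencies(_mask(mask), toy_labels)
        report = background_audit({"all": t})
        assert report.iloc[0]["background_rf"] == 0.0
        assert report.iloc[0]["rank"] == report.iloc[0]["n_regions"]

    def test_constructed_background_fraction(self, toy_labels):
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        bg = np.argwhere(toy_labels.labels == 0)
        n = len(bg)
        take = bg[: max(1, n // 100)]
        mask[tuple(take.T)] = 1
        t = relative_frequencies(_mask(mask), toy_labels)
        assert t.rf_of(0) == pytest.approx(len(take) / n)

    def test_rank_matches_independent_sort(self, rng, toy_labels):
        mask = rng.integers(0, 2, size=(6, 6, 6))
        t = relative_frequencies(_mask(mask), toy_labels)
        report = background_audit({"x": t})
        df = t.table.sort_values(["rf", "region_id"], ascending=[False, True])
        expected = list(df["region_id"]).index(0) + 1
        assert report.iloc[0]["rank"] == expected
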