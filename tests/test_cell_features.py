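import copy

import numpy as np
import pandas as pd
import pytest

from conftest import disk_mask
from ifishquant import cell_features as cf
from ifishquant import io_background as iob
from ifishquant import membrane_seg as ms
from ifishquant import spot_detect as sd


def three_cell_setup():
    nuclei = np.zeros((60, 180), np.int32)
    centers = [(30, 30), (30, 90), (30, 150)]
    for lab, c in enumerate(centers, 1):
        nuclei[disk_mask((60, 180), c, 12)] = lab
    mem = ms.membrane_segment(np.zeros((60, 180)), nuclei)
    spots = []
    for lab, (r, c) in enumerate(centers, 1):
        for dc in (-4, 4):
            spots.append(
                sd.Spot(
                    label=len(spots) + 1,
                    area=20.0,
                    centroid=(r, c + dc),
                    mean_intensity=0.9,
                    min_intensity=0.5,
                    features=np.zeros(12),
                    nucleus=lab,
                )
            )
    return nuclei, mem, spots


class TestMapSegments:
    def test_three_cells_two_spots_each(self):
        nuclei, mem, spots = three_cell_setup()
        records = cf.map_segments(nuclei, mem, spots, spot_channel="FISH")
        assert len(records) == 3
        for rec in records:
            assert rec.spot_area["FISH"] == 40.0
            assert rec.copies["FISH"] == 2
            assert rec.membrane_label == rec.nucleus_label

    def test_membrane_containing_two_nuclei_raises(self):
        nuclei = np.zeros((40, 80), np.int32)
        nuclei[disk_mask((40, 80), (20, 20), 8)] = 1
        nuclei[disk_mask((40, 80), (20, 60), 8)] = 2
        labels = np.ones((40, 80), np.int32)  # one membrane over both
        mem = ms.MembraneMap(labels=labels, owner={1: 1})
        with pytest.raises(cf.MappingError, match=r"\[1, 2\]"):
            cf.map_segments(nuclei, mem)

    def test_no_spots_copy_number_zero(self):
        nuclei, mem, _ = three_cell_setup()
        records = cf.map_segments(nuclei, mem, [], spot_channel="FISH")
        assert all(r.copies["FISH"] == 0 for r in records)


class TestMeasureCells:
    def test_constant_channel_zero_background(self):
        nuclei, mem, _ = three_cell_setup()
        stack = iob.ImageStack(
            channels=[np.full((60, 180), 0.3), np.full((60, 180), 7.0)],
            stains=["DAPI", "nuclear"],
            magnification=60,
            names=["DAPI", "ER"],
        )
        bgs = {"ER": iob.BackgroundEstimate(global_mean=0.0)}
        records = cf.map_segments(nuclei, mem)
        records = cf.measure_cells(
            records, stack, bgs, nuclei=nuclei, membranes=mem
        )
        for rec in records:
            assert rec.raw["ER"] == pytest.approx(7.0)
            assert rec.global_adj["ER"] == pytest.approx(7.0)
            assert rec.area == pytest.approx(np.pi * 12**2, rel=0.05)

    def test_planted_two_class_intensities_recovered(self, measured_records):
        records, truth, *_ = measured_records
        # ER (ring-adjusted) must recover the planted contrast per class
        levels = {"tumor": 0.5, "stroma": 0.15}
        for cls, planted in levels.items():
            vals = [
                r.ring_adj["ER"]
                for r in records
                if truth[r.nucleus_label] == cls
            ]
            assert np.mean(vals) == pytest.approx(planted, rel=0.02)

    def test_membrane_cov_separates_complete_from_broken(self):
        from ifishquant import synth

        covs = {}
        for completeness in (1.0, 0.5):
            spec = synth.SceneSpec(
                n_cells=10,
                height=350,
                width=350,
                seed=31,
                membrane_completeness=completeness,
                spots_per_cell=0,
            )
            stack, nuclei, *_ = synth.generate_scene(spec)
            mem = ms.membrane_segment(stack.channel("HER2"), nuclei)
            records = cf.map_segments(nuclei, mem)
            records = cf.measure_cells(
                records, stack, {}, nuclei=nuclei, membranes=mem
            )
            covs[completeness] = np.mean(
                [r.membrane_cov["HER2"] for r in records]
            )
        # broken rings vary more along the band than complete rings
        assert covs[0.5] > covs[1.0]


class TestEditLabels:
    def test_glue_conserves_area(self):
        nuclei, *_ = three_cell_setup()
        a1 = (nuclei == 1).sum() + (nuclei == 2).sum()
        out = cf.edit_labels(nuclei, [dict(op="glue", a=1, b=2)])
        assert (out == 1).sum() == a1
        assert not (out == 2).any()

    def test_cut_disk_along_diameter(self):
        labels = disk_mask((50, 50), (25, 25), 15).astype(np.int32)
        total = labels.sum()
        out = cf.edit_labels(
            labels, [dict(op="cut", label=1, path=[[0, 25], [49, 25]])]
        )
        areas = sorted(
            int((out == lab).sum()) for lab in np.unique(out) if lab > 0
        )
        assert len(areas) == 2
        assert sum(areas) == total  # conservation incl. the cut line
        assert abs(areas[0] - areas[1]) <= 31  # one column of the diameter

    def test_trash_removes_only_target(self):
        nuclei, *_ = three_cell_setup()
        out = cf.edit_labels(nuclei, [dict(op="trash", label=2)])
        assert not (out == 2).any()
        np.testing.assert_array_equal(out == 1, nuclei == 1)
        np.testing.assert_array_equal(out == 3, nuclei == 3)

    def test_cut_not_crossing_warns_noop(self):
        labels = disk_mask((50, 50), (25, 25), 10).astype(np.int32)
        with pytest.warns(UserWarning, match="does not split"):
            out = cf.edit_labels(
                labels, [dict(op="cut", label=1, path=[[0, 0], [0, 49]])]
            )
        np.testing.assert_array_equal(out, labels)

    def test_glue_missing_label_raises(self):
        labels = disk_mask((30, 30), (15, 15), 8).astype(np.int32)
        with pytest.raises(cf.MappingError, match="missing label 9"):
            cf.edit_labels(labels, [dict(op="glue", a=1, b=9)])

    def test_paint_and_erase(self):
        labels = np.zeros((40, 40), np.int32)
        square = [[5, 5], [5, 15], [15, 15], [15, 5]]
        out = cf.edit_labels(labels, [dict(op="paint", polygon=square)])
        assert out.max() == 1
        assert (out == 1).sum() > 50
        out2 = cf.edit_labels(out, [dict(op="erase", polygon=square)])
        assert not out2.any()


class TestClassifyCells:
    def test_separable_classes_high_accuracy(self, measured_records):
        records, truth, *_ = measured_records
        recs = copy.deepcopy(records)
        by_class: dict[str, list[int]] = {}
        for r in recs:
            by_class.setdefault(truth[r.nucleus_label], []).append(r.cell_id)
        training = {
            cid: cls for cls, ids in by_class.items() for cid in ids[:5]
        }
        recs = cf.classify_cells(recs, training)
        test = [r for r in recs if r.cell_id not in training]
        acc = np.mean([r.cell_class == truth[r.nucleus_label] for r in test])
        assert acc >= 0.95

    def test_minimal_training_one_per_class(self, measured_records):
        records, truth, *_ = measured_records
        recs = copy.deepcopy(records)
        seen: dict[str, int] = {}
        for r in recs:
            cls = truth[r.nucleus_label]
            if cls not in seen:
                seen[cls] = r.cell_id
        recs = cf.classify_cells(recs, {cid: c for c, cid in seen.items()})
        assert all(r.cell_class is not None for r in recs)

    def test_permuted_labels_chance_level(self, measured_records):
        records, truth, *_ = measured_records
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(5):
            recs = copy.deepcopy(records)
            ids = [r.cell_id for r in recs][:10]
            shuffled = rng.permutation(
                [truth[r.nucleus_label] for r in recs[:10]]
            )
            training = dict(zip(ids, shuffled))
            if len(set(training.values())) < 2:
                continue
            recs = cf.classify_cells(recs, training)
            test = [r for r in recs if r.cell_id not in training]
            accs.append(
                np.mean([r.cell_class == truth[r.nucleus_label] for r in test])
            )
        assert np.mean(accs) < 0.85  # far from the separable-data score

    def test_invariant_to_record_order_and_duplication(self, measured_records):
        records, truth, *_ = measured_records
        by_class: dict[str, list[int]] = {}
        for r in records:
            by_class.setdefault(truth[r.nucleus_label], []).append(r.cell_id)
        training = {
            cid: cls for cls, ids in by_class.items() for cid in ids[:3]
        }
        a = cf.classify_cells(copy.deepcopy(records), training)
        shuffled = copy.deepcopy(records)[::-1]
        b = cf.classify_cells(shuffled, training)
        got_a = {r.cell_id: r.cell_class for r in a}
        got_b = {r.cell_id: r.cell_class for r in b}
        assert got_a == got_b

    def test_single_class_rejected(self, measured_records):
        records, *_ = measured_records
        with pytest.raises(ValueError, match="2 classes"):
            cf.classify_cells(
                copy.deepcopy(records), {records[0].cell_id: "only"}
            )

    def test_more_than_four_classes_rejected(self, measured_records):
        records, *_ = measured_records
        training = {
            records[i].cell_id: f"class{i}" for i in range(5)
        }
        with pytest.raises(ValueError, match="more than 4"):
            cf.classify_cells(copy.deepcopy(records), training)


class TestApplyThresholds:
    def make_record(self, er, her2):
        rec = cf.CellRecord(cell_id=1, nucleus_label=1)
        rec.ring_adj["ER"] = er
        rec.global_adj["HER2"] = her2
        return rec

    RULES = [
        cf.ThresholdRule("ER", 50.0, "ring"),
        cf.ThresholdRule("HER2", 300.0, "global"),
    ]

    def test_double_positive(self):
        out = cf.apply_thresholds([self.make_record(60, 350)], self.RULES)
        assert out.loc[0, "category"] == "ER+/HER2+"

    def test_double_negative(self):
        out = cf.apply_thresholds([self.make_record(0, 0)], self.RULES)
        assert out.loc[0, "category"] == "ER-/HER2-"

    def test_boundary_value_is_positive(self):
        out = cf.apply_thresholds([self.make_record(50, 299.9)], self.RULES)
        assert out.loc[0, "category"] == "ER+/HER2-"

    def test_absent_stain_rejected(self):
        rec = cf.CellRecord(cell_id=1, nucleus_label=1)
        with pytest.raises(KeyError):
            cf.apply_thresholds([rec], [cf.ThresholdRule("KI67", 10.0, "raw")])


class TestTopologyMap:
    def make_record(self, cid, a, b, centroid=(5.0, 5.0)):
        rec = cf.CellRecord(cell_id=cid, nucleus_label=cid, centroid=centroid)
        rec.global_adj["A"] = a
        rec.global_adj["B"] = b
        return rec

    def test_balanced_and_pure_ratios(self):
        labels = np.zeros((10, 30), np.int32)
        labels[:, :10], labels[:, 10:20], labels[:, 20:] = 1, 2, 3
        records = [
            self.make_record(1, 5.0, 5.0),
            self.make_record(2, 7.0, 0.0),
            self.make_record(3, 0.0, 0.0),
        ]
        table, rgb = cf.topology_map(records, "A", "B", labels)
        assert table.ratio.iloc[0] == 0.5
        assert table.ratio.iloc[1] == 1.0
        assert np.isnan(table.ratio.iloc[2])
        # undefined ratio renders neutral grey
        assert np.allclose(rgb[5, 25], 0.5)

    def test_planted_gradient_monotone_ratio(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        labels = np.arange(1, 21).repeat(5)[None, :].repeat(4, axis=0)
        records = []
        for cid in range(1, 21):
            a = cid / 20 + rng.normal(0, 0.001)
            records.append(
                self.make_record(cid, a, 1.0, centroid=(2.0, cid * 5 - 2.5))
            )
        table, _ = cf.topology_map(records, "A", "B", labels)
        rho = spearmanr(table.col, table.ratio).statistic
        assert rho >= 0.99


class TestCsvRoundTrip:
    def test_records_round_trip_exactly(self, tmp_path, measured_records):
        records, *_ = measured_records
        frame = cf.records_to_frame(records)
        path = tmp_path / "cells.csv"
        frame.to_csv(path, index=False)
        back = cf.read_cells_csv(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.cell_id == b.cell_id
            assert a.raw == b.raw
            assert a.ring_adj == b.ring_adj
            assert a.copies == b.copies
            assert a.centroid == b.centroid
            assert a.cell_class == b.cell_class
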