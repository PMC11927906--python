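"""Fold planning, cross-validation hygiene, and the ensemble well verdict."""

import numpy as np
import pytest

from platescreen import (
    ClassifierConfig, CropDataset, FoldPlan, ensemble_well_verdict, percent_ctl,
    plan_leave_plates_out, run_cv, well_verdict_multiclass,
)
from platescreen.ensemble import crop_ensemble_verdicts, dose_response_table


class TestFoldPlan:
    def test_seven_plates_four_groups_sizes(self):
        plan = plan_leave_plates_out([f"P{i}" for i in range(7)], 4, seed=0)
        assert sorted(len(g) for g in plan.groups) == [1, 2, 2, 2]
        assert plan.plate_ids == {f"P{i}" for i in range(7)}

    def test_validation_crop_counts_per_group(self):
        # 450 crops/plate: 2-plate groups hold 900 validation images, the
        # 1-plate group 450
        plan = plan_leave_plates_out([f"P{i}" for i in range(7)], 4, seed=1)
        counts = sorted(450 * len(g) for g in plan.groups)
        assert counts == [450, 900, 900, 900]

    def test_equal_groups_is_leave_one_plate_out(self):
        plan = plan_leave_plates_out(["A", "B", "C"], 3, seed=5)
        assert all(len(g) == 1 for g in plan.groups)

    def test_more_groups_than_plates_rejected(self):
        with pytest.raises(ValueError):
            plan_leave_plates_out(["A", "B"], 3)

    def test_plate_in_two_groups_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan(groups=(("A", "B"), ("B",)))

    def test_seeded_shuffle_is_reproducible(self):
        ids = [f"P{i}" for i in range(7)]
        assert plan_leave_plates_out(ids, 4, seed=3) == plan_leave_plates_out(ids, 4, seed=3)


def _toy_dataset(n_plates=4, wells=2, crops=5, n_classes=2, seed=0):
    """Feature-space dataset with a severity-linked mean shift per class."""
    rng = np.random.default_rng(seed)
    X, y, pids, wids, cids = [], [], [], [], []
    for p in range(n_plates):
        for c in range(n_classes):
            for w in range(wells):
                for k in range(crops):
                    X.append(rng.normal(c * 1.5, 1.0, size=22))
                    y.append(c)
                    pids.append(f"P{p}")
                    wids.append(f"C{c}W{w}")
                    cids.append(k)
    return CropDataset(X=np.vstack(X), class_index=np.array(y),
                       plate_ids=np.array(pids), well_ids=np.array(wids),
                       crop_index=np.array(cids))


class TestRunCV:
    def test_one_model_per_group_and_disjoint_validation(self):
        ds = _toy_dataset()
        plan = plan_leave_plates_out([f"P{i}" for i in range(4)], 4, seed=0)
        folds = run_cv(ds, plan, ClassifierConfig(n_classes=2, epochs=3))
        assert len(folds) == 4
        assert sum(f.n_validation for f in folds) == len(ds)
        seen = [p for f in folds for p in f.validation_plates]
        assert sorted(seen) == [f"P{i}" for i in range(4)]

    def test_no_plate_leaks_between_train_and_validation(self):
        ds = _toy_dataset()
        plan = plan_leave_plates_out([f"P{i}" for i in range(4)], 2, seed=1)
        for group in plan.groups:
            train_plates = set(ds.plate_ids[~np.isin(ds.plate_ids, list(group))])
            assert train_plates.isdisjoint(group)

    def test_augmented_crops_never_validate(self):
        ds = _toy_dataset()
        aug = ds.augmented.copy()
        aug[::3] = True
        ds.augmented = aug
        plan = plan_leave_plates_out([f"P{i}" for i in range(4)], 4, seed=0)
        folds = run_cv(ds, plan, ClassifierConfig(n_classes=2, epochs=2))
        expected = [int(((np.isin(ds.plate_ids, g)) & ~aug).sum()) for g in plan.groups]
        assert [f.n_validation for f in folds] == expected

    def test_missing_class_in_training_split_is_diagnosed(self):
        ds = _toy_dataset(n_plates=2)
        ds.class_index[ds.plate_ids == "P0"] = 0  # P0 now single-class
        plan = FoldPlan(groups=(("P1",), ("P0",)))
        with pytest.raises(ValueError, match="missing"):
            run_cv(ds, plan, ClassifierConfig(n_classes=2, epochs=2))


class TestWellVerdict:
    def test_unanimous_control(self):
        v = ensemble_well_verdict(np.ones((15, 4), dtype=int))
        assert v.mean_score == 1.0
        assert v.predicted == "CTL"

    def test_29_of_60_is_lps(self):
        R = np.zeros((15, 4), dtype=int)
        R.ravel()[:29] = 1
        v = ensemble_well_verdict(R)
        assert v.mean_score == pytest.approx(29 / 60)
        assert v.predicted == "LPS"

    def test_exact_tie_rounds_up_to_control(self):
        R = np.zeros((15, 4), dtype=int)
        R.ravel()[:30] = 1
        v = ensemble_well_verdict(R)
        assert v.mean_score == 0.5
        assert v.predicted == "CTL"

    def test_verdict_symmetric_in_crop_and_model_order(self):
        rng = np.random.default_rng(0)
        R = rng.integers(0, 2, (15, 4))
        v = ensemble_well_verdict(R)
        assert ensemble_well_verdict(R[::-1]).mean_score == v.mean_score
        assert ensemble_well_verdict(R[:, ::-1]).predicted == v.predicted

    def test_denominator_is_crops_times_models(self):
        R = np.zeros((15, 4), dtype=int)
        R[0, 0] = 1
        assert ensemble_well_verdict(R).mean_score == pytest.approx(1 / 60)

    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError):
            ensemble_well_verdict(np.full((15, 4), 0.5))


class TestMulticlassVerdict:
    @pytest.mark.parametrize("k", range(6))
    def test_unanimity_under_both_rules(self, k):
        labels = [k] * 15
        assert well_verdict_multiclass(labels, "mean_round") == k
        assert well_verdict_multiclass(labels, "majority") == k

    def test_mean_round_hand_case(self):
        labels = [2] * 8 + [3] * 7  # mean 2.467 -> 2
        assert well_verdict_multiclass(labels) == 2

    def test_half_tie_rounds_up(self):
        labels = [2] * 5 + [3] * 5  # mean 2.5 -> 3 under round-half-up
        assert well_verdict_multiclass(labels) == 3

    def test_majority_differs_from_mean_when_skewed(self):
        labels = [0] * 8 + [5] * 7
        assert well_verdict_multiclass(labels, "majority") == 0
        assert well_verdict_multiclass(labels, "mean_round") == 2

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            well_verdict_multiclass([1, 2, 7])


class TestPercentCtl:
    def test_all_control_is_hundred_percent(self):
        wells = [("c", 1.0, np.ones((15, 4), dtype=int)) for _ in range(3)]
        (pt,) = percent_ctl(wells)
        assert pt.pct_ctl_mean == 100.0
        assert pt.sem == 0.0
        assert pt.n_wells == 3

    def test_hand_computed_mean_and_sem(self):
        # wells with 9/15 and 12/15 control crops -> 60% and 80%:
        # mean 70, sem = sd({60, 80}, ddof=1)/sqrt(2) = 10
        def well(k):
            R = np.zeros((15, 4), dtype=int)
            R[:k] = 1
            return R

        (pt,) = percent_ctl([("c", 2.0, well(9)), ("c", 2.0, well(12))])
        assert pt.pct_ctl_mean == pytest.approx(70.0)
        assert pt.sem == pytest.approx(10.0)

    def test_crop_verdict_thresholds_model_mean(self):
        R = np.array([[1, 1, 0, 0]] * 15)  # model mean 0.5 -> control
        assert (crop_ensemble_verdicts(R) == 1).all()
        R = np.array([[1, 0, 0, 0]] * 15)
        assert (crop_ensemble_verdicts(R) == 0).all()

    def test_doses_grouped_separately(self):
        wells = [("c", d, np.ones((15, 4), dtype=int)) for d in (0.0, 1.0)]
        pts = percent_ctl(wells)
        assert [p.dose for p in pts] == [0.0, 1.0]
        table = dose_response_table(pts)
        assert list(table.columns) == ["compound", "dose", "pct_ctl_mean", "sem", "n_wells"]
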