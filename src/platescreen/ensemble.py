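"""Leave-plates-out cross-validation and the ensemble well verdict.

Plates — never individual crops — are dealt into validation groups, so a
model is always evaluated on plates it has never seen and plate-level batch
effects cannot leak into validation scores.  Seven plates form four groups
of sizes (2, 2, 2, 1) by default, yielding four fold models.

At screening time every well contributes a binary prediction matrix
R[i, j] in {0, 1} (crop i, fold model j; 1 = control-like).  The well
verdict rounds the grand mean of R: with 15 crops and 4 models that is 60
member predictions, and the well is called control iff the mean is >= 0.5
(round-half-up, ties resolve toward control).  The quantitative screening
readout is percent-CTL: the share of a well's crops whose model-mean score
crosses 0.5, averaged over replicate wells per (compound, dose) with its
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classifier import ClassifierConfig, TrainedModel, train_classifier, predict_class
from .stats import accuracy, confusion, macro_f1

__all__ = [
    "FoldPlan",
    "FoldResult",
    "WellVerdict",
    "DoseResponsePoint",
    "CropDataset",
    "plan_leave_plates_out",
    "run_cv",
    "ensemble_well_verdict",
    "well_verdict_multiclass",
    "crop_ensemble_verdicts",
    "percent_ctl",
    "dose_response_table",
]


@dataclass(frozen=True)
class FoldPlan:
    """Partition of plates into validation groups (plates never split)."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty group in fold plan")
            dup = seen & set(g)
            if dup:
                raise ValueError(f"plate(s) {sorted(dup)} assigned to multiple groups")
            seen |= set(g)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def plate_ids(self) -> set[str]:
        return {p for g in self.groups for p in g}


def plan_leave_plates_out(
    plate_ids: Sequence[str], n_groups: int = 4, seed: int = 0
) -> FoldPlan:
    """Shuffle plates (seeded) and deal them into groups as evenly as possible.

    For 7 plates and 4 groups the sizes are exactly (2, 2, 2, 1).  With
    n_groups == n_plates this degenerates to leave-one-plate-out.
    """
    plates = list(plate_ids)
    if len(set(plates)) != len(plates):
        raise ValueError("duplicate plate ids")
    if n_groups > len(plates):
        raise ValueError(f"n_groups={n_groups} exceeds n_plates={len(plates)}")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    order = [plates[i] for i in rng.permutation(len(plates))]
    base, rem = divmod(len(plates), n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    groups = []
    at = 0
    for s in sizes:
        groups.append(tuple(order[at:at + s]))
        at += s
    return FoldPlan(groups=tuple(groups))


@dataclass
class CropDataset:
    """Feature-level view of a crop collection with full provenance."""

    X: np.ndarray
    class_index: np.ndarray
    plate_ids: np.ndarray
    well_ids: np.ndarray
    crop_index: np.ndarray
    augmented: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if self.augmented is None:
            self.augmented = np.zeros(n, dtype=bool)
        for name in ("class_index", "plate_ids", "well_ids", "crop_index", "augmented"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match X")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "CropDataset":
        return CropDataset(
            X=self.X[mask], class_index=self.class_index[mask],
            plate_ids=self.plate_ids[mask], well_ids=self.well_ids[mask],
            crop_index=self.crop_index[mask], augmented=self.augmented[mask],
        )


@dataclass
class FoldResult:
    """One fold: its model, held-out group, and validation metrics."""

    model: TrainedModel
    validation_plates: tuple[str, ...]
    image_accuracy: float
    image_macro_f1: float
    image_confusion: np.ndarray
    well_accuracy: float
    well_confusion: np.ndarray
    n_validation: int


def run_cv(
    dataset: CropDataset,
    plan: FoldPlan,
    cfg: ClassifierConfig | None = None,
    well_rule: str = "mean_round",
) -> list[FoldResult]:
    """Train one model per group on all other plates; validate on the group.

    Augmented crops participate only in training.  Per fold, image-wise and
    well-wise confusion matrices are retained.
    """
    cfg = cfg or ClassifierConfig()
    have = set(np.unique(dataset.plate_ids))
    missing = plan.plate_ids - have
    if missing:
        raise ValueError(f"fold plan references absent plates: {sorted(missing)}")
    all_classes = np.unique(dataset.class_index)
    results = []
    for group in plan.groups:
        in_group = np.isin(dataset.plate_ids, list(group))
        train = dataset.subset(~in_group)
        val = dataset.subset(in_group & ~dataset.augmented)
        train_classes = np.unique(train.class_index)
        if len(train_classes) < len(all_classes):
            absent = sorted(set(all_classes) - set(train_classes))
            raise ValueError(
                f"class(es) {absent} missing from training split for group {group}")
        model = train_classifier(train.X, train.class_index, cfg)
        pred = predict_class(model, val.X)
        cm = confusion(val.class_index, pred, labels=all_classes, level="image")
        # well-wise: aggregate the 15 crop labels of each validation well
        well_true, well_pred = [], []
        for (p, w) in sorted(set(zip(val.plate_ids, val.well_ids))):
            m = (val.plate_ids == p) & (val.well_ids == w)
            well_true.append(int(val.class_index[m][0]))
            well_pred.append(well_verdict_multiclass(pred[m], rule=well_rule))
        wcm = confusion(well_true, well_pred, labels=all_classes, level="well")
        results.append(FoldResult(
            model=model,
            validation_plates=tuple(group),
            image_accuracy=accuracy(val.class_index, pred),
            image_macro_f1=macro_f1(cm),
            image_confusion=cm,
            well_accuracy=accuracy(well_true, well_pred),
            well_confusion=wcm,
            n_validation=len(val),
        ))
    return results


@dataclass(frozen=True)
class WellVerdict:
    """Ensemble decision for one well."""

    well_id: str
    mean_score: float
    predicted: str  # "CTL" or "LPS"

    @property
    def is_ctl(self) -> bool:
        return self.predicted == "CTL"


def ensemble_well_verdict(R: np.ndarray, well_id: str = "") -> WellVerdict:
    """Round the grand mean of the binary prediction matrix.

    mean_score = sum(R) / (n_crops * n_models); the well is control iff
    mean_score >= 0.5 (round-half-up: the exact tie resolves to control).
    """
    R = np.asarray(R)
    if R.ndim != 2:
        raise ValueError("R must be n_crops x n_models")
    if not np.isin(R, (0, 1)).all():
        raise ValueError("R entries must be 0 or 1")
    mean = float(R.sum()) / R.size
    return WellVerdict(well_id=well_id, mean_score=mean,
                       predicted="CTL" if mean >= 0.5 else "LPS")


def well_verdict_multiclass(crop_labels: Sequence[int], rule: str = "mean_round") -> int:
    """Aggregate a well's crop-level class labels into one well label.

    ``mean_round`` (default, ordinal-aware): round-half-up of the mean
    label.  ``majority``: most frequent label, ties to the lower class.
    """
    labels = np.asarray(crop_labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    if labels.min() < 0 or labels.max() > 5:
        raise ValueError("labels must be in 0..5")
    if rule == "mean_round":
        return int(np.floor(labels.mean() + 0.5))
    if rule == "majority":
        counts = np.bincount(labels, minlength=6)
        return int(np.argmax(counts))
    raise ValueError(f"unknown rule {rule!r}")


def crop_ensemble_verdicts(R: np.ndarray) -> np.ndarray:
    """Per-crop ensemble verdict: mean over models thresholded at 0.5."""
    R = np.asarray(R, dtype=float)
    return (R.mean(axis=1) >= 0.5).astype(int)


@dataclass(frozen=True)
class DoseResponsePoint:
    """Percent-CTL readout at one (compound, dose)."""

    compound: str
    dose: float
    pct_ctl_mean: float
    sem: float
    n_wells: int


def percent_ctl(
    wells: Sequence[tuple[str, float, np.ndarray]]
) -> list[DoseResponsePoint]:
    """Aggregate per-well prediction matrices into dose-response points.

    ``wells`` holds (compound, dose, R) per well, R of shape
    (n_crops, n_models).  Per well the percent of crops whose ensemble
    verdict is control is computed; per (compound, dose) the mean and the
    standard error across wells (ddof=1; 0 for a single well).
    """
    per_well: dict[tuple[str, float], list[float]] = {}
    for compound, dose, R in wells:
        verdicts = crop_ensemble_verdicts(R)
        pct = 100.0 * float(verdicts.mean())
        per_well.setdefault((compound, float(dose)), []).append(pct)
    points = []
    for (compound, dose), pcts in sorted(per_well.items()):
        arr = np.asarray(pcts)
        sem = float(sps.sem(arr, ddof=1)) if len(arr) > 1 else 0.0
        points.append(DoseResponsePoint(
            compound=compound, dose=dose, pct_ctl_mean=float(arr.mean()),
            sem=sem, n_wells=len(arr)))
    return points


def dose_response_table(points: Sequence[DoseResponsePoint]) -> pd.DataFrame:
    return pd.DataFrame([
        {"compound": p.compound, "dose": p.dose, "pct_ctl_mean": p.pct_ctl_mean,
         "sem": p.sem, "n_wells": p.n_wells}
        for p in points
    ])
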