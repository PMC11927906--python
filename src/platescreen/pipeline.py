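"""End-to-end orchestration: simulate -> crop -> features -> CV -> screen.

These functions stream wells one at a time (render, stitch, crop, extract
features, discard pixels), so a full multi-plate experiment runs in modest
memory.  Per-plate pixel sums are accumulated alongside, which makes exact
per-fold channel normalization statistics available by pooling the training
plates of a fold without re-rendering anything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .classifier import ClassifierConfig, TrainedModel, train_classifier, predict_binary
from .ensemble import (
    CropDataset, FoldPlan, FoldResult, plan_leave_plates_out, run_cv,
    crop_ensemble_verdicts, ensemble_well_verdict, percent_ctl, dose_response_table,
)
from .imaging import CropGridSpec, crops_from_tiles, isolate_channel
from .preprocessing import AugmentationPolicy, ChannelStats, apply_op, select_augmentation
from .stats import build_agreement_table, confusion, macro_f1, mcnemar
from .synthetic import (
    CompoundModel, MorphologyParams, PlateData, PlateEffectSampler, SeverityLabel, WellSpec,
)

log = logging.getLogger("platescreen")

__all__ = [
    "build_feature_dataset",
    "fold_channel_stats",
    "binary_labels",
    "train_binary_models",
    "well_prediction_matrix",
    "simulate_screen_plate",
    "simulate_test_plate",
    "screen_wells",
    "evaluate_binary_test",
    "run_pipeline",
]


def _well_crops(plate: PlateData, spec: CropGridSpec, overlap: float, channel: str | None):
    for well, tiles in plate.iter_wells():
        crops = crops_from_tiles(
            tiles, spec, overlap_fraction=overlap,
            plate_id=plate.plate_id, well_id=well.well_id,
            class_index=well.label.class_index, compound=well.compound or "",
            dose=well.dose,
        )
        if channel is not None:
            crops = [isolate_channel(c, channel) for c in crops]
        yield well, crops


def build_feature_dataset(
    plates: Sequence[PlateData],
    spec: CropGridSpec,
    overlap: float = 0.0,
    policy: AugmentationPolicy | None = None,
    channel: str | None = None,
) -> tuple[CropDataset, dict]:
    """Stream all wells into a feature dataset, with optional augmentation.

    Augmented copies (one operator each, seeded, ~policy.fraction of all
    crops) are appended with ``augmented=True``.  Returns the dataset and
    per-plate pixel sums ``{plate_id: (n, sum, sumsq)}`` for later
    fold-level channel statistics.  ``channel`` restricts to a single
    channel role (others zero-filled) for single-channel experiments.
    """
    from .classifier import extract_features

    total = sum(len(p.wells) for p in plates) * spec.n_crops
    plan = dict(select_augmentation(total, policy)) if policy else {}
    aug_rng = np.random.default_rng(
        np.random.SeedSequence([policy.rng_seed, 2])) if policy else None

    rows, labels, pids, wids, cids, augs = [], [], [], [], [], []
    plate_sums: dict = {}
    counter = 0
    for plate in plates:
        n = 0
        s1 = np.zeros(3)
        s2 = np.zeros(3)
        log.info("features: plate %s", plate.plate_id)
        for well, crops in _well_crops(plate, spec, overlap, channel):
            for c in crops:
                px01 = c.pixels.astype(np.float64) / 255.0
                n += px01.shape[0] * px01.shape[1]
                s1 += px01.sum(axis=(0, 1))
                s2 += (px01 ** 2).sum(axis=(0, 1))
                rows.append(extract_features(c))
                labels.append(c.class_index)
                pids.append(c.plate_id)
                wids.append(c.well_id)
                cids.append(c.crop_index)
                augs.append(False)
                op = plan.get(counter)
                if op is not None:
                    from dataclasses import replace

                    aug_px = np.clip(np.rint(apply_op(op, px01, aug_rng) * 255.0),
                                     0, 255).astype(np.uint8)
                    rows.append(extract_features(replace(c, pixels=aug_px, augmented=True)))
                    labels.append(c.class_index)
                    pids.append(c.plate_id)
                    wids.append(c.well_id)
                    cids.append(c.crop_index)
                    augs.append(True)
                counter += 1
        plate_sums[plate.plate_id] = (n, s1, s2)
    ds = CropDataset(
        X=np.vstack(rows), class_index=np.asarray(labels),
        plate_ids=np.asarray(pids), well_ids=np.asarray(wids),
        crop_index=np.asarray(cids), augmented=np.asarray(augs),
    )
    return ds, plate_sums


def fold_channel_stats(plate_sums: Mapping, train_plates: Sequence[str]) -> ChannelStats:
    """Pool per-plate pixel sums of the training plates into ChannelStats."""
    n = 0
    s1 = np.zeros(3)
    s2 = np.zeros(3)
    for p in train_plates:
        pn, p1, p2 = plate_sums[p]
        n += pn
        s1 += p1
        s2 += p2
    mu = s1 / n
    sigma = np.sqrt(np.maximum(s2 / n - mu ** 2, 0.0))
    if np.any(sigma <= 0):
        raise ValueError("constant channel across training plates")
    return ChannelStats(mu=tuple(mu), sigma=tuple(sigma), n_pixels=n)


def binary_labels(ds: CropDataset) -> tuple[CropDataset, np.ndarray]:
    """Restrict to control (class 0) and mild-LPS (class 1) crops.

    Binary label 1 = control, 0 = LPS-treated, matching the screening
    convention in which 1 marks a control-like crop.
    """
    mask = np.isin(ds.class_index, (0, 1))
    sub = ds.subset(mask)
    return sub, (sub.class_index == 0).astype(int)


def train_binary_models(
    ds: CropDataset,
    plan: FoldPlan,
    cfg: ClassifierConfig | None = None,
    plate_sums: Mapping | None = None,
) -> list[tuple[TrainedModel, float]]:
    """One binary (CTL vs mild LPS) model per fold group, with held-out F1.

    Training uses crops of classes 0 and 1 on the fold's training plates
    (augmented copies included); validation F1 is the binary macro F1 on
    the held-out group's unaugmented class-0/1 crops.
    """
    cfg = cfg or ClassifierConfig(n_classes=2)
    sub, y = binary_labels(ds)
    out = []
    for group in plan.groups:
        in_group = np.isin(sub.plate_ids, list(group))
        tr = ~in_group
        va = in_group & ~sub.augmented
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training split for group {group} lacks both classes")
        stats = None
        if plate_sums is not None:
            train_plates = [p for p in plate_sums if p not in group]
            stats = fold_channel_stats(plate_sums, train_plates)
        model = train_classifier(sub.X[tr], y[tr], cfg, channel_stats=stats)
        pred = predict_binary(model, sub.X[va])
        f1 = macro_f1(confusion(y[va], pred, labels=(0, 1)))
        out.append((model, float(f1)))
    return out


def well_prediction_matrix(models: Sequence[TrainedModel], X_well: np.ndarray) -> np.ndarray:
    """R[i, j]: binary verdict of model j on crop i of one well."""
    return np.column_stack([predict_binary(m, X_well) for m in models])


def simulate_screen_plate(
    compounds: Mapping[str, CompoundModel],
    doses: Mapping[str, Sequence[float]],
    wells_per_dose: int,
    params: MorphologyParams,
    effect_sampler: PlateEffectSampler,
    seed: int,
    tile_size: int,
    background_class: int = 1,
) -> PlateData:
    """A screening plate: replicate compound wells on a mild-LPS background."""
    layout = []
    for name in compounds:
        for d in doses[name]:
            for r in range(wells_per_dose):
                layout.append(WellSpec(
                    well_id=f"{name}_d{d:g}_r{r}",
                    label=SeverityLabel(background_class),
                    compound=name, dose=float(d)))
    return synthetic.generate_plate(
        plate_id="SCREEN", layout=layout, params=params,
        effect_sampler=effect_sampler, seed=seed, compounds=dict(compounds),
        tile_size=tile_size)


def simulate_test_plate(
    ctl_wells: int,
    lps_wells: int,
    params: MorphologyParams,
    effect_sampler: PlateEffectSampler,
    seed: int,
    tile_size: int,
) -> PlateData:
    """A held-out test plate of control and mild-LPS wells."""
    layout = [WellSpec(well_id=f"CTL{r}", label=SeverityLabel(0)) for r in range(ctl_wells)]
    layout += [WellSpec(well_id=f"LPS{r}", label=SeverityLabel(1)) for r in range(lps_wells)]
    return synthetic.generate_plate(
        plate_id="TEST", layout=layout, params=params,
        effect_sampler=effect_sampler, seed=seed, tile_size=tile_size)


def screen_wells(
    models: Sequence[TrainedModel],
    plate: PlateData,
    spec: CropGridSpec,
    overlap: float = 0.0,
    channel: str | None = None,
) -> list[tuple[str, float, np.ndarray]]:
    """Per-well (compound, dose, R) prediction matrices for a screen plate."""
    from .classifier import feature_matrix

    out = []
    for well, crops in _well_crops(plate, spec, overlap, channel):
        X = feature_matrix(crops)
        out.append((well.compound or "", float(well.dose),
                    well_prediction_matrix(models, X)))
    return out


def evaluate_binary_test(
    models: Sequence[TrainedModel],
    val_f1s: Sequence[float],
    plate: PlateData,
    spec: CropGridSpec,
    overlap: float = 0.0,
) -> dict:
    """Compare the ensemble against the best single fold model on a test plate.

    Crop-level truths are 1 for control wells and 0 for LPS wells.  The
    ensemble's crop verdict averages the fold models' binary predictions and
    thresholds at 0.5; the best model is the fold with highest validation
    F1.  Returns F1 for both, the agreement table (``a`` = crops only the
    ensemble got right), both McNemar variants, and well-level verdicts.
    """
    from .classifier import feature_matrix

    true, ens, well_rows = [], [], []
    per_model: list[list[int]] = [[] for _ in models]
    best_idx = int(np.argmax(val_f1s))
    for well, crops in _well_crops(plate, spec, overlap, None):
        X = feature_matrix(crops)
        R = well_prediction_matrix(models, X)
        t = 1 if well.label.class_index == 0 else 0
        true.extend([t] * len(crops))
        ens.extend(crop_ensemble_verdicts(R).tolist())
        for j in range(len(models)):
            per_model[j].extend(R[:, j].tolist())
        v = ensemble_well_verdict(R, well_id=well.well_id)
        well_rows.append({"well_id": well.well_id, "true": t,
                          "mean_score": v.mean_score, "predicted": v.predicted})
    true_a = np.asarray(true)
    ens_a = np.asarray(ens)
    best_a = np.asarray(per_model[best_idx])
    model_f1s = [macro_f1(confusion(true_a, np.asarray(p), labels=(0, 1)))
                 for p in per_model]
    table = build_agreement_table(true_a, ens_a, best_a)
    a, b = table.discordant
    result = {
        "n_images": int(len(true_a)),
        "ensemble_f1": macro_f1(confusion(true_a, ens_a, labels=(0, 1))),
        "best_model_f1": model_f1s[best_idx],
        "per_model_f1": model_f1s,
        "best_model_index": best_idx,
        "agreement_table": {
            "both_correct": table.both_correct, "ensemble_only": table.a_only,
            "best_only": table.b_only, "both_wrong": table.both_wrong,
        },
        "wells": well_rows,
    }
    if a + b > 0:
        for cc in (False, True):
            r = mcnemar(a, b, continuity=cc)
            key = "mcnemar_continuity" if cc else "mcnemar"
            result[key] = {"a": r.a, "b": r.b, "statistic": r.statistic,
                           "p_value": r.p_value, "continuity": r.continuity}
    return result


# ---------------------------------------------------------------------------
# full run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg, out_dir: Path | str | None = None) -> dict:
    """Execute the whole pipeline from a :class:`~platescreen.config.RunConfig`.

    Stages: simulate development/test/screen plates, crop and featurize,
    leave-plates-out CV (6-class), per-fold binary models, ensemble test
    evaluation with McNemar, dose-response screen.  All randomness derives
    from the single config seed.  Writes manifests, metrics, models and a
    hashed run manifest into the output directory, and returns the summary.
    """
    from .config import RunConfig, stage_seeds

    assert isinstance(cfg, RunConfig)
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    params = cfg.morphology()
    sampler = cfg.effect_sampler()
    spec = cfg.crop_spec()

    log.info("stage=simulate plates=%d tile=%d", cfg.simulate.n_plates, cfg.simulate.tile_size)
    plates = synthetic.generate_experiment(
        n_plates=cfg.simulate.n_plates, wells_per_class=cfg.simulate.wells_per_class,
        params=params, effect_sampler=sampler, seed=seeds["simulate"],
        tile_size=cfg.simulate.tile_size)

    policy = cfg.augment_policy(seeds["augment"])
    log.info("stage=features augmentation_fraction=%.2f", policy.fraction)
    ds, plate_sums = build_feature_dataset(plates, spec, cfg.crop.overlap_fraction, policy)
    manifest = pd.DataFrame({
        "plate_id": ds.plate_ids, "well_id": ds.well_ids, "crop_index": ds.crop_index,
        "class_index": ds.class_index, "augmented": ds.augmented,
    })
    manifest.to_csv(out / "crop_manifest.csv", index=False)

    stats = fold_channel_stats(plate_sums, [p.plate_id for p in plates])
    stats.to_json(out / "channel_stats.json")

    log.info("stage=cv n_groups=%d", cfg.n_groups)
    plan = plan_leave_plates_out([p.plate_id for p in plates], cfg.n_groups,
                                 seed=seeds["foldplan"])
    mc_cfg = cfg.classifier_config(n_classes=6, seed=seeds["classifier"])
    folds = run_cv(ds, plan, mc_cfg)
    fold_metrics = []
    for i, f in enumerate(folds):
        f.model.save(out / f"model_multiclass_fold{i}.json")
        pd.DataFrame(f.image_confusion.counts).to_csv(
            out / f"confusion_image_fold{i}.csv", index=False)
        pd.DataFrame(f.well_confusion.counts).to_csv(
            out / f"confusion_well_fold{i}.csv", index=False)
        fold_metrics.append({
            "fold": i, "validation_plates": list(f.validation_plates),
            "n_validation": f.n_validation,
            "image_accuracy": f.image_accuracy, "image_macro_f1": f.image_macro_f1,
            "well_accuracy": f.well_accuracy,
        })
    (out / "fold_metrics.json").write_text(json.dumps(fold_metrics, indent=1))

    log.info("stage=binary_models")
    bin_cfg = cfg.classifier_config(n_classes=2, seed=seeds["classifier"] + 1)
    binary = train_binary_models(ds, plan, bin_cfg, plate_sums)
    models = [m for m, _ in binary]
    val_f1s = [f for _, f in binary]
    for i, m in enumerate(models):
        m.save(out / f"model_binary_fold{i}.json")

    log.info("stage=test_eval")
    test_plate = simulate_test_plate(
        cfg.test_set.ctl_wells, cfg.test_set.lps_wells, params, sampler,
        seeds["test"], cfg.simulate.tile_size)
    test_eval = evaluate_binary_test(models, val_f1s, test_plate, spec,
                                     cfg.crop.overlap_fraction)
    test_eval["validation_f1_per_fold"] = val_f1s
    (out / "test_eval.json").write_text(json.dumps(test_eval, indent=1))

    log.info("stage=screen compounds=%d", len(cfg.screen.compounds))
    summary = {"fold_metrics": fold_metrics, "test_eval": test_eval}
    if cfg.screen.compounds:
        compounds = {k: v.model() for k, v in cfg.screen.compounds.items()}
        doses = {k: v.doses for k, v in cfg.screen.compounds.items()}
        screen_plate = simulate_screen_plate(
            compounds, doses, cfg.screen.wells_per_dose, params, sampler,
            seeds["screen"], cfg.simulate.tile_size)
        wells = screen_wells(models, screen_plate, spec, cfg.crop.overlap_fraction)
        points = percent_ctl(wells)
        table = dose_response_table(points)
        table.to_csv(out / "dose_response.csv", index=False)
        summary["dose_response"] = table.to_dict(orient="records")
    else:
        log.warning("stage=screen no compound wells configured; empty table")
        dose_response_table([]).to_csv(out / "dose_response.csv", index=False)
        summary["dose_response"] = []

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "run_manifest.json")
    (out / "run_manifest.json").write_text(json.dumps(
        {"seed": cfg.seed, "files": {p.name: _sha256(p) for p in files}}, indent=1))
    summary["out_dir"] = str(out)
    return summary
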