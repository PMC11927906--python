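"""Canned desk-scale experiments on the synthetic study conditions.

Each function simulates plates from scratch at a fixed, documented scale,
runs the full pipeline path under test, and returns plain numbers.  They
back the repeatable claims the package makes about itself:

* ``ensemble_vs_single`` — with strong plate batch effects, the rounded-mean
  ensemble of the fold models is at least as good (held-out binary F1) as
  the median single fold model;
* ``dose_monotonicity`` — a full-rescue compound produces a percent-CTL
  readout that increases with dose;
* ``severity_recovery`` — the crop classifier's held-out predictions track
  the true simulated severity class.

Scales (plate counts, wells, tile sizes) are chosen for minutes-scale
single-CPU runs; they are smaller than a real screening campaign and are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .classifier import ClassifierConfig
from .ensemble import percent_ctl, plan_leave_plates_out, run_cv
from .imaging import CropGridSpec
from .pipeline import (
    build_feature_dataset, evaluate_binary_test, screen_wells,
    simulate_screen_plate, simulate_test_plate, train_binary_models,
)
from .synthetic import (
    CompoundModel, MorphologyParams, PlateEffectSampler, SeverityLabel,
    WellSpec, generate_plate,
)

__all__ = ["ensemble_vs_single", "dose_monotonicity", "severity_recovery"]

#: strong plate batch effects used by the mitigation experiments
STRONG_EFFECTS = PlateEffectSampler(gain_log_sd=0.5, offset_max=0.15, blur_max_px=1.0)

_TILE = 120
_CROP = 128


def _binary_plates(n_plates: int, wells_per_class: int, seed: int,
                   params: MorphologyParams, sampler: PlateEffectSampler):
    layout = [WellSpec(f"C{c}W{r}", SeverityLabel(c))
              for c in (0, 1) for r in range(wells_per_class)]
    ss = np.random.SeedSequence(seed).generate_state(2 * n_plates).astype(np.int64) % 2**31
    return [generate_plate(f"P{i}", layout, params, sampler,
                           seed=int(ss[2 * i]), plate_seed=int(ss[2 * i + 1]),
                           tile_size=_TILE)
            for i in range(n_plates)]


def ensemble_vs_single(
    seed: int,
    n_plates: int = 4,
    wells_per_class: int = 4,
    test_wells: int = 4,
    compound: CompoundModel | None = None,
    doses: tuple = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0),
    wells_per_dose: int = 2,
) -> dict:
    """One simulation seed of the batch-effect-mitigation study.

    Simulates control/mild-LPS plates under strong plate effects, runs
    leave-one-plate-out binary training, and evaluates the ensemble against
    each single fold model on an unseen test plate.  If a compound is given
    the same fold models also screen a dose ladder, giving the Spearman
    correlation of percent-CTL with dose.
    """
    params = MorphologyParams()
    sampler = STRONG_EFFECTS
    spec = CropGridSpec(crop_size=_CROP)
    plates = _binary_plates(n_plates, wells_per_class, seed, params, sampler)
    ds, _ = build_feature_dataset(plates, spec)
    plan = plan_leave_plates_out([p.plate_id for p in plates], n_plates, seed=seed)
    cfg = ClassifierConfig(n_classes=2, seed=seed % 2**31)
    fits = train_binary_models(ds, plan, cfg)
    models = [m for m, _ in fits]
    val_f1s = [f for _, f in fits]
    test = simulate_test_plate(test_wells, test_wells, params, sampler,
                               seed=(seed * 9973 + 7) % 2**31, tile_size=_TILE)
    ev = evaluate_binary_test(models, val_f1s, test, spec)
    out = {
        "ensemble_f1": ev["ensemble_f1"],
        "median_single_f1": float(np.median(ev["per_model_f1"])),
        "per_model_f1": ev["per_model_f1"],
    }
    if compound is not None:
        screen = simulate_screen_plate(
            {"cmpd": compound}, {"cmpd": list(doses)}, wells_per_dose,
            params, sampler, seed=(seed * 7919 + 3) % 2**31, tile_size=_TILE)
        points = percent_ctl(screen_wells(models, screen, spec))
        xs = [p.dose for p in points]
        ys = [p.pct_ctl_mean for p in points]
        if np.ptp(ys) == 0:
            # readout saturated across the whole ladder: no rank information
            rho = float("nan")
        else:
            rho = float(sps.spearmanr(xs, ys).statistic)
        out["dose_spearman_rho"] = rho
        out["dose_response"] = [(p.dose, p.pct_ctl_mean, p.sem) for p in points]
    return out


def dose_monotonicity(
    seeds: range | list,
    ec50: float = 0.5,
    hill: float = 1.0,
    max_rescue: float = 1.0,
) -> dict:
    """Dose-response monotonicity over simulation seeds.

    Returns per-seed Spearman rho of percent-CTL against dose (NaN for a
    seed whose curve saturates at a constant level; ``mean_rho`` ignores
    those), plus the rho of the seed-averaged dose curve.
    """
    compound = CompoundModel(ec50=ec50, hill=hill, max_rescue=max_rescue)
    rhos, curves, ens_f1, med_f1 = [], [], [], []
    for s in seeds:
        r = ensemble_vs_single(int(s), compound=compound)
        rhos.append(r["dose_spearman_rho"])
        curves.append([y for (_, y, _) in r["dose_response"]])
        ens_f1.append(r["ensemble_f1"])
        med_f1.append(r["median_single_f1"])
    doses = [d for (d, _, _) in r["dose_response"]]
    mean_curve = np.mean(curves, axis=0)
    pooled_rho = float(sps.spearmanr(doses, mean_curve).statistic)
    return {"per_seed_rho": rhos, "mean_rho": float(np.nanmean(rhos)),
            "pooled_rho": pooled_rho, "doses": doses,
            "mean_curve": mean_curve.tolist(),
            "ensemble_f1": ens_f1, "median_single_f1": med_f1}


def severity_recovery(
    seed: int,
    n_plates: int = 4,
    wells_per_class: int = 2,
) -> dict:
    """Held-out severity prediction across the full 6-class ladder.

    Leave-one-plate-out CV on a 6-class experiment; pools every fold's
    held-out crop predictions and reports their Spearman correlation with
    the true severity class.
    """
    params = MorphologyParams()
    sampler = PlateEffectSampler()  # mild plate effects
    spec = CropGridSpec(crop_size=_CROP)
    layout = [WellSpec(f"C{c}W{r}", SeverityLabel(c))
              for c in range(6) for r in range(wells_per_class)]
    ss = np.random.SeedSequence(seed).generate_state(2 * n_plates).astype(np.int64) % 2**31
    plates = [generate_plate(f"P{i}", layout, params, sampler,
                             seed=int(ss[2 * i]), plate_seed=int(ss[2 * i + 1]),
                             tile_size=_TILE)
              for i in range(n_plates)]
    ds, _ = build_feature_dataset(plates, spec)
    plan = plan_leave_plates_out([p.plate_id for p in plates], n_plates, seed=seed)
    folds = run_cv(ds, plan, ClassifierConfig(n_classes=6, seed=seed % 2**31))
    true, pred = [], []
    from .classifier import predict_class

    for group, fold in zip(plan.groups, folds):
        mask = np.isin(ds.plate_ids, list(group)) & ~ds.augmented
        true.extend(ds.class_index[mask].tolist())
        pred.extend(np.asarray(predict_class(fold.model, ds.X[mask])).tolist())
    rho = float(sps.spearmanr(true, pred).statistic)
    acc = float(np.mean(np.asarray(true) == np.asarray(pred)))
    return {"spearman_rho": rho, "heldout_accuracy": acc, "n_crops": len(true),
            "image_macro_f1": [f.image_macro_f1 for f in folds]}
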