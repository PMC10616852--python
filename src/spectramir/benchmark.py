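"""The built-in three-target synthetic benchmark.

Emulates the full validation experiment: per-class single-species scenes
provide labeled training crops; a 1:1:1 calibration mixture supplies the
confusion matrix and the reference count vector; a 2:5:3 test mixture is
classified blind, unconfused, divided by the reference and normalized.  The
recovered composition, its resampling confidence intervals, the noise-crop
fraction and the classifier metrics are all returned in one result dict.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import (ConfusionMatrix, class_metrics, confusion, count_vector,
                        estimate_uncertainty, ratio_estimate, unconfuse)
from .classify import NOISE_LABEL, ClassifyConfig, classify_crops, train_from_crops
from .detect import DetectConfig
from .pipeline import (PipelineConfig, SceneBlock, label_crops_from_truth,
                       process_stack, stage_seed)
from .scene import SceneConfig, render_scene, sample_ground_truth
from .simulator import SimulatorConfig, build_panel, panel_distinctness
from .spectra import fixture_dispersion, fixture_dyes, fixture_filter, rpa_adjust

log = logging.getLogger(__name__)


def default_benchmark_config(seed: int = 0, **overrides) -> PipelineConfig:
    """The standard benchmark configuration.

    25 FOVs of 250 molecules per mixture (about 5,000 after FOV pruning),
    4 training FOVs of 250 molecules per class (about 1,700 labeled crops
    per single-species dataset; training scenes share the mixtures' molecule
    density so the classifier sees deployment-like crowding), 20% spurious
    blobs, default camera noise.
    """
    scene = SceneBlock(n_fov=25,
                       counts_per_class={"miR-15b": 84, "miR-155": 83,
                                         "miR-126": 83})
    return PipelineConfig(seed=seed, scene=scene, **overrides)


def _split_counts(total: int, ratio) -> list[int]:
    """Largest-remainder split of ``total`` proportional to ``ratio``."""
    ratio = np.asarray(ratio, dtype=float)
    exact = total * ratio / ratio.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(exact - base)[::-1]
    base[order[:rem]] += 1
    return base.tolist()


def _scene_config(block: SceneBlock, counts: dict[str, int],
                  n_fov: int) -> SceneConfig:
    return SceneConfig(fov_shape=block.fov_shape, n_fov=n_fov,
                       counts_per_class=counts, margin=block.margin,
                       min_separation_px=block.min_separation_px,
                       spurious_rate=block.spurious_rate,
                       brightness_median=block.brightness_median,
                       brightness_sigma=block.brightness_sigma,
                       background_level=block.background_level,
                       background_rel_amp=block.background_rel_amp,
                       background_jitter=block.background_jitter)


def run_benchmark_from_config(cfg: PipelineConfig,
                              artifacts_dir: Path | None = None) -> dict:
    """Run the complete benchmark defined by a :class:`PipelineConfig`."""
    t_start = time.time()
    seed = cfg.seed
    sim_cfg = SimulatorConfig(sigma_px=cfg.simulator.sigma_px,
                              laser_lines_nm=cfg.simulator.laser_lines_nm,
                              noise_gaussian_mean=cfg.simulator.noise_gaussian_mean,
                              noise_gaussian_var=cfg.simulator.noise_gaussian_var,
                              poisson_scale=cfg.simulator.poisson_scale)
    curve = rpa_adjust(fixture_dispersion(), cfg.simulator.rpa_deg)
    panel = build_panel([e.model_dump() for e in cfg.panel], fixture_dyes(),
                        fixture_filter(), curve, sim_cfg)
    class_names = [e.class_label for e in cfg.panel]
    panel_report = panel_distinctness(list(panel.values()),
                                      sigma_px=cfg.simulator.sigma_px)
    min_dist = min(b.interspot_distance_px for b in panel.values())
    detect_cfg = DetectConfig(threshold_k=cfg.detect.threshold_k,
                              d_merge=cfg.detect.d_merge,
                              sigma_floor=cfg.detect.sigma_floor)

    def process(gt, stage):
        stack = render_scene(gt, panel, sim_cfg,
                             seed=stage_seed(seed, f"render-{stage}"))
        ps = process_stack(stack, detect_cfg, cfg.keep_fraction,
                           cfg.denoise_method, panel_min_distance=min_dist)
        truth = gt.for_fovs(ps.noisy.fov_ids)
        labels = label_crops_from_truth(ps.crops.index, truth,
                                        cfg.classify.label_tolerance_px)
        return ps, labels

    # --- training on single-species scenes -------------------------------
    train_crops, train_labels = [], []
    for cls in class_names:
        scfg = _scene_config(cfg.scene, {cls: cfg.train_molecules_per_fov},
                             cfg.train_fov_per_class)
        gt = sample_ground_truth(scfg, seed=stage_seed(seed, f"truth-{cls}"))
        ps, labels = process(gt, f"train-{cls}")
        cap = cfg.classify.max_labeled_per_dataset
        train_crops.append(ps.crops.denoised[:cap])
        train_labels.append(labels[:cap])
        log.info("training scene %s: %d crops (%d labeled %s)",
                 cls, len(labels[:cap]), int((labels[:cap] == cls).sum()), cls)
    crops = np.concatenate(train_crops)
    labels = np.concatenate(train_labels)
    ccfg = ClassifyConfig(n_components=cfg.classify.n_components,
                          svm_c=cfg.classify.svm_c,
                          n_extra=cfg.classify.n_extra,
                          noise_sd=cfg.classify.noise_sd)
    model = train_from_crops(crops, labels, ccfg,
                             seed=stage_seed(seed, "classifier"))
    log.info("trained on %d labeled crops; validation accuracy %.3f",
             len(labels), model.validation["accuracy"])

    # --- mixtures ---------------------------------------------------------
    total_per_fov = sum(cfg.scene.counts_per_class.values())

    def run_mixture(name, ratio):
        counts = dict(zip(class_names, _split_counts(total_per_fov, ratio)))
        scfg = _scene_config(cfg.scene, counts, cfg.scene.n_fov)
        gt = sample_ground_truth(scfg, seed=stage_seed(seed, f"truth-{name}"))
        ps, true_labels = process(gt, name)
        pred = classify_crops(model, ps.crops.denoised)
        return {"name": name, "gt": gt, "scene": ps, "true": true_labels,
                "pred": pred, "h": count_vector(pred, model.classes)}

    ref = run_mixture("ref-111", (1, 1, 1))
    mix = run_mixture("mix", cfg.ratio_mix)

    # --- calibration ------------------------------------------------------
    n_sub = min(cfg.calibrate.label_subset_size, len(ref["true"]))
    cm = confusion(ref["true"][:n_sub], ref["pred"][:n_sub], model.classes)
    metrics = class_metrics(cm)
    h_ref_prime = unconfuse(cm, ref["h"])
    h_mix_prime = unconfuse(cm, mix["h"])
    point = ratio_estimate(h_mix_prime, h_ref_prime, model.classes)
    unc = estimate_uncertainty(cm, ref["h"], mix["h"],
                               n_reps=cfg.calibrate.n_reps,
                               count_cv=cfg.calibrate.count_cv,
                               seed=stage_seed(seed, "uncertainty"))

    noise_fraction = float((ref["pred"] == NOISE_LABEL).mean())
    mir_classes = [c for c in model.classes if c != NOISE_LABEL]
    idx = [model.classes.index(c) for c in mir_classes]
    c = cm.counts
    mir_true_total = c[idx, :].sum()
    cross = sum(c[i, j] for i in idx for j in idx if i != j)
    cross_confusion = float(cross / mir_true_total) if mir_true_total else np.nan

    ratio_map = dict(zip(class_names, cfg.ratio_mix))
    true_ratio = np.array([ratio_map[c] for c in mir_classes], dtype=float)
    result = {
        "classes": mir_classes,
        "panel_report": panel_report,
        "interspot_distances": {k: b.interspot_distance_px
                                for k, b in panel.items()},
        "model": model,
        "confusion": cm,
        "class_metrics": metrics,
        "h_ref": ref["h"], "h_mix": mix["h"],
        "h_ref_prime": h_ref_prime, "h_mix_prime": h_mix_prime,
        "point_estimate": point,
        "uncertainty": unc,
        "noise_crop_fraction": noise_fraction,
        "cross_confusion": cross_confusion,
        "n_crops_ref": len(ref["pred"]), "n_crops_mix": len(mix["pred"]),
        "true_composition": (true_ratio / true_ratio.sum()),
        "ratio": {
            "classes": mir_classes,
            "parts_of_ten": (unc.composition * 10).tolist(),
            "half_widths_parts_of_ten": (unc.half_widths * 10).tolist(),
            "point_parts_of_ten": (point.composition * 10).tolist(),
            "n_reps": unc.n_reps, "count_cv": unc.count_cv,
            "seed": seed,
        },
        "elapsed_s": time.time() - t_start,
    }

    if artifacts_dir is not None:
        _write_artifacts(Path(artifacts_dir), result, ref, mix)
    return result


def _write_artifacts(out: Path, result: dict, ref: dict, mix: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result["panel_report"].to_csv(out / "panel_report.csv", index=False)
    result["confusion"].to_frame().to_csv(out / "confusion.csv")
    for part in (ref, mix):
        name = part["name"]
        part["gt"].to_csv(out / f"truth_{name}.csv")
        part["scene"].locs.to_csv(out / f"locs_{name}.csv", index=False)
        pd.DataFrame({"crop_id": part["scene"].crops.index["crop_id"],
                      "true_label": part["true"],
                      "predicted": part["pred"]}).to_csv(
            out / f"pred_{name}.csv", index=False)
    counts = pd.DataFrame({"class": result["model"].classes,
                           "h_ref": result["h_ref"], "h_mix": result["h_mix"],
                           "h_ref_prime": result["h_ref_prime"],
                           "h_mix_prime": result["h_mix_prime"]})
    counts.to_csv(out / "counts.csv", index=False)
    result["model"].save(out / "model.joblib")


def run_benchmark(seed: int = 0, cfg: PipelineConfig | None = None,
                  artifacts_dir=None) -> dict:
    """Run the standard-size benchmark (see :func:`default_benchmark_config`)."""
    cfg = cfg or default_benchmark_config(seed)
    return run_benchmark_from_config(cfg, artifacts_dir=artifacts_dir)


def evaluate_separable(model, seed: int = 0, n_fov: int = 6,
                       molecules_per_fov: int = 80,
                       cfg: PipelineConfig | None = None) -> dict:
    """Classifier quality under favourable imaging conditions.

    Renders a sparse 1:1:1 scene (large molecule separation, narrow
    brightness spread, few spurious blobs) so that crops rarely overlap, then
    classifies it with a trained model and reports the confusion matrix,
    per-class recall and the miR-to-miR cross-confusion fraction.
    """
    cfg = cfg or default_benchmark_config(seed)
    sim_cfg = SimulatorConfig(sigma_px=cfg.simulator.sigma_px,
                              laser_lines_nm=cfg.simulator.laser_lines_nm,
                              noise_gaussian_mean=cfg.simulator.noise_gaussian_mean,
                              noise_gaussian_var=cfg.simulator.noise_gaussian_var,
                              poisson_scale=cfg.simulator.poisson_scale)
    curve = rpa_adjust(fixture_dispersion(), cfg.simulator.rpa_deg)
    panel = build_panel([e.model_dump() for e in cfg.panel], fixture_dyes(),
                        fixture_filter(), curve, sim_cfg)
    class_names = [e.class_label for e in cfg.panel]
    counts = dict(zip(class_names, _split_counts(molecules_per_fov, (1, 1, 1))))
    scfg = SceneConfig(fov_shape=cfg.scene.fov_shape, n_fov=n_fov,
                       counts_per_class=counts, min_separation_px=16.0,
                       spurious_rate=0.1,
                       brightness_median=cfg.scene.brightness_median,
                       brightness_sigma=0.2,
                       background_level=cfg.scene.background_level)
    gt = sample_ground_truth(scfg, seed=stage_seed(seed, "separable-truth"))
    stack = render_scene(gt, panel, sim_cfg,
                         seed=stage_seed(seed, "separable-render"))
    ps = process_stack(stack, DetectConfig(threshold_k=cfg.detect.threshold_k,
                                           d_merge=cfg.detect.d_merge,
                                           sigma_floor=cfg.detect.sigma_floor),
                       cfg.keep_fraction, cfg.denoise_method)
    truth = gt.for_fovs(ps.noisy.fov_ids)
    labels = label_crops_from_truth(ps.crops.index, truth,
                                    cfg.classify.label_tolerance_px)
    pred = classify_crops(model, ps.crops.denoised)
    cm = confusion(labels, pred, model.classes)
    metrics = class_metrics(cm)
    mir = [c for c in model.classes if c != NOISE_LABEL]
    idx = [model.classes.index(c) for c in mir]
    c = cm.counts
    mir_total = c[idx, :].sum()
    cross = sum(c[i, j] for i in idx for j in idx if i != j)
    return {"confusion": cm, "class_metrics": metrics,
            "recall": {cls: float(metrics.recall[cls]) for cls in mir},
            "cross_confusion": float(cross / mir_total) if mir_total else np.nan,
            "n_crops": len(pred)}
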