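"""Configuration and orchestration of the end-to-end workflow.

Coordinates: scene generation -> median subtraction and FOV pruning ->
denoising slot -> blob detection and crop extraction -> ground-truth crop
labeling (the deterministic stand-in for visual tagging) -> PCA+SVM training
and classification -> confusion-matrix calibration and uncertainty.

All pixel coordinates are 0-based ``(row, col)`` with row = dispersion axis.
Every stochastic stage derives its seed deterministically from the global
seed, so a rerun with the same config reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .classify import NOISE_LABEL
from .detect import DetectConfig, detect_stack, extract_crops, merge_and_filter
from .preprocess import denoise, subtract_and_prune, subtract_median
from .scene import FOVStack, GroundTruth

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def label_crops_from_truth(crop_index: pd.DataFrame, gt: GroundTruth,
                           tolerance_px: float = 1.0) -> np.ndarray:
    """Label crops from ground truth, replacing visual tagging.

    A crop receives a molecule's class iff its anchor localization lies
    within ``tolerance_px`` of that molecule's top-blob truth position in the
    same FOV; every other crop (bottom blobs, spurious blobs, mismatches) is
    labeled noise.
    """
    from scipy.spatial import cKDTree

    labels = np.full(len(crop_index), NOISE_LABEL, dtype=object)
    mols = gt.molecules()
    for fov, sub in crop_index.groupby("fov_id"):
        tru = mols[mols["fov_id"] == fov]
        if tru.empty:
            continue
        tree = cKDTree(tru[["row", "col"]].to_numpy(float))
        d, j = tree.query(sub[["row", "col"]].to_numpy(float))
        hit = d <= tolerance_px
        labels[sub.index.to_numpy()[hit]] = tru["class_label"].to_numpy()[j[hit]]
    return labels


@dataclass
class ProcessedScene:
    """Result of the image-processing front end on one stack."""

    noisy: FOVStack            # median-subtracted, pruned
    denoised: FOVStack
    prune_report: object
    locs: pd.DataFrame
    crops: object              # CropSet


def process_stack(stack: FOVStack, detect_cfg: DetectConfig | None = None,
                  keep_fraction: float = 0.8, denoise_method: str = "none",
                  panel_min_distance: float | None = None) -> ProcessedScene:
    """Median subtraction, pruning, denoising, detection and cropping."""
    detect_cfg = detect_cfg or DetectConfig()
    sub = subtract_median(stack)
    kept, report = subtract_and_prune(sub, keep_fraction)
    den = denoise(kept, denoise_method)
    locs = detect_stack(den, detect_cfg)
    fov_shape = kept.data.shape[1:]
    locs = merge_and_filter(locs, fov_shape, detect_cfg,
                            panel_min_distance=panel_min_distance)
    crops = extract_crops(kept, den, locs, detect_cfg)
    return ProcessedScene(kept, den, report, locs, crops)


# ---------------------------------------------------------------------------
# configuration schema (unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PanelEntry(_Strict):
    class_label: str
    dye_a: str
    dye_b: str


class SceneBlock(_Strict):
    fov_shape: tuple[int, int] = (256, 256)
    n_fov: int = 20
    counts_per_class: dict[str, int]
    margin: int = 24
    min_separation_px: float = 8.0
    spurious_rate: float = 0.2
    brightness_median: float = 2000.0
    brightness_sigma: float = 0.3
    background_level: float = 20.0
    background_rel_amp: float = 0.3
    background_jitter: float = 0.0


class SimulatorBlock(_Strict):
    rpa_deg: float = 177.5
    sigma_px: float = 1.15
    laser_lines_nm: tuple[float, ...] = (488.0, 561.0, 638.0)
    noise_gaussian_mean: float = 0.3
    noise_gaussian_var: float = 4.0
    poisson_scale: float = 1.0


class DetectBlock(_Strict):
    threshold_k: float = 5.0
    d_merge: float = 2.0
    sigma_floor: float = 0.6


class ClassifyBlock(_Strict):
    n_components: int = 20
    svm_c: float = 10.0
    n_extra: int = 2
    noise_sd: float = 0.05
    label_tolerance_px: float = 1.0
    max_labeled_per_dataset: int = 1700


class CalibrateBlock(_Strict):
    n_reps: int = 10_000
    count_cv: float = 0.05
    label_subset_size: int = 4000


class PipelineConfig(_Strict):
    """Schema-validated configuration of the full synthetic experiment."""

    seed: int = 0
    panel: list[PanelEntry] = Field(
        default_factory=lambda: [PanelEntry(**e) for e in _default_panel_spec()])
    scene: SceneBlock
    simulator: SimulatorBlock = SimulatorBlock()
    detect: DetectBlock = DetectBlock()
    classify: ClassifyBlock = ClassifyBlock()
    calibrate: CalibrateBlock = CalibrateBlock()
    keep_fraction: float = 0.8
    denoise_method: str = "none"
    ratio_mix: tuple[float, float, float] = (2.0, 5.0, 3.0)
    train_fov_per_class: int = 4
    train_molecules_per_fov: int = 250

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return PipelineConfig(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _default_panel_spec() -> list[dict]:
    from .simulator import DEFAULT_PANEL_SPEC

    return DEFAULT_PANEL_SPEC


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic experiment and write every artifact.

    Executes generate -> preprocess -> detect -> crop -> label-from-truth ->
    train -> classify -> calibrate, writing CSV/JSON/TIFF artifacts plus a
    manifest with the config hash.  Returns the benchmark result dict.
    """
    from pathlib import Path

    from . import benchmark

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = benchmark.run_benchmark_from_config(config, artifacts_dir=out)
    manifest = {"config_hash": config.config_hash(),
                "config": config.model_dump(),
                "seed": config.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "ratio.json").write_text(json.dumps(result["ratio"], indent=2))
    return result
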