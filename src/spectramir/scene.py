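"""Synthetic multi-FOV scenes with known ground truth.

Stands in for real microscope data: each field of view (FOV) carries a known
number of barcoded molecules per class at rejection-sampled positions, plus
spurious single-Gaussian blobs, on a smooth inhomogeneous background shared
across FOVs, with Poisson+Gaussian camera noise.

Conventions: pixel coordinates are 0-based ``(row, col)`` with the row axis
being the dispersion axis; a ground-truth position is the centre of the
molecule's *top* (shortest-wavelength) blob.  Rows are sampled on integers
and columns on half-integers so a rendered barcode patch (top blob at patch
position (2, 4.5)) pastes at integer offsets without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import SimulatorConfig, SpectralBarcode, add_noise

SPURIOUS_LABEL = "spurious"


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, per-class molecule counts and photophysics.

    ``counts_per_class`` are exact molecule counts *per FOV*; spurious blobs
    are added at ``spurious_rate`` times the molecule count.  Brightness is
    the total photon count of a molecule, drawn log-normally.  Intensities
    are in photons: the default background of 20 photons/px and median
    brightness of 2000 photons give top-blob peak SNR around 20.
    """

    fov_shape: tuple[int, int] = (256, 256)
    n_fov: int = 20
    counts_per_class: dict[str, int] = field(default_factory=dict)
    margin: int = 24
    min_separation_px: float = 8.0
    spurious_rate: float = 0.2
    brightness_median: float = 2000.0
    brightness_sigma: float = 0.3
    spurious_brightness_factor: float = 0.7
    background_level: float = 20.0
    background_rel_amp: float = 0.3
    background_jitter: float = 0.0
    max_tries_per_point: int = 200

    def __post_init__(self) -> None:
        h, w = self.fov_shape
        if self.margin < 0 or 2 * self.margin >= min(h, w):
            raise ValueError("margin leaves no usable area")
        if any(c < 0 for c in self.counts_per_class.values()):
            raise ValueError("counts must be >= 0")
        if not (0 <= self.spurious_rate):
            raise ValueError("spurious_rate must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-molecule truth records plus the scene configuration.

    ``records`` columns: fov_id, class_label, row, col, brightness.
    """

    records: pd.DataFrame
    config: SceneConfig
    seed: int

    def molecules(self) -> pd.DataFrame:
        """Truth records excluding spurious blobs."""
        return self.records[self.records["class_label"] != SPURIOUS_LABEL]

    def for_fovs(self, fov_ids) -> "GroundTruth":
        keep = self.records["fov_id"].isin(list(fov_ids))
        return GroundTruth(self.records[keep].reset_index(drop=True),
                           self.config, self.seed)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @staticmethod
    def read_csv(path, config: SceneConfig | None = None,
                 seed: int = 0) -> "GroundTruth":
        df = pd.read_csv(path)
        return GroundTruth(df, config or SceneConfig(), seed)


@dataclass
class FOVStack:
    """A stack of FOV images (n_fov, rows, cols) with acquisition metadata."""

    data: np.ndarray
    fov_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.fov_ids = np.asarray(self.fov_ids, dtype=int)
        if self.data.ndim != 3 or self.data.shape[0] != self.fov_ids.size:
            raise ValueError("stack must be (n_fov, rows, cols) matching fov_ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack values must be finite")

    def select(self, keep_mask) -> "FOVStack":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return FOVStack(self.data[keep_mask], self.fov_ids[keep_mask],
                        dict(self.meta))

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data, photometric="minisblack")

    @staticmethod
    def read_tiff(path, fov_ids=None) -> "FOVStack":
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        ids = np.arange(data.shape[0]) if fov_ids is None else fov_ids
        return FOVStack(data.astype(np.float32), ids)


def sample_ground_truth(config: SceneConfig, seed: int = 0) -> GroundTruth:
    """Rejection-sample molecule and spurious-blob positions for every FOV.

    Positions honour the margin and a pairwise minimum separation within each
    FOV; per-class counts are met exactly.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    h, w = config.fov_shape
    n_mol = sum(config.counts_per_class.values())
    n_spur = int(round(config.spurious_rate * n_mol))
    labels = [lbl for lbl, n in config.counts_per_class.items() for _ in range(n)]
    labels += [SPURIOUS_LABEL] * n_spur

    rows_out = []
    min_sep2 = config.min_separation_px ** 2
    for fov in range(config.n_fov):
        placed_r: list[float] = []
        placed_c: list[float] = []
        for lbl in labels:
            for _ in range(config.max_tries_per_point):
                r = float(rng.integers(config.margin, h - config.margin))
                c = float(rng.integers(config.margin, w - config.margin)) + 0.5
                if placed_r:
                    d2 = (np.asarray(placed_r) - r) ** 2 + (np.asarray(placed_c) - c) ** 2
                    if d2.min() < min_sep2:
                        continue
                placed_r.append(r)
                placed_c.append(c)
                break
            else:
                raise ValueError("scene too dense: cannot satisfy min_separation_px")
            bright = config.brightness_median * np.exp(
                config.brightness_sigma * rng.standard_normal())
            if lbl == SPURIOUS_LABEL:
                bright *= config.spurious_brightness_factor
            rows_out.append({"fov_id": fov, "class_label": lbl,
                             "row": placed_r[-1], "col": placed_c[-1],
                             "brightness": bright})
    df = pd.DataFrame(rows_out, columns=["fov_id", "class_label", "row",
                                         "col", "brightness"])
    return GroundTruth(df, config, seed)


def background_field(config: SceneConfig, seed: int = 0) -> np.ndarray:
    """Smooth inhomogeneous background: low-order 2-D polynomial in photons."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB6]))
    h, w = config.fov_shape
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    coef = rng.uniform(-1, 1, size=5)
    shape = (coef[0] * y + coef[1] * x + coef[2] * y * x
             + coef[3] * y ** 2 + coef[4] * x ** 2)
    denom = max(np.abs(shape).max(), 1e-12)
    rel = config.background_rel_amp * shape / denom
    return config.background_level * (1.0 + rel)


def _stamp(canvas: np.ndarray, patch: np.ndarray, row0: int, col0: int,
           scale: float) -> None:
    """Add ``scale * patch`` onto canvas with its origin at (row0, col0)."""
    h, w = canvas.shape
    ph, pw = patch.shape
    r0, r1 = max(row0, 0), min(row0 + ph, h)
    c0, c1 = max(col0, 0), min(col0 + pw, w)
    if r0 >= r1 or c0 >= c1:
        return
    canvas[r0:r1, c0:c1] += scale * patch[r0 - row0:r1 - row0, c0 - col0:c1 - col0]


def _gaussian_patch(sigma: float, radius: int = 6) -> np.ndarray:
    g = np.arange(-radius, radius + 1, dtype=float)
    gr = np.exp(-0.5 * (g / sigma) ** 2)
    gc = np.exp(-0.5 * ((g - 0.5) / sigma) ** 2)  # centre on a half-integer col
    patch = np.outer(gr, gc)
    return patch / patch.sum()


def render_scene(gt: GroundTruth, barcodes: dict[str, SpectralBarcode],
                 sim_cfg: SimulatorConfig | None = None,
                 seed: int | None = None,
                 noise: bool = True,
                 background: bool = True) -> FOVStack:
    """Render the ground truth into a noisy multi-FOV image stack.

    Each molecule adds its class's noiseless barcode patch scaled by its
    brightness, with the patch's top-blob centre at the truth position.
    Spurious blobs are single Gaussians.  The background field is identical
    across FOVs (so pixel-wise median subtraction removes it exactly) unless
    ``background_jitter`` is set; camera noise is applied per FOV.
    """
    sim_cfg = sim_cfg or SimulatorConfig(noise_gaussian_var=4.0)
    cfg = gt.config
    seed = gt.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CE]))
    h, w = cfg.fov_shape

    missing = (set(gt.records["class_label"].unique())
               - set(barcodes) - {SPURIOUS_LABEL})
    if missing:
        raise ValueError(f"no barcode for class(es): {sorted(missing)}")

    bg = background_field(cfg, seed) if background else np.zeros((h, w))
    spur_patch = _gaussian_patch(sim_cfg.sigma_px)
    spur_radius = spur_patch.shape[0] // 2

    frames = []
    for fov in range(cfg.n_fov):
        img = bg.copy()
        if background and cfg.background_jitter > 0:
            img *= 1.0 + cfg.background_jitter * rng.standard_normal()
        sub = gt.records[gt.records["fov_id"] == fov]
        for rec in sub.itertuples(index=False):
            r, c = float(rec.row), float(rec.col)
            if rec.class_label == SPURIOUS_LABEL:
                _stamp(img, spur_patch, int(round(r)) - spur_radius,
                       int(round(c - 0.5)) - spur_radius, rec.brightness)
            else:
                bc = barcodes[rec.class_label]
                row0 = int(round(r - bc.top_blob[0]))
                col0 = int(round(c - bc.top_blob[1]))
                _stamp(img, bc.patch, row0, col0, rec.brightness)
        img = np.clip(img, 0.0, None)
        if noise:
            img = add_noise(img, sim_cfg, seed=rng)
        frames.append(img)
    return FOVStack(np.stack(frames), np.arange(cfg.n_fov),
                    meta={"seed": seed,
                          "background_level": cfg.background_level,
                          "noise": noise})
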