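"""Blob detection, duplicate merging, boundary filtering and crop extraction.

Diffraction-limited spots are found with a difference-of-Gaussians band-pass
and a robust (MAD-based) intensity threshold, then refined to sub-pixel
precision with a 2-D Gaussian least-squares fit.  Because every barcode is a
dual-spot PSF, each molecule is detected (at least) twice — once per blob —
and a 24x10 crop is extracted around *every* localization; only the crop
anchored on the top blob contains the full barcode, the rest are "noise"
crops for the classifier to absorb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.optimize import least_squares

from .scene import FOVStack
from .simulator import ANCHOR_COL, ANCHOR_ROW

log = logging.getLogger(__name__)

LOC_COLUMNS = ["fov_id", "row", "col", "intensity", "sigma"]


@dataclass(frozen=True)
class DetectConfig:
    """Detection thresholds and crop geometry.

    The detection threshold is expressed in robust noise units: a candidate
    must exceed ``threshold_k`` robust standard deviations (1.4826*MAD) above
    the image median of the band-passed image.  Localizations whose fitted
    width falls below ``sigma_floor`` are rejected as single-pixel artifacts.
    """

    dog_sigma_narrow: float = 1.0
    dog_sigma_wide: float = 2.0
    threshold_k: float = 5.0
    fit_halfwidth: int = 3
    sigma_floor: float = 0.6
    sigma_ceil: float = 5.0
    d_merge: float = 2.0
    crop_shape: tuple[int, int] = (24, 10)
    anchor: tuple[float, float] = (ANCHOR_ROW, ANCHOR_COL)


def _fit_gaussian(window: np.ndarray, r0: float, c0: float,
                  sigma0: float = 1.2):
    """Least-squares fit of an isotropic 2-D Gaussian + offset to a window."""
    h, w = window.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    z = window.ravel()

    def resid(p):
        amp, r, c, sig, off = p
        g = amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sig ** 2))
        return (g + off).ravel() - z

    amp0 = max(window.max() - np.median(window), 1e-6)
    p0 = [amp0, r0, c0, sigma0, float(np.median(window))]
    try:
        res = least_squares(resid, p0, method="lm", max_nfev=200)
    except Exception:       # pragma: no cover - defensive
        return None
    amp, r, c, sig, off = res.x
    sig = abs(sig)
    if amp <= 0 or not (0 <= r <= h - 1) or not (0 <= c <= w - 1):
        return None
    return amp, r, c, sig


def detect_blobs(image: np.ndarray, cfg: DetectConfig | None = None) -> pd.DataFrame:
    """Find blobs in one image; returns columns row, col, intensity, sigma.

    Band-pass filter, robust-threshold local maxima, then a 2-D Gaussian
    least-squares refinement for sub-pixel position; fits narrower than the
    single-pixel floor are rejected.
    """
    cfg = cfg or DetectConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_blobs expects a 2-D image")
    dog = (gaussian_filter(img, cfg.dog_sigma_narrow)
           - gaussian_filter(img, cfg.dog_sigma_wide))
    med = np.median(dog)
    mad = np.median(np.abs(dog - med))
    thr = med + cfg.threshold_k * 1.4826 * mad
    if mad == 0 and not np.any(dog > thr):
        return pd.DataFrame(columns=["row", "col", "intensity", "sigma"])

    is_peak = (dog == maximum_filter(dog, size=3)) & (dog > thr)
    is_peak[:2, :] = is_peak[-2:, :] = False
    is_peak[:, :2] = is_peak[:, -2:] = False
    # a blob centred between pixels produces a plateau of equal maxima;
    # keep one candidate per connected plateau
    from scipy.ndimage import label as cc_label

    lab, n_cc = cc_label(is_peak)
    rows, cols = [], []
    for comp in range(1, n_cc + 1):
        rr, cc = np.nonzero(lab == comp)
        rows.append(int(round(rr.mean())))
        cols.append(int(round(cc.mean())))
    rows, cols = np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)

    hw = cfg.fit_halfwidth
    out = []
    for r, c in zip(rows, cols):
        r0, r1 = r - hw, r + hw + 1
        c0, c1 = c - hw, c + hw + 1
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            continue
        fit = _fit_gaussian(img[r0:r1, c0:c1], float(hw), float(hw))
        if fit is None:
            continue
        amp, fr, fc, sig = fit
        if not (cfg.sigma_floor <= sig <= cfg.sigma_ceil):
            continue
        out.append({"row": r0 + fr, "col": c0 + fc,
                    "intensity": amp, "sigma": sig})
    df = pd.DataFrame(out, columns=["row", "col", "intensity", "sigma"])
    return df.sort_values(["row", "col"], ignore_index=True)


def detect_stack(stack: FOVStack, cfg: DetectConfig | None = None) -> pd.DataFrame:
    """Run :func:`detect_blobs` on every FOV; adds the fov_id column."""
    cfg = cfg or DetectConfig()
    frames = []
    for fid, img in zip(stack.fov_ids, stack.data):
        df = detect_blobs(img, cfg)
        df.insert(0, "fov_id", int(fid))
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def crop_box(row: float, col: float, crop_shape=(24, 10),
             anchor=(ANCHOR_ROW, ANCHOR_COL)) -> tuple[int, int]:
    """Top-left corner of the crop box anchored on a localization."""
    r0 = int(round(row - anchor[0]))
    c0 = int(round(col - anchor[1]))
    return r0, c0


def _merge_once(rows: np.ndarray, cols: np.ndarray, intens: np.ndarray,
                sigmas: np.ndarray, d_merge: float):
    from scipy.spatial import cKDTree

    pts = np.column_stack([rows, cols])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(d_merge, output_type="ndarray")
    parent = np.arange(len(rows))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        pi, pj = find(i), find(j)
        if pi != pj:
            parent[pj] = pi
    roots = np.array([find(i) for i in range(len(rows))])
    out_r, out_c, out_i, out_s = [], [], [], []
    for root in np.unique(roots):
        m = roots == root
        out_r.append(rows[m].mean())
        out_c.append(cols[m].mean())
        out_i.append(intens[m].mean())
        out_s.append(sigmas[m].mean())
    return (np.asarray(out_r), np.asarray(out_c),
            np.asarray(out_i), np.asarray(out_s), len(out_r) < len(rows))


def merge_and_filter(locs: pd.DataFrame, fov_shape: tuple[int, int],
                     cfg: DetectConfig | None = None,
                     panel_min_distance: float | None = None) -> pd.DataFrame:
    """Merge near-duplicate localizations and drop boundary ones.

    Localizations closer than ``d_merge`` (single linkage, iterated to a fixed
    point so the operation is idempotent) are replaced by their mean position.
    Any localization whose crop box would exit the FOV is then discarded.
    """
    cfg = cfg or DetectConfig()
    if panel_min_distance is not None and cfg.d_merge >= panel_min_distance:
        raise ValueError("merge would fuse barcode spots: d_merge "
                         f"{cfg.d_merge} >= panel minimum interspot distance "
                         f"{panel_min_distance}")
    h, w = fov_shape
    ch, cw = cfg.crop_shape
    frames = []
    for fid, sub in locs.groupby("fov_id", sort=True):
        r = sub["row"].to_numpy(float)
        c = sub["col"].to_numpy(float)
        inten = sub["intensity"].to_numpy(float)
        sig = sub["sigma"].to_numpy(float)
        changed = len(r) > 1
        while changed and len(r) > 1:
            r, c, inten, sig, changed = _merge_once(r, c, inten, sig, cfg.d_merge)
        df = pd.DataFrame({"fov_id": int(fid), "row": r, "col": c,
                           "intensity": inten, "sigma": sig})
        r0 = np.round(df["row"] - cfg.anchor[0]).astype(int)
        c0 = np.round(df["col"] - cfg.anchor[1]).astype(int)
        inside = (r0 >= 0) & (r0 + ch <= h) & (c0 >= 0) & (c0 + cw <= w)
        frames.append(df[inside])
    if not frames:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["fov_id", "row", "col"], ignore_index=True)


@dataclass
class CropSet:
    """Crops cut around each localization from the noisy and denoised stacks.

    ``index`` columns: crop_id, fov_id, row, col, intensity, sigma.
    """

    noisy: np.ndarray       # (n, 24, 10)
    denoised: np.ndarray    # (n, 24, 10)
    index: pd.DataFrame
    n_skipped: int = 0

    def __len__(self) -> int:
        return self.noisy.shape[0]

    def to_files(self, noisy_path, denoised_path, index_path) -> None:
        import tifffile

        tifffile.imwrite(noisy_path, self.noisy.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(denoised_path, self.denoised.astype(np.float32),
                         photometric="minisblack")
        self.index.to_csv(index_path, index=False)

    @staticmethod
    def from_files(noisy_path, denoised_path, index_path) -> "CropSet":
        import tifffile

        return CropSet(tifffile.imread(noisy_path),
                       tifffile.imread(denoised_path),
                       pd.read_csv(index_path))


def extract_crops(noisy: FOVStack, denoised: FOVStack, locs: pd.DataFrame,
                  cfg: DetectConfig | None = None) -> CropSet:
    """Cut a crop around every localization from both stacks.

    The crop is anchored with the blob at ``cfg.anchor``; boxes that would
    leave the FOV (possible only if the boundary filter was skipped) are
    skipped and counted.
    """
    cfg = cfg or DetectConfig()
    ch, cw = cfg.crop_shape
    id_of = {int(f): i for i, f in enumerate(noisy.fov_ids)}
    crops_n, crops_d, keep_rows = [], [], []
    skipped = 0
    for rec in locs.itertuples(index=False):
        page = id_of[int(rec.fov_id)]
        r0, c0 = crop_box(rec.row, rec.col, (ch, cw), cfg.anchor)
        h, w = noisy.data.shape[1:]
        if r0 < 0 or c0 < 0 or r0 + ch > h or c0 + cw > w:
            skipped += 1
            continue
        crops_n.append(noisy.data[page, r0:r0 + ch, c0:c0 + cw])
        crops_d.append(denoised.data[page, r0:r0 + ch, c0:c0 + cw])
        keep_rows.append(rec)
    if skipped:
        log.info("extract_crops: skipped %d out-of-bounds boxes", skipped)
    index = pd.DataFrame(keep_rows, columns=locs.columns)
    index.insert(0, "crop_id", np.arange(len(index)))
    shape = (len(crops_n), ch, cw)
    return CropSet(np.asarray(crops_n, dtype=np.float32).reshape(shape),
                   np.asarray(crops_d, dtype=np.float32).reshape(shape),
                   index, n_skipped=skipped)
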