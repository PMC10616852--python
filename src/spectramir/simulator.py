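"""Rendering of prism-dispersed dual-spot PSFs for fluorophore pairs.

A probe carries two dyes at a sub-diffraction separation, so both emitters
share one physical position.  The dispersing prism pair shifts each emission
wavelength down the image rows according to the dispersion calibration, so a
dye's image is a sum of per-wavelength Gaussians and a dye *pair* produces a
dual-spot PSF whose interspot distance encodes the color combination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import DispersionCurve, FilterCurve, FluorophoreSpectrum, effective_emission

log = logging.getLogger(__name__)

#: default crop/patch geometry shared with the detection stage: the top blob
#: sits at row 2, columns centred so the blob straddles cols 4 and 5.
ANCHOR_ROW = 2.0
ANCHOR_COL = 4.5


@dataclass(frozen=True)
class SimulatorConfig:
    """Rendering and noise parameters.

    ``sigma_px`` is the per-wavelength diffraction-limited Gaussian width
    (1.15 px).  The camera noise model is Poisson shot noise (``poisson_scale``
    photons per intensity unit; 0 disables it) plus additive Gaussian noise
    with constant mean 0.3 and configurable variance.
    """

    sigma_px: float = 1.15
    laser_lines_nm: tuple[float, ...] = (488.0, 561.0, 638.0)
    patch_shape: tuple[int, int] = (24, 10)
    noise_gaussian_mean: float = 0.3
    noise_gaussian_var: float = 0.01
    poisson_scale: float = 1.0
    truncate_sigmas: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be > 0")
        rows, cols = self.patch_shape
        if rows < 24 or cols < 10:
            raise ValueError("patch_shape must be at least 24 rows x 10 cols")
        if self.poisson_scale < 0:
            raise ValueError("poisson_scale must be >= 0")


@dataclass(frozen=True)
class SpectralBarcode:
    """A dye pair, its rendered noiseless dual-spot PSF and interspot distance.

    ``patch`` holds the noiseless render with the top (shorter-wavelength)
    blob centred at ``top_blob`` = (ANCHOR_ROW, ANCHOR_COL); the patch total
    equals the summed excitation efficiencies of the two dyes (up to edge
    truncation).
    """

    class_label: str
    dye_a: FluorophoreSpectrum
    dye_b: FluorophoreSpectrum
    patch: np.ndarray
    interspot_distance_px: float
    top_blob: tuple[float, float] = (ANCHOR_ROW, ANCHOR_COL)
    efficiency: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.patch) < -1e-9):
            raise ValueError("noiseless PSF must be non-negative")
        if self.interspot_distance_px < 0:
            raise ValueError("interspot distance must be >= 0")


def excitation_efficiency(spec: FluorophoreSpectrum,
                          laser_lines_nm) -> tuple[float, float]:
    """Best single-line excitation efficiency and the chosen laser line.

    The probe is excited by all lasers simultaneously; the efficiency factor
    is the excitation-spectrum value at the laser wavelength, and with several
    lines the maximum over lines is used.
    """
    lines = [l for l in laser_lines_nm
             if spec.wavelengths_nm[0] <= l <= spec.wavelengths_nm[-1]]
    if not lines:
        raise ValueError("no laser line inside the excitation grid")
    effs = [spec.excitation_at(l) for l in lines]
    i = int(np.argmax(effs))
    return float(effs[i]), float(lines[i])


def render_fluorophore(spec: FluorophoreSpectrum, filt: FilterCurve,
                       curve: DispersionCurve, cfg: SimulatorConfig,
                       shape: tuple[int, int] | None = None,
                       anchor: tuple[float, float] | None = None) -> np.ndarray:
    """Noiseless dispersed image of a single dye.

    Each emission wavelength contributes an isotropic Gaussian of width
    ``cfg.sigma_px`` displaced down the rows by the dispersion curve, with
    amplitude proportional to the filtered emission.  The summed image is
    normalized to unit total intensity and multiplied by the excitation
    efficiency, so the returned patch sums to the efficiency factor up to
    truncation at the patch edges.

    ``anchor`` is the (row, col) of zero dispersion displacement.
    """
    rows, cols = shape if shape is not None else cfg.patch_shape
    if anchor is None:
        anchor = (ANCHOR_ROW, ANCHOR_COL)
    row0, col0 = anchor

    em = effective_emission(spec, filt)
    eff, line = excitation_efficiency(spec, cfg.laser_lines_nm)
    if eff <= 0.0:
        warnings.warn(f"{spec.name}: zero excitation efficiency at all laser "
                      "lines; rendering a zero image")
        return np.zeros((rows, cols))
    log.debug("render %s: efficiency %.3f at %.0f nm", spec.name, eff, line)

    nz = em > 0
    if not np.any(nz):
        return np.zeros((rows, cols))
    w = em[nz]
    centers = row0 + curve.displacement_at(spec.wavelengths_nm[nz])

    sig = cfg.sigma_px
    trunc = cfg.truncate_sigmas * sig
    r = np.arange(rows, dtype=float)
    c = np.arange(cols, dtype=float)

    dr = r[None, :] - centers[:, None]           # (n_wl, rows)
    g_rows = np.exp(-0.5 * (dr / sig) ** 2)
    g_rows[np.abs(dr) > trunc] = 0.0
    dc = c - col0
    g_cols = np.exp(-0.5 * (dc / sig) ** 2)
    g_cols[np.abs(dc) > trunc] = 0.0

    row_profile = w @ g_rows                      # (rows,)
    img = np.outer(row_profile, g_cols)
    # analytic mass of the untruncated sum of Gaussians; keeps the contract
    # "patch total = efficiency" exact up to edge truncation only
    total = float(w.sum() * 2.0 * np.pi * sig ** 2)
    if total <= 0:
        return np.zeros((rows, cols))
    return img * (eff / total)


def _refine_peak(profile: np.ndarray, idx: int) -> float:
    """Sub-pixel peak position by log-parabolic 3-point interpolation.

    Exact for a sampled Gaussian; falls back to the integer position at the
    array boundary or with non-positive neighbours.
    """
    if idx <= 0 or idx >= profile.size - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1: idx + 2]
    if min(y0, y1, y2) <= 0:
        denom = y0 - 2 * y1 + y2
        return float(idx) if denom >= 0 else float(idx + 0.5 * (y0 - y2) / denom)
    l0, l1, l2 = np.log([y0, y1, y2])
    denom = l0 - 2 * l1 + l2
    if denom >= 0:
        return float(idx)
    return float(idx + 0.5 * (l0 - l2) / denom)


def profile_peaks(profile: np.ndarray, min_rel_height: float = 0.05) -> list[float]:
    """Sub-pixel positions of local maxima of a 1-D profile, tallest first.

    Plateau maxima (exactly equal neighbouring samples, as produced by a
    Gaussian centred between two pixels) are reported at the plateau centre;
    sharp maxima are refined by log-parabolic interpolation.
    """
    from scipy.signal import find_peaks

    if profile.max() <= 0:
        return []
    idx, props = find_peaks(profile, height=min_rel_height * profile.max(),
                            plateau_size=(1, None))
    positions = []
    for i, left, right in zip(idx, props["left_edges"], props["right_edges"]):
        if right > left:
            positions.append((0.5 * (left + right), profile[i]))
        else:
            positions.append((_refine_peak(profile, int(i)), profile[i]))
    positions.sort(key=lambda t: -t[1])
    return [p for p, _ in positions]


def render_pair(class_label: str, dye_a: FluorophoreSpectrum,
                dye_b: FluorophoreSpectrum, filt: FilterCurve,
                curve: DispersionCurve, cfg: SimulatorConfig) -> SpectralBarcode:
    """Render a dual-fluorophore barcode: sum of the two single-dye images.

    The pair is rendered on a tall canvas, the two dominant blobs are located
    on the dispersion-axis profile with sub-pixel refinement, and the patch is
    re-rendered so the top blob sits exactly at (ANCHOR_ROW, ANCHOR_COL).
    """
    rows, cols = cfg.patch_shape
    max_disp = float(np.max(curve.displacement_px))
    pad = int(np.ceil(cfg.truncate_sigmas * cfg.sigma_px)) + 2
    canvas_rows = rows + int(np.ceil(max_disp)) + 2 * pad

    def _render(row0: float, shape_rows: int) -> np.ndarray:
        a = render_fluorophore(dye_a, filt, curve, cfg, shape=(shape_rows, cols),
                               anchor=(row0, ANCHOR_COL))
        b = render_fluorophore(dye_b, filt, curve, cfg, shape=(shape_rows, cols),
                               anchor=(row0, ANCHOR_COL))
        return a + b

    img = _render(float(pad), canvas_rows)
    peaks = profile_peaks(img.sum(axis=1))
    if not peaks:
        raise ValueError(f"barcode {class_label}: empty render")
    if len(peaks) == 1:
        top, distance = peaks[0], 0.0
    else:
        two = sorted(peaks[:2])
        top, distance = two[0], two[1] - two[0]

    # second pass: shift the zero-dispersion anchor so the measured top blob
    # lands exactly on the patch anchor row
    row0 = float(pad) + (ANCHOR_ROW - top)
    patch = _render(row0, canvas_rows)[:rows]
    # one refinement iteration against residual asymmetry
    peaks2 = profile_peaks(patch.sum(axis=1))
    if peaks2:
        resid = sorted(peaks2[:2])[0] - ANCHOR_ROW
        if abs(resid) > 1e-3:
            row0 -= resid
            patch = _render(row0, canvas_rows)[:rows]

    eff_a, _ = excitation_efficiency(dye_a, cfg.laser_lines_nm)
    eff_b, _ = excitation_efficiency(dye_b, cfg.laser_lines_nm)
    return SpectralBarcode(class_label, dye_a, dye_b,
                           np.clip(patch, 0.0, None), float(distance),
                           efficiency=(eff_a, eff_b))


def add_noise(img: np.ndarray, cfg: SimulatorConfig,
              seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Poisson shot noise plus additive Gaussian camera noise.

    The image is scaled by ``poisson_scale`` (photons per intensity unit),
    Poisson-sampled and rescaled; Gaussian noise with mean
    ``noise_gaussian_mean`` and variance ``noise_gaussian_var`` is then added.
    Deterministic for a fixed seed.
    """
    if cfg.noise_gaussian_var < 0:
        raise ValueError("noise variance must be >= 0")
    if np.any(np.asarray(img) < 0):
        raise ValueError("noiseless image must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.asarray(img, dtype=float)
    if cfg.poisson_scale > 0:
        out = rng.poisson(out * cfg.poisson_scale).astype(float) / cfg.poisson_scale
    out = out + rng.normal(cfg.noise_gaussian_mean,
                           np.sqrt(cfg.noise_gaussian_var), size=out.shape)
    return out


def panel_distinctness(barcodes: list[SpectralBarcode],
                       min_gap_px: float | None = None,
                       sigma_px: float = 1.15) -> pd.DataFrame:
    """Pairwise |Δ interspot distance| gaps, flagging hard-to-separate pairs.

    Pairs whose distance gap is below ``min_gap_px`` (default 2 sigma_px) are
    flagged as at risk of confusion.
    """
    if len(barcodes) < 2:
        raise ValueError("need at least 2 barcodes")
    if min_gap_px is None:
        min_gap_px = 2.0 * sigma_px
    rows = []
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            a, b = barcodes[i], barcodes[j]
            gap = abs(a.interspot_distance_px - b.interspot_distance_px)
            rows.append({"class_a": a.class_label, "class_b": b.class_label,
                         "gap_px": gap, "flagged": gap < min_gap_px})
    return pd.DataFrame(rows)


def build_panel(panel_spec: list[dict], dyes: dict[str, FluorophoreSpectrum],
                filt: FilterCurve, curve: DispersionCurve,
                cfg: SimulatorConfig) -> dict[str, SpectralBarcode]:
    """Render every barcode of a panel: list of {class_label, dye_a, dye_b}."""
    panel: dict[str, SpectralBarcode] = {}
    for entry in panel_spec:
        label = entry["class_label"]
        panel[label] = render_pair(label, dyes[entry["dye_a"]],
                                   dyes[entry["dye_b"]], filt, curve, cfg)
    return panel


#: default three-target panel; all classes share the short-wavelength dye so
#: the top blob is spectrally identical and identity is carried by the
#: interspot distance alone.
DEFAULT_PANEL_SPEC = [
    {"class_label": "miR-15b", "dye_a": "af488like", "dye_b": "af568like"},
    {"class_label": "miR-155", "dye_a": "af488like", "dye_b": "af647like"},
    {"class_label": "miR-126", "dye_a": "af568like", "dye_b": "af647like"},
]


def default_panel(rpa_deg: float = 177.5,
                  cfg: SimulatorConfig | None = None) -> dict[str, SpectralBarcode]:
    """The built-in three-class barcode panel at the given prism angle."""
    from .spectra import fixture_dispersion, fixture_dyes, fixture_filter
    from .spectra import rpa_adjust as _rpa

    cfg = cfg or SimulatorConfig()
    curve = _rpa(fixture_dispersion(), rpa_deg)
    return build_panel(DEFAULT_PANEL_SPEC, fixture_dyes(), fixture_filter(),
                       curve, cfg)
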