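"""Fluorophore spectra, emission filters and prism-dispersion calibration.

All spectral quantities live on a common 1 nm wavelength grid (400-850 nm by
default).  CSV import (``wavelength_nm,value``) resamples onto that grid by
linear interpolation.  A small library of parametric skew-Gaussian fixture
dyes approximating common Alexa-class fluorophores is provided so that the
simulator works out of the box without any downloaded vendor spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WL_MIN_NM = 400.0
WL_MAX_NM = 850.0
WL_STEP_NM = 1.0


def default_grid() -> np.ndarray:
    """The package-wide wavelength grid: 400-850 nm at 1 nm steps."""
    n = int(round((WL_MAX_NM - WL_MIN_NM) / WL_STEP_NM)) + 1
    return WL_MIN_NM + WL_STEP_NM * np.arange(n)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with >=2 points")
    if not np.all(np.isfinite(wl)) or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be finite and strictly ascending")
    return wl


@dataclass(frozen=True)
class FluorophoreSpectrum:
    """Excitation and emission spectrum of one dye on a shared grid.

    Excitation is a unitless efficiency in [0, 1]; emission is a unitless
    non-negative intensity density (its absolute scale is irrelevant, the
    renderer normalizes total intensity).
    """

    name: str
    wavelengths_nm: np.ndarray
    excitation: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths_nm)
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        if ex.shape != wl.shape or em.shape != wl.shape:
            raise ValueError("excitation/emission must share the wavelength grid")
        if not (np.all(np.isfinite(ex)) and np.all(np.isfinite(em))):
            raise ValueError("spectra must be finite")
        if np.any(ex < 0) or np.any(em < 0):
            raise ValueError("spectra must be non-negative")
        if np.any(ex > 1 + 1e-12):
            raise ValueError("excitation efficiency must be <= 1")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)

    def excitation_at(self, wavelength_nm: float) -> float:
        """Excitation efficiency at the grid point nearest to ``wavelength_nm``."""
        idx = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        return float(self.excitation[idx])


@dataclass(frozen=True)
class FilterCurve:
    """Transmission curve of the (multiband) emission filter, in [0, 1]."""

    wavelengths_nm: np.ndarray
    transmission: np.ndarray

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths_nm)
        tr = np.asarray(self.transmission, dtype=float)
        if tr.shape != wl.shape:
            raise ValueError("transmission must share the wavelength grid")
        if not np.all(np.isfinite(tr)) or np.any(tr < 0) or np.any(tr > 1 + 1e-12):
            raise ValueError("transmission must be finite and within [0, 1]")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "transmission", tr)


@dataclass(frozen=True)
class DispersionCurve:
    """Wavelength -> pixel displacement along the dispersion axis.

    ``rpa_deg`` records the relative prism angle already applied to the curve;
    ``None`` marks the reference (maximum-dispersion) calibration.  Dispersion
    displaces longer wavelengths further down the image rows.
    """

    wavelengths_nm: np.ndarray
    displacement_px: np.ndarray
    rpa_deg: float | None = None

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths_nm)
        d = np.asarray(self.displacement_px, dtype=float)
        if d.shape != wl.shape:
            raise ValueError("displacement must share the wavelength grid")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement must be finite")
        if np.any(np.diff(d) < -1e-9):
            raise ValueError("displacement must be monotonically non-decreasing")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "displacement_px", d)

    def displacement_at(self, wavelengths_nm) -> np.ndarray:
        """Linear interpolation of the displacement at given wavelengths."""
        return np.interp(np.asarray(wavelengths_nm, dtype=float),
                         self.wavelengths_nm, self.displacement_px)


def effective_emission(spec: FluorophoreSpectrum, filt: FilterCurve) -> np.ndarray:
    """Emission actually visible on the camera: emission x filter transmission.

    Returned on ``spec``'s wavelength grid; the filter is resampled by linear
    interpolation (zero outside its range) when the grids differ.
    """
    lo = max(spec.wavelengths_nm[0], filt.wavelengths_nm[0])
    hi = min(spec.wavelengths_nm[-1], filt.wavelengths_nm[-1])
    if lo > hi:
        raise ValueError("no spectral overlap between spectrum and filter")
    if (spec.wavelengths_nm.shape == filt.wavelengths_nm.shape
            and np.allclose(spec.wavelengths_nm, filt.wavelengths_nm)):
        tr = filt.transmission
    else:
        tr = np.interp(spec.wavelengths_nm, filt.wavelengths_nm,
                       filt.transmission, left=0.0, right=0.0)
    return spec.emission * tr


def rpa_adjust(curve: DispersionCurve, rpa_deg: float) -> DispersionCurve:
    """Scale a reference dispersion curve to a relative prism angle (RPA).

    The two prisms rotated to a relative angle RPA produce a total dispersion
    scaled by sin((180 - RPA) / 2) relative to the aligned (RPA=0) reference;
    RPA=180 cancels the dispersion entirely.
    """
    if not (0.0 < rpa_deg <= 180.0):
        raise ValueError(f"rpa_deg must be in (0, 180], got {rpa_deg}")
    factor = np.sin(np.deg2rad((180.0 - rpa_deg) / 2.0))
    return DispersionCurve(curve.wavelengths_nm,
                           curve.displacement_px * factor,
                           rpa_deg=float(rpa_deg))


# ---------------------------------------------------------------------------
# fixtures: parametric dyes, multiband filter, dispersion calibration
# ---------------------------------------------------------------------------

def skew_gaussian(wl: np.ndarray, center: float, sigma: float,
                  skew: float = 0.0) -> np.ndarray:
    """Skew-normal-shaped spectral band with unit peak."""
    from scipy.stats import skewnorm

    pdf = skewnorm.pdf(wl, a=skew, loc=center, scale=sigma)
    peak = pdf.max()
    return pdf / peak if peak > 0 else pdf


def _make_dye(name: str, ex_center: float, ex_sigma: float, ex_peak: float,
              em_center: float, em_sigma: float, em_skew: float,
              ex_tail: float = 0.0) -> FluorophoreSpectrum:
    wl = default_grid()
    ex = ex_peak * skew_gaussian(wl, ex_center, ex_sigma, skew=-2.0)
    if ex_tail > 0:
        # broad short-wavelength absorption shoulder seen in cyanine-class dyes
        ex = np.maximum(ex, ex_tail * skew_gaussian(wl, ex_center - 90.0, 45.0))
    em = skew_gaussian(wl, em_center, em_sigma, skew=em_skew)
    return FluorophoreSpectrum(name, wl, np.clip(ex, 0.0, 1.0), em)


def fixture_dyes() -> dict[str, FluorophoreSpectrum]:
    """Synthetic stand-ins for AF405/488/568/647-class dyes.

    Parametric skew-Gaussian shapes, not vendor data: excitation peaks sit
    near the matching laser line and emission is Stokes-shifted with the
    usual red tail.
    """
    dyes = [
        _make_dye("af405like", 401, 22, 0.95, 424, 18, 3.0),
        _make_dye("af488like", 493, 24, 0.92, 519, 16, 3.5),
        _make_dye("af568like", 577, 26, 0.88, 602, 18, 3.0, ex_tail=0.25),
        _make_dye("af647like", 651, 26, 0.90, 669, 16, 3.0, ex_tail=0.30),
    ]
    return {d.name: d for d in dyes}


_FILTER_BANDS = ((425, 455), (500, 545), (580, 635), (665, 725), (780, 840))


def fixture_filter(edge_nm: float = 4.0) -> FilterCurve:
    """Five-band emission filter fixture with raised-cosine band edges."""
    wl = default_grid()
    tr = np.zeros_like(wl)
    for lo, hi in _FILTER_BANDS:
        flat = (wl >= lo) & (wl <= hi)
        tr[flat] = np.maximum(tr[flat], 0.95)
        for edge, sign in ((lo, 1.0), (hi, -1.0)):
            ramp = (wl > edge - edge_nm) & (wl < edge + edge_nm) & ~flat
            x = sign * (wl[ramp] - edge) / edge_nm  # -1 outside .. +1 inside
            tr[ramp] = np.maximum(tr[ramp], 0.95 * 0.5 * (1 + np.sin(0.5 * np.pi * x)))
    return FilterCurve(wl, np.clip(tr, 0.0, 1.0))


# Reference (RPA=0) control points chosen so the adjusted curve spans ~23 px
# at the default acquisition angle of 177.5 deg.
_DISPERSION_KNOTS_NM = (400.0, 460.0, 520.0, 605.0, 672.0, 760.0, 850.0)
_DISPERSION_KNOTS_PX_AT_177_5 = (0.0, 1.8, 4.0, 8.5, 17.2, 21.0, 23.4)


def fixture_dispersion() -> DispersionCurve:
    """Monotone-cubic reference dispersion calibration fixture.

    Returned unadjusted (``rpa_deg=None``); apply :func:`rpa_adjust` with the
    acquisition angle before rendering.
    """
    from scipy.interpolate import PchipInterpolator

    wl = default_grid()
    ref_scale = np.sin(np.deg2rad((180.0 - 177.5) / 2.0))
    knots_px = np.asarray(_DISPERSION_KNOTS_PX_AT_177_5) / ref_scale
    disp = PchipInterpolator(_DISPERSION_KNOTS_NM, knots_px)(wl)
    return DispersionCurve(wl, disp, rpa_deg=None)


# ---------------------------------------------------------------------------
# CSV I/O  (columns: wavelength_nm,value — header required)
# ---------------------------------------------------------------------------

def _read_two_column_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns 'wavelength_nm,value'")
    order = np.argsort(df["wavelength_nm"].to_numpy())
    return (df["wavelength_nm"].to_numpy(float)[order],
            df["value"].to_numpy(float)[order])


def _resample(wl_src, val, grid) -> np.ndarray:
    return np.interp(grid, wl_src, val, left=0.0, right=0.0)


def read_filter_csv(path) -> FilterCurve:
    wl_src, val = _read_two_column_csv(path)
    grid = default_grid()
    return FilterCurve(grid, np.clip(_resample(wl_src, val, grid), 0.0, 1.0))


def read_dispersion_csv(path, rpa_deg: float | None = None) -> DispersionCurve:
    wl_src, val = _read_two_column_csv(path)
    grid = default_grid()
    disp = np.interp(grid, wl_src, val)  # extend flat, keep monotone
    return DispersionCurve(grid, disp, rpa_deg=rpa_deg)


def read_spectrum_csv(excitation_path, emission_path, name: str) -> FluorophoreSpectrum:
    grid = default_grid()
    wl_ex, ex = _read_two_column_csv(excitation_path)
    wl_em, em = _read_two_column_csv(emission_path)
    return FluorophoreSpectrum(name, grid,
                               np.clip(_resample(wl_ex, ex, grid), 0.0, 1.0),
                               np.clip(_resample(wl_em, em, grid), 0.0, None))


def write_curve_csv(path, wavelengths_nm, values) -> None:
    pd.DataFrame({"wavelength_nm": wavelengths_nm, "value": values}).to_csv(
        path, index=False)
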