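"""Reflectance-cube preprocessing: band trimming, smoothing, masking, normalization.

The default chain prepares an airborne imaging-spectroscopy cube for spectral
feature extraction:

1. :func:`trim_bands` — drop atmospheric water-absorption windows
   (1340–1455 nm and 1790–1955 nm by default) and the noisy spectrum ends,
   keeping 400–2400 nm.
2. :func:`savgol_smooth` — Savitzky–Golay polynomial smoothing (order 3,
   window 7) along the band axis, applied independently within each
   contiguous wavelength segment so the filter never blends across the gaps
   left by trimming.
3. :func:`ndvi` + :func:`mask_vegetation` — mask non-vegetated pixels with
   NDVI below a threshold (0.8 by default; pixels exactly at the threshold
   are kept).
4. :func:`shade_mask` — optional NIR-quantile shadow mask, off by default.
5. :func:`brightness_normalize` — divide every valid pixel spectrum by its
   L2 norm, removing per-pixel brightness/illumination scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .cube import SpectralCube
from .errors import (
    EmptySpectrumError,
    NoValidPixelsError,
    ParameterError,
    ValidationError,
)

#: Atmospheric water-vapour absorption windows (nm) commonly removed from
#: airborne VSWIR reflectance.
DEFAULT_DROP_WINDOWS: Tuple[Tuple[float, float], ...] = (
    (1340.0, 1455.0),
    (1790.0, 1955.0),
)
#: Usable spectral range (nm); outside it, detector noise dominates.
DEFAULT_KEEP_RANGE: Tuple[float, float] = (400.0, 2400.0)
DEFAULT_NDVI_THRESHOLD = 0.8
DEFAULT_RED_WL = 670.0
DEFAULT_NIR_WL = 800.0
DEFAULT_SG_ORDER = 3
DEFAULT_SG_WINDOW = 7


@dataclass(frozen=True)
class BandWindow:
    """Closed wavelength interval [lo, hi] in nm."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError(f"BandWindow lo {self.lo} > hi {self.hi}")

    def contains(self, wl: np.ndarray) -> np.ndarray:
        return (wl >= self.lo) & (wl <= self.hi)


def _as_windows(
    windows: Sequence[Tuple[float, float] | BandWindow],
) -> List[BandWindow]:
    return [w if isinstance(w, BandWindow) else BandWindow(*w) for w in windows]


def trim_bands(
    cube: SpectralCube,
    drop_windows: Sequence[Tuple[float, float] | BandWindow] = DEFAULT_DROP_WINDOWS,
    keep_range: Tuple[float, float] | BandWindow = DEFAULT_KEEP_RANGE,
) -> SpectralCube:
    """Remove bands inside any drop window or outside the keep range.

    A band is retained iff its center wavelength lies inside ``keep_range``
    (closed interval) and inside no ``drop_window``. Band order is preserved.

    Raises
    ------
    EmptySpectrumError
        If every band is removed.
    """
    if cube.n_bands < 1:
        raise ValidationError("cube has no bands")
    keep_w = keep_range if isinstance(keep_range, BandWindow) else BandWindow(*keep_range)
    wl = cube.wavelengths
    keep = keep_w.contains(wl)
    for w in _as_windows(drop_windows):
        keep &= ~w.contains(wl)
    if not keep.any():
        raise EmptySpectrumError(
            "band trimming removed every band (empty spectrum)"
        )
    return cube.with_reflectance(
        cube.reflectance[:, :, keep], wavelengths=wl[keep]
    )


def contiguous_segments(
    wavelengths: np.ndarray, gap_factor: float = 1.5
) -> List[Tuple[int, int]]:
    """Split a wavelength grid into contiguous segments at sampling gaps.

    A gap is declared wherever the spacing exceeds ``gap_factor`` times the
    median spacing — e.g. the 100+ nm holes left by removing water-absorption
    windows from a ~10 nm grid. Returns half-open index ranges
    ``[(start, stop), ...]``.
    """
    n = len(wavelengths)
    if n <= 1:
        return [(0, n)]
    spacing = np.diff(wavelengths)
    median = float(np.median(spacing))
    breaks = np.nonzero(spacing > gap_factor * median)[0]
    edges = [0, *(int(b) + 1 for b in breaks), n]
    return list(zip(edges[:-1], edges[1:]))


def savgol_smooth(
    cube: SpectralCube,
    order: int = DEFAULT_SG_ORDER,
    window: int = DEFAULT_SG_WINDOW,
    gap_factor: float = 1.5,
) -> SpectralCube:
    """Savitzky–Golay smoothing of every pixel spectrum along the band axis.

    Each contiguous wavelength segment (see :func:`contiguous_segments`) is
    filtered independently so the polynomial fit never spans the gaps left by
    band trimming. At segment edges the filter fits a polynomial to the last
    full window (scipy's ``interp`` treatment), keeping output length equal
    to input and reproducing polynomials up to ``order`` exactly everywhere.

    Parameters
    ----------
    order
        Polynomial order of the local least-squares fit.
    window
        Filter window length in bands; must be odd and greater than ``order``.

    Raises
    ------
    ParameterError
        If the window is even or not greater than the order, or a segment is
        shorter than the window.
    """
    if window % 2 == 0 or window <= order:
        raise ParameterError(
            f"Savitzky-Golay window must be odd and > order; got "
            f"window={window}, order={order}"
        )
    out = cube.reflectance.copy()
    for start, stop in contiguous_segments(cube.wavelengths, gap_factor):
        if stop - start < window:
            raise ParameterError(
                f"wavelength segment {cube.wavelengths[start]:.0f}-"
                f"{cube.wavelengths[stop - 1]:.0f} nm has {stop - start} bands,"
                f" fewer than the filter window {window}"
            )
        out[:, :, start:stop] = savgol_filter(
            out[:, :, start:stop],
            window_length=window,
            polyorder=order,
            axis=2,
            mode="interp",
        )
    return cube.with_reflectance(out)


def ndvi(
    cube: SpectralCube,
    red_wl: float = DEFAULT_RED_WL,
    nir_wl: float = DEFAULT_NIR_WL,
) -> np.ndarray:
    """Normalized difference vegetation index per pixel.

    NDVI = (R_nir − R_red) / (R_nir + R_red), using the bands nearest to the
    requested wavelengths. Pixels where the denominator is zero yield NaN.

    Raises
    ------
    ParameterError
        If red and NIR snap to the same band.
    """
    i_red = cube.nearest_band(red_wl)
    i_nir = cube.nearest_band(nir_wl)
    if i_red == i_nir:
        raise ParameterError(
            f"red ({red_wl} nm) and NIR ({nir_wl} nm) wavelengths snap to the "
            f"same band at {cube.wavelengths[i_red]:.1f} nm"
        )
    red = cube.reflectance[:, :, i_red]
    nir = cube.reflectance[:, :, i_nir]
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(denom != 0, (nir - red) / denom, np.nan)
    return index


def mask_vegetation(
    cube: SpectralCube,
    ndvi_map: np.ndarray,
    threshold: float = DEFAULT_NDVI_THRESHOLD,
) -> SpectralCube:
    """Flag pixels with NDVI strictly below the threshold (or undefined) invalid.

    Pixels with NDVI exactly equal to the threshold are kept. Reflectance is
    untouched; only the validity mask shrinks.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ParameterError(f"NDVI threshold must be in [-1, 1]; got {threshold}")
    ndvi_map = np.asarray(ndvi_map, dtype=float)
    if ndvi_map.shape != cube.spatial_shape:
        raise ValidationError(
            f"NDVI map shape {ndvi_map.shape} does not match cube spatial "
            f"shape {cube.spatial_shape}"
        )
    keep = np.isfinite(ndvi_map) & (ndvi_map >= threshold)
    return cube.with_mask(cube.valid_mask & keep)


def shade_mask(
    cube: SpectralCube,
    nir_wl: float = DEFAULT_NIR_WL,
    quantile: float = 0.2,
) -> SpectralCube:
    """Optional shadow mask: drop valid pixels with low NIR reflectance.

    Valid pixels whose NIR reflectance (nearest band to ``nir_wl``) is at or
    below the given quantile of the valid-pixel NIR distribution are flagged
    invalid. Shadowed canopy reflects little in the NIR, so a low quantile
    removes mostly shaded pixels. Off by default in the pipeline.
    """
    if not 0.0 <= quantile < 1.0:
        raise ParameterError(f"quantile must be in [0, 1); got {quantile}")
    if cube.n_valid == 0:
        raise NoValidPixelsError("shade_mask: no valid pixels")
    if quantile == 0.0:
        return cube.with_mask(cube.valid_mask)
    nir = cube.reflectance[:, :, cube.nearest_band(nir_wl)]
    cutoff = np.quantile(nir[cube.valid_mask], quantile)
    return cube.with_mask(cube.valid_mask & (nir > cutoff))


def brightness_normalize(cube: SpectralCube) -> SpectralCube:
    """Divide each valid pixel spectrum by its Euclidean (L2) norm.

    Removes per-pixel brightness/illumination scaling: two pixels whose
    spectra are positive scalar multiples of each other become identical.
    Invalid pixels are left untouched.

    Raises
    ------
    ValidationError
        If a valid pixel has an all-zero spectrum (names the coordinates).
    """
    refl = cube.reflectance.copy()
    norms = np.linalg.norm(refl, axis=2)
    zero_valid = (norms == 0) & cube.valid_mask
    if zero_valid.any():
        r, c = np.argwhere(zero_valid)[0]
        raise ValidationError(
            f"brightness_normalize: all-zero spectrum at valid pixel "
            f"(row={r}, col={c})"
        )
    scale = np.where(cube.valid_mask & (norms > 0), norms, 1.0)
    refl /= scale[:, :, None]
    return cube.with_reflectance(refl)


def default_pipeline(
    cube: SpectralCube,
    drop_windows: Sequence[Tuple[float, float]] = DEFAULT_DROP_WINDOWS,
    keep_range: Tuple[float, float] = DEFAULT_KEEP_RANGE,
    sg_order: int = DEFAULT_SG_ORDER,
    sg_window: int = DEFAULT_SG_WINDOW,
    ndvi_threshold: float = DEFAULT_NDVI_THRESHOLD,
    red_wl: float = DEFAULT_RED_WL,
    nir_wl: float = DEFAULT_NIR_WL,
    shade_mask_enabled: bool = False,
    shade_mask_quantile: float = 0.2,
) -> SpectralCube:
    """Run the full preprocessing chain with the standard defaults.

    trim → Savitzky–Golay → NDVI mask → (optional shade mask) → brightness
    normalization. Returns the cleaned cube; the validity mask reflects all
    masking steps.
    """
    cube = trim_bands(cube, drop_windows, keep_range)
    cube = savgol_smooth(cube, sg_order, sg_window)
    cube = mask_vegetation(cube, ndvi(cube, red_wl, nir_wl), ndvi_threshold)
    if shade_mask_enabled:
        cube = shade_mask(cube, nir_wl=nir_wl, quantile=shade_mask_quantile)
    if cube.n_valid == 0:
        raise NoValidPixelsError("preprocessing left no valid pixels")
    return brightness_normalize(cube)
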