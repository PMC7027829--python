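"""In-memory container for a hyperspectral reflectance image.

A :class:`SpectralCube` holds a (rows, cols, bands) reflectance array, the
band-center wavelengths in nanometres, and a boolean validity mask that tracks
which pixels are usable vegetated pixels. The mask only ever shrinks as
preprocessing steps (NDVI masking, shade masking) are applied; invalid pixels
are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .errors import ValidationError

# GDAL-style affine geotransform: (x0, dx, rx, y0, ry, dy)
GeoTransform = Tuple[float, float, float, float, float, float]


@dataclass
class SpectralCube:
    """Reflectance image cube with wavelengths and a pixel validity mask.

    Parameters
    ----------
    reflectance
        Array of shape (rows, cols, bands), unitless reflectance
        (typically in [0, ~1.2]).
    wavelengths
        Band-center wavelengths in nm, strictly increasing, one per band.
    valid_mask
        Boolean (rows, cols) array, True where the pixel is usable.
        Defaults to all True.
    geotransform
        Optional GDAL-style affine transform mapping pixel to map
        coordinates.
    nodata_value
        Optional sentinel marking missing reflectance in the raw data.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    valid_mask: Optional[np.ndarray] = None
    geotransform: Optional[GeoTransform] = None
    nodata_value: Optional[float] = None
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValidationError(
                f"reflectance must be 3-D (rows, cols, bands); got shape "
                f"{self.reflectance.shape}"
            )
        if self.wavelengths.ndim != 1 or (
            self.wavelengths.size != self.reflectance.shape[2]
        ):
            raise ValidationError(
                f"wavelengths length {self.wavelengths.size} does not match "
                f"band count {self.reflectance.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(
            np.diff(self.wavelengths) > 0
        ):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.spatial_shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.spatial_shape:
                raise ValidationError(
                    f"valid_mask shape {self.valid_mask.shape} does not match "
                    f"spatial shape {self.spatial_shape}"
                )
        if self.nodata_value is not None:
            hit = self.reflectance == self.nodata_value
            self.valid_mask &= ~hit.any(axis=2)
        if np.isnan(self.reflectance[self.valid_mask]).any():
            raise ValidationError("NaN reflectance among pixels flagged valid")
        self._validated = True

    @property
    def spatial_shape(self) -> Tuple[int, int]:
        return self.reflectance.shape[:2]

    @property
    def n_rows(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_cols(self) -> int:
        return self.reflectance.shape[1]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_pixel_coords(self) -> np.ndarray:
        """(row, col) coordinates of valid pixels, row-major, as (n, 2) int array."""
        rows, cols = np.nonzero(self.valid_mask)
        return np.column_stack([rows, cols])

    def valid_spectra(self) -> np.ndarray:
        """Spectra of valid pixels as an (n_valid, bands) array, row-major order."""
        return self.reflectance[self.valid_mask]

    def with_reflectance(
        self,
        reflectance: np.ndarray,
        wavelengths: Optional[np.ndarray] = None,
    ) -> "SpectralCube":
        """Copy of this cube with new reflectance (and optionally wavelengths)."""
        return replace(
            self,
            reflectance=reflectance,
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            valid_mask=self.valid_mask.copy(),
            _validated=False,
        )

    def with_mask(self, valid_mask: np.ndarray) -> "SpectralCube":
        """Copy of this cube with a new validity mask."""
        return replace(self, valid_mask=np.asarray(valid_mask, dtype=bool),
                       _validated=False)

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band whose center wavelength is closest to the request."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
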