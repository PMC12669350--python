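"""Quantitative backscattered-electron (qBEI) grey-level calibration.

In qBEI, the backscattered-electron signal of a flat, polished bone section
grows monotonically with the local mean atomic number ``Z``, so brighter
pixels correspond to more highly mineralized matrix.  Calibration anchors the
8-bit grey scale on two pure reference materials imaged in the same session —
carbon (Z = 6) and aluminum (Z = 13) — and composes two affine maps:

1. grey level -> mean atomic number, anchored at the measured mean grey values
   of the carbon and aluminum standards;
2. mean atomic number -> calcium content (wt% Ca), anchored at the
   osteoid-equivalent composition (0 wt% Ca) and pure hydroxyapatite
   (39.86 wt% Ca).

Both maps are strictly increasing, so the composition is invertible; the
inverse (Ca -> grey) is what the synthetic phantom generator uses to render
images, which makes calibration round trips exact up to 8-bit quantization.

Compartment masks label every pixel as cancellous (trabecular) bone, cortical
bone, or outside the section; all downstream analyses are run per compartment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError

# compartment mask labels
OUTSIDE = 0
CANCELLOUS = 1
CORTICAL = 2

#: Default boundary between unmineralized/void and mineralized matrix, wt% Ca.
#: The same threshold separates osteocyte lacunae from matrix in OLS analysis.
DEFAULT_MINERALIZATION_THRESHOLD = 5.2


@dataclass
class GreyImage:
    """8-bit backscattered-electron image with pixel size and compartment mask.

    Parameters
    ----------
    pixels
        2-D integer array of grey levels in [0, 255].
    pixel_size
        Edge length of one pixel in micrometres (1.8 for BMDD overview
        images, 0.88 for OLS detail images).
    compartment_mask
        Integer label array of the same shape: 0 outside the section,
        1 cancellous, 2 cortical.
    """

    pixels: np.ndarray
    pixel_size: float
    compartment_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.compartment_mask = np.asarray(self.compartment_mask)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.compartment_mask.shape != self.pixels.shape:
            raise ValueError("compartment_mask shape must match pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("grey levels must lie in [0, 255]")


@dataclass(frozen=True)
class CalibrationCurve:
    """Two-segment affine map grey -> mean atomic number -> wt% Ca.

    The anchors are configuration, not measurement: ``(z_carbon, z_aluminum)``
    pin the grey->Z segment to the reference standards and
    ``(z_ca_zero, ca_zero)`` / ``(z_hydroxyapatite, ca_hydroxyapatite)`` pin
    the Z->Ca segment.  With the defaults the carbon standard maps to
    0 wt% Ca (the osteoid-equivalent anchor) and pure hydroxyapatite to
    39.86 wt% Ca.
    """

    grey_carbon: float
    grey_aluminum: float
    z_carbon: float = 6.0
    z_aluminum: float = 13.0
    z_ca_zero: float = 6.0
    ca_zero: float = 0.0
    z_hydroxyapatite: float = 14.06
    ca_hydroxyapatite: float = 39.86

    # ------------------------------------------------------------------ maps
    def grey_to_z(self, grey):
        """Mean atomic number for a grey level (affine, unclamped)."""
        slope = (self.z_aluminum - self.z_carbon) / (self.grey_aluminum - self.grey_carbon)
        return self.z_carbon + (np.asarray(grey, dtype=float) - self.grey_carbon) * slope

    def z_to_ca(self, z):
        """wt% Ca for a mean atomic number (affine, unclamped)."""
        slope = (self.ca_hydroxyapatite - self.ca_zero) / (self.z_hydroxyapatite - self.z_ca_zero)
        return self.ca_zero + (np.asarray(z, dtype=float) - self.z_ca_zero) * slope

    def ca(self, grey):
        """wt% Ca for a grey level (strictly increasing, unclamped)."""
        return self.z_to_ca(self.grey_to_z(grey))

    def grey(self, ca):
        """Inverse map: (possibly fractional) grey level for a wt% Ca value."""
        z_slope = (self.z_aluminum - self.z_carbon) / (self.grey_aluminum - self.grey_carbon)
        ca_slope = (self.ca_hydroxyapatite - self.ca_zero) / (self.z_hydroxyapatite - self.z_ca_zero)
        z = self.z_ca_zero + (np.asarray(ca, dtype=float) - self.ca_zero) / ca_slope
        return self.grey_carbon + (z - self.z_carbon) / z_slope

    @property
    def ca_per_grey(self) -> float:
        """Quantization step: wt% Ca spanned by one grey level."""
        return float(self.ca(1.0) - self.ca(0.0))

    @property
    def ca_max(self) -> float:
        """wt% Ca of a saturated (grey 255) pixel."""
        return float(self.ca(255))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "grey_carbon", "grey_aluminum", "z_carbon", "z_aluminum",
            "z_ca_zero", "ca_zero", "z_hydroxyapatite", "ca_hydroxyapatite")}


@dataclass
class CaImage:
    """Per-pixel calcium concentration map (wt% Ca).

    ``ca`` is NaN outside the compartment mask; mineralized pixels are exactly
    those with ``ca >= mineralization_threshold``.
    """

    ca: np.ndarray
    pixel_size: float
    compartment_mask: np.ndarray
    mineralization_threshold: float = DEFAULT_MINERALIZATION_THRESHOLD

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.compartment_mask = np.asarray(self.compartment_mask)
        if self.ca.shape != self.compartment_mask.shape:
            raise ValueError("ca and compartment_mask shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        inside = self.compartment_mask != OUTSIDE
        if np.nanmin(np.where(inside, self.ca, 0.0)) < 0:
            raise ValueError("ca must be non-negative where defined")

    def in_compartment(self, compartment: int | None = None) -> np.ndarray:
        """Boolean mask of tissue pixels (optionally of one compartment)."""
        if compartment is None:
            return self.compartment_mask != OUTSIDE
        return self.compartment_mask == compartment

    def mineralized_mask(self, compartment: int | None = None) -> np.ndarray:
        """Boolean mask of mineralized-matrix pixels."""
        with np.errstate(invalid="ignore"):
            mineralized = self.ca >= self.mineralization_threshold
        return mineralized & self.in_compartment(compartment)


def fit_calibration(grey_carbon: float, grey_aluminum: float, **anchors) -> CalibrationCurve:
    """Build a calibration curve from measured reference grey values.

    Parameters
    ----------
    grey_carbon, grey_aluminum
        Mean grey values of the carbon and aluminum standards; must satisfy
        ``0 <= grey_carbon < grey_aluminum <= 255``.
    **anchors
        Optional overrides for the atomic-number / calcium anchor constants
        (see :class:`CalibrationCurve`).

    Raises
    ------
    CalibrationError
        If the reference greys are reversed, equal, or out of range, or the
        anchors do not yield a strictly increasing grey -> Ca map.
    """
    if not (0 <= grey_carbon < grey_aluminum <= 255):
        raise CalibrationError(
            f"need 0 <= grey_carbon < grey_aluminum <= 255, got "
            f"({grey_carbon}, {grey_aluminum})")
    curve = CalibrationCurve(grey_carbon=float(grey_carbon),
                             grey_aluminum=float(grey_aluminum), **anchors)
    if curve.ca_per_grey <= 0:
        raise CalibrationError("anchor constants give a non-increasing grey->Ca map")
    return curve


def apply_calibration(
    image: GreyImage,
    curve: CalibrationCurve,
    mineralization_threshold: float = DEFAULT_MINERALIZATION_THRESHOLD,
) -> CaImage:
    """Convert a grey-level image to a calcium concentration map.

    Grey levels that the affine map sends below 0 wt% (darker than the
    osteoid anchor: resin, background) are clamped to 0.  Pixels outside the
    compartment mask are set to NaN.
    """
    ca = np.clip(curve.ca(image.pixels.astype(float)), 0.0, None)
    ca[image.compartment_mask == OUTSIDE] = np.nan
    return CaImage(ca=ca, pixel_size=image.pixel_size,
                   compartment_mask=image.compartment_mask,
                   mineralization_threshold=mineralization_threshold)


# ---------------------------------------------------------------------- I/O

def load_grey_image(image_path, mask_path, pixel_size: float) -> GreyImage:
    """Read an 8-bit single-channel TIFF/PNG image and its label mask."""
    from imageio.v3 import imread  # supports both TIFF and PNG

    pixels = np.asarray(imread(image_path))
    mask = np.asarray(imread(mask_path))
    return GreyImage(pixels=pixels, pixel_size=pixel_size, compartment_mask=mask)


def save_ca_image(ca_image: CaImage, path, curve: CalibrationCurve | None = None) -> None:
    """Write a floating-point Ca map as TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, ca_image.ca.astype(np.float32))
    tifffile.imwrite(path.with_suffix(".mask.tif"),
                     ca_image.compartment_mask.astype(np.uint8))
    meta = {
        "pixel_size_um": ca_image.pixel_size,
        "mineralization_threshold_wtpct": ca_image.mineralization_threshold,
    }
    if curve is not None:
        meta["calibration"] = curve.to_dict()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_ca_image(path) -> CaImage:
    """Read a Ca map written by :func:`save_ca_image`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return CaImage(
        ca=tifffile.imread(path).astype(float),
        pixel_size=meta["pixel_size_um"],
        compartment_mask=tifffile.imread(path.with_suffix(".mask.tif")),
        mineralization_threshold=meta["mineralization_threshold_wtpct"],
    )
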