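"""Image standardization: normalization against grey standards, green-channel
extraction, cut-out, masking and rescaling to the common analysis scale.

All downstream feature extraction assumes images in the standardized
:class:`EggImage` form: linear intensities in [0, 1], a single connected
elliptical mask, black (zero) background outside the mask, and a fixed
spatial scale of 29 pixels per mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import label as _cc_label, regionprops
from skimage.transform import rescale as _sk_rescale

#: Common analysis scale, pixels per mm.
STANDARD_SCALE = 29.0

#: Black border retained around the mask bounding box after cut-out, px.
MASK_MARGIN = 5


@dataclass(frozen=True)
class GreyStandard:
    """A grey reference patch measured in the same frame as the egg.

    Parameters
    ----------
    measured : float
        Mean linear pixel value of the patch in the raw frame (> 0).
    reflectance : float
        Known reflectance fraction of the patch, in (0, 1).
    """

    measured: float
    reflectance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.reflectance < 1.0):
            raise ValueError(f"reflectance must be in (0, 1), got {self.reflectance}")
        if self.measured <= 0:
            raise ValueError(f"measured value must be > 0, got {self.measured}")


@dataclass
class EggImage:
    """A standardized single-channel egg image plus metadata.

    ``pixels`` holds linear intensities in [0, 1] with everything outside
    ``mask`` set to zero; ``scale`` is in pixels per mm (29 after
    standardization).
    """

    pixels: np.ndarray
    mask: np.ndarray
    scale: float
    egg_id: str = ""
    species: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must match pixels shape")
        if self.scale <= 0:
            raise ValueError("scale must be positive (px per mm)")

    @property
    def is_masked(self) -> bool:
        """True if every pixel outside the mask is exactly zero."""
        return bool(np.all(self.pixels[~self.mask] == 0.0))

    def major_axis_mm(self) -> float:
        """Length of the mask's major axis in mm (ellipse-equivalent)."""
        props = regionprops(self.mask.astype(np.uint8))
        if not props:
            raise ValueError("empty mask")
        return props[0].axis_major_length / self.scale


def normalize_image(
    raw: np.ndarray, standards: Sequence[GreyStandard] | GreyStandard
) -> np.ndarray:
    """Map raw linear intensities to reflectance using grey standards.

    With one standard the map is gain-only (multiplicative): the standard's
    measured value maps to its known reflectance.  With two standards the map
    is linear (gain + offset) through both (measured, reflectance) points.
    Output is clipped to [0, 1].

    Raises
    ------
    ValueError
        If two standards have equal measured values (degenerate fit), or if
        more than two standards are supplied.
    """
    if isinstance(standards, GreyStandard):
        standards = [standards]
    raw = np.asarray(raw, dtype=float)
    if len(standards) == 1:
        s = standards[0]
        gain = s.reflectance / s.measured
        out = raw * gain
    elif len(standards) == 2:
        a, b = standards
        if a.measured == b.measured:
            raise ValueError(
                "degenerate normalization: both standards have equal measured "
                f"value {a.measured}"
            )
        gain = (a.reflectance - b.reflectance) / (a.measured - b.measured)
        offset = a.reflectance - gain * a.measured
        out = raw * gain + offset
    else:
        raise ValueError(f"expected 1 or 2 grey standards, got {len(standards)}")
    return np.clip(out, 0.0, 1.0)


def green_channel(rgb: np.ndarray) -> np.ndarray:
    """Extract the green plane of an RGB frame, unchanged.

    The green channel approximates the spectral sensitivity of the avian
    double cones thought to drive pattern processing.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {rgb.shape}")
    return np.array(rgb[:, :, 1], dtype=float)


def cutout_and_rescale(
    image: np.ndarray,
    mask: np.ndarray,
    native_scale: float,
    *,
    target_scale: float = STANDARD_SCALE,
    margin: int = MASK_MARGIN,
    egg_id: str = "",
    species: str | None = None,
    year: int | None = None,
) -> EggImage:
    """Cut the egg out of its frame and standardize the spatial scale.

    The frame is resampled (bilinear) from ``native_scale`` to
    ``target_scale`` px/mm, pixels outside the mask are zeroed (artificial
    black background) and the result is cropped to the mask bounding box
    plus a fixed black margin.

    Raises
    ------
    ValueError
        If the mask is empty or ``native_scale`` is not positive.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if native_scale <= 0:
        raise ValueError(f"native_scale must be positive, got {native_scale}")
    if not mask.any():
        raise ValueError("empty mask: nothing to cut out")
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")

    factor = target_scale / native_scale
    if factor != 1.0:
        image = _sk_rescale(image, factor, order=1, anti_aliasing=factor < 1.0)
        mask = _sk_rescale(mask.astype(float), factor, order=0) > 0.5

    # keep only the largest connected mask component
    lab = _cc_label(mask)
    if lab.max() > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (1 + int(np.argmax(sizes)))

    image = np.where(mask, image, 0.0)

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = image[r0:r1, c0:c1]
    crop_mask = mask[r0:r1, c0:c1]
    pad = ((margin, margin), (margin, margin))
    crop = np.pad(crop, pad)
    crop_mask = np.pad(crop_mask, pad)

    return EggImage(
        pixels=np.clip(crop, 0.0, 1.0),
        mask=crop_mask,
        scale=target_scale,
        egg_id=egg_id,
        species=species,
        year=year,
    )
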