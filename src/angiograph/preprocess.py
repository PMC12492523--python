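"""Segmentation of tubule structures from brightfield microscopy images.

Raw tube-formation images are turned into clean binary masks in four steps:
grayscale conversion, Gaussian smoothing (sigma ~ 1 px) to suppress
high-frequency noise, Otsu binarization, and removal of 8-connected
components smaller than a minimum object size (64 px by default) that would
otherwise seed spurious graph components.

Foreground polarity: Otsu yields a threshold, not a polarity.  In brightfield
tube-formation assays the tubules occupy a minority of the field, so by
default the side of the threshold holding the *smaller* pixel fraction is
taken as foreground; set ``invert_foreground`` to flip this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import filters, measure

__all__ = [
    "PreprocessConfig",
    "load_image",
    "to_grayscale",
    "gaussian_smooth",
    "binarize_otsu",
    "remove_small_objects",
    "preprocess_image",
    "GRAYSCALE_WEIGHTS",
]

logger = logging.getLogger(__name__)

#: ITU-R BT.709 / sRGB luminance weights (R, G, B), the convention used by
#: scikit-image's ``rgb2gray``.
GRAYSCALE_WEIGHTS: tuple[float, float, float] = (0.2125, 0.7154, 0.0721)


@dataclass
class PreprocessConfig:
    """Parameters of the mask-extraction pipeline.

    gaussian_sigma
        Standard deviation of the smoothing kernel, in pixels.
    min_object_size
        8-connected components with *fewer* than this many pixels are
        removed; components of exactly this size are kept.
    invert_foreground
        If False (default) the minority side of the Otsu threshold is
        foreground; if True, the majority side.
    """

    gaussian_sigma: float = 1.0
    min_object_size: int = 64
    invert_foreground: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.min_object_size < 0:
            raise ValueError("min_object_size must be >= 0")


def load_image(path) -> np.ndarray:
    """Read a JPEG/PNG/TIFF image as a 2-D grayscale or 3-channel array.

    RGBA alpha channels are dropped.  Bit depth is preserved.
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality {img.ndim} for {path!r}")
    return img


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to single-channel luminance.

    Single-channel input is returned unchanged.  RGB input is combined with
    the BT.709 weights in :data:`GRAYSCALE_WEIGHTS` (which sum to 1), so the
    intensity scale of the input is preserved: an image with all channels
    equal to v maps to v everywhere.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image.astype(np.float64) @ np.asarray(GRAYSCALE_WEIGHTS)
    raise ValueError(
        f"expected a 2-D grayscale or HxWx3 RGB image, got shape {image.shape}"
    )


def gaussian_smooth(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass filter with reflect padding.

    Reflect padding keeps constant images exactly constant at the borders.
    ``sigma == 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if sigma == 0:
        return gray
    return filters.gaussian(gray, sigma=sigma, mode="reflect", preserve_range=True)


def binarize_otsu(
    gray: np.ndarray, invert_foreground: bool = False
) -> tuple[np.ndarray, float]:
    """Threshold with Otsu's method and pick the foreground side.

    Returns ``(mask, threshold)``.  The threshold maximizes between-class
    variance of the intensity histogram.  Foreground is the minority-fraction
    side of the threshold unless ``invert_foreground`` is set.

    A constant image has no threshold; an all-background mask is returned
    with ``threshold = nan`` and a warning, so batch runs survive blank
    fields.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.all(gray == gray.flat[0]):
        warnings.warn(
            "constant image: Otsu threshold undefined, returning empty mask",
            stacklevel=2,
        )
        logger.warning("binarize_otsu: constant image, empty mask returned")
        return np.zeros(gray.shape, dtype=bool), float("nan")

    threshold = float(filters.threshold_otsu(gray))
    bright = gray > threshold
    bright_fraction = bright.mean()
    # minority side = tubules by default
    mask = bright if bright_fraction <= 0.5 else ~bright
    if invert_foreground:
        mask = ~mask
    return mask, threshold


def remove_small_objects(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected foreground components with fewer than min_size pixels.

    Strict inequality: a component of exactly ``min_size`` pixels survives.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return mask.copy()
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False  # background
    return keep[labels]


def preprocess_image(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Full pipeline: grayscale -> smooth -> Otsu -> small-object removal."""
    config = config or PreprocessConfig()
    stage = "to_grayscale"
    try:
        gray = to_grayscale(image)
        stage = "gaussian_smooth"
        smooth = gaussian_smooth(gray, config.gaussian_sigma)
        stage = "binarize_otsu"
        mask, _ = binarize_otsu(smooth, config.invert_foreground)
        stage = "remove_small_objects"
        return remove_small_objects(mask, config.min_object_size)
    except ValueError as exc:
        raise ValueError(f"preprocessing failed at stage '{stage}': {exc}") from exc
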