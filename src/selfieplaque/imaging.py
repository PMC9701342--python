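"""Color representation and automatic-thresholding primitives.

Images are plain ``numpy`` rasters: an RGB smile photograph is an
``(H, W, 3)`` uint8 array, a single channel is an ``(H, W)`` uint8 array,
and a mask is an ``(H, W)`` boolean array.  The HSB (hue-saturation-
brightness, a.k.a. HSV) decomposition is byte-scaled: every channel lives
in [0, 255], with hue mapped from degrees by ``deg * 255 / 360`` — the
8-bit convention of classical image-analysis software, which is what the
downstream saturation thresholds are calibrated against.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv, hsv2rgb

__all__ = [
    "rgb_to_hsb",
    "hsb_to_rgb",
    "channel_histogram",
    "otsu_threshold",
    "apply_band_threshold",
]


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("empty image: height and width must be >= 1")
    if image.dtype != np.uint8:
        arr = np.asarray(image)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("RGB channel values must lie in [0, 255]")
        image = arr.astype(np.uint8)
    return image


def rgb_to_hsb(image: np.ndarray) -> np.ndarray:
    """Decompose an RGB image into byte-scaled hue/saturation/brightness.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
        24-bit RGB raster.

    Returns
    -------
    (H, W, 3) uint8 array
        Channels are hue, saturation, brightness, each rescaled to
        [0, 255] (hue: degrees * 255/360, rounded; saturation and
        brightness: unit fraction * 255, rounded).  Gray pixels
        (r = g = b) have saturation 0.
    """
    image = _validate_rgb(image)
    hsv = rgb2hsv(image)  # floats in [0, 1]; hue is fraction of a turn
    return np.rint(hsv * 255.0).astype(np.uint8)


def hsb_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_hsb` (up to +/-1 per channel from rounding)."""
    hsb = np.asarray(hsb)
    if hsb.ndim != 3 or hsb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) HSB raster, got shape {hsb.shape}")
    rgb = hsv2rgb(hsb.astype(np.float64) / 255.0)
    return np.rint(rgb * 255.0).astype(np.uint8)


def channel_histogram(channel: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """256-bin intensity histogram of a byte channel, optionally masked.

    Only pixels where ``mask`` is true are counted; the counts always sum
    to the number of pixels considered.
    """
    channel = np.asarray(channel)
    if channel.dtype != np.uint8:
        if channel.size and (channel.min() < 0 or channel.max() > 255):
            raise ValueError("channel values must lie in [0, 255]")
        channel = channel.astype(np.uint8)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != channel.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match channel shape {channel.shape}"
            )
        channel = channel[mask]
    return np.bincount(channel.ravel(), minlength=256).astype(np.int64)


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's automatic threshold from a 256-bin histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split into classes {value <= t} and {value > t}.  Ties are broken by
    the smallest maximizing level.  A histogram whose mass sits on a
    single level returns that level (degenerate but defined: the
    at-or-below class then selects everything).
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram: no pixels to threshold")

    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0])

    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                    # pixels at or below t
    mu_cum = np.cumsum(hist * levels)
    mu_total = mu_cum[-1]
    w1 = total - w0
    # valid splits have both classes populated
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(sigma_b))          # argmax returns the smallest maximizer


def apply_band_threshold(
    channel: np.ndarray,
    low: int,
    high: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean raster true where ``low <= value <= high`` (closed band).

    Band ends are inclusive at both ends. With a mask, pixels outside
    the mask are always false.
    """
    if not (0 <= low <= high <= 255):
        raise ValueError(f"invalid band [{low}, {high}]: need 0 <= low <= high <= 255")
    channel = np.asarray(channel)
    selected = (channel >= low) & (channel <= high)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != channel.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match channel shape {channel.shape}"
            )
        selected &= mask
    return selected
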