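"""Tooth-region masks.

The study protocol this tool reproduces cuts the six anterior teeth out of
the smile photograph by hand (an "object selection" step in an image
editor).  That manual step is modeled here as a file contract: the tooth
region arrives as a PNG mask whose nonzero pixels mean "tooth".  The mask
defines TA, the total tooth area in pixels, which is the denominator of
every plaque-fraction measurement.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["MaskError", "load_mask", "total_area", "crop_to_mask"]


class MaskError(ValueError):
    """Raised for unusable tooth masks (bad file, wrong size, empty)."""


def load_mask(path: str | Path, expected_dims: tuple[int, int] | None = None) -> np.ndarray:
    """Load a binary tooth mask from a PNG (or any 8-bit raster) file.

    Nonzero pixels mean "tooth"; antialiased edge values binarize to true.
    For RGB(A) files a pixel is tooth if any color channel is nonzero.

    Parameters
    ----------
    path : path to the mask file
    expected_dims : optional (height, width) of the image the mask belongs
        to; a mismatch is rejected.

    Returns
    -------
    (H, W) boolean array with at least one true pixel.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise MaskError(f"mask file not found: {path}") from None
    except Exception as exc:  # Pillow raises various decode errors
        raise MaskError(f"unreadable mask file {path}: {exc}") from exc

    if arr.ndim == 3:
        mask = np.any(arr[:, :, :3] != 0, axis=2)
    else:
        mask = arr != 0

    if expected_dims is not None and mask.shape != tuple(expected_dims):
        raise MaskError(
            f"mask dimensions {mask.shape} do not match image dimensions {tuple(expected_dims)}"
        )
    if not mask.any():
        raise MaskError(f"empty tooth mask: {path} has no nonzero pixel")
    return mask


def total_area(mask: np.ndarray) -> int:
    """Total tooth area TA: the count of true pixels in the mask."""
    mask = np.asarray(mask, dtype=bool)
    return int(mask.sum())


def crop_to_mask(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restrict an image to the mask's bounding box, blanking non-tooth pixels.

    Pixels outside the mask are set to the background sentinel (0, 0, 0);
    they must additionally be excluded from all histograms via the
    returned cropped mask, so the sentinel value can never bias a
    threshold.

    Returns
    -------
    (cropped_image, cropped_mask) : the image restricted to the mask's
    bounding box with outside-mask pixels black, and the matching mask.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise MaskError(
            f"mask dimensions {mask.shape} do not match image dimensions {image.shape[:2]}"
        )
    if not mask.any():
        raise MaskError("empty tooth mask: nothing to crop to")

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub_mask = mask[r0:r1, c0:c1]
    sub_img = image[r0:r1, c0:c1].copy()
    sub_img[~sub_mask] = 0
    return sub_img, sub_mask
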