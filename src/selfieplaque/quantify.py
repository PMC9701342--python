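"""Plaque detection and selfie-index calibration.

Plaque pixels are found inside the tooth mask by thresholding the
*saturation* channel only — hue and brightness are left unconstrained at
[0, 255] — because both visible plaque and dye-disclosed plaque are far
more saturated than sound enamel.  The plaque-area fraction
``100 * PA / TA`` (percent of tooth pixels that are plaque) is then mapped
to a full-mouth index estimate by a linear calibration:

    SVPI = -7.50 + 1.14 * fraction_pct      (visible plaque)
    SDPI = 40.62 + 0.44 * fraction_pct      (disclosed plaque)

These shipped coefficients were fitted clinically against the Visible
Plaque Index and the O'Leary disclosed index; :func:`fit_calibration`
refits them by ordinary least squares from new paired observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imaging import apply_band_threshold, channel_histogram, otsu_threshold
from .masks import MaskError

__all__ = [
    "PlaqueMeasurement",
    "CalibrationModel",
    "VISIBLE_MODEL",
    "DISCLOSED_MODEL",
    "detect_plaque",
    "plaque_fraction",
    "apply_calibration",
    "fit_calibration",
]

SATURATION = 1  # channel index of saturation in an HSB raster


def plaque_fraction(pa: int, ta: int) -> float:
    """Percent of tooth area covered by plaque: ``100 * PA / TA``."""
    if ta <= 0:
        raise ValueError("TA must be positive (empty tooth mask)")
    if not 0 <= pa <= ta:
        raise ValueError(f"PA must satisfy 0 <= PA <= TA, got PA={pa}, TA={ta}")
    return 100.0 * pa / ta


@dataclass(frozen=True)
class PlaqueMeasurement:
    """Plaque area PA, tooth area TA (pixels) and detection provenance."""

    pa: int
    ta: int
    mode: str = "auto_otsu"          # how the saturation band was chosen
    band: tuple[int, int] = (0, 255)  # effective saturation band applied

    def __post_init__(self) -> None:
        if not 0 <= self.pa <= self.ta:
            raise ValueError(f"need 0 <= PA <= TA, got PA={self.pa}, TA={self.ta}")

    @property
    def fraction_pct(self) -> float:
        return plaque_fraction(self.pa, self.ta)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from plaque-area fraction (percent) to a full-mouth index.

    ``intercept`` is in index percent; ``slope`` in index percent per
    percent of plaque-covered area.  ``mode`` tags whether the model is
    for visible or dye-disclosed plaque.
    """

    intercept: float
    slope: float
    mode: str = "visible"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("calibration coefficients must be finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"mode": self.mode, "intercept": self.intercept, "slope": self.slope},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        data = json.loads(Path(path).read_text())
        return cls(
            intercept=float(data["intercept"]),
            slope=float(data["slope"]),
            mode=str(data.get("mode", "visible")),
        )


#: Shipped default calibrations (clinically fitted coefficients).
VISIBLE_MODEL = CalibrationModel(intercept=-7.5, slope=1.14, mode="visible")
DISCLOSED_MODEL = CalibrationModel(intercept=40.62, slope=0.44, mode="disclosed")


def apply_calibration(
    model: CalibrationModel, fraction_pct: float, clamp: bool = False
) -> float:
    """Estimated full-mouth index: ``intercept + slope * fraction_pct``.

    Unclamped by default — the visible-mode intercept is negative, so raw
    estimates near zero plaque fall below 0.  Pass ``clamp=True`` for a
    presentation value restricted to [0, 100].
    """
    value = model.intercept + model.slope * float(fraction_pct)
    if clamp:
        value = min(100.0, max(0.0, value))
    return value


def fit_calibration(
    fractions_pct: "np.typing.ArrayLike",
    indices_pct: "np.typing.ArrayLike",
    mode: str = "visible",
) -> CalibrationModel:
    """Ordinary-least-squares refit of a calibration model.

    Fits ``index = intercept + slope * fraction`` by the closed-form
    normal equations from paired (anterior plaque fraction, full-mouth
    index) observations.

    Raises
    ------
    ValueError
        For fewer than 3 pairs, mismatched lengths, or a predictor with
        zero variance.
    """
    x = np.asarray(fractions_pct, dtype=np.float64).ravel()
    y = np.asarray(indices_pct, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"paired lists must match in length: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 calibration pairs, got {x.size}")
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in plaque fractions: slope is unidentifiable")
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    return CalibrationModel(intercept=intercept, slope=slope, mode=mode)


def detect_plaque(
    hsb: np.ndarray,
    mask: np.ndarray,
    mode: str = "auto_otsu",
    band: tuple[int, int] | None = None,
    plaque_class: str = "high",
) -> tuple[np.ndarray, PlaqueMeasurement]:
    """Detect plaque pixels inside the tooth mask by saturation thresholding.

    Parameters
    ----------
    hsb : (H, W, 3) uint8 HSB raster (see :func:`selfieplaque.rgb_to_hsb`)
    mask : (H, W) boolean tooth mask defining TA
    mode : ``"auto_otsu"`` computes Otsu's threshold on the within-mask
        saturation histogram and keeps the ``plaque_class`` side
        (``"high"``: saturation above the threshold — the default, since
        plaque and disclosing dye are the high-saturation class);
        ``"fixed_band"`` keeps the supplied closed saturation ``band``,
        reproducing a manually chosen saturation window.
    band : required (low, high) saturation window for ``fixed_band`` mode.

    Returns
    -------
    (plaque_raster, measurement) : boolean raster (a subset of the mask)
    and the PA/TA measurement with the effective band recorded.

    Notes
    -----
    Hue and brightness are never constrained (their implicit band is
    [0, 255]); only saturation discriminates plaque from enamel.
    """
    hsb = np.asarray(hsb)
    mask = np.asarray(mask, dtype=bool)
    if hsb.ndim != 3 or hsb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) HSB raster, got shape {hsb.shape}")
    if hsb.shape[:2] != mask.shape:
        raise ValueError(
            f"mask dimensions {mask.shape} do not match image dimensions {hsb.shape[:2]}"
        )
    ta = int(mask.sum())
    if ta == 0:
        raise MaskError("empty tooth mask: TA = 0")

    saturation = hsb[:, :, SATURATION]
    if mode == "auto_otsu":
        if band is not None:
            raise ValueError("band is only valid in fixed_band mode")
        t = otsu_threshold(channel_histogram(saturation, mask))
        if plaque_class == "high":
            low, high = min(t + 1, 255), 255
        elif plaque_class == "low":
            low, high = 0, t
        else:
            raise ValueError(f"unknown plaque_class {plaque_class!r}; use 'high' or 'low'")
    elif mode == "fixed_band":
        if band is None:
            raise ValueError("fixed_band mode requires a (low, high) saturation band")
        low, high = int(band[0]), int(band[1])
    else:
        raise ValueError(f"unknown detection mode {mode!r}; use 'auto_otsu' or 'fixed_band'")

    plaque = apply_band_threshold(saturation, low, high, mask)
    measurement = PlaqueMeasurement(pa=int(plaque.sum()), ta=ta, mode=mode, band=(low, high))
    return plaque, measurement
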