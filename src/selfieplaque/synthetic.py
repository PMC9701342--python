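"""Synthetic smiles and cohorts with known ground truth.

Real study data for this pipeline are clinical photographs that cannot be
shipped, so every end-to-end test runs on generated inputs whose truth is
known exactly:

* :func:`generate_smile` draws a smile-like image — a row of anterior
  teeth (low-saturation enamel) on a dark oral background, with
  high-saturation plaque blobs along the cervical (gingival) margins —
  together with its tooth mask, the exact plaque raster, and the exact
  plaque-covered fraction.  The plaque pixel count is hit exactly, so the
  returned fraction is pixel-count truth, not a target.
* :func:`generate_cohort` simulates a paired clinical/selfie cohort:
  per-subject plaque fractions, full-mouth and anterior clinical indices
  generated from a known calibration plus Gaussian noise, and per-surface
  dichotomous records whose computed index reproduces the table values to
  surface-count quantization.

All randomness flows from one ``numpy`` Generator seeded by the spec, so
equal seeds give byte-identical images and tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .indices import ANTERIOR_TEETH, SURFACES, VALID_TEETH, SurfaceRecord
from .quantify import (
    DISCLOSED_MODEL,
    VISIBLE_MODEL,
    CalibrationModel,
    apply_calibration,
)

__all__ = ["SmileSpec", "CohortSpec", "SmileSample", "generate_smile", "generate_cohort"]


@dataclass(frozen=True)
class SmileSpec:
    """Parameters of one synthetic smile image.

    Defaults emulate a natural-smile photograph: six anterior teeth (four
    incisors, two canines), near-white enamel (saturation ~17/255), and a
    strongly saturated fuchsin-like plaque color (~204/255), separated by
    well over 100 saturation levels so a bimodal threshold exists.
    """

    n_teeth: int = 6
    width: int = 640
    height: int = 480
    tooth_color: tuple[int, int, int] = (230, 225, 215)
    plaque_color: tuple[int, int, int] = (200, 40, 120)
    background_color: tuple[int, int, int] = (20, 10, 10)
    target_fraction_pct: float = 25.0
    noise_sd: float = 3.0
    plaque_placement: str = "cervical"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction_pct <= 100.0:
            raise ValueError("target_fraction_pct must lie in [0, 100]")
        if self.n_teeth < 1 or self.width < 8 or self.height < 8:
            raise ValueError("need n_teeth >= 1 and at least an 8x8 canvas")
        for c in (self.tooth_color, self.plaque_color, self.background_color):
            if any(not 0 <= v <= 255 for v in c):
                raise ValueError(f"color {c} out of byte range")


class SmileSample(NamedTuple):
    image: np.ndarray        # (H, W, 3) uint8
    mask: np.ndarray         # (H, W) bool tooth mask
    plaque: np.ndarray       # (H, W) bool ground-truth plaque raster
    true_fraction_pct: float


def _teeth_mask(spec: SmileSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of per-tooth ellipses across the middle of the canvas."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    margin = 0.08 * w
    slot = (w - 2 * margin) / spec.n_teeth
    cy = 0.5 * h
    for i in range(spec.n_teeth):
        cx = margin + (i + 0.5) * slot
        ax = 0.42 * slot
        # canines (outermost teeth) drawn slightly shorter than incisors
        outer = i == 0 or i == spec.n_teeth - 1
        ay = (0.20 if outer else 0.24) * h * (1.0 + 0.05 * rng.standard_normal())
        ay = max(ay, 3.0)
        mask |= ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    return mask


def generate_smile(spec: SmileSpec) -> SmileSample:
    """Render a synthetic smile with an exactly known plaque fraction.

    The requested ``target_fraction_pct`` is converted to a pixel count
    against the generated tooth area; if no pixel count achieves the
    target within 0.5 percentage points (possible only for tiny tooth
    areas) the spec is rejected, reporting the closest achievable value.
    Plaque pixels are placed along the cervical margin of each tooth
    (where plaque accumulates clinically) with a jittered, wavy depth
    profile; ``plaque_placement="uniform"`` scatters them instead.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _teeth_mask(spec, rng)
    ta = int(mask.sum())
    if ta == 0:
        raise ValueError("degenerate spec: tooth mask is empty")

    n_plaque = int(round(spec.target_fraction_pct / 100.0 * ta))
    achievable = 100.0 * n_plaque / ta
    if abs(achievable - spec.target_fraction_pct) > 0.5:
        raise ValueError(
            f"target fraction {spec.target_fraction_pct}% unreachable at this "
            f"resolution (TA={ta} px); closest achievable is {achievable:.3f}%"
        )

    plaque = np.zeros_like(mask)
    if n_plaque > 0:
        rows, cols = np.nonzero(mask)
        if spec.plaque_placement == "cervical":
            # depth of each tooth pixel below the mask's top edge in its
            # column; jitter makes the plaque margin wavy
            top = np.full(spec.width, np.iinfo(np.int64).max, dtype=np.int64)
            np.minimum.at(top, cols, rows)
            depth = rows - top[cols]
            key = depth + 2.5 * rng.standard_normal(depth.size)
        elif spec.plaque_placement == "uniform":
            key = rng.random(rows.size)
        else:
            raise ValueError(
                f"unknown plaque_placement {spec.plaque_placement!r}; "
                "use 'cervical' or 'uniform'"
            )
        order = np.argsort(key, kind="stable")[:n_plaque]
        plaque[rows[order], cols[order]] = True

    image = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    image[:] = spec.background_color
    image[mask] = spec.tooth_color
    image[plaque] = spec.plaque_color
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return SmileSample(
        image=image,
        mask=mask,
        plaque=plaque,
        true_fraction_pct=100.0 * n_plaque / ta,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic paired clinical/selfie cohort.

    ``fraction_distribution`` gives the across-subject distribution of
    the anterior plaque-area fraction: ``("uniform", low, high)`` or
    ``("beta", a, b, scale)``, in percent.  The supplied calibrations are
    the *generative truth* linking fraction to full-mouth index; the
    clinical index is that truth plus Gaussian noise (``index_noise_sd``),
    clamped to [0, 100].  Anterior partial indices deviate from the
    full-mouth value by ``anterior_noise_sd``.  Disclosing dye reveals
    plaque that visual inspection misses, so each subject's disclosed
    fraction is the visible fraction plus a non-negative increment.
    """

    n_subjects: int = 47
    fraction_distribution: tuple = ("uniform", 0.0, 60.0)
    index_noise_sd: float = 2.0
    anterior_noise_sd: float = 5.0
    disclosed_gain_mean: float = 20.0
    disclosed_gain_sd: float = 10.0
    calibration_visible: CalibrationModel = field(default=VISIBLE_MODEL)
    calibration_disclosed: CalibrationModel = field(default=DISCLOSED_MODEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need n_subjects >= 3")


def _draw_fractions(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    kind, *params = spec.fraction_distribution
    if kind == "uniform":
        low, high = params
        f = rng.uniform(low, high, size=spec.n_subjects)
    elif kind == "beta":
        a, b, scale = params
        f = scale * rng.beta(a, b, size=spec.n_subjects)
    else:
        raise ValueError(f"unknown fraction distribution {kind!r}")
    return np.clip(f, 0.0, 100.0)


def _surface_records(
    full_pct: float,
    anterior_pct: float,
    disclosed: bool,
    rng: np.random.Generator,
) -> list[SurfaceRecord]:
    """Sample dichotomous surface records reproducing the two index values.

    Positive surfaces are allocated within anterior/posterior strata so
    that both the full-mouth and the anterior index are matched to the
    nearest achievable surface count (full dentition without third
    molars: 28 teeth x 4 surfaces = 112; anterior: 12 x 4 = 48).
    """
    anterior = sorted(ANTERIOR_TEETH)
    posterior = sorted(VALID_TEETH - ANTERIOR_TEETH)
    ant_surfaces = [(t, s) for t in anterior for s in SURFACES]
    post_surfaces = [(t, s) for t in posterior for s in SURFACES]
    n_ant, n_post = len(ant_surfaces), len(post_surfaces)
    n_total = n_ant + n_post

    k_total = int(round(full_pct / 100.0 * n_total))
    k_ant = int(round(anterior_pct / 100.0 * n_ant))
    k_ant = min(k_ant, k_total)
    k_post = k_total - k_ant
    if k_post > n_post:
        warnings.warn(
            "full-mouth and anterior index values are jointly infeasible at "
            "this surface count; posterior positives clipped",
            stacklevel=2,
        )
        k_post = n_post

    pos: set[tuple[int, str]] = set()
    idx_ant = rng.choice(n_ant, size=k_ant, replace=False)
    pos.update(ant_surfaces[i] for i in idx_ant)
    idx_post = rng.choice(n_post, size=k_post, replace=False)
    pos.update(post_surfaces[i] for i in idx_post)

    return [
        SurfaceRecord(tooth=t, surface=s, plaque_present=(t, s) in pos, disclosed=disclosed)
        for t, s in ant_surfaces + post_surfaces
    ]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, list[SurfaceRecord]]]:
    """Simulate a paired clinical/selfie cohort.

    Returns
    -------
    table : DataFrame with one row per subject and columns
        ``subject_id, fraction_pct, fraction_disclosed_pct, VPI, DPI,
        SVPI, SDPI, VPIant, DPIant`` (all index columns in percent).
        Selfie indices (SVPI/SDPI) are the noiseless calibration of the
        subject's fraction; clinical indices add observation noise.
    records : per-subject lists of :class:`SurfaceRecord` (both arms)
        whose computed indices reproduce the table columns to within
        100 / n_surfaces.
    """
    rng = np.random.default_rng(spec.seed)
    f_vis = _draw_fractions(spec, rng)
    gain = np.abs(rng.normal(spec.disclosed_gain_mean, spec.disclosed_gain_sd, spec.n_subjects))
    f_dis = np.clip(f_vis + gain, 0.0, 100.0)

    def clinical(model: CalibrationModel, frac: np.ndarray) -> np.ndarray:
        truth = model.intercept + model.slope * frac
        noisy = truth + rng.normal(0.0, spec.index_noise_sd, spec.n_subjects)
        return np.clip(noisy, 0.0, 100.0)

    vpi = clinical(spec.calibration_visible, f_vis)
    dpi = clinical(spec.calibration_disclosed, f_dis)
    svpi = np.array([apply_calibration(spec.calibration_visible, f) for f in f_vis])
    sdpi = np.array([apply_calibration(spec.calibration_disclosed, f) for f in f_dis])
    vpi_ant = np.clip(vpi + rng.normal(0.0, spec.anterior_noise_sd, spec.n_subjects), 0, 100)
    dpi_ant = np.clip(dpi + rng.normal(0.0, spec.anterior_noise_sd, spec.n_subjects), 0, 100)

    ids = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "fraction_pct": f_vis,
            "fraction_disclosed_pct": f_dis,
            "VPI": vpi,
            "DPI": dpi,
            "SVPI": svpi,
            "SDPI": sdpi,
            "VPIant": vpi_ant,
            "DPIant": dpi_ant,
        }
    )

    records: dict[str, list[SurfaceRecord]] = {}
    for i, sid in enumerate(ids):
        recs = _surface_records(vpi[i], vpi_ant[i], disclosed=False, rng=rng)
        recs += _surface_records(dpi[i], dpi_ant[i], disclosed=True, rng=rng)
        records[sid] = recs
    return table, records
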