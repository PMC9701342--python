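"""End-to-end runs: image + mask -> plaque fraction -> selfie index -> report.

A subject run executes crop -> HSB decomposition -> saturation-threshold
plaque detection -> area fraction -> calibration, and writes a
self-describing JSON report (the configuration is echoed into the report,
so re-running from it reproduces the numbers).  A cohort run maps a
manifest of subjects through the same pipeline, optionally joins clinical
surface records, and writes a Spearman correlation table over the
resulting scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import rgb_to_hsb
from .indices import compute_index, read_surface_records
from .masks import load_mask, crop_to_mask
from .quantify import (
    DISCLOSED_MODEL,
    VISIBLE_MODEL,
    CalibrationModel,
    apply_calibration,
    detect_plaque,
)
from .stats import correlation_matrix

__all__ = ["RunConfig", "SubjectReport", "run_subject", "run_cohort", "CohortReport"]

logger = logging.getLogger("selfieplaque")

EXIT_OK = 0
EXIT_PARTIAL = 1
EXIT_INPUT_ERROR = 2


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a measurement run.

    ``mode`` selects the calibration (visible vs dye-disclosed plaque);
    ``threshold_mode`` selects automatic (Otsu) or manual (fixed
    saturation band) plaque detection; ``fraction_scale`` controls
    whether the calibration consumes the percent fraction (default) or
    the unit ratio PA/TA.
    """

    mode: str = "visible"                 # visible | disclosed
    threshold_mode: str = "auto_otsu"     # auto_otsu | fixed_band
    band: tuple[int, int] | None = None   # required iff fixed_band
    plaque_class: str = "high"            # Otsu class treated as plaque
    calibration_path: str | None = None   # JSON model overriding the default
    fraction_scale: str = "percent"       # percent | unit
    output_dir: str = "."
    write_overlay: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("visible", "disclosed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold_mode == "fixed_band":
            if self.band is None:
                raise ValueError("fixed_band threshold mode requires a saturation band")
        elif self.threshold_mode == "auto_otsu":
            if self.band is not None:
                raise ValueError("band is only valid with threshold_mode='fixed_band'")
        else:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.fraction_scale not in ("percent", "unit"):
            raise ValueError(f"unknown fraction_scale {self.fraction_scale!r}")

    def calibration(self) -> CalibrationModel:
        if self.calibration_path is not None:
            return CalibrationModel.from_json(self.calibration_path)
        return VISIBLE_MODEL if self.mode == "visible" else DISCLOSED_MODEL


@dataclass(frozen=True)
class SubjectReport:
    """Per-subject measurement with full provenance."""

    subject_id: str
    image: str
    mask: str
    pa: int
    ta: int
    fraction_pct: float
    selfie_index: float           # unclamped calibration output
    selfie_index_clamped: float   # restricted to [0, 100] for presentation
    config: dict

    def to_json_dict(self) -> dict:
        return asdict(self)


def _load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def run_subject(
    image_path: str | Path,
    mask_path: str | Path,
    config: RunConfig,
    subject_id: str | None = None,
    write_report: bool = True,
) -> SubjectReport:
    """Measure one subject's smile image against its tooth mask.

    Writes ``<subject_id>.report.json`` (and, if configured, an overlay
    PNG with detected plaque pixels rendered black) into the configured
    output directory.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    sid = subject_id or image_path.stem
    image = _load_image(image_path)
    mask = load_mask(mask_path, expected_dims=image.shape[:2])
    cropped, cropped_mask = crop_to_mask(image, mask)
    hsb = rgb_to_hsb(cropped)
    plaque, meas = detect_plaque(
        hsb,
        cropped_mask,
        mode=config.threshold_mode,
        band=config.band,
        plaque_class=config.plaque_class,
    )
    fraction = meas.fraction_pct
    model = config.calibration()
    scale = fraction if config.fraction_scale == "percent" else fraction / 100.0
    index = apply_calibration(model, scale)
    report = SubjectReport(
        subject_id=sid,
        image=str(image_path),
        mask=str(mask_path),
        pa=meas.pa,
        ta=meas.ta,
        fraction_pct=fraction,
        selfie_index=index,
        selfie_index_clamped=min(100.0, max(0.0, index)),
        config={**asdict(config), "effective_band": list(meas.band),
                "calibration": {"mode": model.mode, "intercept": model.intercept,
                                "slope": model.slope}},
    )
    if write_report:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{sid}.report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2) + "\n"
        )
        if config.write_overlay:
            overlay = cropped.copy()
            overlay[plaque] = 0  # detected plaque in black
            Image.fromarray(overlay).save(out / f"{sid}.overlay.png")
    return report


@dataclass(frozen=True)
class CohortReport:
    reports: list
    skipped: list            # (subject_id, error message)
    scores: pd.DataFrame     # per-subject score table
    correlations: "pd.DataFrame | None"


def run_cohort(
    manifest_csv: str | Path,
    config: RunConfig,
    records_csv: str | Path | None = None,
) -> CohortReport:
    """Run the pipeline over a manifest of subjects and correlate scores.

    The manifest CSV needs columns ``subject_id, image, mask`` (paths
    relative to the manifest's directory or absolute).  If a per-surface
    records CSV is supplied, clinical indices (full-mouth and anterior)
    are computed per subject and included in the correlation table.
    Failures on individual subjects are logged and skipped; only a run
    with zero successes is an error.
    """
    manifest_csv = Path(manifest_csv)
    manifest = pd.read_csv(manifest_csv, dtype=str)
    for col in ("subject_id", "image", "mask"):
        if col not in manifest.columns:
            raise ValueError(f"manifest {manifest_csv} missing column {col!r}")
    base = manifest_csv.parent

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    reports, skipped = [], []
    for row in manifest.itertuples(index=False):
        try:
            reports.append(
                run_subject(resolve(row.image), resolve(row.mask), config,
                            subject_id=row.subject_id)
            )
        except Exception as exc:
            logger.warning("skipping subject %s: %s", row.subject_id, exc)
            skipped.append((row.subject_id, str(exc)))
    if not reports:
        raise ValueError("all subjects failed; nothing to report")

    index_name = "SVPI" if config.mode == "visible" else "SDPI"
    scores = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reports],
            "fraction_pct": [r.fraction_pct for r in reports],
            index_name: [r.selfie_index for r in reports],
        }
    )

    if records_csv is not None:
        clinical_name = "VPI" if config.mode == "visible" else "DPI"
        disclosed = config.mode == "disclosed"
        by_subject = read_surface_records(records_csv)
        full, ant = [], []
        for sid in scores["subject_id"]:
            recs = by_subject.get(sid)
            if recs is None:
                full.append(np.nan)
                ant.append(np.nan)
                continue
            full.append(compute_index(recs, disclosed=disclosed).value_pct)
            ant.append(compute_index(recs, disclosed=disclosed, scope="anterior").value_pct)
        scores[clinical_name] = full
        scores[clinical_name + "ant"] = ant

    numeric = scores.drop(columns="subject_id").dropna()
    correlations = None
    if len(numeric) >= 3 and numeric.shape[1] >= 2:
        try:
            correlations = correlation_matrix(numeric).rho
        except ValueError as exc:
            logger.warning("correlation matrix unavailable: %s", exc)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "cohort_scores.csv", index=False)
    if correlations is not None:
        correlations.to_csv(out / "cohort_correlations.csv")
        (out / "cohort_correlations.json").write_text(
            json.dumps(correlations.round(10).to_dict(), indent=2) + "\n"
        )
    (out / "cohort_summary.json").write_text(
        json.dumps(
            {
                "n_subjects": len(reports),
                "n_skipped": len(skipped),
                "skipped": [{"subject_id": s, "error": e} for s, e in skipped],
                "config": asdict(config),
            },
            indent=2,
        )
        + "\n"
    )
    return CohortReport(reports=reports, skipped=skipped, scores=scores,
                        correlations=correlations)
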