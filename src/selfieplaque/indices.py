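"""Clinical plaque indices from per-surface dichotomous records.

Two reference indices are supported, both defined as the percentage of
examined tooth surfaces scored positive for plaque:

* **VPI** (Visible Plaque Index, Ainamo & Bay): presence/absence of
  plaque by visual examination, no staining (``disclosed=False``).
* **DPI** (O'Leary disclosed index): presence/absence after a disclosing
  dye is applied (``disclosed=True``).

Teeth are identified by FDI two-digit codes; third molars (18, 28, 38,
48) are excluded.  Four surfaces per tooth (buccal, lingual, mesial,
distal — the O'Leary convention) is assumed uniformly for both indices so
they are comparable; missing teeth simply contribute no records, and the
denominator is always the observed surface count.  Anterior-only partial
indices (VPIant / DPIant) restrict to the twelve incisors and canines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceRecord",
    "ClinicalIndexResult",
    "ANTERIOR_TEETH",
    "SURFACES",
    "VALID_TEETH",
    "compute_index",
    "anterior_subset",
    "mean_index_difference",
    "read_surface_records",
    "write_surface_records",
]

SURFACES = ("buccal", "lingual", "mesial", "distal")

#: FDI codes of the twelve anterior teeth (incisors and canines).
ANTERIOR_TEETH = frozenset({13, 12, 11, 21, 22, 23, 33, 32, 31, 41, 42, 43})

#: All scoreable FDI codes: quadrants 1-4, positions 1-7 (no third molars).
VALID_TEETH = frozenset(10 * q + p for q in (1, 2, 3, 4) for p in range(1, 8))


@dataclass(frozen=True)
class SurfaceRecord:
    """One dichotomous plaque observation on one tooth surface."""

    tooth: int                 # FDI two-digit code, third molars excluded
    surface: str               # buccal / lingual / mesial / distal
    plaque_present: bool
    disclosed: bool            # observed after disclosing solution?

    def __post_init__(self) -> None:
        if self.tooth not in VALID_TEETH:
            raise ValueError(
                f"invalid FDI tooth code {self.tooth} (third molars excluded)"
            )
        if self.surface not in SURFACES:
            raise ValueError(f"invalid surface {self.surface!r}; expected one of {SURFACES}")


@dataclass(frozen=True)
class ClinicalIndexResult:
    """Percent of examined surfaces positive for plaque."""

    value_pct: float
    n_surfaces: int
    scope: str  # "full_mouth" or "anterior"


def anterior_subset(records: Iterable[SurfaceRecord]) -> list[SurfaceRecord]:
    """Records restricted to the twelve anterior teeth, order preserved."""
    return [r for r in records if r.tooth in ANTERIOR_TEETH]


def compute_index(
    records: Iterable[SurfaceRecord],
    disclosed: bool,
    scope: str = "full_mouth",
) -> ClinicalIndexResult:
    """Plaque index: percent of matching surfaces with plaque present.

    ``disclosed=False`` computes the VPI, ``disclosed=True`` the O'Leary
    DPI.  ``scope="anterior"`` restricts to the twelve anterior teeth.
    Duplicate (tooth, surface) pairs within the selected observations are
    rejected; integer arithmetic is used up to the final division, so the
    result is exactly ``100 * positives / n_surfaces``.
    """
    if scope not in ("full_mouth", "anterior"):
        raise ValueError(f"unknown scope {scope!r}; use 'full_mouth' or 'anterior'")
    selected = [r for r in records if r.disclosed == disclosed]
    if scope == "anterior":
        selected = anterior_subset(selected)
    if not selected:
        raise ValueError(
            f"no surface records match disclosed={disclosed}, scope={scope!r}"
        )
    keys = [(r.tooth, r.surface) for r in selected]
    if len(set(keys)) != len(keys):
        seen: set[tuple[int, str]] = set()
        dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate surface record for tooth {dup[0]}, {dup[1]} surface")
    positives = sum(r.plaque_present for r in selected)
    n = len(selected)
    return ClinicalIndexResult(value_pct=100.0 * positives / n, n_surfaces=n, scope=scope)


def mean_index_difference(
    index_a: Sequence[float], index_b: Sequence[float]
) -> float:
    """Mean of pairwise differences ``b - a`` between two paired index lists."""
    a = np.asarray(index_a, dtype=np.float64)
    b = np.asarray(index_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired lists must match in length: {a.size} vs {b.size}")
    return float(np.mean(b - a))


# -- CSV interchange ---------------------------------------------------------
# Columns: subject_id, tooth (FDI), surface, plaque_present (0/1),
# disclosed (0/1).  Strict header, comma-separated, UTF-8.

_COLUMNS = ["subject_id", "tooth", "surface", "plaque_present", "disclosed"]


def read_surface_records(path: str | Path) -> dict[str, list[SurfaceRecord]]:
    """Read per-surface records grouped by subject from a CSV file."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"surface-record CSV {path} missing columns: {missing}")
    out: dict[str, list[SurfaceRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            SurfaceRecord(
                tooth=int(row.tooth),
                surface=str(row.surface),
                plaque_present=bool(int(row.plaque_present)),
                disclosed=bool(int(row.disclosed)),
            )
        )
    return out


def write_surface_records(
    records_by_subject: dict[str, Iterable[SurfaceRecord]], path: str | Path
) -> None:
    """Write per-surface records for several subjects to CSV."""
    rows = [
        {
            "subject_id": sid,
            "tooth": r.tooth,
            "surface": r.surface,
            "plaque_present": int(r.plaque_present),
            "disclosed": int(r.disclosed),
        }
        for sid, recs in records_by_subject.items()
        for r in recs
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
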