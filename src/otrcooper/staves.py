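"""Stave records, populations, OTR class labelling, and CSV I/O.

A stave is one shaped oak board destined either for the curved barrel wall
(``part="body"``) or for one of the two flat circular ends (``part="head"``).
Each stave carries its geometry in millimetres and its oxygen transmission
rate (OTR) in hPa/h — the rate of oxygen partial-pressure change measured
through the wood, which is the quantity the selection methods optimize.
"Grain" (the width of the annual growth ring, mm) is carried as metadata
only; it never enters any computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PART_HEAD = "head"
PART_BODY = "body"
PARTS = (PART_HEAD, PART_BODY)

#: CSV columns of the stave interchange format.
REQUIRED_COLUMNS = ("id", "part", "width_mm", "length_mm", "otr_hpa_h")
OPTIONAL_COLUMNS = ("grain_mm", "otr_class")


@dataclass
class Stave:
    """One piece of oak wood.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a population.
    part : {"head", "body"}
        Which barrel element the stave is shaped for.
    width, length : float
        Millimetres, strictly positive.
    otr : float
        Oxygen transmission rate in hPa/h, non-negative.
    grain : float, optional
        Annual-ring width in mm; metadata only.
    otr_class : {"L", "M", "H"}, optional
        Low/mid/high OTR class label, derived via :func:`classify_stave`.
    """

    id: str
    part: str
    width: float
    length: float
    otr: float
    grain: float | None = None
    otr_class: str | None = None

    def __post_init__(self):
        if self.part not in PARTS:
            raise ValueError(f"unknown stave part {self.part!r}; expected one of {PARTS}")
        if not (self.width > 0 and math.isfinite(self.width)):
            raise ValueError(f"stave {self.id!r}: width must be finite and > 0, got {self.width}")
        if not (self.length > 0 and math.isfinite(self.length)):
            raise ValueError(f"stave {self.id!r}: length must be finite and > 0, got {self.length}")
        if not (self.otr >= 0 and math.isfinite(self.otr)):
            raise ValueError(f"stave {self.id!r}: otr must be finite and >= 0, got {self.otr}")
        if self.otr_class is not None and self.otr_class not in ("L", "M", "H"):
            raise ValueError(f"stave {self.id!r}: otr_class must be L, M or H, got {self.otr_class!r}")


@dataclass(frozen=True)
class ClassThresholds:
    """Per-part (low, high) OTR thresholds splitting staves into L/M/H classes."""

    body_low_high: tuple[float, float]
    head_low_high: tuple[float, float]

    def __post_init__(self):
        for name, (low, high) in (("body", self.body_low_high), ("head", self.head_low_high)):
            if not low < high:
                raise ValueError(f"{name} thresholds must satisfy low < high, got ({low}, {high})")

    def for_part(self, part: str) -> tuple[float, float]:
        if part == PART_BODY:
            return self.body_low_high
        if part == PART_HEAD:
            return self.head_low_high
        raise ValueError(f"unknown part {part!r}")


#: Thresholds used to preclassify the cooperage staves into low/mid/high OTR
#: groups: 0.0157 and 0.0396 hPa/h for body staves, 0.0230 and 0.0434 hPa/h
#: for head staves.
DEFAULT_THRESHOLDS = ClassThresholds(body_low_high=(0.0157, 0.0396), head_low_high=(0.0230, 0.0434))


def classify_stave(stave: Stave, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> str:
    """Return the OTR class of a stave: "L", "M" or "H".

    Values exactly equal to a threshold fall in the middle class, so that
    "low" and "high" remain strict.
    """
    low, high = thresholds.for_part(stave.part)
    if stave.otr < low:
        return "L"
    if stave.otr > high:
        return "H"
    return "M"


def assign_classes(staves: Iterable[Stave], thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> list[Stave]:
    """Return copies of *staves* with ``otr_class`` filled in from *thresholds*."""
    return [replace(s, otr_class=classify_stave(s, thresholds)) for s in staves]


def _check_unique_ids(staves: Sequence[Stave]) -> None:
    seen: set[str] = set()
    for s in staves:
        if s.id in seen:
            raise ValueError(f"duplicate stave id {s.id!r} in population")
        seen.add(s.id)


def read_staves(path: str | Path) -> list[Stave]:
    """Read a stave population from the standard CSV format.

    The file must have columns ``id,part,width_mm,length_mm,otr_hpa_h``;
    ``grain_mm`` and ``otr_class`` are optional. Duplicate ids are rejected.
    """
    df = pd.read_csv(path, dtype={"id": str, "part": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("width_mm", "length_mm", "otr_hpa_h") + tuple(c for c in ("grain_mm",) if c in df.columns):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col!r} contains non-numeric values") from exc
    staves = []
    for row in df.itertuples(index=False):
        grain = getattr(row, "grain_mm", None)
        if grain is not None and (isinstance(grain, float) and math.isnan(grain)):
            grain = None
        otr_class = getattr(row, "otr_class", None)
        if isinstance(otr_class, float) and math.isnan(otr_class):
            otr_class = None
        staves.append(
            Stave(
                id=str(row.id),
                part=str(row.part),
                width=float(row.width_mm),
                length=float(row.length_mm),
                otr=float(row.otr_hpa_h),
                grain=None if grain is None else float(grain),
                otr_class=otr_class,
            )
        )
    _check_unique_ids(staves)
    return staves


def write_staves(staves: Sequence[Stave], path: str | Path) -> None:
    """Write a stave population to the standard CSV format (UTF-8, decimal point).

    Floats are written with ``repr`` round-trip precision so that
    read/write cycles preserve every field exactly.
    """
    _check_unique_ids(staves)
    data: dict[str, list] = {
        "id": [s.id for s in staves],
        "part": [s.part for s in staves],
        "width_mm": [repr(s.width) for s in staves],
        "length_mm": [repr(s.length) for s in staves],
        "otr_hpa_h": [repr(s.otr) for s in staves],
    }
    if any(s.grain is not None for s in staves):
        data["grain_mm"] = ["" if s.grain is None else repr(s.grain) for s in staves]
    if any(s.otr_class is not None for s in staves):
        data["otr_class"] = [s.otr_class for s in staves]
    pd.DataFrame(data).to_csv(path, index=False, encoding="utf-8")


def population_summary(staves: Sequence[Stave]) -> dict:
    """Summary statistics per part: count and mean/sd/min/max of otr, width, length.

    The mean OTR is the plain unweighted stave mean (the quantity the
    homogenization targets are defined on). Standard deviations are
    population deviations (ddof=0), so a single stave has sd 0.
    """
    if not staves:
        raise ValueError("cannot summarize an empty population")
    out: dict[str, dict] = {}
    for part in PARTS:
        sub = [s for s in staves if s.part == part]
        if not sub:
            continue
        entry: dict = {"count": len(sub)}
        for feature, getter in (("otr", lambda s: s.otr), ("width", lambda s: s.width), ("length", lambda s: s.length)):
            vals = np.array([getter(s) for s in sub], dtype=float)
            entry[feature] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        out[part] = entry
    return out
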