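"""Encapsulation-efficiency, plate-count and digestion-timeline arithmetic.

Covers the viability bookkeeping around an in vitro (INFOGEST-style)
gastrointestinal digestion: %EE = 100 * Wt/Wi, CFU/mL back-calculation
from Miles-Misra microdrop serial-dilution counts, percent survival on a
linear or log10 scale, and the oral/gastric/intestinal phase timeline
used to label kinetic samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "EfficiencyRecord",
    "PlateCount",
    "Phase",
    "PhaseTimeline",
    "DEFAULT_TIMELINE",
    "encapsulation_efficiency",
    "cfu_from_plate_count",
    "survival_percent",
    "label_phases",
]


@dataclass(frozen=True)
class EfficiencyRecord:
    """Initial load Wi, detected load Wt (CFU) and the resulting %EE."""

    w_initial: float
    w_detected: float
    ee_pct: float


@dataclass(frozen=True)
class PlateCount:
    """Colonies counted on one plated aliquot of a serial dilution."""

    colonies: int
    dilution_exponent: int  # the aliquot came from a 10**-e dilution
    plated_volume_ml: float = 0.01  # Miles-Misra microdrop

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")


@dataclass(frozen=True)
class Phase:
    name: str
    start_min: float
    end_min: float
    ph: float


@dataclass(frozen=True)
class PhaseTimeline:
    """Contiguous, ordered digestion phases; intervals are half-open
    ``[start, end)`` except the final endpoint, which is inclusive."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("timeline needs at least one phase")
        prev_end = None
        for p in self.phases:
            if p.end_min <= p.start_min:
                raise ValueError(f"phase {p.name} has nonpositive duration")
            if prev_end is not None and p.start_min != prev_end:
                raise ValueError("phases must be contiguous and ordered")
            prev_end = p.end_min

    @property
    def end_min(self) -> float:
        return self.phases[-1].end_min

    def label(self, t: float) -> str:
        if t < self.phases[0].start_min or t > self.end_min:
            raise ValueError(f"time {t} outside timeline [0, {self.end_min}]")
        for p in self.phases:
            if p.start_min <= t < p.end_min:
                return p.name
        return self.phases[-1].name  # inclusive final endpoint

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"name": p.name, "start_min": p.start_min, "end_min": p.end_min, "ph": p.ph}
                    for p in self.phases
                ],
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "PhaseTimeline":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(tuple(Phase(p["name"], p["start_min"], p["end_min"], p["ph"]) for p in raw))


#: oral 2 min (pH 7), gastric 2 h (pH 3), intestinal 2 h (pH 7); the
#: intestinal phase is extended to 250 min so the full sampling schedule
#: (which outlasts the 242-min protocol) gets a label.
DEFAULT_TIMELINE = PhaseTimeline(
    (
        Phase("oral", 0.0, 2.0, 7.0),
        Phase("gastric", 2.0, 122.0, 3.0),
        Phase("intestinal", 122.0, 250.0, 7.0),
    )
)


def encapsulation_efficiency(w_detected: float, w_initial: float) -> EfficiencyRecord:
    """%EE = 100 * Wt / Wi."""
    if w_initial <= 0:
        raise ValueError("initial load Wi must be positive")
    if w_detected < 0:
        raise ValueError("detected load Wt must be >= 0")
    return EfficiencyRecord(w_initial, w_detected, 100.0 * w_detected / w_initial)


def cfu_from_plate_count(pc: PlateCount) -> float:
    """CFU/mL = colonies / plated volume * 10**dilution_exponent."""
    return pc.colonies / pc.plated_volume_ml * 10.0**pc.dilution_exponent


def survival_percent(
    final: float, initial: float, scale: Literal["linear", "log10"] = "log10"
) -> float:
    """Percent survival; log10 scale is the CFU convention
    (100 * log10(final) / log10(initial))."""
    if final <= 0 or initial <= 0:
        raise ValueError("CFU values must be positive")
    if scale == "linear":
        return 100.0 * final / initial
    if scale == "log10":
        return 100.0 * np.log10(final) / np.log10(initial)
    raise ValueError(f"unknown scale: {scale!r}")


def label_phases(times: Iterable[float], timeline: PhaseTimeline = DEFAULT_TIMELINE) -> np.ndarray:
    """Phase label for every sampling time."""
    return np.array([timeline.label(float(t)) for t in times], dtype=object)
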