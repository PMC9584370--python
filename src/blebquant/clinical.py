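"""Per-patient clinical classifiers: visual-field loss and duction limits.

Visual-field severity follows the Hodapp-Parrish-Anderson banding of the
perimetric mean deviation (MD, dB): mild above −6 dB, moderate down to
−12 dB, severe below.  MD values exactly on a band edge are assigned to
the worse category.

Ocular motility is assessed over eight ductions measured on a Goldmann
perimeter; a direction counts as significantly restricted when at least
10° of excursion is lost relative to the normal adult reference — a
threshold reflecting the repeatability of the measurement and
age-related decline.  The reference excursions ship as an editable CSV
(``data/normative_ductions.csv``); they are a configuration convention,
not a measured property of any cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np

from .errors import IncompleteDataError, ParameterError

__all__ = [
    "DIRECTIONS",
    "DuctionSet",
    "classify_vf",
    "load_normative_ductions",
    "restricted_ductions",
    "restriction_total",
]

#: The eight Goldmann-perimeter duction directions.
DIRECTIONS: Tuple[str, ...] = (
    "elevation",
    "depression",
    "adduction",
    "abduction",
    "elevation_in_abduction",
    "elevation_in_adduction",
    "depression_in_abduction",
    "depression_in_adduction",
)

#: Minimum loss of excursion (degrees) that counts as restricted.
RESTRICTION_THRESHOLD = 10.0


def load_normative_ductions() -> Dict[str, float]:
    """Normal adult duction excursions (degrees) from the packaged table."""
    ref: Dict[str, float] = {}
    with resources.files("blebquant.data").joinpath("normative_ductions.csv").open() as fh:
        for row in csv.DictReader(fh):
            ref[row["direction"]] = float(row["degrees"])
    missing = set(DIRECTIONS) - set(ref)
    if missing:
        raise IncompleteDataError(f"normative table lacks directions: {sorted(missing)}")
    return ref


@dataclass
class DuctionSet:
    """Measured ductions (degrees) with their normative reference."""

    measured: Dict[str, float]
    reference: Dict[str, float] = field(default_factory=load_normative_ductions)

    def __post_init__(self) -> None:
        for d, v in self.measured.items():
            if not 0 <= v <= 120:
                raise ParameterError(f"duction '{d}' = {v}° outside [0, 120]°")
        for d, v in self.reference.items():
            if v <= 0:
                raise ParameterError(f"reference duction '{d}' must be positive")


def classify_vf(md: float) -> str:
    """Hodapp-Parrish-Anderson visual-field loss category from MD (dB).

    Returns ``"mild"`` (MD > −6), ``"moderate"`` (−12 < MD ≤ −6) or
    ``"severe"`` (MD ≤ −12); band-edge values take the worse category.
    """
    md = float(md)
    if not np.isfinite(md):
        raise ParameterError(f"MD must be finite, got {md}")
    if md > -6:
        return "mild"
    if md > -12:
        return "moderate"
    return "severe"


def restricted_ductions(d: DuctionSet) -> Tuple[bool, List[str]]:
    """Flag directions with at least 10° of lost excursion.

    Returns ``(any_restricted, flagged_directions)``; every restricted
    direction is reported, in the canonical direction order.

    Raises
    ------
    IncompleteDataError
        naming the first missing direction.
    """
    flagged = []
    for direction in DIRECTIONS:
        if direction not in d.measured:
            raise IncompleteDataError(f"missing duction measurement: '{direction}'")
        if direction not in d.reference:
            raise IncompleteDataError(f"missing normative reference: '{direction}'")
        if d.reference[direction] - d.measured[direction] >= RESTRICTION_THRESHOLD:
            flagged.append(direction)
    return bool(flagged), flagged


def restriction_total(d: DuctionSet) -> float:
    """Total motility restriction: degrees lost summed over flagged directions.

    This is the scalar used when correlating overall restriction with
    morphometry; summing only over flagged directions keeps sub-threshold
    measurement noise out of the total.
    """
    _, flagged = restricted_ductions(d)
    return float(sum(d.reference[x] - d.measured[x] for x in flagged))
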