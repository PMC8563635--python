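"""The four-band age grouping used throughout the model.

Age is grouped into 0-14, 15-39, 40-64 and 65+ years: childhood (where
registry data are richest), younger adulthood, middle age and older age.
Bands are half-open integer-year intervals [0,15), [15,40), [40,65),
[65,cap); the open-ended band is capped (default 99 years) so that
person-year arithmetic stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_CAP_AGE: float = 99.0


@dataclass(frozen=True)
class AgeBand:
    """One age band: half-open interval [start, end); ``end is None`` = open-ended."""

    label: str
    start: float
    end: float | None

    def end_age(self, cap_age: float = DEFAULT_CAP_AGE) -> float:
        return cap_age if self.end is None else self.end

    def contains(self, age: float, cap_age: float = DEFAULT_CAP_AGE) -> bool:
        return self.start <= age < self.end_age(cap_age)


#: Fixed, totally ordered band set; order is load-bearing everywhere.
BANDS: tuple[AgeBand, ...] = (
    AgeBand("0-14", 0.0, 15.0),
    AgeBand("15-39", 15.0, 40.0),
    AgeBand("40-64", 40.0, 65.0),
    AgeBand("65+", 65.0, None),
)

BAND_LABELS: tuple[str, ...] = tuple(b.label for b in BANDS)
N_BANDS: int = len(BANDS)

_LABEL_TO_INDEX = {b.label: i for i, b in enumerate(BANDS)}


def band_index(label: str) -> int:
    """Index of a band by label; raises KeyError for unknown labels."""
    return _LABEL_TO_INDEX[label]


def band_edges(cap_age: float = DEFAULT_CAP_AGE) -> list[float]:
    """Band boundary ages [0, 15, 40, 65, cap_age]."""
    if cap_age <= BANDS[-1].start:
        raise ValueError(f"cap_age must exceed {BANDS[-1].start}, got {cap_age}")
    return [b.start for b in BANDS] + [cap_age]


def band_of_age(age: float, cap_age: float = DEFAULT_CAP_AGE) -> int:
    """Band index containing an attained age; ages at/above cap fall in the last band."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    for i, b in enumerate(BANDS):
        if b.contains(age, cap_age):
            return i
    return N_BANDS - 1
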