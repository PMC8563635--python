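"""Extrapolate childhood incidence to adult bands and convert rates to counts.

Adult type 1 diabetes incidence is poorly observed globally, so adult-band
rates are obtained by scaling the childhood (0-14 y) rate with fixed
ratios. The core ratio set (1.00 / 0.50 / 0.30 / 0.25, derived from Danish
registry data) is the default; an alternative set (1.00 / 0.57 / 0.28 /
0.19, from a large Chinese population study) ships as the "china" preset
for sensitivity work. Scaled rates applied to band populations give
incident case numbers stratified by onset age; counts are carried as real
numbers and only rounded at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_LABELS, N_BANDS
from .errors import StructuralError


@dataclass(frozen=True)
class ScalingRatios:
    """Incidence-rate ratios of each band relative to childhood (band 0 == 1)."""

    values: tuple[float, ...] = (1.00, 0.50, 0.30, 0.25)
    name: str = "core"

    def __post_init__(self) -> None:
        if len(self.values) != N_BANDS:
            raise StructuralError(
                f"expected {N_BANDS} ratios, got {len(self.values)}"
            )
        if self.values[0] != 1.0:
            raise ValueError(f"childhood ratio must be exactly 1.0, got {self.values[0]}")
        if any(v < 0 for v in self.values):
            raise ValueError(f"ratios must be >= 0, got {self.values}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


RATIO_PRESETS: dict[str, ScalingRatios] = {
    "core": ScalingRatios((1.00, 0.50, 0.30, 0.25), name="core"),
    "china": ScalingRatios((1.00, 0.57, 0.28, 0.19), name="china"),
}


def get_ratio_preset(name: str) -> ScalingRatios:
    try:
        return RATIO_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown ratio preset {name!r}; known: {sorted(RATIO_PRESETS)}"
        ) from None


def scale_incidence_rates(
    childhood_rate: float, ratios: ScalingRatios | None = None
) -> np.ndarray:
    """Age-specific rates per 100,000 person-years: rate(band) = childhood × ratio(band)."""
    if childhood_rate < 0:
        raise ValueError(f"childhood rate must be >= 0, got {childhood_rate}")
    ratios = ratios or RATIO_PRESETS["core"]
    return childhood_rate * ratios.as_array()


def compute_incident_cases(rates: np.ndarray, population: np.ndarray) -> np.ndarray:
    """Incident cases per year per band: rate × population / 100,000.

    Linear in both arguments; fractional counts are deliberate.
    """
    rates = np.asarray(rates, dtype=float)
    population = np.asarray(population, dtype=float)
    if rates.shape != (N_BANDS,) or population.shape != (N_BANDS,):
        raise StructuralError(
            f"rates and population must both have shape ({N_BANDS},); "
            f"got {rates.shape} and {population.shape}"
        )
    if (rates < 0).any() or (population < 0).any():
        raise ValueError("rates and population must be non-negative")
    return rates * population / 1e5
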