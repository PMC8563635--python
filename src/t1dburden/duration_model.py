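"""Child-mortality penalty and penalty-adjusted mean disease duration.

Mean remaining lifetime with type 1 diabetes depends heavily on access to
insulin and care. The model captures this with a single country-level
scalar: the penalty Pen = CM / 130, where CM is the under-5 child mortality
rate per 1000 live births and 130 sits just above the highest national CM
observed in the reference year. Mean duration for an onset band is then

    D(band) = max( max_duration(band) × (1 − Pen), min_duration )

with band maxima 60.4 / 43.4 / 21.1 / 8.5 years (remaining life expectancy
from onset under optimal, Danish-level care) and a global floor of 0.5
years reflecting very short survival where insulin access is severely
limited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import BAND_LABELS, N_BANDS, band_index

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DurationParams:
    """Global maxima per onset band, duration floor, and the penalty constant."""

    max_duration: tuple[float, ...] = (60.4, 43.4, 21.1, 8.5)
    min_duration: float = 0.5
    penalty_constant: float = 130.0

    def __post_init__(self) -> None:
        if len(self.max_duration) != N_BANDS:
            raise ValueError(f"need {N_BANDS} maxima, got {len(self.max_duration)}")
        if any(d <= 0 for d in self.max_duration):
            raise ValueError(f"max durations must be > 0, got {self.max_duration}")
        if any(a <= b for a, b in zip(self.max_duration, self.max_duration[1:])):
            raise ValueError(
                "max duration must strictly decrease with onset band, "
                f"got {self.max_duration}"
            )
        if self.min_duration < 0:
            raise ValueError(f"min_duration must be >= 0, got {self.min_duration}")
        if self.penalty_constant <= 0:
            raise ValueError(
                f"penalty_constant must be > 0, got {self.penalty_constant}"
            )

    def max_as_array(self) -> np.ndarray:
        return np.asarray(self.max_duration, dtype=float)


def penalty(cm: float, params: DurationParams | None = None) -> float:
    """Pen = CM / penalty_constant, clamped to 1 for out-of-era CM values.

    The constant was chosen just above the highest observed CM, so the clamp
    only fires on inputs outside that era; it logs rather than errors so the
    model degrades gracefully under synthetic stress inputs.
    """
    params = params or DurationParams()
    if cm < 0:
        raise ValueError(f"cm must be >= 0, got {cm}")
    pen = cm / params.penalty_constant
    if pen > 1.0:
        logger.warning(
            "CM %.1f exceeds penalty constant %.0f; clamping Pen to 1",
            cm,
            params.penalty_constant,
        )
        pen = 1.0
    return pen


def mean_duration(
    onset_band: str | int, pen: float, params: DurationParams | None = None
) -> float:
    """Penalty-adjusted mean duration (years) for one onset band."""
    params = params or DurationParams()
    if not 0.0 <= pen <= 1.0:
        raise ValueError(f"pen must lie in [0, 1], got {pen}")
    g = band_index(onset_band) if isinstance(onset_band, str) else int(onset_band)
    return max(params.max_duration[g] * (1.0 - pen), params.min_duration)


def mean_durations(pen: float, params: DurationParams | None = None) -> np.ndarray:
    """Vector of penalty-adjusted mean durations across all onset bands."""
    params = params or DurationParams()
    if not 0.0 <= pen <= 1.0:
        raise ValueError(f"pen must lie in [0, 1], got {pen}")
    return np.maximum(params.max_as_array() * (1.0 - pen), params.min_duration)
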