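"""Steady-state prevalence by onset age and its allocation to attained age.

Under epidemiological steady state (annual new cases equal annual deaths
among cases) prevalence factorises as P = I × D: prevalent cases in an
onset band are incident cases per year times mean disease duration.

A prevalent person belongs to one onset band forever but moves through
attained-age bands as they age. The allocation step distributes each onset
band's prevalent pool over attained bands in proportion to the expected
person-years an incident case spends in each band, computed from a
cumulative-survival schedule: S(onset → end of band b) for each band at or
after onset. Between schedule knots survival is interpolated linearly; if
the schedule gives no value at the cap age, survival falls linearly to
zero there, and a knot at the cap age truncates (everyone alive at cap
dies there). Person-years per band are trapezoidal integrals of this
piecewise-linear curve.

``simulate_steady_state`` is an independent discrete-time cohort
bookkeeping of the same process, used to validate the analytic identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .bands import BAND_LABELS, BANDS, DEFAULT_CAP_AGE, N_BANDS, band_edges, band_of_age
from .errors import StructuralError, ValidationError

#: Mean onset ages within each band (years). Within-band placement only
#: affects the onset band's own person-year overlap, not totals.
DEFAULT_MEAN_ONSET_AGES: tuple[float, ...] = (7.5, 27.0, 52.0, 72.0)


@dataclass(frozen=True)
class SurvivalSchedule:
    """Mean onset age and cumulative survival knots per onset band.

    ``knots[g]`` is a sorted tuple of ``(age, S)`` pairs with ages strictly
    inside ``(mean_onset_age[g], cap_age]``; S is cumulative survival from
    onset (S at onset is implicitly 1). The minimal schedule carries knots
    at the ends of each closed band; extra knots (e.g. 5-year steps inside
    the open 65+ band, or a value at cap_age) refine the curve.
    """

    mean_onset_age: tuple[float, ...] = DEFAULT_MEAN_ONSET_AGES
    knots: tuple[tuple[tuple[float, float], ...], ...] = (
        (),
        (),
        (),
        (),
    )
    cap_age: float = DEFAULT_CAP_AGE

    def __post_init__(self) -> None:
        if len(self.mean_onset_age) != N_BANDS or len(self.knots) != N_BANDS:
            raise StructuralError(f"schedule needs {N_BANDS} onset bands")
        for g, (a, band) in enumerate(zip(self.mean_onset_age, BANDS)):
            if not band.start <= a < band.end_age(self.cap_age):
                raise ValidationError(
                    f"mean onset age {a} outside band {band.label}"
                )
            prev_age, prev_s = a, 1.0
            for age, s in self.knots[g]:
                if age <= prev_age or age > self.cap_age:
                    raise ValidationError(
                        f"onset band {band.label}: knot ages must increase within "
                        f"({a}, {self.cap_age}], got {age}"
                    )
                if not 0.0 <= s <= prev_s + 1e-12:
                    raise ValidationError(
                        f"onset band {band.label}: cumulative survival must be "
                        f"non-increasing in [0, 1], got S({age})={s} after {prev_s}"
                    )
                prev_age, prev_s = age, s

    # -- piecewise-linear survival curve ------------------------------------

    def curve_points(self, g: int) -> tuple[np.ndarray, np.ndarray]:
        """Knot ages and S values for onset band g, with (onset, 1) prepended
        and, if no knot sits at cap_age, (cap_age, 0) appended."""
        a = self.mean_onset_age[g]
        ages = [a] + [k[0] for k in self.knots[g]]
        svals = [1.0] + [k[1] for k in self.knots[g]]
        if ages[-1] < self.cap_age:
            ages.append(self.cap_age)
            svals.append(0.0)
        return np.asarray(ages), np.asarray(svals)

    def survival_at_age(self, g: int, age: float | np.ndarray) -> np.ndarray:
        """Piecewise-linear cumulative survival at an attained age (0 beyond cap)."""
        ages, svals = self.curve_points(g)
        return np.interp(age, ages, svals, left=1.0, right=0.0)

    # -- YAML round trip -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "cap_age": float(self.cap_age),
            "onset_bands": {
                band.label: {
                    "mean_onset_age": float(self.mean_onset_age[g]),
                    "survival": [[float(a), float(s)] for a, s in self.knots[g]],
                }
                for g, band in enumerate(BANDS)
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurvivalSchedule":
        doc = yaml.safe_load(Path(path).read_text())
        onset = doc["onset_bands"]
        return cls(
            mean_onset_age=tuple(onset[b.label]["mean_onset_age"] for b in BANDS),
            knots=tuple(
                tuple((float(a), float(s)) for a, s in onset[b.label]["survival"])
                for b in BANDS
            ),
            cap_age=float(doc.get("cap_age", DEFAULT_CAP_AGE)),
        )


def _integrate_pw_linear(
    xs: np.ndarray, ys: np.ndarray, lo: float, hi: float
) -> float:
    """Integral of the piecewise-linear curve (xs, ys) over [lo, hi]."""
    if hi <= lo:
        return 0.0
    inner = xs[(xs > lo) & (xs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, xs, ys, left=ys[0], right=ys[-1])
    return float(np.trapezoid(vals, grid))


def person_years_by_band(onset_band: int, schedule: SurvivalSchedule) -> np.ndarray:
    """Expected person-years per incident case spent in each attained band.

    Zero for bands before onset; within the onset band integration starts
    at the mean onset age (S = 1).
    """
    g = int(onset_band)
    a = schedule.mean_onset_age[g]
    if a >= schedule.cap_age:
        raise ValidationError(f"degenerate schedule: onset age {a} at/above cap")
    ages, svals = schedule.curve_points(g)
    edges = band_edges(schedule.cap_age)
    py = np.zeros(N_BANDS)
    for b in range(g, N_BANDS):
        lo = max(edges[b], a)
        hi = edges[b + 1]
        py[b] = _integrate_pw_linear(ages, svals, lo, hi)
    return py


def implied_expectancy(onset_band: int, schedule: SurvivalSchedule) -> float:
    """Penalty-free remaining life expectancy from onset (total person-years)."""
    return float(person_years_by_band(onset_band, schedule).sum())


def person_year_weights(onset_band: int, schedule: SurvivalSchedule) -> np.ndarray:
    """Person-years per attained band normalised to sum exactly to 1."""
    py = person_years_by_band(onset_band, schedule)
    total = py.sum()
    if total <= 0:
        raise ValidationError(f"onset band {onset_band}: zero total person-years")
    w = py / total
    # force exact normalisation against float round-off
    w[int(np.nonzero(w)[0][-1])] += 1.0 - w.sum()
    return w


def prevalence_by_onset(
    incident_cases: np.ndarray, durations: np.ndarray
) -> np.ndarray:
    """P(g) = I(g) × D(g): the steady-state identity per onset band."""
    incident_cases = np.asarray(incident_cases, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if incident_cases.shape != (N_BANDS,) or durations.shape != (N_BANDS,):
        raise StructuralError(
            f"incident cases and durations must both have shape ({N_BANDS},)"
        )
    if (incident_cases < 0).any() or (durations < 0).any():
        raise ValueError("incident cases and durations must be non-negative")
    return incident_cases * durations


def allocation_weights(
    schedule: SurvivalSchedule,
    durations: np.ndarray | None = None,
    tail_truncate: bool = False,
) -> np.ndarray:
    """(onset band × attained band) weight matrix, rows summing to 1.

    Default: proportional person-year weights from the (penalty-free)
    schedule, so band shares are penalty-invariant and the penalty enters
    only through the durations in P = I × D. With ``tail_truncate`` the
    shortened duration instead removes person-years from the oldest
    attained bands first, reading the penalty as curtailing old age.
    """
    W = np.zeros((N_BANDS, N_BANDS))
    for g in range(N_BANDS):
        if not tail_truncate:
            W[g] = person_year_weights(g, schedule)
        else:
            if durations is None:
                raise ValueError("tail_truncate allocation requires durations")
            py = person_years_by_band(g, schedule)
            d = float(durations[g])
            if d >= py.sum():
                W[g] = py / py.sum()
            else:
                cum_before = np.concatenate(([0.0], np.cumsum(py)[:-1]))
                alloc = np.clip(d - cum_before, 0.0, py)
                W[g] = alloc / d
    return W


def allocate_attained_age(
    p_onset: np.ndarray,
    schedule: SurvivalSchedule,
    durations: np.ndarray | None = None,
    tail_truncate: bool = False,
) -> np.ndarray:
    """Redistribute prevalent cases from onset bands to attained bands.

    P_att(b) = Σ_g P_onset(g) × w(g, b); the total is conserved because every
    weight row sums to 1.
    """
    p_onset = np.asarray(p_onset, dtype=float)
    if p_onset.shape != (N_BANDS,):
        raise StructuralError(f"p_onset must have shape ({N_BANDS},)")
    if (p_onset < 0).any():
        raise ValueError("prevalent cases must be non-negative")
    W = allocation_weights(schedule, durations=durations, tail_truncate=tail_truncate)
    return p_onset @ W


def simulate_steady_state(
    incident_cases: np.ndarray,
    schedule: SurvivalSchedule,
    durations: np.ndarray,
    horizon: int | None = None,
) -> np.ndarray:
    """Discrete-time cohort bookkeeping oracle for the steady-state identity.

    Each simulated year injects the annual incident cases of every onset
    band at its mean onset age, ages all cohorts by one year, and kills
    according to the schedule's survival curve with time since onset
    rescaled so that life expectancy matches the supplied durations
    (S'(t) = S(t·E/D)). After ``horizon`` years (≥ cap age, so every cohort
    alive at the start has died or aged out) a mid-year census counts the
    living by attained band. At equilibrium the total approaches
    Σ_g I(g) × D(g) and, when durations equal the schedule's expectancies,
    the band distribution approaches the analytic person-year weights.
    """
    incident_cases = np.asarray(incident_cases, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if incident_cases.shape != (N_BANDS,) or durations.shape != (N_BANDS,):
        raise StructuralError("incident cases and durations must have band shape")
    cap = schedule.cap_age
    if horizon is None:
        horizon = int(np.ceil(cap)) + 1
    if horizon < cap:
        raise ValueError(f"horizon {horizon} shorter than cap age {cap}")

    prevalent = np.zeros(N_BANDS)
    for g in range(N_BANDS):
        if incident_cases[g] == 0:
            continue
        a = schedule.mean_onset_age[g]
        expectancy = implied_expectancy(g, schedule)
        stretch = durations[g] / expectancy  # time rescale so E[duration] = D(g)
        # cohorts[tau] = survivors of the cohort injected tau years ago,
        # censused mid-year (tau + 0.5 years since onset)
        cohort_ages = np.arange(horizon) + 0.5
        alive = incident_cases[g] * schedule.survival_at_age(
            g, a + cohort_ages / stretch
        )
        attained = np.minimum(a + cohort_ages, np.nextafter(cap, 0.0))
        for tau in range(horizon):
            if alive[tau] <= 0:
                break
            prevalent[band_of_age(attained[tau], cap)] += alive[tau]
    return prevalent
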