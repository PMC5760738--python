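"""Empirical pipeline from fecal particle counts to egestion statistics.

Each sample is a vial of flies transferred hourly to fresh vials for 5 h
after a 1-h feeding pulse containing GFP-labelled bacteria and inert
fluorescent microspheres. Hourly fecal counts of the two particle classes,
normalized to the 5-h totals, give a per-sample discrete egestion-time
distribution; its mean and variance are the empirical analogues of the
phase-type μ and σ². The microsphere-to-bacteria count ratio, referenced to
the same ratio in the inoculum, estimates the proportion of ingested
bacteria that is egested (exactly 1 for passive transit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .phase_model import EgestionStats

__all__ = [
    "FecalTimeSeries",
    "InoculumComposition",
    "NormalizedStats",
    "FIELD_UM",
    "SLIDE_MM",
    "bin_times",
    "particles_per_fly",
    "egestion_distribution",
    "stats_from_distribution",
    "proportion_ingested_egested",
    "day_average",
    "normalize_stats",
    "sample_stats",
]

logger = logging.getLogger(__name__)

#: Microscope field of scope, µm (width, height).
FIELD_UM = (4753.7, 6040.2)
#: Slide dimensions, mm (width, height).
SLIDE_MM = (24.0, 30.0)

N_BINS = 5


def bin_times(convention: str = "endpoint") -> np.ndarray:
    """Representative times (hours) for the five hourly bins.

    ``endpoint`` maps hour-k counts to t = k (the default, matching
    "particles egested at each hour"); ``midpoint`` maps them to k − 0.5.
    """
    if convention == "endpoint":
        return np.arange(1.0, N_BINS + 1.0)
    if convention == "midpoint":
        return np.arange(1.0, N_BINS + 1.0) - 0.5
    raise ValidationError(f"unknown bin-time convention {convention!r}")


@dataclass
class FecalTimeSeries:
    """Per-sample hourly egested counts for both particle classes.

    ``bacteria_counts`` and ``sphere_counts`` are the five hourly bins
    (hours 1-5); ``presence_24h``/``presence_48h`` are optional
    presence/absence flags for bacterial colonies in the late samples
    (excluded from moment computation).
    """

    sample_id: str
    treatment: str
    replicate_day: Hashable
    n_flies: int
    bacteria_counts: tuple[float, ...]
    sphere_counts: tuple[float, ...]
    presence_24h: Optional[bool] = None
    presence_48h: Optional[bool] = None

    def __post_init__(self) -> None:
        self.bacteria_counts = tuple(float(x) for x in self.bacteria_counts)
        self.sphere_counts = tuple(float(x) for x in self.sphere_counts)
        for name in ("bacteria_counts", "sphere_counts"):
            counts = getattr(self, name)
            if len(counts) != N_BINS:
                raise ValidationError(
                    f"{self.sample_id}: {name} must have exactly {N_BINS} hourly bins"
                )
            if any(c < 0 for c in counts):
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0")
        if self.n_flies < 1:
            raise ValidationError(f"{self.sample_id}: n_flies must be >= 1")


@dataclass(frozen=True)
class InoculumComposition:
    """Bacteria and microspheres per microscope field in the dosing solution."""

    bacteria_per_field: float
    spheres_per_field: float

    def __post_init__(self) -> None:
        if not (self.bacteria_per_field > 0 and self.spheres_per_field > 0):
            raise ValidationError("inoculum counts must be > 0")


@dataclass(frozen=True)
class NormalizedStats:
    """Bacterial egestion statistics relative to the microsphere control."""

    mu_norm: float
    sigma2_norm: float

    def __post_init__(self) -> None:
        if not (self.mu_norm > 0 and self.sigma2_norm > 0):
            raise ValidationError("normalized statistics must be > 0")


def particles_per_fly(
    scope_count: float,
    aliquot_volume: float = 5.0,
    total_volume: float = 100.0,
    n_flies: int = 50,
) -> float:
    """Scale a microscope-field count to particles per fly.

    The count under one field of scope (4,753.7 × 6,040.2 µm) is scaled to
    the full 24 × 30 mm slide, from the mounted aliquot to the total
    resuspension volume (default 100 µl), then divided by the number of
    flies in the vial:

    ``scope_count × (total/aliquot) × (24 × 30 × 1000²)/(4753.7 × 6040.2) / n_flies``
    """
    if aliquot_volume <= 0 or total_volume <= 0:
        raise ValidationError("volumes must be > 0")
    if aliquot_volume > total_volume:
        raise ValidationError("aliquot volume cannot exceed total volume")
    if n_flies < 1:
        raise ValidationError("n_flies must be >= 1")
    if scope_count < 0:
        raise ValidationError("scope_count must be >= 0")
    slide_um2 = SLIDE_MM[0] * SLIDE_MM[1] * 1000.0**2
    field_um2 = FIELD_UM[0] * FIELD_UM[1]
    return scope_count * (total_volume / aliquot_volume) * (slide_um2 / field_um2) / n_flies


def egestion_distribution(
    series: FecalTimeSeries, particle_class: str = "bacteria"
) -> np.ndarray:
    """Hourly egestion proportions (hour-k count over the 5-h total)."""
    if particle_class == "bacteria":
        counts = np.asarray(series.bacteria_counts, dtype=float)
    elif particle_class == "spheres":
        counts = np.asarray(series.sphere_counts, dtype=float)
    else:
        raise ValidationError(f"unknown particle class {particle_class!r}")
    total = counts.sum()
    if total <= 0:
        raise DegenerateDataError(
            f"{series.sample_id}: zero 5-h {particle_class} total; sample excluded"
        )
    return counts / total


def stats_from_distribution(
    proportions: Sequence[float], times: Optional[Sequence[float]] = None
) -> EgestionStats:
    """Moments of the discrete egestion-time distribution.

    Treats the hourly proportions as an exact probability distribution over
    the bin representative times, so the variance is the population moment
    ``Σ tₖ² pₖ − (Σ tₖ pₖ)²`` (no n−1 correction).
    """
    p = np.asarray(proportions, dtype=float)
    t = bin_times() if times is None else np.asarray(times, dtype=float)
    if p.shape != t.shape:
        raise ValidationError("proportions and bin times must align")
    if np.any(p < 0):
        raise ValidationError("proportions must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions must sum to 1, got {p.sum()}")
    mean = float(p @ t)
    variance = float(p @ t**2) - mean**2
    return EgestionStats(mean, max(variance, 0.0))


def proportion_ingested_egested(
    feces_bacteria: float, feces_spheres: float, inoc: InoculumComposition
) -> float:
    """Proportion of ingested bacteria that is egested over 5 h.

    The fecal bacteria:microsphere ratio divided by the same ratio in the
    inoculum. Uniform detection efficiencies cancel; a zero fecal
    microsphere count leaves the sample uninterpretable.
    """
    if feces_bacteria < 0 or feces_spheres < 0:
        raise ValidationError("fecal counts must be >= 0")
    if feces_spheres == 0:
        raise DegenerateDataError("zero fecal microspheres: sample uninterpretable")
    return (feces_bacteria / feces_spheres) / (
        inoc.bacteria_per_field / inoc.spheres_per_field
    )


def day_average(
    per_sample_values: Mapping[Hashable, Sequence[float]],
) -> dict[Hashable, float]:
    """Average per-sample values within each replicate day.

    Samples sharing a dosing inoculum and day are not independent; the
    per-day means are the independent units for downstream tests.
    """
    out: dict[Hashable, float] = {}
    for day, values in per_sample_values.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise ValidationError(f"replicate day {day!r} has no samples")
        out[day] = float(vals.mean())
    return out


def normalize_stats(bacteria: EgestionStats, spheres: EgestionStats) -> NormalizedStats:
    """μ_norm = μ_b/μ₀ and σ²_norm = σ_b²/σ₀² against the microsphere control."""
    if spheres.variance <= 0:
        raise DegenerateDataError("degenerate microsphere control (zero variance)")
    return NormalizedStats(
        bacteria.mean / spheres.mean, bacteria.variance / spheres.variance
    )


def sample_stats(
    series: FecalTimeSeries, convention: str = "endpoint"
) -> tuple[EgestionStats, EgestionStats]:
    """Per-sample (bacteria, microsphere) egestion statistics."""
    t = bin_times(convention)
    b = stats_from_distribution(egestion_distribution(series, "bacteria"), t)
    s = stats_from_distribution(egestion_distribution(series, "spheres"), t)
    return b, s
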