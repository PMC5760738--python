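"""Partition ingested bacteria into egested / retained / lysed fractions.

The microbial-fate experiment pairs fecal microscopy counts (egested cells)
with whole-body CFU counts (retained viable cells) for vials of flies fed a
bacteria + microsphere pulse. The number ingested is inferred from the
co-ingested microspheres; CFU are converted to microscopy units by a
calibration scalar. The complement of egested + retained is inferred lysed.
Replicate-day structure is hierarchical: samples are averaged within a day
first, and treatment summaries (mean ± SEM) are taken across day means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "FateSample",
    "FatePartition",
    "fate_partition",
    "partition_table",
    "hierarchical_summary",
    "headline_fractions",
    "retention_cv",
    "round_half_up",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FateSample:
    """Matched ingested/egested/retained counts for one vial of flies.

    ``ingested`` and ``egested`` are in microscopy units (cells per vial,
    ingestion inferred from microspheres); ``retained_cfu`` is the summed
    whole-body CFU count; ``conversion`` maps CFU to microscopy units
    (default 1.0 — an explicit, overridable calibration assumption).
    """

    replicate_day: Hashable
    fly_treatment: str
    n_flies: int
    ingested: float
    egested: float
    retained_cfu: float
    conversion: float = 1.0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValidationError("n_flies must be >= 1")
        if min(self.ingested, self.egested, self.retained_cfu) < 0:
            raise ValidationError("counts must be >= 0")
        if not self.conversion > 0:
            raise ValidationError("conversion factor must be > 0")


@dataclass(frozen=True)
class FatePartition:
    """Egested/retained/lysed proportions of ingested cells; sums to 1."""

    egested: float
    retained: float
    lysed: float

    def __post_init__(self) -> None:
        for name in ("egested", "retained", "lysed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} fraction {v} outside [0, 1]")
        if abs(self.egested + self.retained + self.lysed - 1.0) > 1e-9:
            raise ValidationError("partition must sum to 1")


def fate_partition(sample: FateSample) -> FatePartition:
    """Partition one vial's ingested cells; lysed is the complement.

    A negative complement (egested + retained > ingested, e.g. from
    counting noise) is floored at 0 with a logged warning and the other
    fractions rescaled to keep the partition on the simplex.
    """
    if sample.ingested <= 0:
        raise ValidationError("ingested must be > 0")
    egested = sample.egested / sample.ingested
    retained = sample.retained_cfu * sample.conversion / sample.ingested
    lysed = 1.0 - egested - retained
    if lysed < 0:
        logger.warning(
            "day %s %s: egested + retained exceed ingested (lysed %.3f floored at 0)",
            sample.replicate_day,
            sample.fly_treatment,
            lysed,
        )
        warnings.warn("lysed fraction floored at 0", stacklevel=2)
        total = egested + retained
        egested, retained, lysed = egested / total, retained / total, 0.0
    return FatePartition(egested, retained, lysed)


def partition_table(samples: Sequence[FateSample]) -> pd.DataFrame:
    """Per-sample partitions as a tidy table."""
    rows = []
    for s in samples:
        part = fate_partition(s)
        rows.append(
            {
                "replicate_day": s.replicate_day,
                "fly_treatment": s.fly_treatment,
                "n_flies": s.n_flies,
                "egested": part.egested,
                "retained": part.retained,
                "lysed": part.lysed,
            }
        )
    return pd.DataFrame(rows)


FRACTIONS = ("egested", "retained", "lysed")


def hierarchical_summary(
    partitions: pd.DataFrame, include_outliers: bool = False
) -> pd.DataFrame:
    """Treatment-level mean ± SEM of each fraction across replicate days.

    Samples are averaged within a (treatment, day) cell first; the SEM is
    sd/√k over the k day means. Outlier days — zero egested recovery — are
    excluded by default. When included, their unknown retained/lysed values
    (NaN in the input) propagate, so those cells are reported as NaN
    ("not computable") rather than imputed. A single replicate day yields a
    mean with SEM = NaN and ``sem_defined = False``.

    Parameters
    ----------
    partitions : DataFrame
        Columns ``replicate_day, fly_treatment, egested, retained, lysed``
        (one row per vial); NaN marks unknown fractions.
    """
    required = {"replicate_day", "fly_treatment", *FRACTIONS}
    missing = required - set(partitions.columns)
    if missing:
        raise ValidationError(f"partition table missing columns: {sorted(missing)}")
    df = partitions.copy()
    outlier = df["egested"].fillna(-1.0) == 0.0
    if not include_outliers:
        if outlier.any():
            logger.info(
                "excluding %d outlier sample(s) with zero egested recovery",
                int(outlier.sum()),
            )
        df = df[~outlier]
    rows = []
    for treatment, group in df.groupby("fly_treatment", sort=True):
        day_means = group.groupby("replicate_day", sort=True)[list(FRACTIONS)].mean()
        k = len(day_means)
        for frac in FRACTIONS:
            vals = day_means[frac].to_numpy(dtype=float)
            mean = float(np.mean(vals)) if k else np.nan
            sem = float(np.std(vals, ddof=1) / np.sqrt(k)) if k >= 2 else np.nan
            rows.append(
                {
                    "fly_treatment": treatment,
                    "fraction": frac,
                    "mean": mean,
                    "sem": sem,
                    "n_days": k,
                    "sem_defined": k >= 2 and np.isfinite(sem),
                }
            )
    return pd.DataFrame(rows)


def headline_fractions(summary: pd.DataFrame) -> dict[str, int]:
    """Average the treatment means and round to the nearest 5%.

    Produces the headline egested/retained/lysed percentages across
    treatments (e.g. ~35% / ~10% / ~55%).
    """
    out = {}
    for frac in FRACTIONS:
        means = summary.loc[summary["fraction"] == frac, "mean"]
        pct = 100.0 * float(means.mean())
        out[frac] = int(5 * round(pct / 5))
    return out


def retention_cv(per_fly_counts: Sequence[float]) -> float:
    """Coefficient of variation (sd/mean, unbiased sd) of untransformed
    per-fly retained counts — the interhost dispersion metric."""
    counts = np.asarray(list(per_fly_counts), dtype=float)
    if counts.size < 2:
        raise ValidationError("need >= 2 flies for a CV")
    if np.any(counts < 0):
        raise ValidationError("counts must be >= 0")
    mean = counts.mean()
    if mean <= 0:
        raise DegenerateDataError("all-zero retained counts")
    return float(counts.std(ddof=1) / mean)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given precision (report convention).

    Values within 1e-9 of a half-way point (from float arithmetic on
    two-decimal inputs) round up, matching hand-rounded tables.
    """
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(repr(round(float(x), 9))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    )
    return float(q)
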