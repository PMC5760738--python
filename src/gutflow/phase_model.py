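"""Closed-form theory of the unidirectional compartment chain.

A particle (a bacterium or an inert microsphere) traverses an ordered series
of gut compartments (foregut, midgut subregions, hindgut, ...). In
compartment *i* it emigrates forward at per capita rate ``m[i]`` (per hour)
and has net reproduction rate ``r[i] = b[i] - d[i]`` (birth minus
death-or-retention). Conditional on eventual egestion, the time spent in
compartment *i* is exponential with rate ``λᵢ = m[i] - r[i]``, so the
egestion time follows a hypoexponential (phase-type) distribution with stage
rates ``λ``. The model's headline statistics are

* mean egestion time       ``μ  = Σᵢ 1/λᵢ``
* egestion-time variance   ``σ² = Σᵢ 1/λᵢ²``
* proportion egested       ``Πᵢ m[i]/λᵢ``  (expected egested per ingested;
  exactly 1 for inert particles with r ≡ 0, < 1 under net loss, and may
  exceed 1 when some compartment has net growth)
* compartment-number estimate ``μ²/σ²`` (= n exactly for n identical
  compartments).

Because ``σ² ≤ μ²`` always holds for sums of positive terms, the theory
bounds the coefficient of variation of egestion times by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import ChainDomainError, ValidationError

__all__ = [
    "CompartmentChain",
    "EgestionStats",
    "egestion_time_mean",
    "egestion_time_variance",
    "proportion_egested",
    "egestion_time_density",
    "egestion_time_cdf",
    "compartment_number_estimate",
]


@dataclass(frozen=True)
class CompartmentChain:
    """Ordered per-compartment emigration and net-reproduction rates.

    Parameters
    ----------
    m : sequence of float
        Per-compartment forward emigration rates (1/hour), all > 0.
    r : sequence of float
        Per-compartment net reproduction rates (1/hour). ``m[i] - r[i] > 0``
        is required for finite egestion-time moments.
    """

    m: tuple[float, ...]
    r: tuple[float, ...]

    def __post_init__(self) -> None:
        m = tuple(float(x) for x in self.m)
        r = tuple(float(x) for x in self.r)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "r", r)
        if len(m) == 0:
            raise ValidationError("chain needs at least one compartment")
        if len(m) != len(r):
            raise ValidationError(
                f"m and r must have equal length, got {len(m)} and {len(r)}"
            )
        for i, mi in enumerate(m):
            if not np.isfinite(mi) or mi <= 0:
                raise ChainDomainError(
                    f"compartment {i}: emigration rate m={mi} must be > 0"
                )
        for i, (mi, ri) in enumerate(zip(m, r)):
            if not np.isfinite(ri) or mi - ri <= 0:
                raise ChainDomainError(
                    f"compartment {i}: exit rate m - r = {mi - ri} must be > 0"
                )

    @property
    def n_compartments(self) -> int:
        return len(self.m)

    @property
    def exit_rates(self) -> np.ndarray:
        """Stage rates λᵢ = mᵢ − rᵢ of the conditional egestion-time law."""
        return np.asarray(self.m) - np.asarray(self.r)

    @classmethod
    def identical(cls, n: int, m: float, r: float = 0.0) -> "CompartmentChain":
        """A chain of ``n`` identical compartments."""
        if n < 1:
            raise ValidationError("n must be >= 1")
        return cls((m,) * n, (r,) * n)


@dataclass(frozen=True)
class EgestionStats:
    """Mean (hours) and variance (hours²) of an egestion-time distribution."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValidationError(f"mean must be > 0, got {self.mean}")
        if self.variance < 0:
            raise ValidationError(f"variance must be >= 0, got {self.variance}")


def egestion_time_mean(chain: CompartmentChain) -> float:
    """Mean egestion time μ = Σᵢ 1/(mᵢ − rᵢ), in hours."""
    return float(np.sum(1.0 / chain.exit_rates))


def egestion_time_variance(chain: CompartmentChain) -> float:
    """Egestion-time variance σ² = Σᵢ 1/(mᵢ − rᵢ)², in hours²."""
    return float(np.sum(1.0 / chain.exit_rates**2))


def proportion_egested(chain: CompartmentChain) -> float:
    """Expected number of particles egested per particle ingested.

    Equals ``Πᵢ mᵢ/(mᵢ − rᵢ)``: exactly 1 when r ≡ 0 (inert microspheres),
    < 1 under net loss, and may exceed 1 when some compartment has net
    growth (expected-count interpretation of the linear model).
    """
    return float(np.prod(np.asarray(chain.m) / chain.exit_rates))


def _subintensity(chain: CompartmentChain) -> tuple[np.ndarray, np.ndarray]:
    lam = chain.exit_rates
    T = np.diag(-lam)
    if lam.size > 1:
        T += np.diag(lam[:-1], k=1)
    exit_vec = np.zeros(lam.size)
    exit_vec[-1] = lam[-1]
    return T, exit_vec


def egestion_time_density(chain: CompartmentChain, t) -> float | np.ndarray:
    """Hypoexponential density of the conditional egestion time at ``t``.

    Uses the absorbing-chain matrix-exponential form
    ``f(t) = e₀ᵀ exp(T t) s`` with sub-intensity ``T`` built from the stage
    rates λᵢ = mᵢ − rᵢ, which is numerically stable for repeated rates
    (identical compartments), unlike the distinct-rate partial-fraction
    formula.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    T, exit_vec = _subintensity(chain)
    flat = np.atleast_1d(t_arr)
    vals = np.array([expm(T * ti)[0] @ exit_vec for ti in flat])
    if t_arr.ndim == 0:
        return float(vals[0])
    return vals.reshape(t_arr.shape)


def egestion_time_cdf(chain: CompartmentChain, t) -> float | np.ndarray:
    """P(egestion time ≤ t), conditional on eventual egestion."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    T, _ = _subintensity(chain)
    flat = np.atleast_1d(t_arr)
    vals = np.array([1.0 - expm(T * ti)[0].sum() for ti in flat])
    if t_arr.ndim == 0:
        return float(vals[0])
    return vals.reshape(t_arr.shape)


def compartment_number_estimate(stats: EgestionStats) -> float:
    """Estimate the number of (identical) gut compartments as μ²/σ².

    Exact for chains of identical compartments; an index of effective
    compartmentalization otherwise.
    """
    if stats.variance <= 0:
        raise ValidationError("variance must be > 0 for the μ²/σ² estimator")
    return stats.mean**2 / stats.variance
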