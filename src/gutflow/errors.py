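"""Exception hierarchy.

``ValidationError`` marks contract/domain violations (CLI exit code 2);
``DegenerateDataError`` marks data that are formally valid but carry no
information for the requested computation, e.g. a sample with zero egested
particles or a zero-variance t test (CLI exit code 3).
"""


class GutflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GutflowError, ValueError):
    """Input violates a documented pre-condition or invariant."""


class ChainDomainError(ValidationError):
    """Compartment-chain rates outside the model's domain (e.g. mᵢ − rᵢ ≤ 0)."""


class DegenerateDataError(GutflowError):
    """Data are valid but degenerate for the requested statistic."""


class ParticleCapError(GutflowError):
    """Branching simulation exceeded the per-founder particle cap."""
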