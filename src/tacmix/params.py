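"""Parameter vectors and the compact parameter domain.

The transport model has two subject-specific parameters, the normalized
diffusivity ``q1`` of ethanol through the epidermal layer and the normalized
flux gain ``q2`` at the epidermal/dermal boundary.  Both are dimensionless and
strictly positive, and the population analysis restricts them to a compact
rectangle ``Q = [q1_lo, q1_hi] x [q2_lo, q2_hi]`` equipped with a p-metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["ParamVector", "ParamDomain", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised for non-positive or non-finite transport parameters."""


@dataclass(frozen=True)
class ParamVector:
    """One subject's (q1, q2): normalized diffusivity and flux gain."""

    q1: float
    q2: float

    def __post_init__(self) -> None:
        q1 = float(self.q1)
        q2 = float(self.q2)
        if not (math.isfinite(q1) and math.isfinite(q2)):
            raise InvalidParameterError(f"parameters must be finite, got ({self.q1}, {self.q2})")
        if q1 <= 0 or q2 <= 0:
            raise InvalidParameterError(f"parameters must be positive, got ({q1}, {q2})")
        object.__setattr__(self, "q1", q1)
        object.__setattr__(self, "q2", q2)

    def as_tuple(self) -> tuple[float, float]:
        return (self.q1, self.q2)


def as_param_vector(q) -> ParamVector:
    """Coerce a ParamVector, 2-tuple or length-2 array to a ParamVector."""
    if isinstance(q, ParamVector):
        return q
    q1, q2 = q
    return ParamVector(float(q1), float(q2))


@dataclass(frozen=True)
class ParamDomain:
    """Compact rectangle of admissible (q1, q2) with a p-metric.

    ``metric_order`` is the exponent p of the p-metric d_p; ``math.inf`` gives
    the Chebyshev metric.
    """

    q1_lo: float = 0.05
    q1_hi: float = 1.0
    q2_lo: float = 0.05
    q2_hi: float = 1.0
    metric_order: float = field(default=2.0)

    def __post_init__(self) -> None:
        if not (0 < self.q1_lo <= self.q1_hi):
            raise InvalidParameterError(f"need 0 < q1_lo <= q1_hi, got [{self.q1_lo}, {self.q1_hi}]")
        if not (0 < self.q2_lo <= self.q2_hi):
            raise InvalidParameterError(f"need 0 < q2_lo <= q2_hi, got [{self.q2_lo}, {self.q2_hi}]")
        if not (self.metric_order >= 1):
            raise InvalidParameterError(f"metric order must be in [1, inf], got {self.metric_order}")

    def contains(self, q: ParamVector) -> bool:
        return (self.q1_lo <= q.q1 <= self.q1_hi) and (self.q2_lo <= q.q2 <= self.q2_hi)

    def distance(self, qa, qb) -> float:
        """p-metric between two parameter vectors."""
        qa = as_param_vector(qa)
        qb = as_param_vector(qb)
        d1 = abs(qa.q1 - qb.q1)
        d2 = abs(qa.q2 - qb.q2)
        p = self.metric_order
        if math.isinf(p):
            return max(d1, d2)
        return (d1**p + d2**p) ** (1.0 / p)
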