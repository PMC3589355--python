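"""Linear calibration equations and realignment between measurement scales.

A calibration equation ``target = intercept + slope * source`` re-expresses
one method's measurements on the other method's concentration scale.  The
equations are typically fitted by weighted Deming regression and are exactly
invertible; realigned values are deliberately NOT clipped at zero (clipping
would bias downstream difference statistics), a warning lists affected
subjects instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigurationError, DegenerateFitError

__all__ = [
    "CalibrationEquation",
    "realign",
    "invert_equation",
    "compose_equations",
]


@dataclass(frozen=True)
class CalibrationEquation:
    """target = intercept + slope * source."""

    intercept: float
    slope: float
    source_method: str = "A"
    target_method: str = "B"
    provenance: str = "user-supplied"  # "fitted" | "user-supplied"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ConfigurationError("calibration slope must be nonzero")

    def apply(self, values):
        return realign(values, self)

    def invert(self) -> "CalibrationEquation":
        return invert_equation(self)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "CalibrationEquation":
        return cls(**json.loads(payload))

    @classmethod
    def from_fit(
        cls, fit, source_method: str = "A", target_method: str = "B"
    ) -> "CalibrationEquation":
        """Build an equation from a DemingFit of target-on-source."""
        return cls(
            intercept=fit.intercept,
            slope=fit.slope,
            source_method=source_method,
            target_method=target_method,
            provenance="fitted",
        )


def realign(values, eq: CalibrationEquation) -> np.ndarray:
    """Map each value v to intercept + slope * v (source -> target scale).

    Negative results (possible when the intercept is negative and v is small)
    are kept as-is and reported via a warning.
    """
    v = np.asarray(values, dtype=float)
    out = eq.intercept + eq.slope * v
    neg = np.where(out < 0)[0]
    if neg.size:
        warnings.warn(
            f"realignment {eq.source_method}->{eq.target_method} produced "
            f"{neg.size} negative value(s) at positions {neg[:10].tolist()}",
            stacklevel=2,
        )
    return out


def invert_equation(eq: CalibrationEquation) -> CalibrationEquation:
    """Exact inverse: (intercept, slope) -> (-intercept/slope, 1/slope)."""
    if eq.slope == 0:
        raise DegenerateFitError("slope 0 is not invertible")
    return CalibrationEquation(
        intercept=-eq.intercept / eq.slope,
        slope=1.0 / eq.slope,
        source_method=eq.target_method,
        target_method=eq.source_method,
        provenance=eq.provenance,
    )


def compose_equations(
    first: CalibrationEquation, second: CalibrationEquation
) -> CalibrationEquation:
    """Compose A->B with B->C into A->C.

    Flagged with a warning: error propagation across chained equations is not
    modeled, so composed equations should be used with care.
    """
    if first.target_method != second.source_method:
        raise ConfigurationError(
            f"cannot compose {first.source_method}->{first.target_method} "
            f"with {second.source_method}->{second.target_method}"
        )
    warnings.warn(
        "composing calibration equations; uncertainty is not propagated",
        stacklevel=2,
    )
    return CalibrationEquation(
        intercept=second.intercept + second.slope * first.intercept,
        slope=second.slope * first.slope,
        source_method=first.source_method,
        target_method=second.target_method,
        provenance="fitted"
        if (first.provenance == "fitted" and second.provenance == "fitted")
        else "user-supplied",
    )
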