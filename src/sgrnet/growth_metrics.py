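"""Closed-form growth quantities and min-max normalization conventions.

Units used throughout the package: body weight in grams, fork/total length
in centimetres, specific growth rate (SGR) in percent per day, condition
factor (CF) dimensionless (100 * g * cm^-3).

The instantaneous growth coefficient is ``g = (ln W2 - ln W1) / (t2 - t1)``
(per day).  Two SGR conventions exist in the aquaculture literature:

* exponential form: ``SGR = 100 * (e^g - 1)`` — the true percent daily
  weight increment;
* linear form: ``SGR = 100 * g`` — the first-order approximation, standard
  in most feeding-trial reports.

Both are provided; they agree to second order in ``g``.

Normalization maps a feature linearly onto ``[-1, 1]`` (the range of the
tanh activation used by the reservoir): ``x_n = 2 (x - min)/(max - min) - 1``.
Values outside the stored range extrapolate linearly; this is deliberate so
that a trained model can be applied to populations whose features fall
outside the training envelope (the estimate then extrapolates rather than
clipping silently).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRangeError, ValidationError

__all__ = [
    "FeatureRange",
    "sgr_exponential",
    "sgr_linear",
    "growth_coefficient",
    "condition_factor",
    "normalize",
    "denormalize",
    "normalize_array",
    "denormalize_array",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureRange:
    """Min/max of one feature, computed from training data only.

    Stored with a trained model so that new data are normalized with the
    *training* ranges, and normalized network outputs can be mapped back to
    real units.
    """

    name: str
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.min) and math.isfinite(self.max)):
            raise ValidationError(f"non-finite range for feature {self.name!r}")
        if self.max < self.min:
            raise ValidationError(
                f"feature {self.name!r}: max ({self.max}) < min ({self.min})"
            )

    @property
    def span(self) -> float:
        return self.max - self.min


def growth_coefficient(w1: float, w2: float, t1: float, t2: float) -> float:
    """Instantaneous growth coefficient g = (ln W2 - ln W1)/(t2 - t1), day^-1."""
    if w1 <= 0 or w2 <= 0:
        raise ValidationError(f"weights must be positive, got W1={w1}, W2={w2}")
    if t2 <= t1:
        raise ValidationError(f"time interval must be positive, got t1={t1}, t2={t2}")
    return (math.log(w2) - math.log(w1)) / (t2 - t1)


def sgr_exponential(w1: float, w2: float, t1: float, t2: float) -> float:
    """SGR (% day^-1) in the exponential convention, 100 (e^g - 1)."""
    return 100.0 * math.expm1(growth_coefficient(w1, w2, t1, t2))


def sgr_linear(w1: float, w2: float, t1: float, t2: float) -> float:
    """SGR (% day^-1) in the linear convention, 100 g."""
    return 100.0 * growth_coefficient(w1, w2, t1, t2)


def condition_factor(weight: float, length: float) -> float:
    """Fulton's condition factor, 100 * weight(g) / length(cm)^3."""
    if weight <= 0:
        raise ValidationError(f"weight must be positive, got {weight}")
    if length <= 0:
        raise ValidationError(f"length must be positive, got {length}")
    return 100.0 * weight / length**3


def _check_range(r: FeatureRange) -> None:
    if r.span == 0:
        raise DegenerateRangeError(
            f"feature {r.name!r} has a degenerate range (min == max == {r.min}); "
            "a constant feature carries no information"
        )


def normalize(x: float, r: FeatureRange) -> float:
    """Map ``x`` linearly so that [min, max] -> [-1, +1].

    Out-of-range values extrapolate beyond [-1, 1]; a warning is logged
    because they indicate data outside the training envelope.
    """
    _check_range(r)
    y = 2.0 * (x - r.min) / r.span - 1.0
    if y < -1.0 or y > 1.0:
        logger.warning(
            "feature %r value %g outside training range [%g, %g]; extrapolating",
            r.name, x, r.min, r.max,
        )
    return y


def denormalize(y: float, r: FeatureRange) -> float:
    """Exact inverse of :func:`normalize`: [-1, +1] -> [min, max]."""
    _check_range(r)
    return r.min + (y + 1.0) * 0.5 * r.span


def normalize_array(values, r: FeatureRange):
    """Vectorized :func:`normalize` with one out-of-range warning per call."""
    _check_range(r)
    values = np.asarray(values, dtype=float)
    y = 2.0 * (values - r.min) / r.span - 1.0
    out = (y < -1.0) | (y > 1.0)
    if out.any():
        logger.warning(
            "feature %r: %d value(s) outside training range [%g, %g]; extrapolating",
            r.name, int(out.sum()), r.min, r.max,
        )
    return y


def denormalize_array(values, r: FeatureRange):
    """Vectorized :func:`denormalize`."""
    _check_range(r)
    return r.min + (np.asarray(values, dtype=float) + 1.0) * 0.5 * r.span
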