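"""Shared domain types and exceptions.

Conventions used across the package:

* ages are in kyr before present, larger = older;
* uncertainties are stored and propagated at 1 sigma;
* dose rates are Gy/kyr at the interface (mGy/kyr accepted by readers with
  an explicit unit flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class PaleomolarError(Exception):
    """Base class for package errors."""


class ValidationError(PaleomolarError, ValueError):
    """Invalid input data or parameters."""


class NonFiniteAgeError(PaleomolarError, ArithmeticError):
    """No age root exists for the given activity ratios (at/beyond secular
    equilibrium, or outside the model's validity range)."""


class ConvergenceError(PaleomolarError, RuntimeError):
    """An iterative fit or sampler failed to converge."""


#: Roles an age estimate can play in a stratigraphic model.
AGE_ROLES = ("direct", "minimum", "maximum")


@dataclass(frozen=True)
class DecayConstants:
    """Half-lives (years) of the U-series nuclides used by the 230Th clock.

    Defaults are the values used throughout this package: 75,690 yr for
    230Th and 245,250 yr for 234U.
    """

    half_life_230: float = 75_690.0
    half_life_234: float = 245_250.0

    def __post_init__(self) -> None:
        if self.half_life_230 <= 0 or self.half_life_234 <= 0:
            raise ValidationError("half-lives must be strictly positive")
        if self.half_life_230 >= self.half_life_234:
            raise ValidationError("expected half_life_230 < half_life_234 "
                                  "(i.e. lambda_230 > lambda_234)")

    @property
    def lambda_230(self) -> float:
        """Decay constant of 230Th, 1/yr."""
        return math.log(2.0) / self.half_life_230

    @property
    def lambda_234(self) -> float:
        """Decay constant of 234U, 1/yr."""
        return math.log(2.0) / self.half_life_234


@dataclass
class AgeEstimate:
    """An age in kyr with its 1-sigma uncertainty.

    ``role`` records how the estimate constrains the stratigraphy: a
    ``direct`` date, or a ``minimum``/``maximum`` bound on the true age of
    the dated event.
    """

    age: float
    sigma: float
    role: str = "direct"
    unit_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in AGE_ROLES:
            raise ValidationError(f"role must be one of {AGE_ROLES!r}, got {self.role!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.role == "direct" and not math.isfinite(self.age):
            raise ValidationError("a direct age must be finite")

    def __format__(self, spec: str) -> str:
        return f"{self.age:{spec or '.1f'}} +/- {self.sigma:{spec or '.1f'}} kyr"


@dataclass
class Quantity:
    """A value with a 1-sigma uncertainty (used for dose rates etc.)."""

    value: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    def __iter__(self):
        return iter((self.value, self.sigma))
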