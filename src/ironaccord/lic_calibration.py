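"""T2* -> liver iron concentration conversion and five-level iron-burden grading.

The default calibration is the Garbowski power law ``LIC = 31.94 * T2***-1.014``
(LIC in mg/g dry weight, T2* in ms). Coefficients are parameters, not
constants, so alternative calibrations can be swapped in.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "GARBOWSKI_COEFFICIENT",
    "GARBOWSKI_EXPONENT",
    "GradeScale",
    "DEFAULT_GRADE_SCALE",
    "t2star_to_lic",
    "lic_to_t2star",
    "grade",
]

GARBOWSKI_COEFFICIENT = 31.94
GARBOWSKI_EXPONENT = -1.014

GRADE_LABELS: Tuple[str, ...] = ("normal", "slight", "mild", "moderate", "severe")


@dataclass(frozen=True)
class GradeScale:
    """Five-level LIC grading with explicit interval conventions.

    Boundaries (mg/g dry weight) split ``(0, inf)`` into::

        normal   : lic <  b0
        slight   : b0 <= lic <  b1
        mild     : b1 <= lic <  b2
        moderate : b2 <= lic <= b3
        severe   : lic >  b3

    i.e. interior boundaries belong to the higher grade, while the top
    boundary belongs to *moderate* so that ``severe`` is strictly above it
    (matching the printed strict "< b0" and "> b3" at the extremes).
    """

    boundaries: Tuple[float, float, float, float] = (1.8, 3.2, 7.0, 15.0)
    labels: Tuple[str, ...] = GRADE_LABELS

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != 4 or any(x <= 0 for x in b):
            raise ValueError("grade scale needs 4 positive boundaries")
        if any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError("grade boundaries must be strictly increasing")
        if len(self.labels) != 5:
            raise ValueError("grade scale needs 5 labels")

    def grade(self, lic: float) -> str:
        if not np.isfinite(lic) or lic <= 0:
            raise ValueError(f"LIC must be positive and finite, got {lic!r}")
        b0, b1, b2, b3 = self.boundaries
        if lic < b0:
            return self.labels[0]
        if lic < b1:
            return self.labels[1]
        if lic < b2:
            return self.labels[2]
        if lic <= b3:
            return self.labels[3]
        return self.labels[4]

    def interval(self, label: str) -> Tuple[float, float]:
        """Open/half-open numeric support of a grade, as (lo, hi) with the
        convention that draws should respect grade membership of endpoints."""
        b0, b1, b2, b3 = self.boundaries
        intervals = {
            self.labels[0]: (0.0, b0),
            self.labels[1]: (b0, b1),
            self.labels[2]: (b1, b2),
            self.labels[3]: (b2, b3),
            self.labels[4]: (b3, np.inf),
        }
        try:
            return intervals[label]
        except KeyError:
            raise ValueError(f"unknown grade label {label!r}") from None

    def grade_index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_GRADE_SCALE = GradeScale()


def t2star_to_lic(
    t2star: float,
    coefficient: float = GARBOWSKI_COEFFICIENT,
    exponent: float = GARBOWSKI_EXPONENT,
) -> float:
    """Convert T2* (ms) to liver iron concentration (mg/g dry weight)."""
    t2star = float(t2star)
    if not np.isfinite(t2star) or t2star <= 0:
        raise ValueError(f"T2* must be positive and finite, got {t2star!r}")
    return coefficient * t2star**exponent


def lic_to_t2star(
    lic: float,
    coefficient: float = GARBOWSKI_COEFFICIENT,
    exponent: float = GARBOWSKI_EXPONENT,
) -> float:
    """Algebraic inverse of :func:`t2star_to_lic`."""
    lic = float(lic)
    if not np.isfinite(lic) or lic <= 0:
        raise ValueError(f"LIC must be positive and finite, got {lic!r}")
    return (lic / coefficient) ** (1.0 / exponent)


def grade(lic: float, scale: GradeScale = DEFAULT_GRADE_SCALE) -> str:
    """Assign the iron-burden grade for a LIC value."""
    return scale.grade(lic)


def grade_many(lics: Iterable[float], scale: GradeScale = DEFAULT_GRADE_SCALE) -> list:
    return [scale.grade(x) for x in lics]
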