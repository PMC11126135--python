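"""Quadratic interpolation of blood transverse relaxation rates over B0.

Blood T2 shortens steeply with field strength and no measured values exist
at every field of interest.  Following common practice, the relaxation
*rate* R2 = 1000 / T2 (s⁻¹, with T2 in ms) is fitted with a second-order
polynomial in B0 and evaluated at the unmeasured field.  This is a purely
numerical, data-driven construction — it carries no physical dispersion
model, and extrapolating outside the fitted range is known to produce
unreasonable rates (an almost vanishing arterial R2 below 1.5 T), hence
the extrapolation warning.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ExtrapolationWarning, UsageError

__all__ = ["R2Point", "R2Polynomial", "fit_r2_polynomial", "predict_t2"]


@dataclass(frozen=True)
class R2Point:
    """One literature blood relaxation measurement: T2 (ms) at a field (T).

    The rate ``r2`` (s⁻¹) is derived, so r2 * t2 == 1000 holds exactly.
    """

    field_strength: float
    t2: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.field_strength > 0:
            raise DomainError(f"field_strength must be positive, got {self.field_strength}")
        if not self.t2 > 0:
            raise DomainError(f"t2 must be positive, got {self.t2}")

    @property
    def r2(self) -> float:
        """Transverse relaxation rate in s⁻¹."""
        return 1000.0 / self.t2

    @classmethod
    def from_rate(cls, field_strength: float, r2: float, source: str = "") -> "R2Point":
        if not r2 > 0:
            raise DomainError(f"r2 must be positive, got {r2}")
        return cls(field_strength=field_strength, t2=1000.0 / r2, source=source)


@dataclass(frozen=True)
class R2Polynomial:
    """Degree-2 least-squares polynomial R2(B0) with fit diagnostics.

    ``coefficients`` are in descending powers (numpy ``polyfit`` order).
    ``fitted_range`` is the (min, max) field span of the input points;
    evaluations outside it are flagged as extrapolations.
    """

    coefficients: tuple[float, float, float]
    fitted_range: tuple[float, float]
    residual: float
    n_points: int

    def __call__(self, field: float | np.ndarray) -> float | np.ndarray:
        out = np.polyval(self.coefficients, field)
        return float(out) if np.isscalar(field) else out


def fit_r2_polynomial(points: Sequence[R2Point]) -> R2Polynomial:
    """Least-squares quadratic through blood R2 rates versus field strength.

    With exactly three distinct fields the polynomial interpolates the
    points exactly (zero residual).

    Raises
    ------
    UsageError
        If fewer than three distinct field strengths are supplied.
    """
    fields = np.array([p.field_strength for p in points], dtype=float)
    rates = np.array([p.r2 for p in points], dtype=float)
    if np.unique(fields).size < 3:
        raise UsageError(
            "need at least 3 points with distinct field strengths for a quadratic fit"
        )
    coeffs, residuals, *_ = np.polyfit(fields, rates, 2, full=True)
    residual = float(residuals[0]) if residuals.size else 0.0
    return R2Polynomial(
        coefficients=tuple(float(c) for c in coeffs),
        fitted_range=(float(fields.min()), float(fields.max())),
        residual=residual,
        n_points=int(fields.size),
    )


def predict_t2(poly: R2Polynomial, field: float) -> float:
    """T2 (ms) at a field strength from a fitted R2 polynomial.

    Emits :class:`ExtrapolationWarning` when the field lies outside the
    fitted range and raises :class:`DomainError` if the predicted rate is
    non-positive (extrapolated rates below the fitted range are known to
    be unphysical).
    """
    lo, hi = poly.fitted_range
    if not lo <= field <= hi:
        warnings.warn(
            f"field {field} T lies outside the fitted range {lo}-{hi} T; "
            "extrapolated blood R2 rates are unreliable",
            ExtrapolationWarning,
            stacklevel=2,
        )
    r2 = poly(field)
    if r2 <= 0:
        raise DomainError(
            f"predicted R2 = {r2:.3g} s⁻¹ at {field} T is non-positive; "
            "the quadratic interpolation is not valid at this field"
        )
    return 1000.0 / r2
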