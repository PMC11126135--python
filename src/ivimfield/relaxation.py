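"""Three-compartment relaxation weighting of the IVIM perfusion fraction.

In a spin-echo EPI acquisition each non-exchanging compartment contributes
signal proportional to its proton density scaled by the relaxation weight

    w = exp(-TE / T2) * (1 - exp(-TR / T1)).

Because the relaxation times of muscle, arterial blood and venous blood
diverge differently with the main field strength B0, the measured IVIM
perfusion fraction ``f`` depends on B0 even when the underlying
proton-density-weighted blood fraction ``f0`` does not.  This module maps
between ``f`` and ``f0`` for a muscle / arterial / venous compartment
model, estimates the venous-to-arterial volume ratio that reconciles
measurements at two field strengths, predicts ``f`` across fields, and
scans the sensitivity of the mapping to relaxation-time uncertainty.

All perfusion fractions are handled as dimensionless values on [0, 1);
conversion to percent happens only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError

__all__ = [
    "SequenceProtocol",
    "RelaxationSet",
    "CompartmentWeights",
    "PerfusionState",
    "compartment_weight",
    "forward_perfusion_fraction",
    "invert_perfusion_fraction",
    "estimate_venous_arterial_ratio",
    "RatioScanResult",
    "cross_field_prediction",
    "CrossFieldPrediction",
    "sensitivity_curves",
    "FIG_PERTURBATION_PRESETS",
]


@dataclass(frozen=True)
class SequenceProtocol:
    """Acquisition timing context of every weight and fit.

    Parameters
    ----------
    te : float
        Echo time in ms.
    tr : float
        Repetition time in ms.  ``math.inf`` selects the long-TR limit in
        which the T1 saturation factor drops out (used when a study's TR
        is unknown but long).
    b_values : tuple of float
        Diffusion weightings in s/mm², strictly increasing, non-negative.
    averages : tuple of int
        Number of magnitude-averaged repetitions per b-value.
    """

    te: float
    tr: float
    b_values: tuple[float, ...] = (0.0, 50.0, 100.0, 500.0, 600.0)
    averages: tuple[int, ...] = (2, 2, 2, 4, 4)

    def __post_init__(self) -> None:
        if not self.te > 0:
            raise DomainError(f"te must be positive, got {self.te}")
        if not self.tr > self.te:
            raise DomainError(f"tr must exceed te, got tr={self.tr}, te={self.te}")
        b = tuple(float(x) for x in self.b_values)
        a = tuple(int(x) for x in self.averages)
        if len(b) != len(a):
            raise UsageError("b_values and averages must have the same length")
        if any(x < 0 for x in b):
            raise DomainError("b_values must be non-negative")
        if any(y <= x for x, y in zip(b, b[1:])):
            raise UsageError("b_values must be strictly increasing")
        if any(n < 1 for n in a):
            raise UsageError("averages must be positive integers")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "averages", a)

    @classmethod
    def study_default(cls) -> "SequenceProtocol":
        """Diffusion protocol used at both field strengths in the calf study."""
        return cls(te=56.0, tr=2800.0)

    def long_tr(self) -> "SequenceProtocol":
        """Copy of this protocol in the long-TR (full T1 recovery) limit."""
        return dataclasses.replace(self, tr=math.inf)


def compartment_weight(t1: float, t2: float, protocol: SequenceProtocol) -> float:
    """Relaxation weight exp(-TE/T2) * (1 - exp(-TR/T1)) of one compartment.

    Parameters
    ----------
    t1, t2 : float
        Longitudinal and transverse relaxation times in ms.
    protocol : SequenceProtocol
        Supplies TE and TR (ms); ``tr = inf`` drops the T1 factor.

    Returns
    -------
    float
        Dimensionless weight in (0, 1).
    """
    if not t1 > 0:
        raise DomainError(f"t1 must be positive, got {t1}")
    if not t2 > 0:
        raise DomainError(f"t2 must be positive, got {t2}")
    t1_factor = 1.0 if math.isinf(protocol.tr) else 1.0 - math.exp(-protocol.tr / t1)
    return math.exp(-protocol.te / t2) * t1_factor


@dataclass(frozen=True)
class CompartmentWeights:
    """Relaxation weights of the three compartments, each in (0, 1]."""

    w_arterial: float
    w_venous: float
    w_muscle: float

    def __post_init__(self) -> None:
        for name in ("w_arterial", "w_venous", "w_muscle"):
            w = getattr(self, name)
            if not 0 < w <= 1:
                raise DomainError(f"{name} must lie in (0, 1], got {w}")

    def effective_blood(self, ratio_v_a: float) -> float:
        """Volume-weighted blood weight (wa + r*wv) / (1 + r) for fv/fa = r."""
        if not ratio_v_a > 0:
            raise DomainError(f"ratio_v_a must be positive, got {ratio_v_a}")
        return (self.w_arterial + ratio_v_a * self.w_venous) / (1.0 + ratio_v_a)


@dataclass(frozen=True)
class RelaxationSet:
    """T1/T2 of venous blood, arterial blood and tissue at one field strength.

    The ``muscle`` slots hold the non-vascular tissue compartment; for the
    liver cross-field check they carry liver parenchyma times.  Times in ms,
    field strength in tesla.  Oxygen saturations are percentages and, like
    the hematocrit fraction, are metadata only — they document the
    conditions under which the literature times were measured.
    """

    field_strength: float
    t1_venous: float
    t1_arterial: float
    t1_muscle: float
    t2_venous: float
    t2_arterial: float
    t2_muscle: float
    oxygen_saturation_venous: float | None = None
    oxygen_saturation_arterial: float | None = None
    hematocrit: float | None = None
    name: str = ""
    citations: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.field_strength > 0:
            raise DomainError(f"field_strength must be positive, got {self.field_strength}")
        for comp in ("venous", "arterial", "muscle"):
            t1 = getattr(self, f"t1_{comp}")
            t2 = getattr(self, f"t2_{comp}")
            if not t1 > 0:
                raise DomainError(f"t1_{comp} must be positive, got {t1}")
            if not t2 > 0:
                raise DomainError(f"t2_{comp} must be positive, got {t2}")
            if t2 > t1:
                raise DomainError(f"t2_{comp}={t2} exceeds t1_{comp}={t1}")
        object.__setattr__(self, "citations", tuple(self.citations))

    def weights(self, protocol: SequenceProtocol) -> CompartmentWeights:
        """Compute the three compartment weights for an acquisition protocol.

        Weights are always derived on demand from the relaxation times so a
        perturbed set can never carry stale weights.
        """
        return CompartmentWeights(
            w_arterial=compartment_weight(self.t1_arterial, self.t2_arterial, protocol),
            w_venous=compartment_weight(self.t1_venous, self.t2_venous, protocol),
            w_muscle=compartment_weight(self.t1_muscle, self.t2_muscle, protocol),
        )

    def perturb(self, **fractional: float) -> "RelaxationSet":
        """Return a copy with relaxation times scaled by (1 + fraction).

        Keyword names are relaxation-time field names (``t2_venous`` etc.);
        a value of ``-0.15`` shortens that time by 15 %.  Perturbations that
        drive a time non-positive raise :class:`DomainError`.
        """
        changes: dict[str, float] = {}
        for key, frac in fractional.items():
            if key not in (
                "t1_venous", "t1_arterial", "t1_muscle",
                "t2_venous", "t2_arterial", "t2_muscle",
            ):
                raise UsageError(f"unknown relaxation-time field {key!r}")
            if frac <= -1:
                raise DomainError(f"perturbation {key}={frac} drives the time non-positive")
            changes[key] = getattr(self, key) * (1.0 + frac)
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PerfusionState:
    """Proton-density-weighted perfusion state of a voxel.

    ``f0_total`` is the total blood volume fraction without relaxation
    weighting; ``ratio_v_a`` is the venous-to-arterial volume ratio fv/fa.
    The arterial and venous sub-fractions are derived so that their sum
    equals ``f0_total`` exactly in floating point.
    """

    f0_total: float
    ratio_v_a: float

    def __post_init__(self) -> None:
        if not 0 <= self.f0_total < 1:
            raise DomainError(f"f0_total must lie in [0, 1), got {self.f0_total}")
        if not self.ratio_v_a > 0:
            raise DomainError(f"ratio_v_a must be positive, got {self.ratio_v_a}")

    @property
    def f0_arterial(self) -> float:
        return self.f0_total / (1.0 + self.ratio_v_a)

    @property
    def f0_venous(self) -> float:
        # defined by difference so additivity f0_a + f0_v == f0_total is exact
        return self.f0_total - self.f0_arterial


def forward_perfusion_fraction(state: PerfusionState, weights: CompartmentWeights) -> float:
    """Relaxation-weighted perfusion fraction of a three-compartment voxel.

    Computes ``(f0a*wa + f0v*wv) / (f0a*wa + f0v*wv + (1 - f0)*wm)``.
    With equal blood weights this reduces to the two-pool form
    ``f0*wb / (f0*wb + (1 - f0)*wm)``.

    Returns
    -------
    float
        Measured (relaxation-weighted) perfusion fraction in [0, 1).
    """
    blood = state.f0_arterial * weights.w_arterial + state.f0_venous * weights.w_venous
    tissue = (1.0 - state.f0_total) * weights.w_muscle
    return blood / (blood + tissue)


def invert_perfusion_fraction(
    f: float, ratio_v_a: float, weights: CompartmentWeights
) -> float:
    """Proton-density-weighted fraction f0 from a measured perfusion fraction.

    Closed-form inverse of :func:`forward_perfusion_fraction` at a fixed
    venous-to-arterial volume ratio:

        f0 = f * wm / (w_eff * (1 - f) + f * wm),
        w_eff = (wa + r * wv) / (1 + r).

    Round-trips with the forward map to better than 1e-12.
    """
    if not 0 <= f < 1:
        raise DomainError(f"measured f must lie in [0, 1), got {f}")
    w_eff = weights.effective_blood(ratio_v_a)
    return f * weights.w_muscle / (w_eff * (1.0 - f) + f * weights.w_muscle)


def _invert_grid(f: float, grid: np.ndarray, weights: CompartmentWeights) -> np.ndarray:
    """Vectorised :func:`invert_perfusion_fraction` over a ratio grid."""
    w_eff = (weights.w_arterial + grid * weights.w_venous) / (1.0 + grid)
    return f * weights.w_muscle / (w_eff * (1.0 - f) + f * weights.w_muscle)


@dataclass(frozen=True)
class RatioScanResult:
    """Outcome of a venous-to-arterial ratio grid scan.

    ``ratio`` is the grid point minimising the absolute difference of the
    two f0 estimates; ties resolve to the smallest ratio.  The full
    objective is retained for plotting / export.
    """

    ratio: float
    f0_low: float
    f0_high: float
    grid: np.ndarray
    objective: np.ndarray


def estimate_venous_arterial_ratio(
    f_low: float,
    f_high: float,
    relax_low: RelaxationSet,
    relax_high: RelaxationSet,
    protocol: SequenceProtocol,
    grid: Sequence[float] | np.ndarray | None = None,
) -> RatioScanResult:
    """Find the fv/fa ratio reconciling perfusion fractions at two fields.

    Since f0 is a tissue property it cannot depend on B0; the ratio is
    estimated as the grid value for which inverting the measured ``f`` at
    the low and high field yields the same f0.

    Parameters
    ----------
    f_low, f_high : float
        Measured perfusion fractions at the two field strengths, in [0, 1).
    relax_low, relax_high : RelaxationSet
        Relaxation times at the respective field strengths.
    protocol : SequenceProtocol
        Shared acquisition timing.
    grid : array-like, optional
        Candidate ratios; defaults to 0.5–10 in steps of 0.01.

    Returns
    -------
    RatioScanResult
    """
    for name, f in (("f_low", f_low), ("f_high", f_high)):
        if not 0 <= f < 1:
            raise DomainError(f"{name} must lie in [0, 1), got {f}")
    if grid is None:
        grid = np.arange(0.5, 10.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise UsageError("ratio grid is empty")
    if not (grid > 0).all():
        raise DomainError("ratio grid values must be positive")

    f0_low = _invert_grid(f_low, grid, relax_low.weights(protocol))
    f0_high = _invert_grid(f_high, grid, relax_high.weights(protocol))
    objective = np.abs(f0_low - f0_high)
    i = int(np.argmin(objective))  # argmin takes the first = smallest ratio on ties
    return RatioScanResult(
        ratio=float(grid[i]),
        f0_low=float(f0_low[i]),
        f0_high=float(f0_high[i]),
        grid=grid,
        objective=objective,
    )


@dataclass(frozen=True)
class CrossFieldPrediction:
    """Perfusion fraction carried from a reference field to a target field."""

    f0: float
    f_target: float
    ratio_ref_over_target: float


def cross_field_prediction(
    f_ref: float,
    relax_ref: RelaxationSet,
    relax_target: RelaxationSet,
    ratio_v_a: float,
    protocol_ref: SequenceProtocol,
    protocol_target: SequenceProtocol | None = None,
) -> CrossFieldPrediction:
    """Predict the perfusion fraction at another field strength.

    Inverts the three-compartment model at the reference field to obtain
    f0, then applies the forward model at the target field with the same
    f0 and venous-to-arterial ratio.  Passing a protocol with ``tr = inf``
    evaluates the long-TR limit (T1 factors drop out), which is how the
    liver literature comparison is run when the original TR is unknown.
    """
    if protocol_target is None:
        protocol_target = protocol_ref
    f0 = invert_perfusion_fraction(f_ref, ratio_v_a, relax_ref.weights(protocol_ref))
    f_target = forward_perfusion_fraction(
        PerfusionState(f0_total=f0, ratio_v_a=ratio_v_a),
        relax_target.weights(protocol_target),
    )
    return CrossFieldPrediction(
        f0=f0, f_target=f_target, ratio_ref_over_target=f_ref / f_target
    )


#: Relaxation-time perturbations matching the published sensitivity panels:
#: shortened venous T2, halved arterial T2, lengthened muscle T2, and a
#: combined blood-down / muscle-up variation.
FIG_PERTURBATION_PRESETS: dict[str, dict[str, float]] = {
    "venous_t2_-15%": {"t2_venous": -0.15},
    "arterial_t2_-50%": {"t2_arterial": -0.50},
    "muscle_t2_+25%": {"t2_muscle": 0.25},
    "blood_t2_-5%_muscle_t2_+5%": {
        "t2_venous": -0.05,
        "t2_arterial": -0.05,
        "t2_muscle": 0.05,
    },
}

UNPERTURBED_LABEL = "unperturbed"


def sensitivity_curves(
    f0_grid: Sequence[float] | np.ndarray,
    ratio_v_a: float,
    relax: RelaxationSet,
    protocol: SequenceProtocol,
    perturbations: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Families of f(f0) curves under relaxation-time perturbations.

    Always includes the unperturbed curve; each named perturbation adds one
    curve computed with the correspondingly scaled relaxation set.  Use
    :data:`FIG_PERTURBATION_PRESETS` for the published variation scenarios.

    Returns
    -------
    pandas.DataFrame
        Long-format table with columns
        ``(perturbation_label, ratio_v_a, f0, f)``.
    """
    f0_grid = np.asarray(f0_grid, dtype=float)
    if f0_grid.size == 0:
        raise UsageError("f0_grid is empty")
    if ((f0_grid < 0) | (f0_grid >= 1)).any():
        raise DomainError("f0 grid values must lie in [0, 1)")
    perturbations = dict(perturbations or {})

    frames = []
    for label, spec_ in [(UNPERTURBED_LABEL, {})] + list(perturbations.items()):
        weights = relax.perturb(**spec_).weights(protocol)
        f = np.array(
            [
                forward_perfusion_fraction(
                    PerfusionState(f0_total=x, ratio_v_a=ratio_v_a), weights
                )
                for x in f0_grid
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "perturbation_label": label,
                    "ratio_v_a": ratio_v_a,
                    "f0": f0_grid,
                    "f": f,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
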