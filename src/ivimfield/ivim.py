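"""Segmented and biexponential IVIM fitting of ROI-mean signal curves.

The IVIM signal of a perfused tissue is modelled biexponentially,

    S(b) / S0 = f * exp(-b * D*) + (1 - f) * exp(-b * D),

with tissue diffusion coefficient D, pseudo-diffusion coefficient D* and
perfusion fraction f.  When no b-values below ~50 s/mm² are available, D*
cannot be estimated and the first step of a segmented fit is used instead:
an ordinary least-squares line through ln(S/S0) for b >= b_threshold gives
D from the slope, and the extrapolated intercept at b = 0 gives f via the
intercept deficit.

Units: b in s/mm², diffusion coefficients in µm²/ms (= 1e-3 mm²/s); the
product b*D is made dimensionless with an explicit 1e-3 conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, UsageError

__all__ = [
    "SignalCurve",
    "IVIMFitResult",
    "normalize_roi_signals",
    "segmented_fit",
    "biexponential_fit",
    "biexponential_signal",
]

#: µm²/ms -> mm²/s, so that b [s/mm²] * D [µm²/ms] * UNIT = dimensionless
UNIT = 1e-3


@dataclass(frozen=True, eq=False)
class SignalCurve:
    """ROI-mean diffusion-weighted signal versus b-value.

    ``signals`` are magnitudes in arbitrary units; after
    :func:`normalize_roi_signals` they are relative to the b = 0 signal and
    ``normalized`` is set.  ``n_voxels`` optionally records the ROI size
    for SNR bookkeeping.
    """

    b_values: np.ndarray
    signals: np.ndarray
    normalized: bool = False
    n_voxels: int | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if b.ndim != 1 or s.ndim != 1 or b.size != s.size:
            raise UsageError("b_values and signals must be 1-D arrays of equal length")
        if (s <= 0).any():
            raise DataError("signals must be strictly positive magnitudes")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "signals", s)
        if self.normalized and not math.isclose(s[int(np.argmin(b))], 1.0):
            raise DataError("curve flagged normalized but signal at smallest b is not 1")


@dataclass(frozen=True)
class IVIMFitResult:
    """Estimated IVIM parameters with fit diagnostics.

    ``f`` follows the convention selected by ``f_mode``:
    ``"exp"`` (default) back-transforms the log intercept, f = 1 - e^c,
    exact for two-compartment data with fully suppressed perfusion signal;
    ``"linear"`` reads f = -c off the literal linearised signal equation.
    Both are always recoverable from ``intercept_log`` via the
    ``f_from_exp`` / ``f_from_linear`` properties.
    """

    d: float
    f: float
    intercept_log: float
    n_points_used: int
    method: str
    f_mode: str = "exp"
    d_star: float | None = None
    s0: float | None = None
    converged: bool = True
    message: str = ""

    @property
    def f_from_exp(self) -> float:
        return 1.0 - math.exp(self.intercept_log)

    @property
    def f_from_linear(self) -> float:
        return -self.intercept_log


def normalize_roi_signals(raw: SignalCurve) -> SignalCurve:
    """Divide every signal by the b = 0 signal.

    Idempotent; requires a b = 0 entry with positive signal.
    """
    where = np.flatnonzero(raw.b_values == 0)
    if where.size == 0:
        raise UsageError("curve has no b = 0 entry to normalize against")
    s0 = raw.signals[where[0]]
    return replace(raw, signals=raw.signals / s0, normalized=True)


def segmented_fit(
    curve: SignalCurve,
    b_threshold: float = 100.0,
    f_mode: str = "exp",
) -> IVIMFitResult:
    """First step of the segmented IVIM fit on a normalized curve.

    Ordinary least squares of ln(S/S0) against b over the points with
    b >= ``b_threshold`` (default 100 s/mm²).  The negative slope is the
    diffusion coefficient D in µm²/ms; the intercept at b = 0 estimates
    ln(1 - f), read out according to ``f_mode``.

    Points below the threshold retain pseudo-diffusion signal, so with a
    finite D* the estimates carry a known residual bias (D slightly high,
    f slightly low); see the package methods note.
    """
    if f_mode not in ("exp", "linear"):
        raise UsageError(f"f_mode must be 'exp' or 'linear', got {f_mode!r}")
    if not curve.normalized:
        curve = normalize_roi_signals(curve)
    mask = curve.b_values >= b_threshold
    if mask.sum() < 2:
        raise UsageError(
            f"need at least 2 points with b >= {b_threshold}, found {int(mask.sum())}"
        )
    b = curve.b_values[mask]
    logs = np.log(curve.signals[mask])
    slope, intercept = np.polyfit(b, logs, 1)
    d = -slope / UNIT  # slope in 1/(s/mm²) = mm²/s -> µm²/ms
    f = 1.0 - math.exp(intercept) if f_mode == "exp" else -intercept
    return IVIMFitResult(
        d=float(d),
        f=float(f),
        intercept_log=float(intercept),
        n_points_used=int(mask.sum()),
        method="segmented",
        f_mode=f_mode,
    )


def biexponential_signal(
    b: np.ndarray, f: float, d: float, d_star: float, s0: float = 1.0
) -> np.ndarray:
    """Two-compartment IVIM signal model (b in s/mm², D and D* in µm²/ms)."""
    b = np.asarray(b, dtype=float)
    return s0 * (f * np.exp(-b * d_star * UNIT) + (1.0 - f) * np.exp(-b * d * UNIT))


def biexponential_fit(
    curve: SignalCurve,
    init: IVIMFitResult | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    d_star_init: float = 20.0,
) -> IVIMFitResult:
    """Full nonlinear least-squares fit of the biexponential IVIM model.

    Parameters (f, D, D*) are fitted with S0 fixed at 1 on a normalized
    curve.  Initialisation defaults to the segmented-fit estimates with
    ``d_star_init`` for D*.  Default bounds are f in [0, 1), D in
    (0, 5] µm²/ms, D* in (0, 200] µm²/ms; a trust-region reflective solver
    is used so the bounds are honoured.  Non-convergence is flagged on the
    result instead of raising.

    With only a handful of b-values and none below 50 s/mm² the D*
    estimate is poorly conditioned; treat it as diagnostic only.
    """
    if not curve.normalized:
        curve = normalize_roi_signals(curve)
    user_init = init is not None
    if init is None:
        init = segmented_fit(curve)
    if bounds is None:
        lo = np.array([0.0, 1e-6, 1e-3])
        hi = np.array([1.0 - 1e-9, 5.0, 200.0])
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    x0 = np.array([init.f, init.d, init.d_star if init.d_star else d_star_init])
    if ((x0 < lo) | (x0 > hi)).any():
        if user_init:
            raise UsageError(f"initial guess {x0} violates bounds")
        x0 = np.clip(x0, lo, hi)  # noisy segmented estimates may start outside

    def residuals(x: np.ndarray) -> np.ndarray:
        return biexponential_signal(curve.b_values, *x) - curve.signals

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    f, d, d_star = sol.x
    return IVIMFitResult(
        d=float(d),
        f=float(f),
        intercept_log=float(math.log(max(1.0 - f, 1e-300))),
        n_points_used=int(curve.b_values.size),
        method="biexponential",
        f_mode="exp",
        d_star=float(d_star),
        s0=1.0,
        converged=bool(sol.success),
        message=str(sol.message),
    )
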