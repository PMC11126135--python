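"""Rayleigh-based SNR estimation and Rician noise generation.

Magnitude MR images acquired with a single-channel coil have Rician-
distributed voxel noise; where the true signal vanishes the distribution
reduces to a Rayleigh with

    mean = sigma * sqrt(pi / 2),      std = sigma * sqrt(2 - pi / 2),

so the Gaussian noise level sigma can be recovered from either the mean or
the standard deviation of a background (noise-only) ROI.  The two SNR
estimators below divide the mean muscle signal by sigma recovered each
way.  (On multi-channel coils these are approximations only.)

The Rician sampler is shared with the synthetic-study generator; its
noise-floor bias — the mean noisy magnitude always exceeds the true
magnitude — is what drives IVIM parameter bias at low SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UsageError

__all__ = [
    "SNREstimate",
    "estimate_snr",
    "roi_snr",
    "add_rician_noise",
    "RAYLEIGH_MEAN_FACTOR",
    "RAYLEIGH_STD_FACTOR",
]

#: E[Rayleigh(sigma)] / sigma
RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)
#: Std[Rayleigh(sigma)] / sigma
RAYLEIGH_STD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


@dataclass(frozen=True)
class SNREstimate:
    """Signal-to-noise estimates from a muscle ROI and a background ROI.

    ``snr1`` recovers sigma from the background mean, ``snr2`` from the
    background standard deviation.  ``measurable`` is False when the
    background statistics are zero (e.g. integer-rounded high-field data),
    in which case both estimates are NaN.
    """

    snr1: float
    snr2: float
    n_roi: int | None = None
    snr_roi: float | None = None
    measurable: bool = True


def estimate_snr(
    muscle_mean: float,
    noise_mean: float,
    noise_std: float,
    n_roi: int | None = None,
) -> SNREstimate:
    """Estimate SNR = muscle mean / sigma under the Rayleigh background model.

    Parameters
    ----------
    muscle_mean : float
        Mean magnitude in the tissue ROI.
    noise_mean, noise_std : float
        Mean and standard deviation of the magnitude in a signal-free ROI.
    n_roi : int, optional
        If given, ``snr_roi`` = snr1 * sqrt(n_roi) is also reported.

    Returns
    -------
    SNREstimate
        Flagged unmeasurable (NaN estimates) when both background
        statistics are zero.
    """
    if not muscle_mean > 0:
        raise UsageError(f"muscle_mean must be positive, got {muscle_mean}")
    if noise_mean < 0 or noise_std < 0:
        raise UsageError("noise statistics must be non-negative")
    if noise_mean == 0 and noise_std == 0:
        return SNREstimate(snr1=math.nan, snr2=math.nan, n_roi=n_roi, measurable=False)
    snr1 = muscle_mean / (noise_mean * math.sqrt(2.0 / math.pi)) if noise_mean > 0 else math.nan
    snr2 = muscle_mean / (noise_std / RAYLEIGH_STD_FACTOR) if noise_std > 0 else math.nan
    snr_roi = snr1 * math.sqrt(n_roi) if (n_roi and not math.isnan(snr1)) else None
    return SNREstimate(snr1=snr1, snr2=snr2, n_roi=n_roi, snr_roi=snr_roi)


def roi_snr(snr_voxel: float, n_roi: int, rounding: str = "exact") -> float:
    """SNR of an N-voxel ROI mean: single-voxel SNR times sqrt(N).

    ``rounding="paper_style"`` rounds sqrt(N) to the nearest integer
    before multiplying, reproducing the back-of-envelope convention
    (e.g. SNR 7, N = 23 -> 7 * 5 = 35 instead of 33.57).
    """
    if not snr_voxel > 0:
        raise UsageError(f"snr_voxel must be positive, got {snr_voxel}")
    if n_roi < 1:
        raise UsageError(f"n_roi must be >= 1, got {n_roi}")
    if rounding == "exact":
        return snr_voxel * math.sqrt(n_roi)
    if rounding == "paper_style":
        return snr_voxel * round(math.sqrt(n_roi))
    raise UsageError(f"rounding must be 'exact' or 'paper_style', got {rounding!r}")


def add_rician_noise(
    signal: np.ndarray,
    sigma: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Replace true magnitudes by Rician-noised magnitudes.

    Each value s becomes sqrt((s + n1)² + n2²) with n1, n2 independent
    zero-mean Gaussians of standard deviation ``sigma``.  Deterministic
    under a fixed ``seed`` (ignored when ``rng`` is given).
    """
    if sigma < 0:
        raise UsageError(f"sigma must be non-negative, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)
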