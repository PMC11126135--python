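"""Delimited-text signal tables and batch fitting.

The on-disk interchange format is a long-format delimited table with the
columns ``subject, field_T, muscle, state, slice, b_value, signal``; each
(subject, field_T, muscle, state, slice) group is one ROI-mean signal
curve.  The writer side lives in :mod:`ivimfield.simulate`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError, UsageError
from .ivim import SignalCurve, normalize_roi_signals, segmented_fit

__all__ = ["SIGNAL_COLUMNS", "GROUP_KEYS", "read_signal_table", "curves_from_table", "fit_signal_table"]

GROUP_KEYS = ["subject", "field_T", "muscle", "state", "slice"]
SIGNAL_COLUMNS = GROUP_KEYS + ["b_value", "signal"]


def read_signal_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a signal table; the delimiter is sniffed unless given."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = set(SIGNAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def curves_from_table(df: pd.DataFrame) -> dict[tuple, SignalCurve]:
    """Group a long-format table into one SignalCurve per ROI measurement."""
    if df.empty:
        raise UsageError("signal table is empty")
    curves: dict[tuple, SignalCurve] = {}
    for key, grp in df.groupby(GROUP_KEYS, sort=True):
        grp = grp.sort_values("b_value")
        curves[key] = SignalCurve(
            b_values=grp["b_value"].to_numpy(float),
            signals=grp["signal"].to_numpy(float),
        )
    return curves


def fit_signal_table(
    df: pd.DataFrame, b_threshold: float = 100.0, f_mode: str = "exp"
) -> pd.DataFrame:
    """Segmented-fit every curve in a signal table.

    Returns a fit table mirroring the grouping keys plus the estimates
    ``(D, f, method, intercept_log, n_points_used)``.
    """
    rows = []
    for key, curve in curves_from_table(df).items():
        fit = segmented_fit(normalize_roi_signals(curve), b_threshold=b_threshold, f_mode=f_mode)
        rows.append(
            dict(zip(GROUP_KEYS, key))
            | {
                "D": fit.d,
                "f": fit.f,
                "method": fit.method,
                "intercept_log": fit.intercept_log,
                "n_points_used": fit.n_points_used,
            }
        )
    return pd.DataFrame(rows)
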