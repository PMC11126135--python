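"""Normality-gated paired comparisons of IVIM parameters.

For each contrast the Shapiro–Wilk test is run on the paired differences;
if normality is not rejected (p >= alpha) a paired t-test is used,
otherwise the Wilcoxon signed-rank test.  This is deliberately thin glue
around scipy's published tests — the modelling content of the package
lives in the relaxation and fitting modules.

Per-slice values may be treated as observations (as in the source study's
box plots) or averaged per subject first; the per-slice pooling ignores
within-subject correlation, so its p-values are optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, UsageError

__all__ = ["PairedTestResult", "paired_compare", "study_comparisons"]


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one normality-gated paired comparison."""

    normality_p: float
    test_used: str  # "paired-t" | "wilcoxon-signed-rank"
    statistic: float
    p_value: float
    alpha: float = 0.05
    n_pairs: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def paired_compare(x, y, alpha: float = 0.05) -> PairedTestResult:
    """Compare two paired samples with a Shapiro–Wilk-gated test choice.

    Parameters
    ----------
    x, y : array-like
        Paired observations of equal length >= 3, no missing pairs.
    alpha : float
        Significance level for both the normality gate and the final test.

    Returns
    -------
    PairedTestResult
        Two-sided p-value; ``test_used`` is ``"paired-t"`` iff the
        Shapiro–Wilk p on the differences is >= alpha.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise UsageError(f"need at least 3 pairs, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DataError("missing values in paired samples")
    diff = x - y
    if np.all(diff == 0):
        raise DataError("all paired differences are zero; both tests are undefined")

    normality_p = float(sps.shapiro(diff).pvalue)
    if normality_p >= alpha:
        res = sps.ttest_rel(x, y)
        test_used = "paired-t"
    else:
        res = sps.wilcoxon(x, y)
        test_used = "wilcoxon-signed-rank"
    return PairedTestResult(
        normality_p=normality_p,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        n_pairs=int(x.size),
    )


def study_comparisons(
    fits: pd.DataFrame,
    alpha: float = 0.05,
    grouping: str = "slice",
) -> pd.DataFrame:
    """Field-strength and activation contrasts per muscle and parameter.

    Parameters
    ----------
    fits : pandas.DataFrame
        Fit table from :func:`ivimfield.tables.fit_signal_table`.
    grouping : str
        ``"slice"`` treats each (subject, slice) value as an observation;
        ``"subject"`` averages slices per subject before pairing.

    Returns
    -------
    pandas.DataFrame
        One row per (parameter, muscle, contrast) with the gated test's
        name, p-value and significance flag.
    """
    if grouping not in ("slice", "subject"):
        raise UsageError(f"grouping must be 'slice' or 'subject', got {grouping!r}")
    df = fits.copy()
    if grouping == "subject":
        df = (
            df.groupby(["subject", "field_T", "muscle", "state"], as_index=False)[["D", "f"]]
            .mean()
            .assign(slice=0)
        )

    fields = sorted(df["field_T"].unique())
    rows = []
    for parameter in ("f", "D"):
        for muscle, mgrp in df.groupby("muscle"):
            # field contrast within each state
            if len(fields) == 2:
                for state, sgrp in mgrp.groupby("state"):
                    wide = sgrp.pivot_table(
                        index=["subject", "slice"], columns="field_T", values=parameter
                    ).dropna()
                    if len(wide) >= 3:
                        r = paired_compare(wide[fields[0]], wide[fields[1]], alpha=alpha)
                        rows.append(
                            {
                                "parameter": parameter,
                                "muscle": muscle,
                                "contrast": f"{fields[0]}T_vs_{fields[1]}T_{state}",
                                "test_used": r.test_used,
                                "normality_p": r.normality_p,
                                "p_value": r.p_value,
                                "significant": r.significant,
                                "n_pairs": r.n_pairs,
                            }
                        )
            # activation contrast within each field
            for field_value, fgrp in mgrp.groupby("field_T"):
                wide = fgrp.pivot_table(
                    index=["subject", "slice"], columns="state", values=parameter
                ).dropna()
                if {"baseline", "activated"} <= set(wide.columns) and len(wide) >= 3:
                    r = paired_compare(wide["activated"], wide["baseline"], alpha=alpha)
                    rows.append(
                        {
                            "parameter": parameter,
                            "muscle": muscle,
                            "contrast": f"activation_at_{field_value}T",
                            "test_used": r.test_used,
                            "normality_p": r.normality_p,
                            "p_value": r.p_value,
                            "significant": r.significant,
                            "n_pairs": r.n_pairs,
                        }
                    )
    return pd.DataFrame(rows)
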