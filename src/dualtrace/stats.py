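"""Thin statistical helpers shared by the pipeline stages."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def welch_p(a, b, alternative: str = "two-sided") -> float:
    """Unequal-variance (Welch) two-sample t-test p-value.

    Degenerate inputs (both arms with zero variance) are resolved
    deterministically: p = 0 when the means differ in the tested direction,
    1 otherwise.  Fewer than two observations in either arm gives NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        da = a.mean() - b.mean()
        if alternative == "greater":
            return 0.0 if da > 0 else 1.0
        if alternative == "less":
            return 0.0 if da < 0 else 1.0
        return 0.0 if da != 0 else 1.0
    with warnings.catch_warnings():
        # near-identical arms trigger a precision-loss warning; the
        # exactly-degenerate case is handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p-values are the
    default throughout the pipeline). NaNs propagate."""
    p = np.asarray(pvalues, float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
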