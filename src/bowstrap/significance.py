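"""Significance of detected expression.

The bootstrap summarizes each gene's expression as a normal distribution
with the resampled mean μ and standard deviation σ.  The cumulative
normal distribution (CND) p-value is the probability mass that this
distribution places at or below zero expression,

    p = P(X <= 0) = Φ(−μ/σ),

so a p-value close to zero indicates statistically significant levels of
detected expression.  Two degenerate rules apply before the formula:
μ = 0 (the gene never received a read) gives p = 1, and σ = 0 with μ > 0
(identical counts in every iteration, e.g. only uniquely aligning reads)
gives p = 0.  The zero tests are exact floating-point equalities: the
aggregation produces exact zeros in precisely those cases.

Raw CND p-values are adjusted for multiple testing with the
Benjamini–Hochberg step-up false-discovery-rate procedure.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover
    from .bootstrap import ExpressionEstimate

DEFAULT_ALPHA = 0.05


def cnd_pvalue(mean: float, sd: float) -> float:
    """CND p-value for one gene's bootstrap mean and SD."""
    if mean < 0 or sd < 0:
        raise ValueError(f"mean and sd must be non-negative, got ({mean}, {sd})")
    if mean == 0:
        return 1.0
    if sd == 0:
        return 0.0
    # survival function of the standard normal at mean/sd == Phi(-mean/sd)
    return float(norm.sf(mean / sd))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def annotate_significance(estimates: Sequence["ExpressionEstimate"]) -> None:
    """Fill cnd_pvalue and bh_pvalue on a list of estimates, in place."""
    raw = [cnd_pvalue(e.mean_rpkm, e.sd_rpkm) for e in estimates]
    adjusted = bh_adjust(raw)
    for e, p, q in zip(estimates, raw, adjusted):
        e.cnd_pvalue = p
        e.bh_pvalue = float(q)


def call_expressed(
    estimates: Sequence["ExpressionEstimate"], alpha: float = DEFAULT_ALPHA
) -> np.ndarray:
    """Expressed <=> BH-adjusted p-value strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    bh = []
    for e in estimates:
        if e.bh_pvalue is None:
            raise ValueError(f"gene {e.gene!r}: bh_pvalue not populated")
        bh.append(e.bh_pvalue)
    return np.asarray(bh) < alpha
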