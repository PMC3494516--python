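"""Comparison metrics against a known truth.

Given per-gene expressed/unexpressed calls and estimated expression
levels, computes presence/absence accuracy, false-positive percentage,
Spearman rank correlation against the known expression, and MA-plot
coordinates (M = log2 ratio, A = log2 average of calculated vs. known).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .simulate import TruthTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalSummary:
    """One method's scorecard on one dataset."""

    method: str
    accuracy: float
    false_positive_pct: float
    spearman: float
    n_called: int


def _check_lengths(calls: np.ndarray, truth: TruthTable) -> np.ndarray:
    calls = np.asarray(calls, dtype=bool)
    if len(calls) != len(truth.genes):
        raise ValueError(
            f"calls ({len(calls)}) and truth ({len(truth.genes)}) differ in length"
        )
    return calls


def accuracy(calls: np.ndarray, truth: TruthTable) -> float:
    """(TP + TN) / total genes; truth-positive <=> expression weight > 0."""
    calls = _check_lengths(calls, truth)
    positive = truth.expressed
    correct = int((calls & positive).sum() + (~calls & ~positive).sum())
    return correct / len(calls)


def false_positive_pct(calls: np.ndarray, truth: TruthTable) -> float:
    """Percent of *called* genes that are truth-unexpressed; 0 if none called."""
    calls = _check_lengths(calls, truth)
    n_called = int(calls.sum())
    if n_called == 0:
        return 0.0
    false = int((calls & ~truth.expressed).sum())
    return 100.0 * false / n_called

def false_positive_pct_of_negatives(calls: np.ndarray, truth: TruthTable) -> float:
    """Secondary variant: percent of truth-unexpressed genes that are called."""
    calls = _check_lengths(calls, truth)
    n_neg = int((~truth.expressed).sum())
    if n_neg == 0:
        return 0.0
    false = int((calls & ~truth.expressed).sum())
    return 100.0 * false / n_neg


def spearman(calculated: np.ndarray, known: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties) over all genes."""
    calculated = np.asarray(calculated, dtype=float)
    known = np.asarray(known, dtype=float)
    if calculated.shape != known.shape or calculated.ndim != 1:
        raise ValueError("calculated and known must be 1-D vectors of equal length")
    if len(calculated) < 2:
        raise ValueError("need at least two genes")
    if np.all(calculated == calculated[0]) or np.all(known == known[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = spearmanr(calculated, known).statistic
    return float(rho)


def ma_values(
    calculated: np.ndarray, known: np.ndarray, genes: list[str] | None = None
) -> pd.DataFrame:
    """MA coordinates for every gene with both values strictly positive.

    M = log2(calculated / known); A = log2((calculated + known) / 2).
    Pairs with a zero (or negative) value on either side are dropped and
    the dropped count logged.  Returns a frame with columns gene, M, A
    (gene omitted if names are not supplied), indexed by the original
    gene positions.
    """
    calculated = np.asarray(calculated, dtype=float)
    known = np.asarray(known, dtype=float)
    if calculated.shape != known.shape:
        raise ValueError("calculated and known must have equal length")
    keep = (calculated > 0) & (known > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("ma_values: dropped %d gene(s) with a non-positive value", n_dropped)
    calc, ref = calculated[keep], known[keep]
    frame = pd.DataFrame(
        {
            "M": np.log2(calc / ref),
            "A": np.log2((calc + ref) / 2.0),
        },
        index=np.nonzero(keep)[0],
    )
    if genes is not None:
        frame.insert(0, "gene", [genes[i] for i in frame.index])
    return frame


def summarize(
    method: str,
    calls: np.ndarray,
    calculated_rpkm: np.ndarray,
    truth: TruthTable,
) -> EvalSummary:
    """Assemble one method's EvalSummary against the truth table."""
    calls = _check_lengths(calls, truth)
    return EvalSummary(
        method=method,
        accuracy=accuracy(calls, truth),
        false_positive_pct=false_positive_pct(calls, truth),
        spearman=spearman(calculated_rpkm, truth.true_rpkm),
        n_called=int(calls.sum()),
    )
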