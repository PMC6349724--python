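"""Inferential plumbing: Fisher's exact test and Holm-Sidak correction.

``fisher_exact`` is an exact integer implementation: two-sided p by the
probability-ordering rule (sum of hypergeometric probabilities of all
tables, with the observed margins, no more probable than the observed
table), evaluated with exact integer binomial coefficients so that ties
are resolved exactly rather than to floating-point tolerance.

``holm_sidak`` is the step-down Sidak procedure: p-values sorted
ascending are rejected while p(i) <= 1 − (1 − α)^(1/(m−i+1)); adjusted
p-values are the running maximum of 1 − (1 − p(i))^(m−i+1), capped at 1.
Rejections always form a prefix of the sorted list, and lowering α never
adds rejections.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

__all__ = ["ContingencyTable", "fisher_exact", "holm_sidak"]


@dataclass
class ContingencyTable:
    """2x2 non-negative counts with optional row/column labels."""

    counts: np.ndarray
    row_labels: tuple = ("control", "lesion")
    col_labels: tuple = ("positive", "negative")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table needs at least one positive margin")


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample odds
    ratio n11·n22 / (n12·n21), reported as ``inf`` on a zero denominator
    (``nan`` when the numerator is zero too).  The p-value sums the
    conditional hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed
    table's; probabilities are compared as exact integers.
    """
    if isinstance(table, ContingencyTable):
        table = table.counts
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])

    num = a * d
    den = b * c
    if den > 0:
        odds = num / den
    else:
        odds = np.nan if num == 0 else np.inf

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0

    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    total = sum(weights)
    tail = sum(w for w in weights if w <= observed)
    return odds, float(Fraction(tail, total))


def holm_sidak(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Sidak multiple-comparison procedure.

    Returns ``(reject, p_adjusted)`` aligned with the input order.
    Controls the family-wise error rate at ``alpha`` for independent
    tests (and conservatively under positive dependence).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject_sorted = np.zeros(m, dtype=bool)
    adj_sorted = np.empty(m)
    running = 0.0
    still_rejecting = True
    for i, idx in enumerate(order):
        remaining = m - i
        threshold = 1.0 - (1.0 - alpha) ** (1.0 / remaining)
        adj = 1.0 - (1.0 - p[idx]) ** remaining
        running = max(running, min(adj, 1.0))
        adj_sorted[i] = running
        if still_rejecting and p[idx] <= threshold:
            reject_sorted[i] = True
        else:
            still_rejecting = False
    reject = np.zeros(m, dtype=bool)
    p_adj = np.empty(m)
    reject[order] = reject_sorted
    p_adj[order] = adj_sorted
    return reject, p_adj
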