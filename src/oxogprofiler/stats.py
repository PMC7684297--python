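"""Paired Wilcoxon signed-rank inference on per-chromosome condition means.

The final step of the damage-profiling analysis pairs the per-chromosome mean
normalized totals of two conditions and tests the differences with the
Wilcoxon signed-rank test.  Zero differences are removed; absolute
differences are ranked with midranks for ties; ``W+`` and ``W-`` are the rank
sums of positive and negative differences.

Two p-value routes are provided:

* ``exact`` — the permutation distribution of ``W+`` over all ``2^n``
  equiprobable sign assignments, computed by dynamic programming over rank
  sums.  Ranks are doubled before the DP so midranks (half-integers) are
  handled exactly; no enumeration is ever needed, and the DP is polynomial
  in ``n``, not exponential.
* ``normal-approximation`` — the usual large-sample normal approximation,
  mean ``n(n+1)/4`` and variance ``n(n+1)(2n+1)/24`` minus the standard tie
  correction ``sum(t^3 - t)/48``, with optional continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiling import ConditionSummary

__all__ = [
    "WilcoxonResult",
    "ComparisonReport",
    "signed_rank_exact",
    "signed_rank_approx",
    "compare_conditions",
    "fold_change",
    "format_fold",
]

Sidedness = Literal["two-sided", "greater", "less"]

#: largest n for which compare_conditions(method="auto") uses the exact test
EXACT_SIZE_CAP = 25


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic and p-value for one paired comparison."""

    n_pairs_used: int
    w_plus: float
    w_minus: float
    statistic: float
    p_value: float
    sidedness: Sidedness
    method: Literal["exact", "normal-approximation"]


@dataclass
class ComparisonReport:
    """Per-chromosome comparison table plus the test result and verdict."""

    table: pd.DataFrame  # columns: chromosome, mean_a, mean_b, difference
    result: WilcoxonResult
    alpha: float
    condition_a: str = "A"
    condition_b: str = "B"

    @property
    def significant(self) -> bool:
        return self.result.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "alpha": self.alpha,
            "significant": self.significant,
            "test": {
                "method": self.result.method,
                "sidedness": self.result.sidedness,
                "n_pairs_used": self.result.n_pairs_used,
                "w_plus": self.result.w_plus,
                "w_minus": self.result.w_minus,
                "statistic": self.result.statistic,
                "p_value": self.result.p_value,
            },
            "per_chromosome": self.table.to_dict(orient="records"),
        }


def _prepare(differences: Sequence[float]) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Drop zeros, midrank |d|; return (d, ranks, w_plus, w_minus)."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero: signed-rank statistic undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    return d, ranks, w_plus, w_minus


def _exact_pmf(doubled_ranks: np.ndarray) -> np.ndarray:
    """PMF of 2*W+ over all sign assignments, by subset-sum DP.

    ``doubled_ranks`` are integers (midranks times two), so every achievable
    value of 2*W+ is an index into the returned array.  Counts stay exact in
    float64 for n <= 53 (2^n < 2^53).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts / counts.sum()


def signed_rank_exact(
    differences: Sequence[float], sidedness: Sidedness = "two-sided"
) -> WilcoxonResult:
    """Exact signed-rank test from the permutation distribution of W+.

    Two-sided p is ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))``; ``greater``
    tests for positive differences (large W+), ``less`` for negative.
    """
    d, ranks, w_plus, w_minus = _prepare(differences)
    doubled = np.rint(2 * ranks).astype(np.int64)
    pmf = _exact_pmf(doubled)
    idx = int(round(2 * w_plus))
    cdf = float(pmf[: idx + 1].sum())   # P(W+ <= observed)
    sf = float(pmf[idx:].sum())         # P(W+ >= observed)
    if sidedness == "two-sided":
        p = min(1.0, 2.0 * min(cdf, sf))
    elif sidedness == "greater":
        p = sf
    elif sidedness == "less":
        p = cdf
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return WilcoxonResult(
        n_pairs_used=d.size, w_plus=w_plus, w_minus=w_minus,
        statistic=min(w_plus, w_minus), p_value=p,
        sidedness=sidedness, method="exact",
    )


def signed_rank_approx(
    differences: Sequence[float],
    sidedness: Sidedness = "two-sided",
    continuity_correction: bool = True,
) -> WilcoxonResult:
    """Normal approximation to the signed-rank test, with tie correction.

    With a single nonzero difference the approximation is meaningless and the
    exact test is returned instead.
    """
    d, ranks, w_plus, w_minus = _prepare(differences)
    n = d.size
    if n < 2:
        return signed_rank_exact(differences, sidedness)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        raise ValueError("zero variance after tie correction; use the exact test")
    sd = math.sqrt(var)
    dev = w_plus - mean
    cc = 0.5 if continuity_correction else 0.0
    if sidedness == "two-sided":
        z = (abs(dev) - cc) / sd
        p = 2.0 * float(sps.norm.sf(z))
    elif sidedness == "greater":
        p = float(sps.norm.sf((dev - cc) / sd))
    elif sidedness == "less":
        p = float(sps.norm.cdf((dev + cc) / sd))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = min(1.0, max(p, np.finfo(float).tiny))
    return WilcoxonResult(
        n_pairs_used=n, w_plus=w_plus, w_minus=w_minus,
        statistic=min(w_plus, w_minus), p_value=p,
        sidedness=sidedness, method="normal-approximation",
    )


def compare_conditions(
    a: ConditionSummary,
    b: ConditionSummary,
    alpha: float = 0.05,
    method: Literal["auto", "exact", "approx"] = "auto",
    sidedness: Sidedness = "two-sided",
) -> ComparisonReport:
    """Paired signed-rank comparison of two conditions' per-chromosome means.

    Differences are ``b - a`` per chromosome.  ``method="auto"`` uses the
    exact permutation distribution up to ``EXACT_SIZE_CAP`` nonzero pairs and
    the normal approximation beyond.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if set(a.chromosomes) != set(b.chromosomes):
        raise ValueError(
            f"chromosome sets differ: {sorted(a.chromosomes)} vs {sorted(b.chromosomes)}"
        )
    chroms = list(a.chromosomes)
    mean_a = np.array([a.means[c] for c in chroms])
    mean_b = np.array([b.means[c] for c in chroms])
    diffs = mean_b - mean_a
    table = pd.DataFrame(
        {"chromosome": chroms, "mean_a": mean_a, "mean_b": mean_b, "difference": diffs}
    )
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero == 0:
        raise ValueError("all per-chromosome differences are zero: test undefined")
    if method == "exact" or (method == "auto" and n_nonzero <= EXACT_SIZE_CAP):
        result = signed_rank_exact(diffs, sidedness)
    elif method in ("approx", "auto"):
        result = signed_rank_approx(diffs, sidedness)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonReport(
        table=table, result=result, alpha=alpha,
        condition_a=a.condition, condition_b=b.condition,
    )


def fold_change(numerator: float, denominator: float) -> float:
    """Plain ratio ``numerator / denominator`` (denominator must be positive)."""
    if denominator <= 0:
        raise ValueError("fold change undefined for non-positive denominator")
    return numerator / denominator


def format_fold(ratio: float, ndigits: int = 1) -> str:
    """Report a ratio as 'x fold increase' (>=1) or reciprocal 'fold decrease'."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio >= 1:
        return f"{round(ratio, ndigits)} fold increase"
    return f"{round(1.0 / ratio, ndigits)} fold decrease"
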