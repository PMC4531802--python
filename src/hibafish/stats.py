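"""Population-level statistics for break/translocation calling.

Proportions of event-positive nuclei are reported with modified Wald
(Agresti-Coull) 95% confidence intervals: p~ = (x+2)/(n+4) with a normal
half-width z*sqrt(p~(1-p~)/(n+4)), bounds clipped to [0, 1]. This "add two
successes and two failures" variant has near-nominal coverage for small
proportions, which is exactly the regime of rare break events. Pairwise
condition comparisons use the two-sided Fisher exact test for count data
(probability-mass convention: the p-value sums hypergeometric probabilities
of all tables no more probable than the observed one). No multiple-testing
correction is applied; comparisons are reported unadjusted.

The separation/proximity distance threshold is calibrated empirically from
a negative-control (unbroken) condition as the smallest integer pixel
radius covering a target fraction (default 99.8%) of per-Red minimum
Red/Green distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import Thresholds

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "proportion_positive",
    "modified_wald_ci",
    "fisher_exact_comparison",
    "calibrate_threshold",
    "spot_count_histogram",
    "format_percent",
    "condition_summaries",
    "pairwise_comparisons",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Event-positive proportion of one condition, with its 95% CI."""

    condition: str
    event_class: str
    n_nuclei_analyzed: int
    n_positive: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> str:
        return format_percent(self.proportion)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Fisher exact comparison of two conditions' positive rates."""

    condition_a: str
    condition_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    fold_change: float | None


def proportion_positive(
    summaries: pd.DataFrame,
    event_class: str,
) -> tuple[int, int, float]:
    """Count event-positive nuclei among QC-passing ones.

    ``summaries`` is the nucleus-summary table from event calling;
    ``event_class`` is ``"breakage"`` or ``"translocation"``. Returns
    ``(n_positive, n_total, proportion)``.
    """
    col = {"breakage": "breakage_positive",
           "translocation": "translocation_positive"}[event_class]
    passing = summaries[summaries["qc_pass"].astype(bool)]
    n_total = len(passing)
    if n_total == 0:
        raise ValueError("no QC-passing nuclei in condition")
    n_pos = int(passing[col].astype(bool).sum())
    return n_pos, n_total, n_pos / n_total


def modified_wald_ci(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Modified Wald (Agresti-Coull add-2/add-4) binomial proportion CI.

    ``p~ = (x+2)/(n+4)``; half-width ``z * sqrt(p~ (1-p~) / (n+4))`` with
    ``z`` the two-sided normal quantile (1.96 at 95%); clipped to [0, 1].
    """
    if n <= 0 or not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    p = (x + 2.0) / (n + 4.0)
    half = z * np.sqrt(p * (1.0 - p) / (n + 4.0))
    return max(0.0, p - half), min(1.0, p + half)


def fisher_exact_comparison(a_pos: int, a_neg: int, b_pos: int, b_neg: int,
                            condition_a: str = "A",
                            condition_b: str = "B") -> ComparisonResult:
    """Two-sided Fisher exact test on the 2x2 positives/negatives table.

    The fold change is the ratio of condition B's positive proportion to
    condition A's; undefined (None) when the baseline proportion is zero.
    """
    counts = (a_pos, a_neg, b_pos, b_neg)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if a_pos + a_neg == 0 or b_pos + b_neg == 0:
        raise ValueError("both conditions need at least one nucleus")
    _, p = sps.fisher_exact([[a_pos, a_neg], [b_pos, b_neg]], alternative="two-sided")
    pa = a_pos / (a_pos + a_neg)
    pb = b_pos / (b_pos + b_neg)
    fold = pb / pa if pa > 0 else None
    return ComparisonResult(condition_a, condition_b,
                            ((a_pos, a_neg), (b_pos, b_neg)), float(p), fold)


def calibrate_threshold(rg_min_distances: Sequence[float],
                        coverage: float = 0.998) -> int:
    """Smallest integer pixel threshold covering the target distance quantile.

    Input distances come from a negative-control (unbroken) condition after
    QC; the returned ``t`` is the smallest integer with
    ``fraction(d <= t) >= coverage``.
    """
    d = np.asarray(rg_min_distances, dtype=float)
    if d.size == 0:
        raise ValueError("no control distances supplied for calibration")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    q = np.quantile(d, coverage, method="inverted_cdf")
    return int(np.ceil(q))


def spot_count_histogram(nuclei_counts: Sequence[int] | pd.Series) -> pd.Series:
    """Relative frequency of nuclei by spot count (zero-count bin included).

    Accepts the per-nucleus spot counts of one channel (all non-excluded
    nuclei, before QC). Returns a Series indexed by count.
    """
    counts = pd.Series(list(nuclei_counts), dtype=int)
    if counts.empty:
        return pd.Series(dtype=float)
    freq = counts.value_counts(normalize=True).sort_index()
    freq.index.name = "n_spots"
    return freq


def format_percent(p: float) -> str:
    """Mixed-precision percentage: two significant figures below 1%, three above."""
    pct = 100.0 * p
    if pct == 0:
        return "0.00%"
    digits = 2 if pct < 1 else 3
    from decimal import Decimal

    q = float(f"{pct:.{digits}g}")
    # avoid scientific notation for tiny values
    s = np.format_float_positional(q, trim="-")
    return f"{s}%"


# ---------------------------------------------------------------------------
# condition-level tables
# ---------------------------------------------------------------------------

def condition_summaries(
    summaries_by_condition: dict[str, pd.DataFrame],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """One row per condition x event class: counts, proportion, CI bounds."""
    rows = []
    for cond, df in summaries_by_condition.items():
        for ev in ("breakage", "translocation"):
            x, n, p = proportion_positive(df, ev)
            lo, hi = modified_wald_ci(x, n, confidence)
            rows.append((cond, ev, n, x, p, lo, hi, format_percent(p)))
    return pd.DataFrame(
        rows,
        columns=["condition", "event_class", "n_nuclei_analyzed", "n_positive",
                 "proportion", "ci_low", "ci_high", "percent"],
    )


def pairwise_comparisons(summary_table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Fisher comparisons within each event class."""
    rows = []
    for ev, sub in summary_table.groupby("event_class"):
        sub = sub.reset_index(drop=True)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                a, b = sub.iloc[i], sub.iloc[j]
                res = fisher_exact_comparison(
                    int(a["n_positive"]), int(a["n_nuclei_analyzed"] - a["n_positive"]),
                    int(b["n_positive"]), int(b["n_nuclei_analyzed"] - b["n_positive"]),
                    a["condition"], b["condition"],
                )
                rows.append((ev, res.condition_a, res.condition_b,
                             res.p_value,
                             res.fold_change if res.fold_change is not None else np.nan))
    return pd.DataFrame(
        rows, columns=["event_class", "condition_a", "condition_b",
                       "p_value", "fold_change"],
    )
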