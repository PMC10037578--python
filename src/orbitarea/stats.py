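"""Paired cohort comparison of 2D vs 3D defect areas.

The clinical question is paired: every fracture gets both a slice-based 2D
estimate and a surface-based 3D measurement.  The default test is the
Wilcoxon signed-rank test, the standard nonparametric paired comparison
(the paired analogue of the Mann–Whitney U test; an unpaired MWU is
available for completeness).  Per-case fold ratios a3d/a2d are summarized
separately from the ratio of summary means — the two are different
quantities and both are reported, labelled distinctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Summary",
    "PairedTestResult",
    "PairedCohortResult",
    "summarize",
    "fold_stats",
    "paired_test",
    "wilcoxon_signed_rank",
    "count_comparison",
    "compare_cohort",
    "cohort_report",
    "paired_lines_segments",
]

#: absolute tolerance (mm^2) below which two paired areas count as a tie
TIE_TOL = 1e-9

# exact enumeration of the signed-rank null is O(n * S); cap where it stays instant
_EXACT_N_MAX = 25


@dataclass(frozen=True)
class Summary:
    """Five-number descriptive summary (sample SD, n-1 denominator)."""

    mean: float
    median: float
    sd: float
    min: float
    max: float
    n: int


def summarize(areas) -> Summary:
    """Mean (MV), median (MED), sample SD, min and max of a list of areas."""
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise ValueError("cannot summarize an empty list")
    if a.size < 2:
        raise ValueError("need n >= 2 for a sample standard deviation")
    return Summary(
        mean=float(a.mean()),
        median=float(np.median(a)),
        sd=float(a.std(ddof=1)),
        min=float(a.min()),
        max=float(a.max()),
        n=int(a.size),
    )


def fold_stats(a2d, a3d) -> tuple[np.ndarray, Summary]:
    """Per-case fold ratios a3d/a2d and their summary.

    Note the mean of per-case folds is *not* the ratio of mean areas; callers
    wanting the latter should divide the two mean areas explicitly.
    """
    a2d = np.asarray(a2d, dtype=float)
    a3d = np.asarray(a3d, dtype=float)
    if a2d.shape != a3d.shape:
        raise ValueError("paired arrays must have equal length")
    if np.any(a2d <= 0):
        raise ValueError("fold ratios undefined: some 2D areas are zero or negative")
    folds = a3d / a2d
    return folds, summarize(folds)


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str
    statistic: float
    p_value: float
    n_effective: int  # pairs remaining after zero-difference removal
    mode: str  # "exact" or "normal_approx"


def _signed_rank_stats(diff: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(W+, W-, midranks of |diff|) after removing zero differences."""
    ranks = sps.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    w_minus = float(ranks[diff < 0].sum())
    return w_plus, w_minus, ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p over all 2^n equally likely sign assignments.

    Computed by dynamic programming on the distribution of W+ (ranks doubled
    to make midranks integral), which enumerates the same null as a literal
    2^n sweep.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = float(counts[: w2 + 1].sum())
    sf = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def _normal_approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    _vals, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        raise ValueError("degenerate signed-rank variance (all differences tied)")
    dev = w_plus - mu
    z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(a2d, a3d, mode: str = "auto") -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired areas.

    Zero differences are discarded; |differences| are midranked; the
    statistic is W = min(W+, W-).  ``mode``: "exact" (full null enumeration,
    n <= 25), "normal_approx", or "auto" (exact when feasible).
    """
    d = np.asarray(a3d, dtype=float) - np.asarray(a2d, dtype=float)
    d = d[np.abs(d) > TIE_TOL]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: signed-rank test undefined")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError("mode must be auto, exact or normal_approx")
    if mode == "exact" and n > _EXACT_N_MAX:
        raise ValueError(f"exact mode is limited to n <= {_EXACT_N_MAX} pairs")
    use_exact = mode == "exact" or (mode == "auto" and n <= _EXACT_N_MAX)

    w_plus, w_minus, ranks = _signed_rank_stats(d)
    if use_exact:
        p = _exact_signed_rank_p(w_plus, ranks)
        used = "exact"
    else:
        p = _normal_approx_signed_rank_p(w_plus, ranks)
        used = "normal_approx"
    return PairedTestResult(
        test_name="wilcoxon_signed_rank",
        statistic=min(w_plus, w_minus),
        p_value=p,
        n_effective=n,
        mode=used,
    )


def paired_test(a2d, a3d, method: str = "wilcoxon_signed_rank", mode: str = "auto") -> PairedTestResult:
    """Dispatch to the signed-rank test (default) or an unpaired Mann–Whitney U.

    The MWU variant ignores the pairing and is provided for completeness
    only; for paired area measurements the signed-rank test is appropriate.
    """
    if method == "wilcoxon_signed_rank":
        return wilcoxon_signed_rank(a2d, a3d, mode=mode)
    if method == "mann_whitney_u":
        res = sps.mannwhitneyu(np.asarray(a3d, float), np.asarray(a2d, float), alternative="two-sided")
        return PairedTestResult(
            test_name="mann_whitney_u",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_effective=len(np.asarray(a2d)),
            mode="normal_approx" if len(np.asarray(a2d)) > 8 else "exact",
        )
    raise ValueError(f"unknown method {method!r}")


def count_comparison(a2d, a3d, tol: float = TIE_TOL) -> tuple[int, int, int]:
    """(n_3d_larger, n_2d_larger, n_ties) under an absolute tie tolerance."""
    d = np.asarray(a3d, dtype=float) - np.asarray(a2d, dtype=float)
    ties = np.abs(d) <= tol
    return int((d > tol).sum()), int((d < -tol).sum()), int(ties.sum())


@dataclass(frozen=True)
class PairedCohortResult:
    """Everything the paired 2D/3D comparison of one cohort produces."""

    cases: pd.DataFrame  # columns case_id, a2d, a3d, fold
    summary_2d: Summary
    summary_3d: Summary
    summary_fold: Summary
    n_3d_larger: int
    n_2d_larger: int
    n_ties: int
    test: PairedTestResult

    @property
    def n(self) -> int:
        return len(self.cases)


def compare_cohort(
    case_ids,
    a2d,
    a3d,
    method: str = "wilcoxon_signed_rank",
    mode: str = "auto",
) -> PairedCohortResult:
    """Run the full paired comparison: summaries, folds, counts and the test."""
    a2d = np.asarray(a2d, dtype=float)
    a3d = np.asarray(a3d, dtype=float)
    folds, fold_summary = fold_stats(a2d, a3d)
    n3, n2, nt = count_comparison(a2d, a3d)
    cases = pd.DataFrame({"case_id": list(case_ids), "a2d": a2d, "a3d": a3d, "fold": folds})
    return PairedCohortResult(
        cases=cases,
        summary_2d=summarize(a2d),
        summary_3d=summarize(a3d),
        summary_fold=fold_summary,
        n_3d_larger=n3,
        n_2d_larger=n2,
        n_ties=nt,
        test=paired_test(a2d, a3d, method=method, mode=mode),
    )


def cohort_report(result: PairedCohortResult) -> pd.DataFrame:
    """Summary table: rows Mean/Median/SD/Min/Max, columns 2D, 3D, fold."""
    if result.n == 0:
        raise ValueError("empty cohort")
    rows = ["Mean", "Median", "SD", "Minimum", "Maximum"]
    cols = {}
    for name, s in (("2D", result.summary_2d), ("3D", result.summary_3d), ("fold", result.summary_fold)):
        cols[name] = [s.mean, s.median, s.sd, s.min, s.max]
    return pd.DataFrame(cols, index=pd.Index(rows, name="statistic"))


def paired_lines_segments(result: PairedCohortResult) -> pd.DataFrame:
    """One line segment per case for a paired-lines plot (x: method, y: area)."""
    df = result.cases
    return pd.DataFrame(
        {
            "case_id": df["case_id"],
            "x0": 0.0,
            "y0": df["a2d"],
            "x1": 1.0,
            "y1": df["a3d"],
        }
    )
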