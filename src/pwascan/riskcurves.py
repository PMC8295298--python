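"""Cancer risk as a function of gene effect scores.

For a single gene and score model (dominant or recessive), the cohort is
partitioned at score cutoffs: "bottom p%" is the fraction of the cohort
with the lowest scores (the most estimated damage), "top p%" the fraction
with the highest.  Because small tail groups show wild sampling noise, the
prevalence plotted for each group is a *conservative* estimate based on the
95% Wilson score interval for the binomial case fraction: when the interval
covers the cohort-wide baseline rate the estimate is the baseline itself,
and when the interval lies strictly above (below) the baseline the bound
closer to the baseline — the lower (upper) bound — is taken.

A single "most significant" partition is also chosen by scanning score
cutoffs with a two-sided Fisher exact test on the resulting 2x2 table and
keeping the minimizer; it is reported only when that minimum p-value is
below a display gate (1e-3), and being a min over many correlated tests it
is exploratory, not corrected evidence.  All scanned p-values are retained
so users can apply their own correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CutoffPoint",
    "BestCutoff",
    "RiskCurve",
    "wilson_interval",
    "conservative_prevalence",
    "risk_ratio",
    "best_cutoff_fisher",
    "build_risk_curve",
    "plot_risk_curve",
]

DEFAULT_PERCENTILES = (0.005, 0.009, 0.01, 0.02, 0.05, 0.1, 0.25, 0.5)
DISPLAY_P_GATE = 1e-3


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion k/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    # the Wilson bounds are exactly 0 at k=0 and 1 at k=n
    low = 0.0 if k == 0 else float(low)
    high = 1.0 if k == n else float(high)
    return low, high


def conservative_prevalence(
    k: int, n: int, baseline: float, confidence: float = 0.95
) -> float:
    """Shrink a group's case fraction toward the cohort baseline.

    Uses the Wilson interval for k/n: if it covers the baseline, return the
    baseline; if it lies strictly above, return the lower bound; strictly
    below, the upper bound.
    """
    if not (0.0 < baseline < 1.0):
        raise ValueError("baseline must lie in (0, 1)")
    low, high = wilson_interval(k, n, confidence)
    if low > baseline:
        return low
    if high < baseline:
        return high
    return baseline


def risk_ratio(table) -> float:
    """Prevalence ratio from a 2x2 (cases, non-cases) x (group, rest) table.

    Oriented with the larger prevalence in the numerator, so the ratio is
    always >= 1 (directionality is reported separately).  Infinite when one
    group has zero prevalence and the other does not.
    """
    (k_g, m_g), (k_r, m_r) = table
    n_g, n_r = k_g + m_g, k_r + m_r
    if min(k_g, m_g, k_r, m_r) < 0:
        raise ValueError("table cells must be non-negative")
    if n_g < 1 or n_r < 1:
        raise ValueError("both rows need at least one individual")
    p_g, p_r = k_g / n_g, k_r / n_r
    hi, lo = max(p_g, p_r), min(p_g, p_r)
    if hi == lo:
        return 1.0
    if lo == 0.0:
        return float("inf")
    return hi / lo


@dataclass
class CutoffPoint:
    """One percentile group on a risk curve."""

    side: str  # "bottom" | "top" | "all"
    percentile: float
    n_group: int
    k_group: int
    naive_freq: float
    wilson_low: float
    wilson_high: float
    estimate: float


@dataclass
class BestCutoff:
    """The Fisher-exact-optimal partition of the cohort for one gene."""

    side: str
    threshold: float
    table: tuple  # ((k_group, noncases_group), (k_rest, noncases_rest))
    fisher_p: float
    risk_ratio: float
    n_group: int


@dataclass
class RiskCurve:
    """Conservative prevalence estimates over a cutoff grid for one gene."""

    gene_id: str
    phenotype: str
    model: str
    baseline: float
    n_total: int
    k_total: int
    points: list[CutoffPoint] = field(default_factory=list)
    best_cutoff: BestCutoff | None = None
    scanned: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": self.gene_id,
                    "phenotype": self.phenotype,
                    "model": self.model,
                    "side": p.side,
                    "percentile": p.percentile,
                    "n_group": p.n_group,
                    "k_group": p.k_group,
                    "naive_freq": p.naive_freq,
                    "wilson_low": p.wilson_low,
                    "wilson_high": p.wilson_high,
                    "estimate": p.estimate,
                }
                for p in self.points
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def best_cutoff_fisher(
    scores,
    labels,
    p_display: float = DISPLAY_P_GATE,
    max_distinct: int = 10_000,
    grid_points: int = 2_000,
    return_scan: bool = False,
):
    """Scan score cutoffs for the most case-control-separating partition.

    Candidate thresholds are the distinct observed score values (a
    percentile grid of ``grid_points`` when there are more than
    ``max_distinct``); for each threshold t the cohort splits into the
    "bottom" group (score <= t; ties included) and its complement, and a
    two-sided Fisher exact test is applied to the 2x2 case table.  Swapping
    which group is called "bottom" or "top" only swaps the table's rows, so
    each threshold is tested once; the reported side is that of the smaller
    group.  Returns None (no displayable cutoff) when the minimum p-value
    is not below ``p_display``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct scores to place a cutoff")
    if len(distinct) > max_distinct:
        qs = np.linspace(0, 1, grid_points + 1)[1:-1]
        thresholds = np.unique(np.quantile(s, qs))
        thresholds = thresholds[thresholds < distinct[-1]]
    else:
        thresholds = distinct[:-1]  # cutting at the max leaves an empty top

    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    cum_k = np.cumsum(y_sorted)
    K, N = int(y.sum()), len(y)

    # group sizes / case counts for "score <= t" via searchsorted
    n_bottom = np.searchsorted(s_sorted, thresholds, side="right")
    k_bottom = cum_k[n_bottom - 1].astype(int)

    ps = np.empty(len(thresholds))
    for i, (nb, kb) in enumerate(zip(n_bottom, k_bottom)):
        table = [[kb, nb - kb], [K - kb, (N - nb) - (K - kb)]]
        ps[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    scan = pd.DataFrame(
        {"threshold": thresholds, "n_bottom": n_bottom, "k_bottom": k_bottom, "p": ps}
    )
    i_best = int(np.argmin(ps))
    best = None
    if ps[i_best] < p_display:
        nb, kb = int(n_bottom[i_best]), int(k_bottom[i_best])
        if nb <= N - nb:
            side, n_g, k_g = "bottom", nb, kb
        else:
            side, n_g, k_g = "top", N - nb, K - kb
        k_r, n_r = K - k_g, N - n_g
        table = ((k_g, n_g - k_g), (k_r, n_r - k_r))
        best = BestCutoff(
            side=side,
            threshold=float(thresholds[i_best]),
            table=table,
            fisher_p=float(ps[i_best]),
            risk_ratio=risk_ratio(table),
            n_group=n_g,
        )
    return (best, scan) if return_scan else best


def build_risk_curve(
    scores,
    labels,
    percentile_grid=DEFAULT_PERCENTILES,
    gene_id: str = "gene",
    phenotype: str = "phenotype",
    model: str = "dominant",
    confidence: float = 0.95,
    with_best_cutoff: bool = True,
) -> RiskCurve:
    """Build the full risk curve for one gene and score model.

    For each percentile p in the grid (fractions in (0, 0.5]) and each side,
    the group is the floor(p*n) individuals with the lowest (bottom) or
    highest (top) scores under a stable ordering; each group gets a
    conservative Wilson-shrunk prevalence estimate.  The curve includes the
    whole-cohort "All" reference point, whose estimate is the baseline.
    """
    grid = sorted(set(float(p) for p in percentile_grid))
    if not grid:
        raise ValueError("percentile grid must be non-empty")
    if any(not (0.0 < p <= 0.5) for p in grid):
        raise ValueError("percentiles must lie in (0, 0.5]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, k = len(y), int(y.sum())
    if n == 0:
        raise ValueError("empty cohort")
    baseline = k / n
    order = np.argsort(s, kind="stable")
    y_bottom = y[order]
    y_top = y[order[::-1]]

    points: list[CutoffPoint] = []
    for side, y_sorted in (("bottom", y_bottom), ("top", y_top)):
        for p in grid:
            m = int(np.floor(p * n))
            if m < 1:
                continue
            kg = int(y_sorted[:m].sum())
            low, high = wilson_interval(kg, m, confidence)
            points.append(
                CutoffPoint(
                    side=side,
                    percentile=p,
                    n_group=m,
                    k_group=kg,
                    naive_freq=kg / m,
                    wilson_low=low,
                    wilson_high=high,
                    estimate=conservative_prevalence(kg, m, baseline, confidence)
                    if 0.0 < baseline < 1.0
                    else baseline,
                )
            )
    low, high = wilson_interval(k, n, confidence)
    points.append(
        CutoffPoint(
            side="all", percentile=1.0, n_group=n, k_group=k,
            naive_freq=baseline, wilson_low=low, wilson_high=high,
            estimate=baseline,
        )
    )

    curve = RiskCurve(
        gene_id=gene_id, phenotype=phenotype, model=model,
        baseline=baseline, n_total=n, k_total=k, points=points,
    )
    if with_best_cutoff:
        best, scan = best_cutoff_fisher(s, y, return_scan=True)
        curve.best_cutoff = best
        curve.scanned = scan
    return curve


def plot_risk_curve(curve: RiskCurve, path=None, ax=None):
    """Line plot of conservative prevalence vs percentile, baseline dashed."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for side, marker in (("bottom", "o"), ("top", "s")):
        pts = sorted(
            (p for p in curve.points if p.side == side), key=lambda p: p.percentile
        )
        if not pts:
            continue
        x = [p.percentile * 100 for p in pts]
        ax.plot(
            x, [p.estimate * 100 for p in pts], marker=marker, label=f"{side} %"
        )
    ax.axhline(curve.baseline * 100, linestyle="--", color="grey", label="baseline")
    ax.set_xscale("log")
    ax.set_xlabel("percentile of cohort (%)")
    ax.set_ylabel(f"estimated {curve.phenotype} prevalence (%)")
    ax.set_title(f"{curve.gene_id} ({curve.model})")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
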