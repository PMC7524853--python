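"""Group-level statistics: means, CIs, tests vs wild type, dose-response.

Cells are treated as independent units.  The reference comparison is
Welch's unequal-variance two-sample t test (the different strains contain
different cells, so no pairing exists); a permutation test on the mean
difference is available as an option.  No multiple-testing correction is
applied by default; Benjamini–Hochberg is available for metric tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "DoseResponsePoint",
    "summarize_group",
    "fold_change",
    "dose_response",
    "viability_filter",
    "benjamini_hochberg",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean, spread and significance-vs-reference of one condition group."""

    strain: str
    hexose: str
    metric: str
    n_cells: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    p_vs_reference: float = float("nan")
    significant: bool = False


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def summarize_group(
    values: Sequence[float],
    reference_values: Optional[Sequence[float]] = None,
    strain: str = "",
    hexose: str = "",
    metric: str = "",
    test: str = "welch",
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> GroupSummary:
    """Summarize one group of per-cell values, optionally tested vs reference.

    Mean, sample SD (n−1), and a t-based 95% CI; the p-value compares the
    group against ``reference_values`` with Welch's test (default) or a
    permutation test on the difference of means.  With n < 2 the CI is NaN;
    without a reference the p-value is NaN.
    """
    vals = _clean(values)
    n = vals.size
    if n < 1:
        raise ValueError("summarize_group needs at least one finite value")
    mean = float(vals.mean())
    if n >= 2:
        sd = float(vals.std(ddof=1))
        half = sps.t.ppf(1 - ALPHA / 2, df=n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        sd = float("nan")
        ci = (float("nan"), float("nan"))

    p = float("nan")
    if reference_values is not None:
        ref = _clean(reference_values)
        if ref.size >= 2 and n >= 2:
            if test == "welch":
                p = float(sps.ttest_ind(vals, ref, equal_var=False).pvalue)
            elif test == "permutation":
                if rng is None:
                    rng = np.random.default_rng(0)
                res = sps.permutation_test(
                    (vals, ref),
                    lambda a, b: np.mean(a) - np.mean(b),
                    permutation_type="independent",
                    n_resamples=n_permutations,
                    rng=rng,
                )
                p = float(res.pvalue)
            else:
                raise ValueError("test must be 'welch' or 'permutation'")
    return GroupSummary(
        strain=strain,
        hexose=hexose,
        metric=metric,
        n_cells=n,
        mean=mean,
        sd=sd,
        ci95=ci,
        p_vs_reference=p,
        significant=bool(np.isfinite(p) and p < ALPHA),
    )


def fold_change(
    group_expr_mean: float, reference_expr_mean: float
) -> tuple[float, str]:
    """Ratio of group means, e.g. reporter derepression vs wild type.

    Returns ``(value, kind)`` with ``kind`` "ratio" normally; when the
    reference mean is not positive the ratio is undefined and the absolute
    difference is reported instead (``kind`` "difference").
    """
    if reference_expr_mean > 0:
        return group_expr_mean / reference_expr_mean, "ratio"
    return group_expr_mean - reference_expr_mean, "difference"


@dataclass(frozen=True)
class DoseResponsePoint:
    """One expression-level bin of the localization dose-response."""

    expr_marker_level: float  # bin center (mean level of cells in the bin)
    mean_long_localization: float
    n_cells: int


def dose_response(
    expr_levels: Sequence[float],
    mean_long: Sequence[float],
    n_bins: int = 6,
    min_bin_n: int = 10,
) -> tuple[list[DoseResponsePoint], float, float]:
    """Localization vs kinase-expression dose-response.

    Bins cells by quantiles of the expression-marker level and reports each
    bin's mean adapted-phase localization, plus the Spearman rank
    correlation (rho, p) across single cells.  With too few cells for the
    requested bins only the correlation is returned (empty bin list).
    """
    expr = np.asarray(expr_levels, dtype=float)
    loc = np.asarray(mean_long, dtype=float)
    ok = np.isfinite(expr) & np.isfinite(loc)
    expr, loc = expr[ok], loc[ok]
    if expr.size < 3:
        raise ValueError("dose_response needs at least 3 cells")
    rho, p = sps.spearmanr(expr, loc)

    points: list[DoseResponsePoint] = []
    if expr.size >= 2 * min_bin_n and n_bins >= 2:
        try:
            bins = pd.qcut(expr, q=n_bins, duplicates="drop")
        except ValueError:
            bins = None
        if bins is not None and len(bins.categories) >= 2:
            df = pd.DataFrame({"expr": expr, "loc": loc, "bin": bins})
            for _, grp in df.groupby("bin", observed=True):
                if len(grp) >= min_bin_n:
                    points.append(
                        DoseResponsePoint(
                            expr_marker_level=float(grp["expr"].mean()),
                            mean_long_localization=float(grp["loc"].mean()),
                            n_cells=len(grp),
                        )
                    )
            points.sort(key=lambda pt: pt.expr_marker_level)
    return points, float(rho), float(p)


def viability_filter(
    metrics: pd.DataFrame, expr_threshold: Optional[float] = None
) -> tuple[pd.DataFrame, int, float]:
    """Exclude dead/arrested cells from a per-cell metric table.

    Cells flagged dead (``alive`` False, e.g. by the generator or by a
    non-growth track criterion) are removed.  Returns the filtered table,
    the excluded count, and the estimated expression threshold separating
    viable from dead cells — the midpoint between the highest viable and
    lowest dead expression-marker levels (NaN when either side is empty).
    An explicit ``expr_threshold`` instead excludes cells above it.
    """
    df = metrics.copy()
    if expr_threshold is not None:
        dead = df["expr_marker_level"] > expr_threshold
    elif "alive" in df.columns:
        dead = ~df["alive"].astype(bool)
    else:
        dead = pd.Series(False, index=df.index)
    threshold = float("nan")
    lv = df.loc[~dead, "expr_marker_level"].dropna()
    ld = df.loc[dead, "expr_marker_level"].dropna()
    if len(lv) and len(ld):
        threshold = float((lv.max() + ld.min()) / 2.0)
    return df.loc[~dead].copy(), int(dead.sum()), threshold


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (off by default in reports; provided as option)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out
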