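"""Spearman correlations with CI-sign significance and pattern metrics.

A correlation is *significant* when the 95 % confidence interval of the
Spearman coefficient keeps its sign (neither bound crosses zero).  The
point estimate is the tie-aware (mid-rank) Spearman coefficient; the
interval uses the Fisher z-transform with standard error 1/sqrt(n-3)
(the construction is isolated here and can be swapped).

Two pattern metrics summarise the best correlations per self-report
variable: *total* counts significant correlations of magnitude >= 0.5
across wearable variable families, and *contour* counts, for each strong
correlation (|rS| >= 0.8) on an intensity-ordered family, the contiguous
same-sign significant neighbours at lower and higher intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .aggregation import CLR_ORDER, PROCESSED_ORDER

__all__ = [
    "CorrelationResult",
    "ContourResult",
    "TotalCount",
    "ORDERINGS",
    "spearman_with_ci",
    "correlation_grid",
    "select_best",
    "total_metric",
    "contour_metric",
]

#: Intensity orderings per family; raw variables, sleep and the total
#: active duration have no ordering and get no contour.
ORDERINGS = {
    "processed": PROCESSED_ORDER,
    "clr_pa": CLR_ORDER,
    "clr_pa_s": CLR_ORDER,
}


@dataclass(frozen=True)
class CorrelationResult:
    """One PRO-variable x TechRO-variable Spearman result."""

    pro_variable: str
    techro_variable: str
    health_group: str
    n: int
    r_s: float
    ci_low: float
    ci_high: float
    interval_duration: int
    leeway: int
    significant: bool
    family: str = ""


@dataclass
class TotalCount:
    """Counts of strong significant correlations per wearable family."""

    pro_variable: str
    health_group: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ContourResult:
    """A strong correlation with its contiguous same-sign neighbourhood.

    ``lower_count`` / ``higher_count`` are the numbers of contiguous
    significant same-sign correlations at lower / higher intensities.
    ``lower_display`` / ``higher_display`` list the neighbouring rS
    values from the centre outward, terminated by "x" where a present
    variable breaks the run (absent variables terminate silently).
    """

    centre: CorrelationResult
    ordering_family: str
    lower_count: int
    higher_count: int
    lower_display: list = field(default_factory=list)
    higher_display: list = field(default_factory=list)


def spearman_with_ci(
    x,
    y,
    alpha: float = 0.05,
    pro_variable: str = "",
    techro_variable: str = "",
    health_group: str = "all",
    interval_duration: int = 0,
    leeway: int = 0,
    family: str = "",
) -> CorrelationResult | None:
    """Tie-aware Spearman coefficient with a Fisher-z confidence interval.

    Returns None when either input is constant (the coefficient is
    undefined).  For n < 4 the interval is undefined and the result is
    marked non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    r_s = float(stats.spearmanr(x, y).statistic)
    if math.isnan(r_s):
        return None
    if abs(r_s) > 1.0 - 1e-12:  # snap float noise at the boundary
        r_s = math.copysign(1.0, r_s)
    if n < 4:
        ci_low = ci_high = math.nan
        significant = False
    elif abs(r_s) >= 1.0:
        ci_low = ci_high = r_s
        significant = True
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
        z = math.atanh(r_s)
        se = 1.0 / math.sqrt(n - 3)
        ci_low = math.tanh(z - crit * se)
        ci_high = math.tanh(z + crit * se)
        significant = (ci_low > 0 and ci_high > 0) or (ci_low < 0 and ci_high < 0)
    return CorrelationResult(
        pro_variable,
        techro_variable,
        health_group,
        n,
        r_s,
        ci_low,
        ci_high,
        interval_duration,
        leeway,
        significant,
        family,
    )


def correlation_grid(
    observation_sets: dict,
    min_observations: int = 10,
    alpha: float = 0.05,
    **labels,
) -> dict:
    """Spearman result per (duration, leeway) cell.

    ``observation_sets`` maps (duration, leeway) -> (x, y) paired arrays
    as produced by the alignment stage.  Cells smaller than
    ``min_observations`` (or with an undefined coefficient) are omitted.
    """
    grid = {}
    for (duration, leeway), (x, y) in observation_sets.items():
        if len(x) < min_observations:
            continue
        res = spearman_with_ci(
            x, y, alpha, interval_duration=duration, leeway=leeway, **labels
        )
        if res is not None:
            grid[(duration, leeway)] = res
    return grid


def select_best(grid: dict) -> CorrelationResult | None:
    """The significant cell of maximal |rS|.

    Ties break toward smaller duration, then smaller leeway, then larger
    n.  Returns None when no cell is significant.
    """
    candidates = [r for r in grid.values() if r.significant]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda r: (-abs(r.r_s), r.interval_duration, r.leeway, -r.n),
    )


def total_metric(
    best_correlations: list,
    threshold: float = 0.5,
    pro_variable: str = "",
    health_group: str = "all",
) -> TotalCount:
    """Count significant correlations with |rS| >= threshold per family.

    ``best_correlations`` holds one best result per wearable variable
    (the ``family`` attribute assigns it to raw/processed/clr_pa/clr_pa_s).
    """
    out = TotalCount(pro_variable, health_group)
    for res in best_correlations:
        if res is None or not res.significant or abs(res.r_s) < threshold:
            continue
        out.counts[res.family] = out.counts.get(res.family, 0) + 1
    return out


def contour_metric(
    row: dict,
    family: str,
    strong_threshold: float = 0.8,
) -> list:
    """Contour of every strong correlation on an intensity-ordered family.

    ``row`` maps variable id -> best CorrelationResult (or None/missing)
    for one family of one self-report variable.  For each significant
    centre with |rS| >= ``strong_threshold`` the contiguous run of
    significant same-sign neighbours is counted toward lower and higher
    intensities.  Adjacent strong variables each yield their own centre.
    """
    if family not in ORDERINGS:
        raise ValueError(f"family {family!r} has no intensity ordering")
    order = ORDERINGS[family]
    results = [row.get(v) for v in order]
    contours = []
    for idx, centre in enumerate(results):
        if centre is None or not centre.significant or abs(centre.r_s) < strong_threshold:
            continue
        sign = math.copysign(1.0, centre.r_s)

        def run(step: int):
            count, display = 0, []
            j = idx + step
            while 0 <= j < len(results):
                nb = results[j]
                if nb is not None and nb.significant and math.copysign(1.0, nb.r_s) == sign:
                    count += 1
                    display.append(f"{nb.r_s:+.1f}")
                    j += step
                else:
                    if nb is not None:
                        display.append("x")
                    break
            return count, display

        lower_count, lower_display = run(-1)
        higher_count, higher_display = run(+1)
        contours.append(
            ContourResult(centre, family, lower_count, higher_count, lower_display, higher_display)
        )
    return contours
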