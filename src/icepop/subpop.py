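"""Bistable ON-subpopulation estimation from cumulative ranked AGV curves.

A clonal population with a small bright ON fraction produces a cumulative
ranked intensity curve (percentile on x, AGV on y) with two near-linear
regimes: a long shallow OFF regime and a short steep ON regime.  The field
practice is to place slope lines on the two linear parts by hand and read
off the percentile where they cross; the ON fraction is then
``100 - breakpoint percentile`` and the ON mean is the mean AGV above the
breakpoint.  This module automates that geometric procedure as an exhaustive
two-segment least-squares fit, which is deterministic and has no tuning
parameters beyond the search window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BreakpointResult",
    "cumulative_curve",
    "find_breakpoint",
    "subpopulation_summary",
]

#: AGV below which a reported ON subpopulation mean is flagged as under the
#: practical detection floor of the imaging setup.
DETECTION_FLOOR = 10.0


@dataclass
class BreakpointResult:
    """Two-segment breakpoint fit of a cumulative ranked AGV curve.

    ``fraction_on == 100 - breakpoint_percentile`` holds exactly; both are
    percentages.  ``flags`` may contain ``"no_subpopulation"`` (degenerate,
    zero-variance curve) and ``"below_detection"`` (ON mean under the
    detection floor).
    """

    breakpoint_percentile: float
    breakpoint_agv: float
    fraction_on: float
    mean_on_agv: float
    n_cells: int
    fit_quality: float
    flags: tuple[str, ...] = ()

    @property
    def no_subpopulation(self) -> bool:
        return "no_subpopulation" in self.flags


def cumulative_curve(values) -> tuple[np.ndarray, np.ndarray]:
    """Rank values ascending and attach percentiles.

    The i-th of n sorted values (1-based) sits at percentile ``100*i/n``, so
    the largest value is always at 100%.  Ties keep their stable sort order.

    Returns ``(percentiles, sorted_values)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cumulative_curve requires at least one value")
    if values.size < 2:
        raise ValueError("cumulative_curve requires at least 2 values")
    order = np.argsort(values, kind="stable")
    sorted_values = values[order]
    n = values.size
    percentiles = 100.0 * np.arange(1, n + 1) / n
    return percentiles, sorted_values


def _segment_sse(x: np.ndarray, y: np.ndarray):
    """Total squared residual of the best-fit line on every prefix/suffix.

    Uses prefix sums of the first and second moments so that the SSE of a
    simple linear regression on points ``0..k`` (and ``k..n``) is available
    for all k in O(n).  Returns (sse_prefix, sse_suffix, slope/intercept
    arrays for both sides).
    """
    n = x.size

    def prefix_stats(xs, ys):
        c1 = np.cumsum(xs)
        c2 = np.cumsum(xs * xs)
        d1 = np.cumsum(ys)
        d2 = np.cumsum(ys * ys)
        cd = np.cumsum(xs * ys)
        m = np.arange(1, n + 1, dtype=float)
        sxx = c2 - c1 * c1 / m
        syy = d2 - d1 * d1 / m
        sxy = cd - c1 * d1 / m
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(sxx > 0, sxy / sxx, 0.0)
        intercept = d1 / m - slope * c1 / m
        sse = np.maximum(syy - slope * sxy, 0.0)
        return sse, slope, intercept

    sse_pre, slope_pre, icpt_pre = prefix_stats(x, y)
    sse_suf_r, slope_suf_r, icpt_suf_r = prefix_stats(x[::-1], y[::-1])
    return (
        sse_pre,
        slope_pre,
        icpt_pre,
        sse_suf_r[::-1],
        slope_suf_r[::-1],
        icpt_suf_r[::-1],
    )


def find_breakpoint(
    percentiles: np.ndarray,
    values: np.ndarray,
    search_range: tuple[float, float] = (50.0, 99.9),
    min_points_above: int = 3,
    detection_floor: float = DETECTION_FLOOR,
    min_slope_ratio: float = 20.0,
) -> BreakpointResult:
    """Locate the OFF/ON breakpoint of a cumulative ranked AGV curve.

    Every data percentile inside ``search_range`` is tried as a split; a
    least-squares line is fitted on each side and the split minimizing the
    total squared residual wins.  The breakpoint is the intersection of the
    two fitted lines, snapped to the nearest data percentile.  The search is
    restricted to the upper half of the curve because the ON subpopulation
    is by construction the minority.

    A breakpoint is only reported when the fitted ON-segment slope exceeds
    the OFF-segment slope at least ``min_slope_ratio``-fold: a genuinely
    bistable curve has two slope regimes differing by orders of magnitude,
    while the upper tail of a unimodal population produces slope ratios
    around 10 or less.  Curves failing the ratio (and zero-variance flat
    curves) return ``fraction_on = 0`` with the ``"no_subpopulation"`` flag.
    """
    x = np.asarray(percentiles, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("percentiles and values must have equal length")
    n = x.size
    if n < 20:
        raise ValueError(f"breakpoint fit requires >= 20 points, got {n}")

    if np.ptp(y) == 0.0:
        return BreakpointResult(
            breakpoint_percentile=100.0,
            breakpoint_agv=float(y[-1]),
            fraction_on=0.0,
            mean_on_agv=float(y[-1]),
            n_cells=n,
            fit_quality=0.0,
            flags=("no_subpopulation",),
        )

    lo, hi = search_range
    # candidate split k: left segment = points [0..k], right = [k+1..n-1]
    candidates = np.nonzero((x >= lo) & (x <= hi))[0]
    candidates = candidates[(candidates >= 1) & (candidates <= n - 1 - min_points_above)]
    if candidates.size == 0:
        raise ValueError(
            f"no admissible split in percentile range {search_range} leaves "
            f">= {min_points_above} points above"
        )

    sse_pre, slope_pre, icpt_pre, sse_suf, slope_suf, icpt_suf = _segment_sse(x, y)
    total = sse_pre[candidates] + sse_suf[candidates + 1]
    best = candidates[int(np.argmin(total))]

    m1, b1 = slope_pre[best], icpt_pre[best]
    m2, b2 = slope_suf[best + 1], icpt_suf[best + 1]

    # slope-ratio gate against spurious corners in unimodal tails
    distinct = m2 > 0 and (m1 <= 0 or m2 / m1 >= min_slope_ratio)
    if not distinct:
        return BreakpointResult(
            breakpoint_percentile=100.0,
            breakpoint_agv=float(y[-1]),
            fraction_on=0.0,
            mean_on_agv=float(y[-1]),
            n_cells=n,
            fit_quality=float(total.min()),
            flags=("no_subpopulation",),
        )

    if m2 != m1:
        x_cross = (b1 - b2) / (m2 - m1)
    else:
        x_cross = x[best]
    # The crossing must separate the two fitted segments: when the ON regime
    # rises as a near-vertical jump its regression line is shallow and the
    # unconstrained intersection drifts far into the OFF regime, so clamp to
    # the gap between the segments before snapping to a data percentile.
    x_cross = float(np.clip(x_cross, x[best], x[best + 1]))
    idx = int(np.argmin(np.abs(x - x_cross)))
    bp_percentile = float(x[idx])
    bp_agv = float(y[idx])

    above = y[x > bp_percentile]
    if above.size == 0:
        above = y[-1:]
    fraction_on = 100.0 - bp_percentile
    mean_on = float(np.mean(above))

    flags = []
    if mean_on < detection_floor:
        flags.append("below_detection")

    return BreakpointResult(
        breakpoint_percentile=bp_percentile,
        breakpoint_agv=bp_agv,
        fraction_on=fraction_on,
        mean_on_agv=mean_on,
        n_cells=n,
        fit_quality=float(total.min()),
        flags=tuple(flags),
    )


def estimate_on_fraction(values, **kwargs) -> BreakpointResult:
    """Convenience: cumulative curve + breakpoint fit in one call."""
    pct, srt = cumulative_curve(values)
    return find_breakpoint(pct, srt, **kwargs)


def subpopulation_summary(results: list[BreakpointResult]) -> dict:
    """Across-replicate mean ± SD of ON fraction and ON mean AGV.

    Follows the reporting convention of biological-triplicate tables: value
    ± sample SD.  With a single replicate the SD is reported as 0 together
    with a ``"single_replicate"`` flag.
    """
    if not results:
        raise ValueError("no replicate results given")
    fractions = np.array([r.fraction_on for r in results], dtype=float)
    means = np.array([r.mean_on_agv for r in results], dtype=float)
    flags = sorted({f for r in results for f in r.flags})
    if len(results) == 1:
        flags.append("single_replicate")
        sd_fraction = 0.0
        sd_mean = 0.0
    else:
        sd_fraction = float(np.std(fractions, ddof=1))
        sd_mean = float(np.std(means, ddof=1))
    return {
        "n_replicates": len(results),
        "fraction_on_mean": float(np.mean(fractions)),
        "fraction_on_sd": sd_fraction,
        "mean_on_agv_mean": float(np.mean(means)),
        "mean_on_agv_sd": sd_mean,
        "flags": tuple(flags),
    }
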