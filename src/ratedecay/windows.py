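"""Calibration-age time slices: sliding and shrinking windows.

The meta-analysis probes how the strength of time-dependence varies with
timescale by refitting the log-log regression inside nine calibration-age
slices: six sliding windows four orders of magnitude wide
(10^0-10^4, 10^1-10^5, ... 10^5-10^9 years) and three shrinking windows
pinned to the oldest calibrations (10^6-10^9, 10^7-10^9, 10^8-10^9 years).

Window bounds are closed on both ends by default — a point sitting exactly
at 10^4 years belongs to both 10^0-10^4 and 10^1-10^5.  The windows overlap
by construction, so the convention only affects boundary points; a half-open
variant is available for callers who need disjoint accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import Dataset, MarkerClass
from .regress import RegressionResult, loglog_fit, slope_test, subset

__all__ = ["WindowSpec", "standard_windows", "window_subset", "window_grid"]


@dataclass(frozen=True)
class WindowSpec:
    """One calibration-age slice, bounds in years."""

    lower: float
    upper: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(f"window requires 0 < lower < upper, got {self.lower}..{self.upper}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.lower:g}-{self.upper:g} years")

    def contains(self, t: float, *, closed: bool = True) -> bool:
        if closed:
            return self.lower <= t <= self.upper
        return self.lower <= t < self.upper


def standard_windows() -> list[WindowSpec]:
    """The nine canonical windows, in report column order.

    Six sliding windows with upper/lower = 10^4, then three shrinking
    windows with the upper bound fixed at 10^9 years.
    """
    sliding = [
        WindowSpec(10.0**k, 10.0 ** (k + 4), f"10^{k}-10^{k + 4} years") for k in range(6)
    ]
    shrinking = [
        WindowSpec(10.0**k, 10.0**9, f"10^{k}-10^9 years") for k in (6, 7, 8)
    ]
    return sliding + shrinking


def window_subset(data: Dataset, w: WindowSpec, *, closed: bool = True) -> Dataset:
    """Records whose calibration time falls inside the window, order kept."""
    return data.with_records(
        [r for r in data if w.contains(r.calibration_time, closed=closed)],
        f"window {w.label}",
    )


def window_grid(
    data: Dataset,
    windows: Iterable[WindowSpec] | None = None,
    *,
    by_marker_class: bool = True,
    null_slope: float = -1.0,
    closed: bool = True,
) -> list[RegressionResult]:
    """Refit the log-log regression in every (marker class, window) cell.

    Returns one :class:`RegressionResult` per cell, in window order within
    marker class.  Cells with fewer than three points are returned as
    flagged degenerate results (reported, never fitted); populated cells
    also carry the slope-vs-``null_slope`` test used to screen for spurious
    self-correlation.
    """
    if windows is None:
        windows = standard_windows()
    strata: list[tuple[str, Dataset]] = (
        [(mc.value, subset(data, marker_class=mc)) for mc in (MarkerClass.CODING, MarkerClass.NONCODING)]
        if by_marker_class
        else [("all", data)]
    )
    results: list[RegressionResult] = []
    for name, stratum in strata:
        for w in windows:
            cell = window_subset(stratum, w, closed=closed)
            label = f"{name}/{w.label}"
            fit = loglog_fit(cell, subset_label=label)
            if fit.populated:
                fit = slope_test(fit, null_slope)
            results.append(fit)
    return results
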