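"""Log-log regression of rate estimates on calibration age.

The central statistical object of the meta-analysis: ordinary least squares
of y = log10(rate) on x = log10(calibration time), with classical Student-t
inference on the slope against an arbitrary null value b0.  The default null
of interest is b0 = -1, the slope expected when the apparent correlation is
pure spurious self-correlation of the ratio rate = distance/time on its own
denominator.

All statistics follow the textbook simple-regression formulas:

    slope   = Sxy / Sxx
    se      = sqrt(RSS / (n - 2) / Sxx)
    t       = (slope - b0) / se,  p two-sided on n - 2 df

R-squared is unadjusted.  Fits need n >= 3; smaller subsets come back as a
flagged degenerate result with NaN statistics rather than an exception, so a
grid of window fits can report "n/a" cells the way a results table does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError
from .io import CalibrationType, Dataset, MarkerClass, RateEstimate, TaxonGroup

__all__ = ["RegressionResult", "loglog_fit", "loglog_fit_xy", "slope_test", "subset"]

MIN_POINTS = 3  # below this the fit is reported as degenerate, never computed


@dataclass(frozen=True)
class RegressionResult:
    """A fitted log10(rate) ~ log10(time) line and its inference.

    ``slope`` is dimensionless (change in log10 rate per tenfold change in
    calibration age); ``intercept`` is log10(substitutions/site/year) at
    1 year.  ``p_slope_zero`` tests slope = 0; ``p_slope_vs_null`` tests
    slope = ``null_slope`` (filled in by :func:`slope_test`).
    """

    n: int
    slope: float = math.nan
    intercept: float = math.nan
    r_squared: float = math.nan
    se_slope: float = math.nan
    p_slope_zero: float = math.nan
    p_slope_vs_null: float = math.nan
    null_slope: float = math.nan
    subset_label: str = ""
    degenerate: bool = False

    @property
    def populated(self) -> bool:
        return not self.degenerate


def loglog_fit_xy(
    x: Sequence[float], y: Sequence[float], *, subset_label: str = ""
) -> RegressionResult:
    """OLS of y on x from already log-transformed coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < MIN_POINTS:
        return RegressionResult(n=int(n), subset_label=subset_label, degenerate=True)
    xm = x.mean()
    ym = y.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateFitError(
            f"regression undefined: all calibration times equal ({subset_label or 'data'})"
        )
    sxy = float(xc @ (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    tss = float(((y - ym) ** 2).sum())
    r_squared = 1.0 if tss == 0.0 else 1.0 - rss / tss
    # guard tiny negative round-off on perfect fits
    r_squared = min(1.0, max(0.0, r_squared))
    se = math.sqrt(rss / (n - 2) / sxx)
    if se == 0.0:
        p_zero = 0.0 if slope != 0.0 else 1.0
    else:
        p_zero = 2.0 * float(stats.t.sf(abs(slope / se), n - 2))
    return RegressionResult(
        n=int(n),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        se_slope=se,
        p_slope_zero=p_zero,
        subset_label=subset_label,
    )


def loglog_fit(data: Dataset, *, subset_label: str = "") -> RegressionResult:
    """Fit log10(rate) on log10(calibration time) for a dataset."""
    x = np.array([math.log10(r.calibration_time) for r in data])
    y = np.array([math.log10(r.rate) for r in data])
    return loglog_fit_xy(x, y, subset_label=subset_label)


def slope_test(fit: RegressionResult, null_slope: float) -> RegressionResult:
    """Two-sided Student-t test of the fitted slope against ``null_slope``.

    Returns a copy of `fit` with ``p_slope_vs_null`` and ``null_slope``
    filled in.  With ``null_slope = 0`` this reproduces ``p_slope_zero``
    exactly.
    """
    if fit.degenerate:
        raise DegenerateFitError("cannot test the slope of a degenerate fit")
    if fit.se_slope == 0.0:
        p = 0.0 if fit.slope != null_slope else 1.0
    else:
        t = (fit.slope - null_slope) / fit.se_slope
        p = 2.0 * float(stats.t.sf(abs(t), fit.n - 2))
    return replace(fit, p_slope_vs_null=p, null_slope=float(null_slope))


def subset(
    data: Dataset,
    *,
    marker_class: MarkerClass | str | None = None,
    taxon_group: TaxonGroup | str | None = None,
    species: str | None = None,
    calibration_type: CalibrationType | str | None = None,
) -> Dataset:
    """Records matching every supplied filter clause, in original order.

    An empty result is allowed (the caller decides whether n < 3 subsets are
    reported as unfit).
    """
    mc = MarkerClass.parse(marker_class) if marker_class is not None else None
    tg = TaxonGroup.parse(taxon_group) if taxon_group is not None else None
    ct = CalibrationType.parse(calibration_type) if calibration_type is not None else None

    def keep(rec: RateEstimate) -> bool:
        if mc is not None and rec.marker_class is not mc:
            return False
        if tg is not None and rec.taxon_group is not tg:
            return False
        if species is not None and rec.species != species:
            return False
        if ct is not None and rec.calibration_type is not ct:
            return False
        return True

    label = ",".join(
        f"{k}={v}"
        for k, v in (
            ("marker_class", mc and mc.value),
            ("taxon_group", tg and tg.value),
            ("species", species),
            ("calibration_type", ct and ct.value),
        )
        if v is not None
    )
    return data.with_records(
        [r for r in data if keep(r)], f"subset({label or 'all'})"
    )
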