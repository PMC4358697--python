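"""Randomization test for spurious self-correlation (SSC).

A regression of a rate on the timescale over which it was measured is a
regression of a ratio (rate = genetic distance / time) on its own
denominator.  Even with no biological signal at all, such a regression is
expected to show a strong negative relationship — on the log10 scale the
expected slope is exactly -1, since log10(rate) = log10(distance) -
log10(time) and a distance unrelated to time contributes nothing but noise.

The randomization test operationalizes that null.  Each record's implied
total genetic distance d_i = rate_i x time_i is computed; each replicate
draws a uniform random permutation of the distances, rebuilds rates as
permuted distance over the original time, and refits the log-log regression.
The permutation destroys any genuine rate-time relationship while exactly
preserving the marginal distribution of distances, so the resulting slope
distribution is what pure self-correlation would produce for these data.
The observed slope is then located inside that distribution (two-sided
empirical p-value, centered on the null mean, with the standard +1
correction), and a parametric Student-t test of slope = -1 is run alongside.

Because the regressor log10(time) never changes across replicates, all B
replicate slopes reduce to

    slope_b = -1 + xc . log10(d_perm_b) / Sxx

with xc the centered log-times, and are computed in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateFitError, ValidationError
from .io import Dataset
from .regress import MIN_POINTS, RegressionResult, loglog_fit, slope_test

__all__ = ["SSCResult", "distances", "ssc_randomization", "ssc_report"]

#: significance tiers mirroring the conventional star notation
SIGNIFICANCE_TIERS = (0.05, 0.005, 0.0005)


@dataclass(frozen=True)
class SSCResult:
    """Outcome of the distance-randomization test.

    ``empirical_p`` is (1 + #{b : |slope_b - m| >= |observed - m|}) / (B + 1)
    with m the mean of the B null slopes; its floor is 1/(B+1).
    ``mean_null_slope`` is expected to sit near -1 whenever the log-times
    span real variation.
    """

    observed_slope: float
    replicates: int
    mean_null_slope: float
    sd_null_slope: float
    q025_null_slope: float
    q50_null_slope: float
    q975_null_slope: float
    empirical_p: float
    seed: int
    subset_label: str = ""
    #: parametric two-sided p-value of slope = -1 (filled by ssc_report)
    p_slope_vs_minus1: float = float("nan")
    #: True when both tests reject at the configured threshold
    rejects_ssc_null: bool | None = None
    #: full vector of B null slopes, kept only on request
    null_slopes: np.ndarray | None = field(default=None, repr=False, compare=False)


def distances(data: Dataset) -> np.ndarray:
    """Total genetic distance implied by each record: rate x calibration
    time, substitutions/site, in record order."""
    return np.array([r.rate * r.calibration_time for r in data], dtype=float)


def _null_slopes(
    log_t: np.ndarray, log_d: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    xc = log_t - log_t.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateFitError("regression undefined: all calibration times equal")
    # centering log_d costs nothing (permutation keeps the mean) and makes the
    # all-equal-distance limit exactly -1 instead of -1 plus round-off
    dc = log_d - log_d.mean()
    perms = rng.permuted(np.broadcast_to(dc, (B, dc.size)), axis=1)
    return -1.0 + perms @ xc / sxx


def ssc_randomization(
    data: Dataset,
    B: int,
    seed: int,
    *,
    keep_slopes: bool = False,
    subset_label: str = "",
) -> SSCResult:
    """Run the distance-permutation randomization test.

    Parameters
    ----------
    data
        The subset under test (the permutation is done within this subset,
        matching a per-subset analysis).
    B
        Number of random permutations; the published procedure uses 10,000.
    seed
        Seed for the permutation RNG; recorded in the result so any
        randomized distribution can be regenerated bit-identically.
    """
    if B < 1:
        raise ValidationError(f"need at least one replicate, got B={B}")
    n = len(data)
    if n < MIN_POINTS:
        raise DegenerateFitError(f"randomization test needs >= {MIN_POINTS} points, got {n}")
    log_t = np.log10([r.calibration_time for r in data])
    log_d = np.log10(distances(data))
    observed = loglog_fit(data, subset_label=subset_label).slope
    rng = np.random.default_rng(seed)
    slopes = _null_slopes(log_t, log_d, int(B), rng)
    m = float(slopes.mean())
    exceed = int(np.count_nonzero(np.abs(slopes - m) >= abs(observed - m)))
    q025, q50, q975 = np.quantile(slopes, [0.025, 0.5, 0.975])
    return SSCResult(
        observed_slope=float(observed),
        replicates=int(B),
        mean_null_slope=m,
        sd_null_slope=float(slopes.std(ddof=1)) if B > 1 else 0.0,
        q025_null_slope=float(q025),
        q50_null_slope=float(q50),
        q975_null_slope=float(q975),
        empirical_p=(1 + exceed) / (B + 1),
        seed=int(seed),
        subset_label=subset_label,
        null_slopes=slopes if keep_slopes else None,
    )


def ssc_report(
    data: Dataset,
    fit: RegressionResult | None = None,
    *,
    B: int = 10_000,
    seed: int = 0,
    threshold: float = 0.05,
    keep_slopes: bool = False,
) -> SSCResult:
    """Bundle the randomization test with the parametric slope = -1 test.

    A subset is judged inconsistent with pure self-correlation (``
    rejects_ssc_null``) when *both* the empirical p-value and the parametric
    slope-vs--1 p-value fall below `threshold`.
    """
    if fit is None:
        fit = loglog_fit(data)
    if fit.degenerate:
        raise DegenerateFitError("cannot run the SSC report on a degenerate fit")
    tested = slope_test(fit, -1.0)
    res = ssc_randomization(
        data, B, seed, keep_slopes=keep_slopes, subset_label=fit.subset_label
    )
    from dataclasses import replace

    return replace(
        res,
        p_slope_vs_minus1=tested.p_slope_vs_null,
        rejects_ssc_null=bool(
            res.empirical_p < threshold and tested.p_slope_vs_null < threshold
        ),
    )
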