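"""Refit the regression inside the nine standard calibration-age windows.

Six sliding windows four orders of magnitude wide plus three shrinking
windows pinned at 10^9 years show how the strength of time-dependence varies
across timescales.  Cells with fewer than three points are reported as n/a.
"""

from ratedecay import SyntheticConfig, simulate, standard_windows, window_grid

data = simulate(SyntheticConfig(n=300, beta=-0.3, sigma=0.5, seed=7))
grid = window_grid(data, standard_windows())

print(f"{'window':<18}{'class':<11}{'N':>5}{'slope':>8}{'R^2':>7}{'p(b=0)':>10}{'p(b=-1)':>10}")
for cell in grid:
    stratum, window = cell.subset_label.split("/", 1)
    if cell.degenerate:
        print(f"{window:<18}{stratum:<11}{cell.n:>5}{'n/a':>8}{'n/a':>7}{'n/a':>10}{'n/a':>10}")
    else:
        print(
            f"{window:<18}{stratum:<11}{cell.n:>5}{cell.slope:>8.2f}"
            f"{cell.r_squared:>7.2f}{cell.p_slope_zero:>10.2g}{cell.p_slope_vs_null:>10.2g}"
        )
print()
print("Every populated window should recover a negative slope well above -1:")
print("time-dependence is present in each slice, and no slice looks like the")
print("pure self-correlation artifact.  The simulated table contains only")
print("coding-like markers, so the noncoding rows are reported as n/a rather")
print("than silently dropped.")
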