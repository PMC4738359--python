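"""Multiple-threshold multifunctionality.

Each function is expressed as a fraction of its "maximum" — the mean of
its top 5% of observations, which robustifies the denominator against a
single extreme plot.  For every threshold t in 1..99 (percent of that
maximum) we count, per site, how many functions exceed t, and regress
that count on diversity by OLS.  The slope-versus-threshold curve with
its 95% band summarizes whether diversity raises the number of functions
performing beyond each level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import ols_fit

logger = logging.getLogger(__name__)


@dataclass
class StandardizedFunctions:
    """Functions as fractions of their top-5% maxima."""

    fractions: pd.DataFrame
    maxima: pd.Series
    shifts: pd.Series = field(default=None)


def standardize_to_max(
    functions: pd.DataFrame, top_fraction: float = 0.05
) -> StandardizedFunctions:
    """Divide each function by the mean of its top ``top_fraction`` values.

    m = ceil(top_fraction * n) observations enter the maximum, so at
    least one always does.  Functions containing negative values (e.g.
    net N mineralization) are first shifted to non-negative by
    subtracting their minimum; shifts are recorded and logged.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    n = functions.shape[0]
    m = math.ceil(top_fraction * n)
    fractions = pd.DataFrame(index=functions.index)
    maxima = {}
    shifts = {}
    for c in functions.columns:
        x = functions[c].to_numpy(dtype=float)
        shift = 0.0
        if np.nanmin(x) < 0:
            shift = -float(np.nanmin(x))
            x = x + shift
            logger.warning(
                "standardize_to_max: function %r shifted by +%.6g to be non-negative",
                c,
                shift,
            )
        shifts[c] = shift
        top = np.sort(x[np.isfinite(x)])[-m:]
        mx = float(top.mean())
        if mx <= 0:
            raise ValueError(f"function {c!r} has non-positive top-{top_fraction:.0%} maximum")
        maxima[c] = mx
        fractions[c] = x / mx
    return StandardizedFunctions(
        fractions, pd.Series(maxima, name="maximum"), pd.Series(shifts, name="shift")
    )


def count_above_threshold(std: StandardizedFunctions, t: float) -> pd.Series:
    """Per site, number of functions strictly exceeding t percent of maximum."""
    if not (0 <= t <= 99):
        raise ValueError("threshold must be in [0, 99] percent")
    counts = (std.fractions.to_numpy() > t / 100.0).sum(axis=1)
    return pd.Series(counts, index=std.fractions.index, name=f"count_t{t}")


@dataclass
class ThresholdCurve:
    """Per-threshold OLS slopes of (function count ~ diversity)."""

    table: pd.DataFrame  # threshold, slope, se, ci_low, ci_high, p, n, degenerate

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def threshold_slopes(
    functions: pd.DataFrame,
    diversity: pd.Series | np.ndarray,
    grid=None,
    top_fraction: float = 0.05,
    include_zero: bool = False,
) -> ThresholdCurve:
    """OLS slope of function count on diversity at each threshold.

    Thresholds where the count is constant across sites are reported with
    slope 0, CI [0, 0] and a degenerate flag.
    """
    std = standardize_to_max(functions, top_fraction=top_fraction)
    div = np.asarray(
        diversity.reindex(functions.index)
        if isinstance(diversity, pd.Series)
        else diversity,
        dtype=float,
    )
    n = len(div)
    if n != functions.shape[0]:
        raise ValueError("diversity length does not match functions")
    if n < 4:
        raise ValueError("need at least 4 sites")
    if np.std(div) == 0:
        raise ValueError("diversity is constant; slopes undefined")
    if grid is None:
        grid = range(0 if include_zero else 1, 100)
    rows = []
    for t in grid:
        counts = count_above_threshold(std, t).to_numpy(dtype=float)
        if np.all(counts == counts[0]):
            rows.append(
                dict(threshold=t, slope=0.0, se=0.0, ci_low=0.0, ci_high=0.0,
                     p=np.nan, n=n, degenerate=True)
            )
            continue
        fit = ols_fit(counts, pd.DataFrame({"diversity": div}))
        slope = float(fit.params["diversity"])
        se = float(fit.bse["diversity"])
        tcrit = stats.t.ppf(0.975, n - 2)
        rows.append(
            dict(
                threshold=t,
                slope=slope,
                se=se,
                ci_low=slope - tcrit * se,
                ci_high=slope + tcrit * se,
                p=float(fit.pvalues["diversity"]),
                n=n,
                degenerate=False,
            )
        )
    return ThresholdCurve(pd.DataFrame(rows))


def summarize_curve(curve: ThresholdCurve) -> dict:
    """Peak slope and the threshold intervals with one-signed 95% CIs."""
    df = curve.table
    active = df[~df["degenerate"]]
    out = {
        "argmax_threshold": None,
        "max_slope": None,
        "positive_intervals": _intervals(df, df["ci_low"] > 0),
        "negative_intervals": _intervals(df, df["ci_high"] < 0),
    }
    if len(active):
        i = active["slope"].idxmax()
        out["argmax_threshold"] = int(active.loc[i, "threshold"])
        out["max_slope"] = float(active.loc[i, "slope"])
    return out


def _intervals(df: pd.DataFrame, mask: pd.Series) -> list[tuple[int, int]]:
    ts = df.loc[mask & ~df["degenerate"], "threshold"].to_numpy()
    if ts.size == 0:
        return []
    runs = []
    start = prev = int(ts[0])
    for t in ts[1:]:
        t = int(t)
        if t == prev + 1:
            prev = t
        else:
            runs.append((start, prev))
            start = prev = t
    runs.append((start, prev))
    return runs


def plot_threshold_curve(curve: ThresholdCurve, path) -> None:
    """Slope-vs-threshold display with the 95% confidence band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = curve.table
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(df["threshold"], df["ci_low"], df["ci_high"], alpha=0.3,
                    color="tab:blue", label="95% CI")
    ax.plot(df["threshold"], df["slope"], color="tab:blue")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("Threshold (% of maximum)")
    ax.set_ylabel("Slope of count ~ diversity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_count_lines(
    functions: pd.DataFrame, diversity: pd.Series, path, grid=range(5, 100, 5)
) -> None:
    """Count-vs-diversity regression lines, one colour per threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    std = standardize_to_max(functions)
    div = np.asarray(diversity.reindex(functions.index), dtype=float)
    cmap = matplotlib.colormaps["viridis"]
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.linspace(div.min(), div.max(), 50)
    for t in grid:
        counts = count_above_threshold(std, t).to_numpy(dtype=float)
        if np.all(counts == counts[0]):
            continue
        b, a = np.polyfit(div, counts, 1)
        ax.plot(xs, a + b * xs, color=cmap(t / 100), lw=1)
    ax.set_xlabel("Diversity")
    ax.set_ylabel("Number of functions above threshold")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
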