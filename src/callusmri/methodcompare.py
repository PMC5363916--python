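"""Method-agreement statistics: paired Student's t-test and Pearson correlation.

This module reproduces the statistical machinery used to compare two
measurement methods on the same specimens (MRI vs μCT bone volume, MRI vs
histomorphometry tissue fractions): per-method mean ± SD, a two-sided
Student's t-test on the paired differences (an unpaired pooled-variance
mode is available behind a flag), and Pearson's correlation with r², with
significance of the correlation from the exact t transform
t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.  The significance level
is α = 0.05 throughout; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import reports_to_frame
from .volume import DegenerateDataError, ValidationError

__all__ = ["MethodComparison", "pearson", "t_test", "compare_methods", "plot_method_agreement"]

ALPHA = 0.05


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} must be finite")
    return x


def pearson(x, y) -> tuple[float, float, float]:
    """Pearson's r, r², and the two-sided p-value for H0: no correlation.

    Requires n ≥ 3 and non-zero variance in both vectors.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def t_test(x, y, paired: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test between two sets of measurements.

    Paired (default): t = mean(d) / (SD(d)/√n) with n−1 degrees of freedom
    on the differences d = x − y.  Unpaired: pooled-variance Student's t
    with n₁+n₂−2 degrees of freedom.  Zero-variance differences (or two
    constant samples) raise :class:`DegenerateDataError` rather than
    returning a silent p-value.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if paired:
        if len(x) != len(y):
            raise ValidationError("paired t-test requires equal lengths")
        if len(x) < 2:
            raise ValidationError("t-test requires n >= 2")
        d = x - y
        if np.ptp(d) == 0:
            raise DegenerateDataError("zero-variance differences: paired t undefined")
        res = stats.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValidationError("t-test requires n >= 2 per group")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise DegenerateDataError("both samples constant: t undefined")
        res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MethodComparison:
    """Paired per-specimen agreement between two measurement methods."""

    metric: str
    method_a: str
    method_b: str
    n: int
    specimen_ids: tuple[str, ...]
    values_a: np.ndarray
    values_b: np.ndarray
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_t: float
    degenerate_t: bool
    pearson_r: float
    r_squared: float
    p_correlation: float
    paired: bool = True
    alpha: float = ALPHA

    @property
    def significant_difference(self) -> bool:
        return (not self.degenerate_t) and self.p_t < self.alpha

    @property
    def significant_correlation(self) -> bool:
        return self.p_correlation < self.alpha

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "method_a": self.method_a,
            "method_b": self.method_b,
            "n": self.n,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "t": self.t_statistic,
            "p_t": self.p_t,
            "degenerate_t": self.degenerate_t,
            "r": self.pearson_r,
            "r2": self.r_squared,
            "p_r": self.p_correlation,
            "paired": self.paired,
        }


def compare_methods(reports_a, reports_b, metric: str, paired: bool = True) -> MethodComparison:
    """Join two sets of :class:`~callusmri.quantify.QuantReport` rows by specimen
    and compute the full agreement statistics for one metric column.

    ``metric`` names a QuantReport column (e.g. ``BV_mm3`` or ``CA_TA_pct``).
    Unmatched specimens raise a :class:`ValidationError` listing their ids.
    A degenerate paired t-test (identical methods) is flagged, not silently
    reported.
    """
    fa = reports_a if isinstance(reports_a, pd.DataFrame) else reports_to_frame(reports_a)
    fb = reports_b if isinstance(reports_b, pd.DataFrame) else reports_to_frame(reports_b)
    for f, tag in ((fa, "a"), (fb, "b")):
        if metric not in f.columns:
            raise ValidationError(f"metric {metric!r} missing from reports_{tag}")
    only_a = sorted(set(fa["specimen_id"]) - set(fb["specimen_id"]))
    only_b = sorted(set(fb["specimen_id"]) - set(fa["specimen_id"]))
    if only_a or only_b:
        raise ValidationError(
            f"unmatched specimens: only in a={only_a}, only in b={only_b}"
        )
    merged = fa.merge(fb, on="specimen_id", suffixes=("_a", "_b")).sort_values("specimen_id")
    x = merged[f"{metric}_a"].to_numpy(dtype=np.float64)
    y = merged[f"{metric}_b"].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValidationError(f"metric {metric!r} contains missing values")
    try:
        t_stat, p_t = t_test(x, y, paired=paired)
        degenerate = False
    except DegenerateDataError:
        t_stat, p_t, degenerate = float("nan"), float("nan"), True
    r, r2, p_r = pearson(x, y)
    method_a = str(fa["method"].iloc[0]) if "method" in fa else "a"
    method_b = str(fb["method"].iloc[0]) if "method" in fb else "b"
    return MethodComparison(
        metric=metric,
        method_a=method_a,
        method_b=method_b,
        n=len(x),
        specimen_ids=tuple(merged["specimen_id"]),
        values_a=x,
        values_b=y,
        mean_a=float(np.mean(x)),
        sd_a=float(np.std(x, ddof=1)),
        mean_b=float(np.mean(y)),
        sd_b=float(np.std(y, ddof=1)),
        t_statistic=t_stat,
        p_t=p_t,
        degenerate_t=degenerate,
        pearson_r=r,
        r_squared=r2,
        p_correlation=p_r,
        paired=paired,
    )


def plot_method_agreement(comparison: MethodComparison, path) -> None:
    """Scatter the paired values against the identity line y = x and save."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(comparison.values_a, comparison.values_b, color="k", s=18)
    lim = [
        min(comparison.values_a.min(), comparison.values_b.min()),
        max(comparison.values_a.max(), comparison.values_b.max()),
    ]
    pad = 0.05 * (lim[1] - lim[0] or 1.0)
    lim = [lim[0] - pad, lim[1] + pad]
    ax.plot(lim, lim, color="crimson", lw=1, label="y = x")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel(comparison.method_a)
    ax.set_ylabel(comparison.method_b)
    ax.set_title(
        f"{comparison.metric}: r={comparison.pearson_r:.2f}, r²={comparison.r_squared:.2f}"
    )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
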