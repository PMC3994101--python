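"""P-value calibration diagnostics: QQ tables against the Uniform(0,1)
expectation and the genomic-control inflation factor."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["qq_points", "inflation_summary", "qq_plot"]

#: median of a 1-df chi-squared variate, the genomic-control denominator
_CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

_CONVENTIONS = ("mean", "uniform", "midpoint")


def _expected_quantiles(m: int, convention: str) -> np.ndarray:
    i = np.arange(1, m + 1, dtype=float)
    if convention == "mean":       # i/(m+1): no -log10(0) at the extreme rank
        return i / (m + 1)
    if convention == "uniform":    # i/m
        return i / m
    if convention == "midpoint":   # (i - 0.5)/m
        return (i - 0.5) / m
    raise ValueError(f"convention must be one of {_CONVENTIONS}")


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no defined p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return p


def qq_points(pvalues, convention: str = "mean") -> pd.DataFrame:
    """Observed versus expected -log10 p-values, one row per rank.

    Observed p-values are sorted ascending; the expected quantile of rank i
    out of m is i/(m+1) by default (each test treated as independent, so the
    joint null is exactly Uniform(0,1)).  NaN entries (flagged-undefined
    tests) are dropped first.
    """
    p = np.sort(_check_pvalues(pvalues))
    m = p.size
    expected = _expected_quantiles(m, convention)
    return pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(p),
        }
    )


def inflation_summary(pvalues) -> float:
    """Genomic-control lambda: the median 1-df chi-squared statistic implied
    by the p-values divided by its theoretical null median (~0.4549).
    Approximately 1 for well-calibrated tests, >1 under inflation."""
    p = _check_pvalues(pvalues)
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_1DF_MEDIAN)


def qq_plot(pvalues, path, convention: str = "mean", title: str | None = None):
    """Write a QQ plot (-log10 scale) to ``path`` (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = qq_points(pvalues, convention=convention)
    lam = inflation_summary(pvalues)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(
        table["expected_neglog10p"], table["observed_neglog10p"], s=6,
        color="#1f4e79", alpha=0.6, linewidths=0,
    )
    lim = max(table["expected_neglog10p"].max(), table["observed_neglog10p"].max())
    ax.plot([0, lim], [0, lim], color="crimson", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(title or f"QQ plot (lambda = {lam:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return table
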