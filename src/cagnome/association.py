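"""Per-probe association statistics.

Two parallel analyses of the same matrix:

* **continuous** — Pearson and Spearman correlation of each probe's expression
  with the longer CAG allele length across *all* samples, controls included;
* **dichotomous** — two-sample Student's t-test (pooled variance by default,
  Welch optionally) of HD (CAG>35) versus control (CAG<36) samples, with a
  signed linear fold change derived from the log2 mean difference.

Scalar tests delegate to scipy; the genome-wide drivers use vectorised
closed forms (identical formulas) so that scans over tens of thousands of
probes and thousands of subsampling replicates stay fast.  Zero-variance
probes yield flagged, non-significant rows instead of aborting a scan.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleTable, align, GROUP_HD, GROUP_CONTROL

__all__ = [
    "pearson_test",
    "spearman_test",
    "student_t_test",
    "signed_fold_change",
    "run_continuous",
    "run_dichotomous",
    "run_association",
]

_TINY_P = np.nextafter(0.0, 1.0)


class CorrelationResult(NamedTuple):
    stat: float      # r or rho; nan when undefined
    p: float         # 1.0 when the statistic is undefined
    note: str        # empty when the test is well-defined


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    note: str


def pearson_test(x, y) -> CorrelationResult:
    """Two-sided Pearson correlation test.

    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  A
    zero-variance argument gives a flagged result (r = nan, p = 1) rather
    than an exception so genome-wide scans continue.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, 1.0, "zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(max(p, _TINY_P)), "")


def spearman_test(x, y) -> CorrelationResult:
    """Two-sided Spearman rank correlation (mid-ranks for ties; p via the
    t-approximation on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, 1.0, "zero variance")
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return CorrelationResult(np.nan, 1.0, "undefined")
    return CorrelationResult(float(rho), float(max(p, _TINY_P)), "")


def student_t_test(a, b, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test of a versus b.

    Pooled variance ("Student's") by default with df = n_a + n_b - 2;
    ``welch=True`` uses the Welch-Satterthwaite form.  Degenerate inputs are
    flagged: both groups constant and equal means -> t = 0, p = 1; both
    constant with unequal means -> infinite t, p recorded as the smallest
    positive float.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, a.size + b.size - 2.0, 1.0, "both groups constant")
        t = np.inf if np.mean(a) > np.mean(b) else -np.inf
        return TTestResult(t, a.size + b.size - 2.0, _TINY_P, "both groups constant")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(float(res.statistic), df, float(max(res.pvalue, _TINY_P)), "")


def signed_fold_change(mean_hd: float, mean_ctrl: float) -> float:
    """Signed linear fold change from log2 means.

    delta = mean_hd - mean_ctrl; returns 2**delta when delta >= 0 and
    -2**(-delta) otherwise, so the magnitude is always >= 1 and the sign
    says whether expression is higher (+) or lower (-) in HD.
    """
    delta = float(mean_hd) - float(mean_ctrl)
    if delta >= 0:
        return float(2.0**delta)
    return float(-(2.0 ** (-delta)))


# ---------------------------------------------------------------------------
# vectorised genome-wide drivers
# ---------------------------------------------------------------------------

def _rowwise_pearson(values: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every row of ``values`` against ``x``, with two-sided p
    from the exact t transform.  Zero-variance rows give (nan, nan)."""
    n = x.size
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    vc = values - values.mean(axis=1, keepdims=True)
    sv = np.sqrt((vc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc @ xc) / (sv * sx)
    r = np.clip(r, -1.0, 1.0)
    r[sv == 0] = np.nan
    if sx == 0:
        r[:] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, _TINY_P, 1.0)
    p[np.isnan(r)] = np.nan
    # |r| = 1 exactly: infinite t, p underflows to the smallest positive float
    p[np.isinf(t)] = _TINY_P
    return r, p


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=1)


def run_continuous(expr: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Pearson and Spearman statistics of every probe against cag_long over
    all samples.  Returns columns probe_id, r, p_pearson, rho, p_spearman,
    note."""
    expr = align(expr, samples)
    if len(samples.frame) < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = samples.frame["cag_long"].to_numpy(dtype=float)
    values = expr.values
    r, p_r = _rowwise_pearson(values, x)
    rho, p_rho = _rowwise_pearson(_rank_rows(values), stats.rankdata(x))
    note = np.where(np.isnan(r), "zero variance", "")
    out = pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "r": r,
            "p_pearson": np.where(np.isnan(r), 1.0, p_r),
            "rho": rho,
            "p_spearman": np.where(np.isnan(rho), 1.0, p_rho),
            "note": note,
        }
    )
    out.loc[out["note"] != "", ["r", "rho"]] = np.nan
    return out


def pooled_t_pvalues(
    hd: np.ndarray, ctrl: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test of hd (n x a) vs ctrl (n x b).

    Returns (t, df, p); rows where both groups have zero variance get
    t = 0/inf and p = 1/tiny according to the mean difference, and p = nan is
    never produced.
    """
    na, nb = hd.shape[1], ctrl.shape[1]
    ma, mb = hd.mean(axis=1), ctrl.mean(axis=1)
    va = hd.var(axis=1, ddof=1)
    vb = ctrl.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2a, se2b = va / na, vb / nb
            se = np.sqrt(se2a + se2b)
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full(hd.shape[0], na + nb - 2, dtype=float)
        t = (ma - mb) / se
    degenerate = se == 0
    equal = degenerate & (ma == mb)
    t[equal] = 0.0
    t[degenerate & ~equal] = np.where(ma[degenerate & ~equal] > mb[degenerate & ~equal], np.inf, -np.inf)
    df[degenerate & np.isnan(df)] = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.clip(p, _TINY_P, 1.0)
    p[equal] = 1.0
    p[np.isinf(t)] = _TINY_P
    return t, df, p


def run_dichotomous(
    expr: ExpressionMatrix, samples: SampleTable, welch: bool = False
) -> pd.DataFrame:
    """Student's t statistics of every probe, HD versus control.

    Returns columns probe_id, mean_hd, mean_ctrl, delta, fold_change, t_stat,
    df, p_t, note.  Probes constant in both groups are flagged in ``note``.
    """
    expr = align(expr, samples)
    hd_ids = samples.ids_in_group(GROUP_HD)
    ctrl_ids = samples.ids_in_group(GROUP_CONTROL)
    if len(hd_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"each group needs >=2 samples (HD={len(hd_ids)}, control={len(ctrl_ids)})"
        )
    hd = expr.frame.loc[:, hd_ids].to_numpy()
    ctrl = expr.frame.loc[:, ctrl_ids].to_numpy()
    t, df, p = pooled_t_pvalues(hd, ctrl, welch=welch)
    ma, mb = hd.mean(axis=1), ctrl.mean(axis=1)
    delta = ma - mb
    fc = np.where(delta >= 0, 2.0**delta, -(2.0 ** (-delta)))
    note = np.where(np.isinf(t) | ((t == 0) & (p == 1.0) & (hd.var(axis=1, ddof=1) + ctrl.var(axis=1, ddof=1) == 0)), "both groups constant", "")
    return pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "mean_hd": ma,
            "mean_ctrl": mb,
            "delta": delta,
            "fold_change": fc,
            "t_stat": t,
            "df": df,
            "p_t": p,
            "note": note,
        }
    )


def run_association(
    expr: ExpressionMatrix, samples: SampleTable, welch: bool = False
) -> pd.DataFrame:
    """Joined continuous + dichotomous table, one row per probe."""
    cont = run_continuous(expr, samples)
    dich = run_dichotomous(expr, samples, welch=welch)
    cont = cont.rename(columns={"note": "note_continuous"})
    dich = dich.rename(columns={"note": "note_dichotomous"})
    return cont.merge(dich, on="probe_id", validate="one_to_one")
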