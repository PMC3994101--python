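"""Subsampling power simulation and sample-size extrapolation.

The question: how well does a dichotomous HD-vs-control t-test analysis at a
given per-group sample size n recover the probes that a continuous
CAG-length correlation analysis of the *full* panel calls significant?

Procedure, per (n, replicate): draw n HD and n control samples uniformly
without replacement, run the t-test on every probe over that subset, call
significance at the nominal alpha, and score the resulting set against the
fixed full-sample continuous reference set using the concordance rates.
Replicates are independent; each (n, replicate) cell gets its own RNG
substream derived from the master seed, so results do not depend on
execution order.

The two rates are then regressed linearly on n over all replicate-level
points, and the fitted line is solved for the per-group n at which a target
rate would be reached.  Linearity is a modelling convenience chosen for easy
extrapolation; predictions beyond the simulated n range are flagged as
extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import pooled_t_pvalues
from .concordance import call_significant, concordance_counts, concordance_metrics
from .io import ExpressionMatrix, SampleTable, align, GROUP_HD, GROUP_CONTROL

__all__ = [
    "subsample_groups",
    "run_power_simulation",
    "PowerModel",
    "fit_metric_regression",
    "RequiredN",
    "extrapolate_required_n",
]

METRICS = ("detection_rate", "dich_noncag_rate")


def subsample_groups(
    samples: SampleTable, n_per_group: int, rng: np.random.Generator
) -> list[str]:
    """Draw n_per_group HD and n_per_group control sample IDs uniformly
    without replacement within each group."""
    hd = samples.ids_in_group(GROUP_HD)
    ctrl = samples.ids_in_group(GROUP_CONTROL)
    if n_per_group > min(len(hd), len(ctrl)):
        raise ValueError(
            f"n_per_group={n_per_group} exceeds a group size "
            f"(HD={len(hd)}, control={len(ctrl)})"
        )
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2 for a t-test")
    pick_hd = rng.choice(len(hd), size=n_per_group, replace=False)
    pick_ctrl = rng.choice(len(ctrl), size=n_per_group, replace=False)
    return [hd[i] for i in pick_hd] + [ctrl[i] for i in pick_ctrl]


def _replicate_rng(seed: int, n_per_group: int, replicate: int) -> np.random.Generator:
    # one independent substream per (n, replicate) cell
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(n_per_group), int(replicate)])
    )


def run_power_simulation(
    expr: ExpressionMatrix,
    samples: SampleTable,
    reference_set: Iterable[str],
    n_range: Sequence[int],
    n_reps: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    welch: bool = False,
) -> pd.DataFrame:
    """Replicate-level concordance rates of subsampled dichotomous analyses
    against a fixed continuous reference set.

    Returns one row per (n_per_group, replicate) with columns n_per_group,
    replicate, n_dich_significant, detection_rate, dich_noncag_rate.
    An empty reference set leaves detection_rate NaN (undefined, not 0);
    replicates with no dichotomous calls leave dich_noncag_rate NaN.
    """
    expr = align(expr, samples)
    reference_set = set(reference_set)
    hd_ids = samples.ids_in_group(GROUP_HD)
    ctrl_ids = samples.ids_in_group(GROUP_CONTROL)
    values = expr.frame
    probe_index = pd.Index(expr.probe_ids)
    col_pos = {sid: j for j, sid in enumerate(values.columns)}
    mat = values.to_numpy()

    rows = []
    for n in n_range:
        for rep in range(1, n_reps + 1):
            rng = _replicate_rng(seed, n, rep)
            subset = subsample_groups(samples, n, rng)
            hd_cols = [col_pos[s] for s in subset[:n]]
            ctrl_cols = [col_pos[s] for s in subset[n:]]
            # probes constant in both subgroups get p=1 from the degenerate
            # branch and are never called significant
            _, _, p = pooled_t_pvalues(mat[:, hd_cols], mat[:, ctrl_cols], welch=welch)
            dich_set = call_significant(pd.Series(p, index=probe_index), alpha)
            metrics = concordance_metrics(
                concordance_counts(reference_set, dich_set, alpha)
            )
            rows.append(
                (
                    int(n),
                    rep,
                    len(dich_set),
                    metrics.detection_rate,
                    metrics.dich_noncag_rate,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "n_per_group",
            "replicate",
            "n_dich_significant",
            "detection_rate",
            "dich_noncag_rate",
        ],
    )


@dataclass(frozen=True)
class PowerModel:
    """OLS fit of a concordance rate on per-group sample size."""

    metric_name: str
    slope: float        # percent per unit n
    intercept: float    # percent
    r_squared: float
    n_min: int          # simulated range, for flagging extrapolation
    n_max: int
    n_points: int
    required_n: Optional[float] = None


def fit_metric_regression(points: pd.DataFrame, metric_name: str) -> PowerModel:
    """Ordinary least squares of a metric on n over all replicate-level
    points (rows with an undefined metric are dropped)."""
    if metric_name not in METRICS:
        raise ValueError(f"metric_name must be one of {METRICS}")
    sub = points[["n_per_group", metric_name]].dropna()
    n_values = sub["n_per_group"].unique()
    if len(n_values) < 2:
        raise ValueError("need at least 2 distinct sample sizes to fit a line")
    X = sm.add_constant(sub["n_per_group"].to_numpy(dtype=float))
    fit = sm.OLS(sub[metric_name].to_numpy(dtype=float), X).fit()
    return PowerModel(
        metric_name=metric_name,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n_min=int(n_values.min()),
        n_max=int(n_values.max()),
        n_points=int(len(sub)),
    )


class RequiredN(NamedTuple):
    n: float                 # per-group sample size solving the fitted line
    is_extrapolation: bool   # True when outside the simulated n range


def extrapolate_required_n(
    model: PowerModel, target: float, direction: str
) -> RequiredN:
    """Per-group n at which the fitted line meets ``target`` percent.

    direction ``"reach_at_least"`` (rate climbing to the target, needs a
    positive slope) or ``"reduce_to_at_most"`` (rate falling, needs a
    negative slope).  Returns the real-valued solution; callers may ceil.
    """
    if direction not in ("reach_at_least", "reduce_to_at_most"):
        raise ValueError("direction must be reach_at_least or reduce_to_at_most")
    needed_sign = 1.0 if direction == "reach_at_least" else -1.0
    if model.slope == 0 or np.sign(model.slope) != needed_sign:
        raise ValueError(
            f"target unreachable under linear model: slope {model.slope:g} "
            f"cannot {direction.replace('_', ' ')} {target:g}%"
        )
    n_star = (target - model.intercept) / model.slope
    return RequiredN(float(n_star), not (model.n_min <= n_star <= model.n_max))


def fit_power_models(
    points: pd.DataFrame,
    target_detect: float = 80.0,
    target_noncag: float = 20.0,
) -> dict[str, PowerModel]:
    """Fit both metric regressions and solve for the standard targets:
    detecting ``target_detect``% of the continuous reference set, and cutting
    the non-CAG-correlated call rate to ``target_noncag``%."""
    out = {}
    for metric, target, direction in (
        ("detection_rate", target_detect, "reach_at_least"),
        ("dich_noncag_rate", target_noncag, "reduce_to_at_most"),
    ):
        model = fit_metric_regression(points, metric)
        required = extrapolate_required_n(model, target, direction)
        out[metric] = replace(model, required_n=required.n)
    return out
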