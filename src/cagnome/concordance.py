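"""Concordance accounting between continuous and dichotomous significant sets.

Significance calls use a strict nominal threshold (p < alpha, default 0.01,
no multiple-testing correction).  From the two significant sets the module
derives four complementary rates:

* detection_rate      — % of continuous-significant probes also dichotomous-significant
* cont_missed_rate    — % of continuous-significant probes the dichotomous analysis missed
* shared_of_dich_rate — % of dichotomous-significant probes that are CAG-length correlated
* dich_noncag_rate    — % of dichotomous-significant probes that are not

detection + cont_missed = 100 and shared_of_dich + dich_noncag = 100 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "call_significant",
    "ConcordanceCounts",
    "concordance_counts",
    "ConcordanceMetrics",
    "concordance_metrics",
    "DirectionCrossTab",
    "direction_crosstab",
]


def call_significant(pvalues: pd.Series | Mapping[str, float], alpha: float) -> set[str]:
    """Probe IDs with p strictly below alpha.

    ``pvalues`` is indexed by probe ID.  Flagged-undefined p-values (NaN) are
    never called significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    s = pd.Series(pvalues, dtype=float)
    return set(s.index[(s < alpha) & s.notna()].astype(str))


@dataclass(frozen=True)
class ConcordanceCounts:
    n_continuous: int
    n_dichotomous: int
    n_shared: int
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_continuous, self.n_dichotomous, self.n_shared) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_shared > min(self.n_continuous, self.n_dichotomous):
            raise ValueError("shared count exceeds a marginal count")


def concordance_counts(
    cont_set: Iterable[str], dich_set: Iterable[str], alpha: float = 0.01
) -> ConcordanceCounts:
    """Venn cardinalities of the two significant sets."""
    cont = set(cont_set)
    dich = set(dich_set)
    return ConcordanceCounts(len(cont), len(dich), len(cont & dich), alpha)


@dataclass(frozen=True)
class ConcordanceMetrics:
    """The four rates, in percent at full precision.

    A zero denominator leaves the corresponding pair of rates NaN
    (flagged undefined) rather than 0 or 100.
    """

    detection_rate: float
    cont_missed_rate: float
    shared_of_dich_rate: float
    dich_noncag_rate: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Rates rounded for reporting (1 decimal by convention)."""
        return {
            "detection_rate": round(self.detection_rate, ndigits),
            "cont_missed_rate": round(self.cont_missed_rate, ndigits),
            "shared_of_dich_rate": round(self.shared_of_dich_rate, ndigits),
            "dich_noncag_rate": round(self.dich_noncag_rate, ndigits),
        }


def concordance_metrics(counts: ConcordanceCounts) -> ConcordanceMetrics:
    if counts.n_continuous > 0:
        detection = 100.0 * counts.n_shared / counts.n_continuous
        missed = 100.0 * (counts.n_continuous - counts.n_shared) / counts.n_continuous
    else:
        detection = missed = float("nan")
    if counts.n_dichotomous > 0:
        shared_of_dich = 100.0 * counts.n_shared / counts.n_dichotomous
        noncag = 100.0 * (counts.n_dichotomous - counts.n_shared) / counts.n_dichotomous
    else:
        shared_of_dich = noncag = float("nan")
    return ConcordanceMetrics(detection, missed, shared_of_dich, noncag)


@dataclass(frozen=True)
class DirectionCrossTab:
    """Direction agreement between r and the HD-vs-control mean difference.

    ``quadrant_pct`` covers all probes with a defined, nonzero sign on both
    axes (keys ``pos_pos``, ``pos_neg``, ``neg_pos``, ``neg_neg``; first sign
    is r, second is delta); percentages sum to 100.  The four ``shared_*``
    counts partition the shared-significant set the same way.
    """

    quadrant_pct: dict[str, float]
    shared_pos_r_up: int
    shared_pos_r_down: int
    shared_neg_r_up: int
    shared_neg_r_down: int
    n_signed: int

    @property
    def same_direction_pct(self) -> float:
        return self.quadrant_pct["pos_pos"] + self.quadrant_pct["neg_neg"]

    @property
    def opposite_direction_pct(self) -> float:
        return self.quadrant_pct["pos_neg"] + self.quadrant_pct["neg_pos"]


def direction_crosstab(
    cont: pd.DataFrame, dich: pd.DataFrame, shared: Iterable[str]
) -> DirectionCrossTab:
    """Quadrant percentages over all probes and sign counts over the shared
    significant set.

    ``cont`` needs columns probe_id and r; ``dich`` needs probe_id and delta.
    Probes with r = 0 or delta = 0 exactly (or undefined) carry no sign and
    are excluded from the percentages, which are renormalised over the rest.
    """
    merged = cont[["probe_id", "r"]].merge(
        dich[["probe_id", "delta"]], on="probe_id", validate="one_to_one"
    )
    r = merged["r"].to_numpy(dtype=float)
    d = merged["delta"].to_numpy(dtype=float)
    signed = (r != 0) & (d != 0) & ~np.isnan(r) & ~np.isnan(d)
    n_signed = int(signed.sum())
    quad = {"pos_pos": 0.0, "pos_neg": 0.0, "neg_pos": 0.0, "neg_neg": 0.0}
    if n_signed:
        quad["pos_pos"] = 100.0 * np.sum(signed & (r > 0) & (d > 0)) / n_signed
        quad["pos_neg"] = 100.0 * np.sum(signed & (r > 0) & (d < 0)) / n_signed
        quad["neg_pos"] = 100.0 * np.sum(signed & (r < 0) & (d > 0)) / n_signed
        quad["neg_neg"] = 100.0 * np.sum(signed & (r < 0) & (d < 0)) / n_signed
    shared = set(shared)
    in_shared = merged["probe_id"].isin(shared).to_numpy()
    return DirectionCrossTab(
        quadrant_pct=quad,
        shared_pos_r_up=int(np.sum(in_shared & (r > 0) & (d > 0))),
        shared_pos_r_down=int(np.sum(in_shared & (r > 0) & (d < 0))),
        shared_neg_r_up=int(np.sum(in_shared & (r < 0) & (d > 0))),
        shared_neg_r_down=int(np.sum(in_shared & (r < 0) & (d < 0))),
        n_signed=n_signed,
    )
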