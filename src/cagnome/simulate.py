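"""Synthetic sample panels and expression matrices with known CAG-correlation
structure.

The generative model is linear in the longer CAG allele on the log2 scale:
for a correlated probe,

    expression(sample) = baseline + slope * cag_long(sample) + eps,
    eps ~ Normal(0, noise_sd)

with the slope chosen so that the population Pearson correlation with the
panel's CAG lengths equals a target ``true_r``:

    slope = true_r * noise_sd / (sd(cag_long) * sqrt(1 - true_r**2))

Null probes are baseline plus noise.  Because the design points (the panel's
CAG lengths) are fixed, ``true_r`` is exactly the correlation that the sample
Pearson coefficient estimates, which gives every downstream stage a ground
truth to be checked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleTable, infer_group

__all__ = [
    "GeneratorConfig",
    "default_cag_panel",
    "generate_panel",
    "generate_expression",
]

# Fixed 107-sample panel of (longer, shorter) CAG allele lengths.  It is a
# hand-constructed stand-in that reproduces the published marginal statistics
# of the lymphoblastoid cohort -- 41 controls (CAG<36) and 66 HD (CAG>35),
# longer-allele range 15-92 with mean 40.9, shorter-allele mean 17.6 -- not
# the true per-sample genotypes, which were never published.
_DEFAULT_PANEL: list[tuple[int, int]] = [
    (15, 15), (16, 16), (17, 16), (17, 17), (18, 17), (18, 17), (19, 18),
    (19, 18), (19, 18), (20, 19), (20, 19), (20, 20), (21, 15), (21, 16),
    (21, 16), (22, 17), (22, 17), (22, 17), (23, 18), (23, 18), (23, 18),
    (24, 19), (24, 19), (25, 20), (25, 15), (26, 16), (26, 16), (27, 17),
    (27, 17), (28, 17), (28, 18), (29, 18), (29, 18), (30, 19), (30, 19),
    (31, 20), (31, 15), (32, 16), (33, 16), (34, 17), (35, 17),
    (36, 17), (37, 18), (38, 18), (39, 18), (40, 19), (40, 19), (40, 20),
    (41, 15), (41, 16), (41, 16), (41, 17), (42, 17), (42, 17), (43, 18),
    (43, 18), (43, 18), (44, 19), (44, 19), (44, 20), (44, 15), (44, 16),
    (45, 16), (45, 17), (45, 17), (45, 17), (45, 18), (46, 18), (46, 18),
    (46, 19), (46, 19), (46, 20), (47, 15), (47, 16), (47, 16), (47, 17),
    (48, 17), (48, 17), (48, 18), (48, 18), (49, 18), (49, 19), (49, 19),
    (50, 20), (50, 15), (51, 16), (51, 16), (52, 17), (52, 17), (53, 17),
    (53, 18), (54, 18), (55, 18), (56, 19), (58, 20), (60, 21), (62, 16),
    (64, 17), (67, 17), (70, 18), (73, 18), (76, 18), (79, 19), (82, 19),
    (86, 19), (91, 20), (92, 20),
]
# Two cell-line pairs share a donor (107 lines from 105 subjects): the two
# (18,17) controls and two of the (43,18) HD lines.
_DUPLICATE_SUBJECT_PAIRS = [(4, 5), (54, 55)]


def default_cag_panel() -> SampleTable:
    """The fixed 107-sample panel: 41 controls and 66 HD lines.

    Deterministic (a literal list, not random); longer-allele lengths span
    15-92 CAGs with mean 40.9, shorter alleles average 17.6.
    """
    longs = [l for l, _ in _DEFAULT_PANEL]
    shorts = [s for _, s in _DEFAULT_PANEL]
    sample_ids = [f"S{i + 1:03d}" for i in range(len(_DEFAULT_PANEL))]
    subject_ids = [f"U{i + 1:03d}" for i in range(len(_DEFAULT_PANEL))]
    for a, b in _DUPLICATE_SUBJECT_PAIRS:
        subject_ids[b] = subject_ids[a]
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cag_long": longs,
            "cag_short": shorts,
            "group": [infer_group(l) for l in longs],
            "subject_id": subject_ids,
        }
    )
    return SampleTable(frame)


CagSampler = Callable[[np.random.Generator, str, int], np.ndarray]


def default_cag_sampler(rng: np.random.Generator, group: str, size: int) -> np.ndarray:
    """Longer-allele lengths: controls ~ rounded Normal(21, 4) clipped to
    [15, 35]; HD ~ 36 + rounded Gamma(shape 2.2, scale 5) clipped to [36, 92]
    (right-skewed, as adult-onset alleles cluster in the low 40s with a long
    juvenile-onset tail)."""
    if group == "control":
        vals = np.rint(rng.normal(21.0, 4.0, size=size))
        return np.clip(vals, 15, 35).astype(int)
    vals = 36 + np.rint(rng.gamma(2.2, 5.0, size=size))
    return np.clip(vals, 36, 92).astype(int)


def generate_panel(
    n_control: int,
    n_hd: int,
    cag_sampler: Optional[CagSampler] = None,
    seed: int = 0,
) -> SampleTable:
    """Draw a random sample panel with ``n_control`` controls and ``n_hd`` HD
    samples; reproducible given ``seed``.

    The sampler must keep controls within [6, 35] and HD within [36, 250]
    CAGs so that group labels stay consistent with the CAG rule.
    """
    if n_control < 0 or n_hd < 0:
        raise ValueError("group sizes must be non-negative")
    sampler = cag_sampler or default_cag_sampler
    rng = np.random.default_rng(seed)
    rows = []
    for group, size in (("control", n_control), ("HD", n_hd)):
        if size == 0:
            continue
        longs = np.asarray(sampler(rng, group, size), dtype=int)
        lo, hi = (6, 35) if group == "control" else (36, 250)
        if longs.min() < lo or longs.max() > hi:
            raise ValueError(
                f"sampler produced {group} longer alleles outside [{lo}, {hi}]"
            )
        shorts = np.rint(rng.normal(18.0, 2.0, size=size)).astype(int)
        shorts = np.clip(shorts, 9, np.minimum(longs, 30))
        for l, s in zip(longs, shorts):
            rows.append((int(l), int(s), group))
    frame = pd.DataFrame(rows, columns=["cag_long", "cag_short", "group"])
    frame.insert(0, "sample_id", [f"S{i + 1:03d}" for i in range(len(frame))])
    return SampleTable(frame)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic expression generator.

    Defaults emulate the study's effect landscape: a small minority of probes
    correlated with CAG length at |r| between 0.15 and 0.43 (the observed
    coefficients ranged from -0.431 to 0.396), on a log2 intensity scale with
    per-probe baselines ~ Normal(6, 2) and residual noise sd 0.5.
    """

    n_probes: int = 10_000
    frac_correlated: float = 0.05
    r_low: float = 0.15
    r_high: float = 0.43
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    #: optional additive per-sample batch offsets, off by default; when
    #: batch_sd > 0, samples are split into n_batches groups each receiving a
    #: Normal(0, batch_sd) offset (the pipeline otherwise assumes
    #: batch-corrected input)
    batch_sd: float = 0.0
    n_batches: int = 2

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not 0.0 <= self.frac_correlated <= 1.0:
            raise ValueError("frac_correlated must be in [0, 1]")
        if not -1.0 < self.r_low <= self.r_high < 1.0:
            raise ValueError("need -1 < r_low <= r_high < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


# correlations in (-0.02, 0.02) are indistinguishable from null at any
# realistic panel size; the generator never assigns them to "correlated" probes
_MIN_ABS_R = 0.02


def _draw_true_r(rng: np.random.Generator, size: int, r_low: float, r_high: float) -> np.ndarray:
    """Target correlations, uniform on [r_low, r_high].  When the range is
    entirely non-negative it is read as a magnitude range and signs are
    assigned at random (so the default [0.15, 0.43] yields +/- effects)."""
    r = rng.uniform(r_low, r_high, size=size)
    if r_low >= 0.0:
        r = r * rng.choice([-1.0, 1.0], size=size)
    for _ in range(100):
        tiny = np.abs(r) < _MIN_ABS_R
        if not tiny.any():
            break
        r[tiny] = rng.uniform(r_low, r_high, size=int(tiny.sum()))
        if r_low >= 0.0:
            r[tiny] = r[tiny] * rng.choice([-1.0, 1.0], size=int(tiny.sum()))
    r[np.abs(r) < _MIN_ABS_R] = np.sign(r[np.abs(r) < _MIN_ABS_R]) * _MIN_ABS_R
    return r


def slope_for_target_r(true_r: np.ndarray, noise_sd: float, cag_sd: float) -> np.ndarray:
    """Slope (log2 units per CAG) giving population Pearson r = true_r for a
    fixed design with sd(cag_long) = cag_sd and residual sd = noise_sd."""
    true_r = np.asarray(true_r, dtype=float)
    return true_r * noise_sd / (cag_sd * np.sqrt(1.0 - true_r**2))


def generate_expression(
    panel: SampleTable, config: GeneratorConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a log2 expression matrix over ``panel`` plus its ground truth.

    Returns the matrix and a truth table with columns ``probe_id``,
    ``is_correlated``, ``true_r`` and ``slope``.  Fully reproducible from
    ``config.seed``.
    """
    if len(panel.frame) == 0:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(config.seed)
    n_samples = len(panel.frame)
    n_probes = config.n_probes
    n_corr = int(round(config.frac_correlated * n_probes))
    if config.frac_correlated > 0 and n_corr < 1:
        warnings.warn(
            "frac_correlated * n_probes < 1; generating zero correlated probes",
            stacklevel=2,
        )
    cag = panel.frame["cag_long"].to_numpy(dtype=float)
    cag_sd = float(np.std(cag, ddof=1))  # sd over the fixed design points
    if cag_sd == 0 and n_corr > 0:
        raise ValueError("panel CAG lengths are constant; correlation undefined")

    probe_ids = [f"P{i + 1:05d}" for i in range(n_probes)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    true_r = np.zeros(n_probes)
    if n_corr > 0:
        true_r[:n_corr] = _draw_true_r(rng, n_corr, config.r_low, config.r_high)
    slope = slope_for_target_r(true_r, config.noise_sd, cag_sd) if cag_sd > 0 else np.zeros(n_probes)
    slope[n_corr:] = 0.0

    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    values = baseline[:, None] + slope[:, None] * cag[None, :] + noise
    if config.batch_sd > 0:
        batch = np.arange(n_samples) % config.n_batches
        offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
        values = values + offsets[batch][None, :]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=panel.sample_ids)
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_correlated": np.arange(n_probes) < n_corr,
            "true_r": true_r,
            "slope": slope,
        }
    )
    return matrix, truth
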