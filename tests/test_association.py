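import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cagnome import (
    pearson_test,
    run_continuous,
    run_dichotomous,
    signed_fold_change,
    spearman_test,
    student_t_test,
)

# ---------------------------------------------------------------------------
# brute-force reference implementations (closed forms, independent of the
# library code paths under test)
# ---------------------------------------------------------------------------


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - 1)
    r = cov / (x.std(ddof=1) * y.std(ddof=1))
    if abs(r) >= 1:
        return math.copysign(1.0, r), 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, p


def brute_spearman(x, y):
    return brute_pearson(stats.rankdata(x), stats.rankdata(y))


def brute_student_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, 2 * stats.t.sf(abs(t), df=df)


def brute_fold_change(mean_hd, mean_ctrl):
    d = mean_hd - mean_ctrl
    return 2.0**d if d >= 0 else -(2.0 ** -d)


# ---------------------------------------------------------------------------
# scalar tests
# ---------------------------------------------------------------------------


class TestPearson:
    def test_exact_linearity(self):
        assert pearson_test([1, 2, 3, 4], [3, 5, 7, 9]).stat == pytest.approx(1.0)

    def test_exact_anti_linearity(self):
        assert pearson_test([1, 2, 3, 4], [4, 3, 2, 1]).stat == pytest.approx(-1.0)

    def test_matches_closed_form_on_cag_like_vector(self):
        x = [17, 20, 42, 45, 70, 92]
        y = [6.1, 5.8, 6.9, 6.4, 7.3, 7.8]
        r_ref, p_ref = brute_pearson(x, y)
        res = pearson_test(x, y)
        assert res.stat == pytest.approx(r_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_flagged_not_raised(self):
        res = pearson_test([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.stat) and res.p == 1.0 and res.note

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pearson_test([1, 2], [3, 4])


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = [17, 20, 42, 45, 70, 92]
        y = [math.log(v) ** 3 for v in x]
        assert spearman_test(x, y).stat == pytest.approx(1.0)

    def test_ties_use_midranks(self):
        x, y = [17, 17, 40, 48], [1, 2, 3, 4]
        rho_ref, p_ref = brute_spearman(x, y)
        res = spearman_test(x, y)
        assert res.stat == pytest.approx(rho_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_constant_y_flagged(self):
        res = spearman_test([1, 2, 3, 4], [7, 7, 7, 7])
        assert math.isnan(res.stat) and res.p == 1.0


class TestStudentT:
    def test_identical_groups(self):
        res = student_t_test([5, 6, 7], [5, 6, 7])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_pooled_closed_form(self):
        t_ref, df_ref, p_ref = brute_student_t([1, 2, 3], [4, 5, 6])
        res = student_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(t_ref, rel=1e-12)  # -3.674 by hand
        assert res.df == df_ref
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            student_t_test([1], [2, 3])

    def test_both_constant_unequal_means(self):
        res = student_t_test([2, 2], [1, 1])
        assert math.isinf(res.t) and res.t > 0
        assert 0 < res.p <= np.nextafter(0, 1)

    def test_welch_differs_under_unequal_variance(self):
        a, b = [1.0, 1.1, 0.9, 1.05], [5.0, 9.0, 1.0, 7.0]
        pooled = student_t_test(a, b)
        welch = student_t_test(a, b, welch=True)
        assert pooled.df == 6
        assert welch.df != pooled.df and welch.p != pooled.p


class TestFoldChange:
    @pytest.mark.parametrize(
        "mh,mc,expected",
        [(7, 7, 1.0), (8, 7, 2.0), (7, 8, -2.0), (7 + 1.2571, 7, 2.0**1.2571)],
    )
    def test_known_values(self, mh, mc, expected):
        assert signed_fold_change(mh, mc) == pytest.approx(expected)

    def test_printed_maximum_magnitude(self):
        # a log2 difference of 1.2571 corresponds to a +2.39 linear change
        assert round(signed_fold_change(1.2571, 0.0), 2) == 2.39


# ---------------------------------------------------------------------------
# oracle equivalence on random small instances
# ---------------------------------------------------------------------------


def test_all_four_statistics_match_brute_force_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = int(rng.integers(4, 12))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        a = rng.normal(size=int(rng.integers(3, 9)))
        b = rng.normal(loc=0.5, size=int(rng.integers(3, 9)))

        r_ref, pr_ref = brute_pearson(x, y)
        res = pearson_test(x, y)
        assert res.stat == pytest.approx(r_ref, rel=1e-10, abs=1e-12)
        assert res.p == pytest.approx(pr_ref, rel=1e-10, abs=1e-12)

        rho_ref, ps_ref = brute_spearman(x, y)
        res = spearman_test(x, y)
        assert res.stat == pytest.approx(rho_ref, rel=1e-10, abs=1e-12)
        assert res.p == pytest.approx(ps_ref, rel=1e-10, abs=1e-12)

        t_ref, df_ref, pt_ref = brute_student_t(a, b)
        res = student_t_test(a, b)
        assert res.t == pytest.approx(t_ref, rel=1e-10, abs=1e-12)
        assert res.df == df_ref
        assert res.p == pytest.approx(pt_ref, rel=1e-10, abs=1e-12)

        mh, mc = float(rng.normal()), float(rng.normal())
        assert signed_fold_change(mh, mc) == pytest.approx(
            brute_fold_change(mh, mc), rel=1e-10
        )


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

finite_vec = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False),
    min_size=4,
    max_size=12,
)


@settings(max_examples=50, derandomize=True)
@given(finite_vec, st.floats(0.1, 5), st.floats(-10, 10))
def test_pearson_symmetric_and_affine_invariant(y, scale, shift):
    x = list(range(len(y)))
    res_xy = pearson_test(x, y)
    res_yx = pearson_test(y, x)
    if math.isnan(res_xy.stat):
        assert math.isnan(res_yx.stat)
        return
    assert res_xy.stat == pytest.approx(res_yx.stat, rel=1e-9, abs=1e-12)
    scaled = pearson_test([scale * v + shift for v in x], y)
    assert scaled.stat == pytest.approx(res_xy.stat, rel=1e-9, abs=1e-9)
    flipped = pearson_test([-scale * v for v in x], y)
    assert flipped.stat == pytest.approx(-res_xy.stat, rel=1e-9, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(finite_vec)
def test_spearman_invariant_under_strictly_increasing_transform(y):
    x = list(range(len(y)))
    base = spearman_test(x, y)
    warped = spearman_test([math.exp(v / 10) for v in x], y)
    if math.isnan(base.stat):
        assert math.isnan(warped.stat)
    else:
        assert warped.stat == pytest.approx(base.stat, abs=1e-10)


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8),
)
def test_t_test_antisymmetric_in_group_order(a, b):
    ab = student_t_test(a, b)
    ba = student_t_test(b, a)
    assert ab.t == pytest.approx(-ba.t, rel=1e-9, abs=1e-12)
    assert ab.p == pytest.approx(ba.p, rel=1e-9, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(st.floats(-8, 8, allow_nan=False))
def test_fold_change_odd_symmetric_with_unit_floor(delta):
    fc = signed_fold_change(delta, 0.0)
    assert abs(fc) >= 1.0
    expected = 1.0 if delta == 0.0 else -fc
    assert signed_fold_change(0.0, delta) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# genome-wide drivers vs per-row scipy
# ---------------------------------------------------------------------------


def test_run_continuous_matches_scipy_rowwise(small_dataset):
    matrix, _, panel = small_dataset
    cont = run_continuous(matrix, panel).set_index("probe_id")
    x = panel.frame["cag_long"].to_numpy(float)
    rng = np.random.default_rng(1)
    for pid in rng.choice(matrix.probe_ids, size=25, replace=False):
        y = matrix.frame.loc[pid].to_numpy()
        r, p = stats.pearsonr(x, y)
        assert cont.loc[pid, "r"] == pytest.approx(r, rel=1e-10)
        assert cont.loc[pid, "p_pearson"] == pytest.approx(p, rel=1e-8)
        rho, ps = stats.spearmanr(x, y)
        assert cont.loc[pid, "rho"] == pytest.approx(rho, rel=1e-10)
        assert cont.loc[pid, "p_spearman"] == pytest.approx(ps, rel=1e-8)


def test_run_dichotomous_matches_scipy_rowwise(small_dataset):
    matrix, _, panel = small_dataset
    dich = run_dichotomous(matrix, panel).set_index("probe_id")
    hd = matrix.frame[panel.ids_in_group("HD")]
    ctrl = matrix.frame[panel.ids_in_group("control")]
    rng = np.random.default_rng(2)
    for pid in rng.choice(matrix.probe_ids, size=25, replace=False):
        t, p = stats.ttest_ind(hd.loc[pid], ctrl.loc[pid], equal_var=True)
        assert dich.loc[pid, "t_stat"] == pytest.approx(t, rel=1e-10)
        assert dich.loc[pid, "p_t"] == pytest.approx(p, rel=1e-8)


def test_zero_variance_probe_flagged_in_scan(tiny_matrix, tiny_samples):
    cont = run_continuous(tiny_matrix, tiny_samples)
    flagged = cont.set_index("probe_id").loc["P3"]
    assert math.isnan(flagged["r"]) and flagged["p_pearson"] == 1.0
    assert flagged["note"] == "zero variance"


def test_noise_free_correlated_probe_tops_the_table(panel):
    from cagnome import GeneratorConfig, generate_expression

    cfg = GeneratorConfig(
        n_probes=200, frac_correlated=0.005, r_low=0.9, r_high=0.9,
        noise_sd=1e-6, seed=17,
    )
    matrix, truth = generate_expression(panel, cfg)
    assert truth["is_correlated"].sum() == 1
    target = truth.loc[truth["is_correlated"], "probe_id"].iloc[0]
    cont = run_continuous(matrix, panel)
    top = cont.loc[cont["r"].abs().idxmax(), "probe_id"]
    assert top == target


def test_hd_shifted_probe_top_ranked_with_fold_change_two(panel):
    """A constant +1 log2 shift in HD gives the best t-test p and fc ~ +2."""
    rng = np.random.default_rng(3)
    n = len(panel.frame)
    values = rng.normal(6, 0.05, size=(50, n))
    shift = (panel.frame["group"] == "HD").to_numpy(float)
    values[0] += shift
    import cagnome

    matrix = cagnome.ExpressionMatrix(
        pd.DataFrame(values, index=[f"P{i}" for i in range(50)],
                     columns=panel.sample_ids)
    )
    dich = run_dichotomous(matrix, panel)
    best = dich.loc[dich["p_t"].idxmin()]
    assert best["probe_id"] == "P0"
    assert best["fold_change"] == pytest.approx(2.0, abs=0.1)
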