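"""Inferential toolkit against independent oracles (brute force, scipy, pingouin)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from threatdetect.errors import ContractError
from threatdetect.stats import (
    TestResult,
    align_responses,
    art_anova_2x2,
    bootstrap_ci,
    cohen_d_from_t,
    effect_r_from_z,
    paired_t,
    partial_eta_sq,
    rm_anova_2x2,
    spearman,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# effect-size arithmetic (the study's reported statistic/effect-size pairs)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "z,n,expected",
    [(4.03, 52, 0.56), (2.76, 52, 0.38), (2.30, 52, 0.32), (0.0, 52, 0.0)],
)
def test_effect_r_from_z(z, n, expected):
    assert round(effect_r_from_z(z, n), 2) == expected


@pytest.mark.parametrize(
    "t,n,expected",
    [(5.52, 52, 0.77), (2.57, 52, 0.36), (-1.67, 52, -0.23), (0.0, 52, 0.0)],
)
def test_cohen_d_from_t(t, n, expected):
    assert round(cohen_d_from_t(t, n), 2) == expected


@pytest.mark.parametrize(
    "F,df1,df2,expected",
    [(5.33, 1, 51, 0.09), (1.00, 1, 51, 0.02), (0.80, 1, 51, 0.02), (0.0, 1, 51, 0.0)],
)
def test_partial_eta_sq(F, df1, df2, expected):
    assert round(partial_eta_sq(F, df1, df2), 2) == expected


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _brute_force_wilcoxon_p(diffs, tails="two"):
    """Independent exact p: enumerate every sign assignment of the ranked |d|."""
    diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    observed = ranks[diffs > 0].sum()
    totals = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(ranks))
    ]
    totals = np.asarray(totals)
    ge = np.mean(totals >= observed - 1e-12)
    le = np.mean(totals <= observed + 1e-12)
    if tails == "greater":
        return ge
    if tails == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def test_identical_vectors_are_degenerate():
    x = np.arange(8.0)
    res = wilcoxon_signed_rank(x, x.copy())
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert "degenerate" in res.note


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("tails", ["two", "greater"])
def test_small_sample_p_matches_exact_enumeration(seed, tails):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.3, 1, 8)
    y = rng.normal(0, 1, 8)
    res = wilcoxon_signed_rank(x, y, tails=tails)  # auto -> exact for n <= 12
    assert res.p_value == pytest.approx(_brute_force_wilcoxon_p(x - y, tails), abs=1e-12)


def test_exact_p_matches_scipy_on_tie_free_data(rng):
    x = rng.normal(0.5, 1, 10)
    y = rng.normal(0.0, 1, 10)
    res = wilcoxon_signed_rank(x, y)
    assert res.p_value == pytest.approx(sps.wilcoxon(x, y, method="exact").pvalue, abs=1e-12)


def test_normal_approximation_matches_scipy(rng):
    x = rng.normal(0.2, 1, 52)
    y = rng.normal(0.0, 1, 52)
    res = wilcoxon_signed_rank(x, y)
    scipy_p = sps.wilcoxon(x, y, method="approx", correction=True).pvalue
    assert res.p_value == pytest.approx(scipy_p, rel=1e-9)
    assert res.effect_size == pytest.approx(abs(res.statistic) / np.sqrt(52))


def test_wilcoxon_invariant_to_common_shift(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 1, 30)
    a = wilcoxon_signed_rank(x, y)
    b = wilcoxon_signed_rank(x + 5.0, y + 5.0)
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_matches_hand_computation():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.2, 1.9, 3.4, 3.8, 5.1])
    res = paired_t(x, y)
    assert res.statistic == pytest.approx(-0.7492686492653537)
    assert res.p_value == pytest.approx(0.4953543088910333)
    assert res.df == (1, 4)
    assert res.effect_size == pytest.approx(res.statistic / np.sqrt(5))


def test_paired_t_one_tailed_halves_p_in_matching_direction(rng):
    x = rng.normal(0.5, 1, 40)
    y = rng.normal(0.0, 1, 40)
    two = paired_t(x, y, tails="two")
    one = paired_t(x, y, tails="greater")
    if two.statistic > 0:
        assert one.p_value == pytest.approx(two.p_value / 2)


def test_paired_t_rejects_zero_variance():
    x = np.arange(5.0)
    with pytest.raises(ContractError):
        paired_t(x, x + 1.0)


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA and ART
# ---------------------------------------------------------------------------

def _long_2x2(rng, n=20, a_effect=0.0, b_effect=0.0, ab_effect=0.0, noise=1.0):
    rows = []
    subj_int = rng.normal(0, 1, n)
    for i in range(n):
        for ai, a in enumerate(["a1", "a2"]):
            for bi, b in enumerate(["b1", "b2"]):
                mu = (
                    subj_int[i]
                    + a_effect * (ai - 0.5)
                    + b_effect * (bi - 0.5)
                    + ab_effect * (ai - 0.5) * (bi - 0.5)
                )
                rows.append(
                    {"subject_id": i, "A": a, "B": b, "value": mu + noise * rng.normal()}
                )
    return pd.DataFrame(rows)


def test_rm_anova_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    data = _long_2x2(rng, a_effect=0.5, ab_effect=0.3)
    mine = rm_anova_2x2(data)
    ref = pg.rm_anova(data=data, dv="value", within=["A", "B"], subject="subject_id",
                      detailed=True).set_index("Source")
    assert mine["A"].statistic == pytest.approx(ref.loc["A", "F"], rel=1e-8)
    assert mine["B"].statistic == pytest.approx(ref.loc["B", "F"], rel=1e-8)
    assert mine["A x B"].statistic == pytest.approx(ref.loc["A * B", "F"], rel=1e-8)


def test_rm_anova_f_is_squared_paired_t(rng):
    data = _long_2x2(rng, a_effect=0.4)
    wide = data.pivot_table(index="subject_id", columns=["A", "B"], values="value")
    a_margin_1 = wide[("a1", "b1")] + wide[("a1", "b2")]
    a_margin_2 = wide[("a2", "b1")] + wide[("a2", "b2")]
    t = paired_t((a_margin_1 / 2).to_numpy(), (a_margin_2 / 2).to_numpy())
    res = rm_anova_2x2(data)["A"]
    assert res.statistic == pytest.approx(t.statistic**2, rel=1e-8)
    assert res.effect_size == pytest.approx(partial_eta_sq(res.statistic, 1, 19))


def test_purely_additive_noiseless_data_have_zero_interaction(rng):
    data = _long_2x2(rng, a_effect=1.0, b_effect=0.5, ab_effect=0.0, noise=0.0)
    # noiseless additive data: the interaction contrast is exactly zero
    res = rm_anova_2x2(data)
    assert res["A x B"].statistic == pytest.approx(0.0, abs=1e-12)


def test_rm_anova_rejects_missing_cells(rng):
    data = _long_2x2(rng).iloc[:-1]
    with pytest.raises(ContractError):
        rm_anova_2x2(data)


def test_art_alignment_sums_to_zero_within_other_factor(rng):
    data = _long_2x2(rng, a_effect=0.7, b_effect=0.4, ab_effect=0.2)
    aligned = align_responses(data, "A")
    for b in ("b1", "b2"):
        assert aligned[data["B"] == b].sum() == pytest.approx(0.0, abs=1e-9)


def test_art_decisions_invariant_to_monotone_transform(rng):
    data = _long_2x2(rng, a_effect=0.8, ab_effect=0.0)
    base = art_anova_2x2(data)
    warped = data.copy()
    warped["value"] = np.exp(warped["value"] / 2.0)  # strictly monotone
    trans = art_anova_2x2(warped)
    # ART works on ranks of aligned data; alignment uses cell means, so the
    # transform can move F slightly, but the accept/reject decisions match
    for key in base:
        assert (base[key].p_value < 0.05) == (trans[key].p_value < 0.05)


# ---------------------------------------------------------------------------
# Spearman and bootstrap
# ---------------------------------------------------------------------------

def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert spearman(x, x**3).statistic == pytest.approx(1.0)
    assert spearman(x, -np.sqrt(x + 1)).statistic == pytest.approx(-1.0)


def test_spearman_with_ties_matches_pearson_on_midranks(rng):
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
    y = rng.normal(0, 1, 8)
    res = spearman(x, y)
    expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
    assert res.statistic == pytest.approx(expected, rel=1e-12)
    assert res.df == (6, None)


def test_spearman_constant_input_is_degenerate():
    res = spearman(np.ones(10), np.arange(10.0))
    assert np.isnan(res.statistic)
    assert "degenerate" in res.note


def test_bootstrap_is_deterministic_and_constant_data_collapse():
    data = np.arange(20.0)
    stat = lambda a: float(np.mean(a))
    ci1 = bootstrap_ci(data, stat, seed=11)
    ci2 = bootstrap_ci(data, stat, seed=11)
    assert ci1 == ci2
    with pytest.warns(UserWarning):
        lo, hi = bootstrap_ci(np.full(10, 3.0), stat, seed=0)
    assert lo == hi == 3.0


def test_bootstrap_interval_brackets_the_estimate(rng):
    x = rng.normal(1.0, 1.0, 40)
    d = float(np.mean(x) / np.std(x, ddof=1))
    lo, hi = bootstrap_ci(x, lambda a: float(np.mean(a) / np.std(a, ddof=1)),
                          level=0.95, seed=2)
    assert lo < d < hi


def test_testresult_row_schema():
    row = TestResult("demo", 1.0, "t", (1, 10), 0.5, "two", 0.2, "d", 0.95, (0.1, 0.3), 11).to_row()
    assert set(row) == {
        "test_name", "statistic_label", "statistic", "df1", "df2", "p", "tails",
        "effect_label", "effect", "ci_low", "ci_high", "ci_level", "n", "note",
    }
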