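"""Statistical battery: closed-form oracles, cross-implementation checks,
Monte-Carlo calibration."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from articmorph.stats import (
    games_howell,
    shapiro_wilk,
    summary_ci,
    t_test,
    three_way_anova,
)


def test_summary_ci_123():
    """{1,2,3}: mean 2, SD 1, CI half-width t(0.975,2)/sqrt(3)."""
    s = summary_ci([1.0, 2.0, 3.0])
    assert s.estimate == pytest.approx(2.0)
    assert s.statistic == pytest.approx(1.0)
    half = 4.302652729911275 / math.sqrt(3.0)  # t(0.975, 2) * SD / sqrt(n)
    assert s.ci_high - s.estimate == pytest.approx(half, abs=1e-6)
    assert s.ci_low == pytest.approx(2.0 - half, abs=1e-6)


def test_summary_ci_constant_sample_collapses():
    s = summary_ci([4.2] * 6)
    assert s.statistic == 0.0
    assert s.ci_low == s.ci_high == s.estimate == pytest.approx(4.2)
    with pytest.raises(ValueError):
        summary_ci([1.0])


def test_ci_width_shrinks_with_n():
    base = [1.0, 2.0, 3.0, 2.5, 1.5]
    w1 = summary_ci(base)
    w4 = summary_ci(base * 4)
    assert (w4.ci_high - w4.ci_low) < 0.6 * (w1.ci_high - w1.ci_low)


def test_t_test_closed_form_df2():
    """{1,2,3} vs 0: t = 2*sqrt(3); p from the exact df=2 CDF
    P(T <= t) = 1/2 + t / (2 sqrt(2 + t^2))."""
    res = t_test([1.0, 2.0, 3.0], mu0=0.0)
    t = 2.0 * math.sqrt(3.0)
    assert res.statistic == pytest.approx(t, abs=1e-9)
    p_exact = 2.0 * (1.0 - (0.5 + t / (2.0 * math.sqrt(2.0 + t * t))))
    assert res.p_value == pytest.approx(p_exact, abs=1e-9)
    assert res.p_value == pytest.approx(0.0742, abs=5e-5)


def test_paired_self_is_null():
    x = [3.1, 4.5, 2.2, 5.0]
    res = t_test(x, mode="paired", paired_with=x)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_one_tailed_is_half_two_tailed_on_correct_side():
    x = [1.0, 2.0, 3.0]
    two = t_test(x, mu0=0.0)
    one = t_test(x, mu0=0.0, mode="one_sample_one_tailed")
    assert one.tail == "greater"  # direction chosen by the mean
    assert one.p_value == pytest.approx(two.p_value / 2.0, abs=1e-12)
    wrong = t_test(x, mu0=0.0, mode="one_sample_one_tailed", direction="less")
    assert wrong.p_value == pytest.approx(1.0 - one.p_value, abs=1e-12)


def test_paired_mismatched_lengths_error():
    with pytest.raises(ValueError):
        t_test([1.0, 2.0], mode="paired", paired_with=[1.0, 2.0, 3.0])


def test_shapiro_wilk_matches_reference():
    """W and p agree with an independent reference implementation
    (values computed with R's shapiro.test) to 1e-6."""
    x = [2.31, 3.87, 1.02, 4.55, 2.96, 3.14, 0.78, 5.22, 3.41, 2.05, 4.18, 2.66]
    res = shapiro_wilk(x)
    assert res.statistic == pytest.approx(0.9792965798, abs=1e-6)
    assert res.p_value == pytest.approx(0.9806988392, abs=1e-6)
    y = [12.1, 9.8, 15.3, 7.4, 11.0, 20.5, 3.3, 8.8, 14.2, 10.6, 9.1, 13.7]
    res2 = shapiro_wilk(y)
    assert res2.statistic == pytest.approx(0.9756403259, abs=1e-6)
    assert res2.p_value == pytest.approx(0.9600722640, abs=1e-6)
    assert res.statistic <= 1.0


def test_shapiro_wilk_errors():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError, match="zero variance"):
        shapiro_wilk([2.0] * 10)


def test_shapiro_power_against_uniform():
    """Rejection rate at alpha=0.05 for uniform(0,1), n=24, lands in a
    plausible power band."""
    rng = np.random.default_rng(12345)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        x = rng.uniform(0.0, 1.0, 24)
        rejections += shapiro_wilk(x).p_value < 0.05
    assert 0.03 < rejections / reps < 0.30


def _hand_anova_ss(df, response, factors):
    """Brute-force main-effect sums of squares on a balanced design."""
    y = df[response].to_numpy()
    grand = y.mean()
    ss = {}
    for f in factors:
        s = 0.0
        for _, grp in df.groupby(f):
            s += len(grp) * (grp[response].mean() - grand) ** 2
        ss[f] = s
    fitted = np.full(len(df), grand)
    for f in factors:
        means = df.groupby(f)[response].transform("mean").to_numpy()
        fitted += means - grand
    ss["Residual"] = float(((y - fitted) ** 2).sum())
    return ss


def _balanced_toy():
    rows = []
    rng = np.random.default_rng(9)
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            for c in ("c1", "c2"):
                for _ in range(3):
                    y = (
                        1.0
                        + (a == "a2") * 2.0
                        + (b == "b2") * 0.5
                        + (c == "c2") * 0.1
                        + rng.normal(0, 0.3)
                    )
                    rows.append({"A": a, "B": b, "C": c, "y": y})
    return pd.DataFrame(rows)


def test_three_way_anova_balanced_matches_hand_ss():
    df = _balanced_toy()
    table = three_way_anova(df, "y", ("A", "B", "C"))
    hand = _hand_anova_ss(df, "y", ("A", "B", "C"))
    for f in ("A", "B", "C", "Residual"):
        assert table.loc[f, "sum_sq"] == pytest.approx(hand[f], rel=1e-9)
    # F from the same SS arithmetic
    ms_res = hand["Residual"] / table.loc["Residual", "df"]
    for f in ("A", "B", "C"):
        assert table.loc[f, "F"] == pytest.approx(
            (hand[f] / table.loc[f, "df"]) / ms_res, rel=1e-9
        )


def test_anova_ss_decomposition():
    df = _balanced_toy()
    table = three_way_anova(df, "y", ("A", "B", "C"))
    total = ((df["y"] - df["y"].mean()) ** 2).sum()
    assert table["sum_sq"].sum() == pytest.approx(total, abs=1e-9)


def test_anova_detects_effect_and_keeps_null_calibrated():
    """A 2-SD region effect is detected; the null side factor's p-values are
    uniform (alpha-level within a Monte-Carlo band over 200 reps)."""
    rng = np.random.default_rng(77)
    regions = ["dm", "pm", "dl", "pl"]
    hits = 0
    reps = 200
    region_ps = []
    for _ in range(reps):
        rows = []
        for spec in range(6):
            for side in ("left", "right"):
                for i, reg in enumerate(regions):
                    y = rng.normal(0, 1) + (i == 0) * 2.0
                    rows.append({"region": reg, "specimen": f"s{spec}",
                                 "side": side, "value": y})
        df = pd.DataFrame(rows)
        tab = three_way_anova(df, "value", ("region", "specimen", "side"))
        region_ps.append(tab.loc["region", "PR(>F)"])
        hits += tab.loc["side", "PR(>F)"] < 0.05
    assert np.median(region_ps) < 0.001
    assert 0.02 < hits / reps < 0.09


def test_anova_permutation_breaks_effects():
    rng = np.random.default_rng(31)
    ps = []
    for _ in range(20):
        df = _balanced_toy()
        df["y"] = rng.permutation(df["y"].to_numpy())
        tab = three_way_anova(df, "y", ("A", "B", "C"))
        ps.append(tab.loc["A", "PR(>F)"])
    assert np.median(ps) > 0.2


def test_anova_single_level_factor_errors():
    df = _balanced_toy()
    df["C"] = "c1"
    with pytest.raises(ValueError):
        three_way_anova(df, "y", ("A", "B", "C"))


def test_games_howell_identical_groups():
    g = [5.0, 5.1, 4.9, 5.2, 4.8]
    out = games_howell([g, list(g)])
    assert out.loc[0, "p_value"] > 0.999
    assert out.loc[0, "ci_low"] <= 0.0 <= out.loc[0, "ci_high"]


def test_games_howell_matches_pingouin():
    """Pairwise p-values agree with an independent implementation to 1e-4."""
    pg = pytest.importorskip("pingouin")
    g1 = [5.1, 4.8, 6.2, 5.5, 4.9, 5.8, 6.0, 5.2]
    g2 = [7.3, 9.1, 5.5, 8.8, 10.2, 6.7, 7.9, 9.5, 8.1]
    g3 = [4.2, 4.5, 4.1, 4.8, 4.3, 4.6, 4.4]
    mine = games_howell([g1, g2, g3], ["a", "b", "c"])
    df = pd.DataFrame(
        {"v": g1 + g2 + g3, "g": ["a"] * 8 + ["b"] * 9 + ["c"] * 7}
    )
    ref = pg.pairwise_gameshowell(data=df, dv="v", between="g")
    for (_, r1), (_, r2) in zip(mine.iterrows(), ref.iterrows()):
        assert r1["p_value"] == pytest.approx(r2["pval"], abs=1e-4)
        assert r1["df"] == pytest.approx(r2["df"], abs=1e-6)


def test_games_howell_approaches_tukey_when_balanced():
    """With equal variances and sizes the p-values approach Tukey HSD."""
    rng = np.random.default_rng(5)
    groups = [rng.normal(i * 0.08, 1.0, 200) for i in range(3)]
    gh = games_howell(groups)
    tk = sps.tukey_hsd(*groups)
    for k, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
        p_ref = tk.pvalue[i, j]
        assert gh.loc[k, "p_value"] == pytest.approx(p_ref, rel=0.05)


def test_games_howell_fwer_calibration():
    """Family-wise error over 3 null groups, 1000 seeded reps, alpha=0.05."""
    rng = np.random.default_rng(2024)
    reps = 1000
    fw = 0
    for _ in range(reps):
        groups = [rng.normal(0.0, 1.0, 24) for _ in range(3)]
        out = games_howell(groups)
        fw += bool((out["p_value"] < 0.05).any())
    assert 0.03 < fw / reps < 0.08


def test_games_howell_small_group_errors():
    with pytest.raises(ValueError):
        games_howell([[1.0, 2.0], [3.0]])
    with pytest.raises(ValueError):
        games_howell([[1.0, 2.0]])
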