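import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bex
from bex.design import CONDITIONS
from bex.epochs import SubjectERP
from bex.montage import ROIS
from bex.roi_stats import _anova_two_way_array, _contrasts, _gg_epsilon

from conftest import make_epochs


def ss_oracle_two_way(y):
    """First-principles two-way within-subject ANOVA oracle (explicit loops).

    Returns {effect: (F, df1, df2, partial_eta_sq, gg_eps)} computed with
    nothing shared with the implementation under test.
    """
    n, a, b = y.shape
    grand = y.mean()
    sa = np.zeros(a)
    sb = np.zeros(b)
    for i in range(a):
        sa[i] = y[:, i, :].mean()
    for j in range(b):
        sb[j] = y[:, :, j].mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "sA": 0.0, "sB": 0.0, "sAB": 0.0}
    for i in range(a):
        ss["A"] += n * b * (sa[i] - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (sb[j] - grand) ** 2
    for i in range(a):
        for j in range(b):
            cell = y[:, i, j].mean()
            ss["AB"] += n * (cell - sa[i] - sb[j] + grand) ** 2
    for s in range(n):
        ms = y[s].mean()
        for i in range(a):
            ss["sA"] += b * (y[s, i, :].mean() - ms - sa[i] + grand) ** 2
        for j in range(b):
            ss["sB"] += a * (y[s, :, j].mean() - ms - sb[j] + grand) ** 2
        for i in range(a):
            for j in range(b):
                ss["sAB"] += (y[s, i, j] - y[s, i, :].mean()
                              - y[s, :, j].mean() + ms
                              - y[:, i, j].mean() + y[:, i, :].mean()
                              + y[:, :, j].mean() - grand) ** 2

    def gg(mat):
        # Box's epsilon from the double-centered covariance matrix
        k = mat.shape[1]
        v = np.cov(mat, rowvar=False)
        row = v.mean(axis=0)
        dc = v - row[:, None] - row[None, :] + v.mean()
        num = (np.trace(dc)) ** 2
        den = (k - 1) * (dc ** 2).sum()
        return min(1.0, num / den)

    col_a = y.mean(axis=2)
    col_b = y.mean(axis=1)
    # interaction epsilon via orthonormalized interaction contrasts
    ca = np.linalg.svd(np.eye(a) - 1.0 / a)[0][:, :a - 1]
    cb = np.linalg.svd(np.eye(b) - 1.0 / b)[0][:, :b - 1]
    inter_scores = y.reshape(n, a * b) @ np.kron(ca, cb)
    si = np.cov(inter_scores, rowvar=False)
    gg_i = min(1.0, np.trace(si) ** 2 /
               ((a - 1) * (b - 1) * np.trace(si @ si)))

    out = {}
    for name, ss_e, df1, ss_err, df2, eps in (
            ("A", ss["A"], a - 1, ss["sA"], (a - 1) * (n - 1), gg(col_a)),
            ("B", ss["B"], b - 1, ss["sB"], (b - 1) * (n - 1), gg(col_b)),
            ("AB", ss["AB"], (a - 1) * (b - 1), ss["sAB"],
             (a - 1) * (b - 1) * (n - 1), gg_i)):
        F = (ss_e / df1) / (ss_err / df2)
        out[name] = (F, df1, df2, ss_e / (ss_e + ss_err), eps)
    return out


def tidy(y, conds=CONDITIONS, rois=("left", "middle", "right")):
    rows = []
    for s in range(y.shape[0]):
        for i, c in enumerate(conds):
            for j, r in enumerate(rois):
                rows.append((s, c, r, y[s, i, j]))
    return pd.DataFrame(rows, columns=["subject", "condition", "roi",
                                       "amplitude"])


# ---------------------------------------------------------------------------
# ROI amplitudes
# ---------------------------------------------------------------------------

def constant_erp(montage, value, subject=0):
    times = -100.0 + 10.0 * np.arange(100)
    data = {c: np.full((len(montage), len(times)), float(value))
            for c in CONDITIONS}
    return SubjectERP(data=data, n_trials={c: 1 for c in CONDITIONS},
                      times=times, sfreq=100.0,
                      ch_names=tuple(montage.names), subject=subject)


def test_constant_erp_gives_constant_cells(montage):
    table = bex.roi_mean_amplitude([constant_erp(montage, 2.5)])
    assert np.allclose(table["amplitude"], 2.5)
    assert len(table) == 4 * 3


def test_window_contains_seven_samples(montage):
    """500-560 ms inclusive at 100 Hz covers {500, 510, ..., 560}."""
    erp = constant_erp(montage, 0.0)
    tmask = (erp.times >= 500) & (erp.times <= 560)
    assert tmask.sum() == 7


def test_left_roi_is_mean_of_cp1_p1(montage):
    erp = constant_erp(montage, 0.0)
    i_cp1 = erp.channel_index("CP1")
    i_p1 = erp.channel_index("P1")
    erp.data["CC"][i_cp1, :] = 2.0
    erp.data["CC"][i_p1, :] = 4.0
    table = bex.roi_mean_amplitude([erp])
    cell = table[(table["condition"] == "CC") & (table["roi"] == "left")]
    assert cell["amplitude"].iloc[0] == pytest.approx(3.0)


def test_missing_roi_channel_errors(montage):
    erp = constant_erp(montage, 0.0)
    with pytest.raises(KeyError):
        bex.roi_mean_amplitude([erp], rois={"left": ("CP1", "Nope")})


# ---------------------------------------------------------------------------
# Two-way RM ANOVA
# ---------------------------------------------------------------------------

def test_all_equal_cells_give_zero_f():
    y = np.full((6, 4, 3), 1.7)
    res = bex.rm_anova_two_way(tidy(y))
    assert np.allclose(res.anova["F"], 0.0)


def test_matches_ss_oracle_on_random_tables():
    rng = np.random.default_rng(12)
    for n in (5, 8):
        for _ in range(5):
            y = rng.normal(size=(n, 4, 3)) + rng.normal(size=(n, 1, 1))
            res = bex.rm_anova_two_way(tidy(y), posthoc=False)
            oracle = ss_oracle_two_way(y)
            for eff, key in (("condition", "A"), ("roi", "B"),
                             ("condition:roi", "AB")):
                row = res.effect(eff)
                F, df1, df2, eta, eps = oracle[key]
                assert row["F"] == pytest.approx(F, rel=1e-10)
                assert (row["df1"], row["df2"]) == (df1, df2)
                assert row["partial_eta_sq"] == pytest.approx(eta, rel=1e-10)
                assert row["eps"] == pytest.approx(eps, rel=1e-8)


def test_interaction_dfs_for_n23():
    """4 x 3 within factors, n = 23 -> uncorrected interaction dfs (6, 132)."""
    rng = np.random.default_rng(1)
    y = rng.normal(size=(23, 4, 3))
    res = bex.rm_anova_two_way(tidy(y), posthoc=False)
    row = res.effect("condition:roi")
    assert (row["df1"], row["df2"]) == (6, 132)


def test_matches_r_car_anova_frozen_fixture():
    """Frozen cross-check: car::Anova on the same table gives GG eps 0.68824 /
    0.86998 / 0.56917 and p_GG 0.78725 / 0.07144 / 0.46144."""
    rng = np.random.default_rng(7)
    y = rng.normal(size=(8, 4, 3)) + rng.normal(size=(8, 1, 1))
    res = bex.rm_anova_two_way(tidy(y), posthoc=False)
    expected = {"condition": (0.68824, 0.78725), "roi": (0.86998, 0.07144),
                "condition:roi": (0.56917, 0.46144)}
    for eff, (eps, p_gg) in expected.items():
        row = res.effect(eff)
        assert row["eps"] == pytest.approx(eps, abs=5e-6)
        assert row["p_gg"] == pytest.approx(p_gg, abs=5e-6)


def test_main_effects_match_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(21)
    y = rng.normal(size=(9, 4, 3))
    df = tidy(y)
    res = bex.rm_anova_two_way(df, posthoc=False)
    ref = pg.rm_anova(data=df, dv="amplitude",
                      within=["condition", "roi"], subject="subject",
                      detailed=True, effsize="np2")
    for eff in ("condition", "roi"):
        row = res.effect(eff)
        r = ref[ref["Source"] == eff].iloc[0]
        assert row["F"] == pytest.approx(r["F"], rel=1e-9)
        assert row["eps"] == pytest.approx(r["eps"], rel=1e-6)
        assert row["p_gg"] == pytest.approx(r["p_GG_corr"], rel=1e-6)


def test_epsilon_bounds_property():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n, a, b = rng.integers(4, 10), 4, 3
        y = rng.normal(size=(n, a, b)) * rng.uniform(0.2, 3.0, size=(1, a, b))
        res = bex.rm_anova_two_way(tidy(y), posthoc=False)
        for eff, k in (("condition", 4), ("roi", 3), ("condition:roi", None)):
            eps = res.effect(eff)["eps"]
            lo = 1.0 / res.effect(eff)["df1"]
            assert lo - 1e-12 <= eps <= 1.0 + 1e-12


def test_ss_decomposition_consistency():
    rng = np.random.default_rng(8)
    y = rng.normal(size=(7, 4, 3))
    res = bex.rm_anova_two_way(tidy(y), posthoc=False)
    table = res.anova
    ss_sum = table["ss_effect"].sum() + table["ss_error"].sum()
    # add subject SS to complete the decomposition
    m_s = y.mean(axis=(1, 2))
    ss_subj = 12 * ((m_s - y.mean()) ** 2).sum()
    assert ss_sum + ss_subj == pytest.approx(((y - y.mean()) ** 2).sum(),
                                             rel=1e-10)


def test_incomplete_table_errors():
    y = np.zeros((5, 4, 3))
    df = tidy(y)
    with pytest.raises(ValueError, match="incomplete"):
        bex.rm_anova_two_way(df[~((df.subject == 0) &
                                  (df.condition == "CC") &
                                  (df.roi == "left"))])


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def test_tukey_identical_levels_not_significant():
    rng = np.random.default_rng(3)
    noise = rng.normal(0, 0.1, size=(8, 3))
    y = np.stack([noise] * 4, axis=1)  # all condition levels identical
    table = bex.tukey_hsd(tidy(y))
    assert len(table) == 6  # 4 levels -> 6 pairwise comparisons
    assert np.allclose(table["mean_diff"], 0.0)
    assert not table["significant"].any()


def test_tukey_shifted_level_detected():
    rng = np.random.default_rng(4)
    y = rng.normal(0, 0.5, size=(8, 4, 3))
    y[:, 3, :] += 3.0  # WC shifted +3 uV
    table = bex.tukey_hsd(tidy(y))
    wc_rows = table[(table["level_a"] == "WC") | (table["level_b"] == "WC")]
    assert len(wc_rows) == 3
    assert wc_rows["significant"].all()
    assert wc_rows["p"].max() < 1e-6  # +3 uV against sigma 0.5 is unmissable


def test_interaction_posthoc_has_all_cell_pairs():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(6, 4, 3))
    res = bex.rm_anova_two_way(tidy(y))
    cells = res.posthoc["condition:roi"]
    assert len(cells) == 12 * 11 // 2


# ---------------------------------------------------------------------------
# Confidence ANOVA
# ---------------------------------------------------------------------------

def behavior_confidence_table(n, means, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        for c in CONDITIONS:
            for t in range(4):
                rows.append((s, c, t, means[c] + sd * rng.normal()))
    df = pd.DataFrame(rows, columns=["subject", "condition", "trial",
                                     "confidence"])
    return df


def test_confidence_anova_dfs_and_null():
    means = {c: 3.0 for c in CONDITIONS}
    df = behavior_confidence_table(23, means, sd=0.3, seed=2)
    res = bex.confidence_anova(df)
    row = res.effect("condition")
    assert (row["df1"], row["df2"]) == (3, 66)
    equal = behavior_confidence_table(5, means, sd=0.0)
    res0 = bex.confidence_anova(equal)
    assert res0.effect("condition")["F"] == 0.0


def test_confidence_wc_elevated_found_in_posthoc():
    means = {"CC": 3.3, "WW": 3.3, "CW": 3.2, "WC": 4.1}
    df = behavior_confidence_table(23, means, sd=0.4, seed=3)
    res = bex.confidence_anova(df)
    assert res.effect("condition")["p_gg"] < 0.001
    ph = res.posthoc["condition"]
    wc = ph[(ph["level_a"] == "WC") | (ph["level_b"] == "WC")]
    assert wc["significant"].all()


def test_missing_condition_errors():
    means = {c: 3.0 for c in CONDITIONS}
    df = behavior_confidence_table(5, means)
    with pytest.raises(ValueError, match="missing"):
        bex.confidence_anova(df[df["condition"] != "WC"])


def test_gg_corrected_p_uniform_under_null():
    """Exchangeable-cell null: corrected p-values approximately uniform
    (KS not rejecting at 0.01 over 500 simulated tables)."""
    rng = np.random.default_rng(0)
    ps = {"condition": [], "roi": [], "condition:roi": []}
    for _ in range(500):
        y = rng.normal(size=(23, 4, 3)) + rng.normal(size=(23, 1, 1))
        res = _anova_two_way_array(y, "condition", "roi", list(CONDITIONS),
                                   ["l", "m", "r"], posthoc=False)
        for _, row in res.anova.iterrows():
            ps[row["effect"]].append(row["p_gg"])
    for effect, values in ps.items():
        _, p = stats.kstest(values, "uniform")
        assert p > 0.01, f"{effect}: corrected p-values not uniform"
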