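"""Subgroup summaries, contrasts, discriminability AUC, k-means profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import morbidlca as m
from morbidlca.stats import (
    age_bracket_profile,
    compare_subgroups,
    kmeans_age_profiles,
    summarize_subgroups,
    validate_subgroups_auc,
)

CATS = m.ELIXHAUSER_CATEGORIES


def hand_cohort():
    """6 patients, 2 subgroups, outcomes countable by hand."""
    df = pd.DataFrame(0, index=range(6), columns=list(CATS))
    df["liver_disease"] = [1, 1, 0, 0, 0, 0]
    df["age"] = [50.0, 54.0, 70.0, 74.0, 72.0, 68.0]
    df["elective"] = [0, 0, 1, 1, 0, 0]
    df["organ_dysfunction"] = [1, 1, 1, 0, 0, 0]
    df["sepsis"] = [1, 0, 1, 0, 0, 0]
    df["mortality"] = [1, 0, 0, 0, 0, 1]
    return df, np.array([0, 0, 1, 1, 1, 1])


def test_summary_matches_hand_counts():
    df, member = hand_cohort()
    s = summarize_subgroups(member, df)
    assert s.loc[0, "n"] == 2 and s.loc[1, "n"] == 4
    assert s["fraction"].sum() == pytest.approx(1.0)
    assert s.loc[0, "prev_liver_disease"] == pytest.approx(1.0)
    assert s.loc[1, "prev_liver_disease"] == 0.0
    assert s.loc[0, "age_mean"] == pytest.approx(52.0)
    assert s.loc[0, "organ_dysfunction_rate"] == pytest.approx(1.0)
    assert s.loc[0, "sepsis_rate"] == pytest.approx(0.5)
    # conditional mortality uses the conditioning event as denominator:
    # subgroup 1 has 1 death (a non-OD patient), OD patients 1, sepsis 1
    assert s.loc[1, "mortality_rate"] == pytest.approx(0.25)
    assert s.loc[1, "mortality_given_organ_dysfunction"] == 0.0
    assert s.loc[1, "mortality_given_sepsis"] == 0.0
    assert s.loc[0, "mortality_given_sepsis"] == pytest.approx(1.0)
    # t-based CI on subgroup 0 ages: mean 52 +/- t_{.975,1} * sd/sqrt(2)
    half = sps.t.ppf(0.975, 1) * np.std([50, 54], ddof=1) / np.sqrt(2)
    assert s.loc[0, "age_ci_low"] == pytest.approx(52 - half)
    assert s.loc[0, "age_ci_high"] == pytest.approx(52 + half)


def test_summary_single_subgroup_equals_cohort():
    df, _ = hand_cohort()
    s = summarize_subgroups(np.zeros(6, dtype=int), df)
    assert s.loc[0, "fraction"] == 1.0
    assert s.loc[0, "prev_liver_disease"] == pytest.approx(df["liver_disease"].mean())


def test_summary_severity_columns_optional():
    df, member = hand_cohort()
    df["sofa"] = [8, 6, 4, 2, 2, 4]
    s = summarize_subgroups(member, df)
    assert s.loc[0, "sofa_mean"] == pytest.approx(7.0)


def test_chi_square_matches_closed_form():
    """2x2 table [[10,20],[20,10]]: Pearson X^2 = N(ad-bc)^2/(r1 r2 c1 c2)."""
    member = np.repeat([0, 1], 30)
    df = pd.DataFrame({"flag": [1] * 10 + [0] * 20 + [1] * 20 + [0] * 10})
    res = compare_subgroups(member, df, categorical=["flag"], continuous=[])
    expected = 60 * (10 * 10 - 20 * 20) ** 2 / (30 * 30 * 30 * 30)
    assert res.loc[0, "statistic"] == pytest.approx(expected, abs=1e-10)
    assert res.loc[0, "df"] == 1


def test_chi_square_pearson_formula_oracle():
    """Independently coded Pearson formula on random small tables."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        r, c = rng.integers(2, 6, size=2)
        labels = rng.integers(0, r, size=400)
        vals = rng.integers(0, c, size=400)
        df = pd.DataFrame({"v": vals})
        res = compare_subgroups(labels, df, categorical=["v"], continuous=[])
        tab = pd.crosstab(labels, vals).to_numpy().astype(float)
        expected_counts = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        pearson = ((tab - expected_counts) ** 2 / expected_counts).sum()
        assert res.loc[0, "statistic"] == pytest.approx(pearson, abs=1e-10)


def test_identical_blocks_give_zero_chi_square():
    df = pd.DataFrame({"flag": [1, 0, 1, 0, 1, 0, 1, 0]})
    member = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    res = compare_subgroups(member, df, categorical=["flag"], continuous=[])
    assert res.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)


def test_anova_null_p_values_are_uniform():
    """Equal-mean groups: ANOVA p-values ~ U(0,1) (KS sanity check)."""
    rng = np.random.default_rng(4)
    pvals = []
    member = np.repeat([0, 1], 30)
    for _ in range(1000):
        df = pd.DataFrame({"x": rng.normal(0, 1, 60)})
        res = compare_subgroups(member, df, categorical=[], continuous=["x"])
        pvals.append(res.loc[0, "p_value"])
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_single_level_variable_skipped():
    df = pd.DataFrame({"flag": [1, 1, 1, 1]})
    res = compare_subgroups(np.array([0, 0, 1, 1]), df,
                            categorical=["flag"], continuous=[])
    assert res.loc[0, "note"] == "single level"
    assert "p_value" not in res.columns or pd.isna(res.loc[0].get("p_value"))


def test_auc_separable_and_null():
    rng = np.random.default_rng(5)
    member = np.repeat([0, 1], 100)
    X = np.vstack([rng.normal(0, 0.3, (100, 3)), rng.normal(3, 0.3, (100, 3))])
    aucs = validate_subgroups_auc(member, X, seed=0)
    assert (aucs > 0.99).all()
    shuffled = rng.permutation(member)
    null_aucs = validate_subgroups_auc(shuffled, X, seed=0)
    assert np.abs(null_aucs - 0.5).max() < 0.12


def test_auc_small_subgroup_reduces_folds():
    rng = np.random.default_rng(6)
    member = np.array([0] * 3 + [1] * 97)
    X = rng.normal(size=(100, 2))
    aucs = validate_subgroups_auc(member, X, seed=0, n_folds=5)
    assert set(aucs.index) == {0, 1}  # computed despite the tiny class


def test_age_bracket_profile_counts():
    ind = np.zeros((4, 30), dtype=int)
    ind[0, 0] = ind[1, 0] = 1  # category 0 in two young patients
    age = np.array([20.0, 22.0, 70.0, 72.0])
    prof = age_bracket_profile(ind, age)
    assert prof.loc[CATS[0], "16-24"] == pytest.approx(1.0)
    assert prof.loc[CATS[0], "65-84"] == 0.0


def test_kmeans_recovers_three_archetype_patterns():
    """Rising-with-age, flat-low, and mid-life-peak prevalence profiles
    separate into three clusters."""
    rng = np.random.default_rng(7)
    rising = np.array([0.05, 0.15, 0.3, 0.5, 0.6])
    flat = np.array([0.01, 0.02, 0.02, 0.03, 0.02])
    midpeak = np.array([0.05, 0.3, 0.35, 0.15, 0.05])
    rows, truth = [], []
    for arch_id, arch in enumerate((rising, flat, midpeak)):
        for _ in range(10):
            rows.append(np.clip(arch + rng.normal(0, 0.015, 5), 0, 1))
            truth.append(arch_id)
    labels = kmeans_age_profiles(np.array(rows), k=3, seed=0)
    # each archetype's rows share one label, distinct across archetypes
    groups = [set(labels[np.array(truth) == a]) for a in range(3)]
    assert all(len(g) == 1 for g in groups)
    assert len(set.union(*groups)) == 3


def test_kmeans_duplicates_cocluster_and_trivial_k():
    X = np.array([[0.1] * 5, [0.1] * 5, [0.9] * 5, [0.5] * 5])
    labels = kmeans_age_profiles(X, k=2, seed=0)
    assert labels[0] == labels[1]
    full = kmeans_age_profiles(X[[0, 2, 3]], k=3, seed=0)
    assert len(set(full)) == 3  # every distinct profile its own cluster
    with pytest.raises(ValueError):
        kmeans_age_profiles(X, k=0)
    with pytest.raises(ValueError):
        kmeans_age_profiles(X, k=5)


def test_default_cohort_auc_and_outcome_ordering(small_cohort, small_dataset):
    """On the default six-class cohort, every generating class is
    discriminable one-vs-rest (AUC > 0.8), and the hepatic/addiction class
    shows the highest sepsis and organ-dysfunction rates."""
    labels = small_cohort.true_class
    aucs = validate_subgroups_auc(labels, small_dataset.one_hot(), seed=0)
    assert (aucs > 0.8).all(), aucs

    df = small_cohort.cohort.copy()
    for j, cat in enumerate(CATS):
        df[cat] = small_cohort.indicators[:, j]
    s = summarize_subgroups(labels, df)
    hep = 2  # class order: hepatic/addiction is the third class
    assert s["sepsis_rate"].idxmax() == hep
    assert s["organ_dysfunction_rate"].idxmax() == hep
    assert s["mortality_given_sepsis"].idxmax() == hep
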