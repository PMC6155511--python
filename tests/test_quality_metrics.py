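import numpy as np
import pandas as pd
import pytest

import repenroll.quality_metrics as qm


@pytest.fixture
def response_frame():
    rng = np.random.default_rng(0)
    base = rng.integers(1, 6, size=(40, 8)).astype(float)
    df = pd.DataFrame(base, columns=[f"q{i}" for i in range(1, 9)])
    df["q9"] = df["q1"] + rng.normal(0, 0.4, 40)   # strong synonym of q1
    df["q10"] = df["q2"] + rng.normal(0, 0.4, 40)  # strong synonym of q2
    return df


def test_select_synonym_pairs_duplicate_column_first():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    df["e"] = df["a"]
    pairs = qm.select_synonym_pairs(df, q=1)
    assert set(pairs[0]) == {"a", "e"}


def test_select_synonym_pairs_greedy_matches_exhaustive(response_frame):
    """With well-separated correlations, greedy equals the best disjoint pairing."""
    from itertools import permutations

    df = response_frame[["q1", "q2", "q9", "q10", "q3", "q4"]]
    corr = df.corr().abs()
    cols = list(df.columns)
    best, best_val = None, -np.inf
    for perm in permutations(cols):
        pairing = [tuple(sorted(perm[i: i + 2])) for i in range(0, 6, 2)]
        val = sum(corr.loc[a, b] for a, b in pairing)
        if val > best_val:
            best_val, best = val, set(map(frozenset, pairing))
    got = qm.select_synonym_pairs(df, q=3)
    assert set(map(frozenset, got)) == best


def test_synonym_correlation_identical_and_antimatched():
    pairs = [("a1", "a2"), ("b1", "b2"), ("c1", "c2"), ("d1", "d2")]
    row = {"a1": 1, "a2": 1, "b1": 3, "b2": 3, "c1": 5, "c2": 5, "d1": 2, "d2": 2}
    assert qm.synonym_correlation(row, pairs) == pytest.approx(1.0)
    anti = {"a1": 1, "a2": 5, "b1": 3, "b2": 3, "c1": 5, "c2": 1, "d1": 2, "d2": 4}
    assert qm.synonym_correlation(anti, pairs) == pytest.approx(-1.0)


def test_synonym_correlation_matches_direct_formula():
    pairs = [("a1", "a2"), ("b1", "b2"), ("c1", "c2"), ("d1", "d2")]
    row = {"a1": 1, "a2": 2, "b1": 4, "b2": 3, "c1": 5, "c2": 5, "d1": 2, "d2": 1}
    expected = np.corrcoef([1, 4, 5, 2], [2, 3, 5, 1])[0, 1]
    assert qm.synonym_correlation(row, pairs) == pytest.approx(expected)


def test_synonym_correlation_degenerate_is_nan():
    pairs = [("a1", "a2"), ("b1", "b2"), ("c1", "c2")]
    row = {"a1": 3, "a2": 1, "b1": 3, "b2": 4, "c1": 3, "c2": 2}  # firsts constant
    assert np.isnan(qm.synonym_correlation(row, pairs))


def _scales():
    return [
        qm.ScaleDefinition("s1", ("s1a", "s1b", "s1c", "s1d")),
        qm.ScaleDefinition("s2", ("s2a", "s2b", "s2c", "s2d")),
        qm.ScaleDefinition("s3", ("s3a", "s3b", "s3c", "s3d")),
        qm.ScaleDefinition("s4", ("s4a", "s4b", "s4c", "s4d")),
    ]


def test_even_odd_uniform_within_scale_is_one():
    row = {}
    for lvl, sc in zip((1, 4, 2, 5), _scales()):
        for item in sc.items:
            row[item] = lvl
    assert qm.even_odd_consistency(row, _scales()) == pytest.approx(1.0)


def test_even_odd_zero_raw_is_zero_corrected():
    # 2*rho/(1+rho) has fixed point 0
    assert 2 * 0.0 / (1 + 0.0) == 0.0
    row = {}
    odd_vals, even_vals = (1, 2, 3, 4), (3, 3, 1, 4)  # rho computed below
    for o, e, sc in zip(odd_vals, even_vals, _scales()):
        row[sc.items[0]] = row[sc.items[2]] = o
        row[sc.items[1]] = row[sc.items[3]] = e
    rho = np.corrcoef(odd_vals, even_vals)[0, 1]
    assert qm.even_odd_consistency(row, _scales()) == pytest.approx(2 * rho / (1 + rho))


def test_scale_requires_four_items():
    with pytest.raises(ValueError, match="4 items"):
        qm.ScaleDefinition("tiny", ("a", "b", "c"))


def test_distance_from_average_properties():
    df = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [2.0, 6.0, 4.0]})
    d = qm.distance_from_average(df)
    assert d.iloc[2] == pytest.approx(0.0)           # exactly at the mean
    assert d.iloc[0] == pytest.approx(d.iloc[1])     # symmetric respondents
    assert d.iloc[0] == pytest.approx(np.sqrt(1 + 4))


def test_run_statistic_examples():
    pages = {"p1": [f"i{k}" for k in range(6)]}
    allsame = {f"i{k}": 3 for k in range(6)}
    assert qm.run_statistic(allsame, pages) == pytest.approx(1.0)
    alternating = {f"i{k}": k % 2 for k in range(6)}
    assert qm.run_statistic(alternating, pages) == pytest.approx(0.0)
    run3 = dict(zip([f"i{k}" for k in range(6)], [1, 2, 2, 2, 1, 3]))
    assert qm.run_statistic(run3, pages) == pytest.approx((3 - 1) / (6 - 1))


def test_run_statistic_short_pages_skipped():
    pages = {"short": ["a", "b"], "long": ["c", "d", "e", "f", "g"]}
    row = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 2, "f": 1, "g": 1}
    assert qm.run_statistic(row, pages) == pytest.approx((3 - 1) / (5 - 1))
    assert np.isnan(qm.run_statistic({"a": 1, "b": 1}, {"short": ["a", "b"]}))


def test_summarize_by_group_single_group_reproduces_full_sample():
    rng = np.random.default_rng(4)
    profiles = pd.DataFrame(
        {
            "completion_minutes": rng.exponential(20, 30),
            "synonym_corr": rng.uniform(-1, 1, 30),
            "fake_name": rng.random(30) < 0.1,
        }
    )
    out = qm.summarize_by_group(profiles, np.repeat("all", 30))
    pd.testing.assert_series_equal(out["all"], out["full_sample"], check_names=False)
    assert 0 <= out.loc["fake_name", "all"] <= 100


def test_group_means_reconstruct_full_sample_mean():
    rng = np.random.default_rng(9)
    profiles = pd.DataFrame({"synonym_corr": rng.uniform(-1, 1, 50)})
    groups = rng.choice(["a", "b", "c"], 50)
    out = qm.summarize_by_group(profiles, groups)
    sizes = pd.Series(groups).value_counts()
    weighted = sum(out.loc["synonym_corr", g] * sizes[g] for g in sizes.index) / 50
    assert weighted == pytest.approx(out.loc["synonym_corr", "full_sample"])


def test_cross_tabulate_margins():
    clusters = ["other"] * 6 + ["c1"] * 3 + ["c2"] * 1
    classes = [1, 1, 2, 2, 3, 3, 2, 2, 2, 3]
    tab = qm.cross_tabulate(clusters, classes)
    assert tab.loc["Total", "Total"] == 10
    assert tab.loc["c1", 2] == 3
    assert list(tab.loc["Total"][:-1]) == [2, 5, 3]


def test_quality_profiles_assembly(response_frame):
    df = response_frame.copy()
    rng = np.random.default_rng(2)
    df["completion_minutes"] = rng.exponential(20, len(df))
    df["fake_name"] = rng.random(len(df)) < 0.1
    pages = {"p1": ["q1", "q2", "q3", "q4", "q5"], "p2": ["q6", "q7", "q8", "q9", "q10"]}
    profiles = qm.quality_profiles(
        df,
        pages=pages,
        synonym_items=[c for c in df.columns if c.startswith("q")],
        q_pairs=3,
        flag_cols=["fake_name"],
    )
    assert {"completion_minutes", "synonym_corr", "distance_from_average",
            "mean_run_statistic", "fake_name"} <= set(profiles.columns)
    corr_ok = profiles["synonym_corr"].dropna()
    assert ((corr_ok >= -1) & (corr_ok <= 1)).all()
    assert (profiles["mean_run_statistic"].dropna() >= 0).all()
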