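"""Preprocessing semantics: dummy encoding, NZV, correlation filter,
centering/scaling, complete-case; all learned on training rows only."""

import math

import numpy as np
import pandas as pd
import pytest

from omicforest import (
    DesignMatrix,
    Preprocessor,
    center_scale,
    drop_incomplete,
    drop_nzv,
    dummy_encode,
    find_correlated,
    nzv_report,
)
from omicforest.preprocess import PreprocessState, correlation_matrix


def _dm(df, categorical=(), target=None):
    if target is None:
        df = df.copy()
        df["log2_intensity"] = np.arange(len(df), dtype=float)
    return DesignMatrix.from_frame(df, categorical=categorical)


# ---- dummy encoding --------------------------------------------------------

def test_dummy_encode_expands_each_level():
    df = pd.DataFrame({"strand": ["+", "-", "+", "-"],
                       "x": [1.0, 2.0, 3.0, 4.0]})
    dm = _dm(df, categorical=["strand"])
    out = dummy_encode(dm)
    dcols = [c for c in out.table.columns if c.startswith("strand.")]
    assert len(dcols) == 2
    assert (out.table[dcols].sum(axis=1) == 1).all()
    assert (out.table["x"] == df["x"]).all()


def test_dummy_encode_single_level_gives_constant_column():
    df = pd.DataFrame({"Organism": ["Human"] * 4, "x": [1.0, 2.0, 3.0, 4.0]})
    out = dummy_encode(_dm(df, categorical=["Organism"]))
    dcols = [c for c in out.table.columns if c.startswith("Organism.")]
    assert len(dcols) == 1
    assert (out.table[dcols[0]] == 1).all()
    # and the downstream variance filter removes it
    report = nzv_report(out)
    assert report.table.loc[dcols[0], "zeroVar"]


def test_dummy_encode_seven_versions():
    df = pd.DataFrame({"Version..sequence.": [str(v) for v in
                                              [1, 2, 3, 4, 5, 6, 7, 1, 2, 3]],
                       "x": np.arange(10.0)})
    out = dummy_encode(_dm(df, categorical=["Version..sequence."]))
    assert sum(c.startswith("Version..sequence..") for c in out.table.columns) == 7


# ---- near-zero variance ----------------------------------------------------

def test_nzv_constant_column_is_zero_variance():
    df = pd.DataFrame({"Organism": np.ones(50), "x": np.arange(50.0)})
    rep = nzv_report(df)
    assert rep.table.loc["Organism", "freqRatio"] == math.inf
    assert bool(rep.table.loc["Organism", "zeroVar"])
    assert bool(rep.table.loc["Organism", "nzv"])
    assert not rep.table.loc["x", "nzv"]


def test_nzv_six_to_one_ratio_not_flagged():
    # 7 rows: modal 6x, second 1x -> freqRatio 6, percentUnique 28.6
    df = pd.DataFrame({"g": [0, 0, 0, 0, 0, 0, 1]})
    rep = nzv_report(df)
    assert rep.table.loc["g", "freqRatio"] == pytest.approx(6.0)
    assert rep.table.loc["g", "percentUnique"] == pytest.approx(100 * 2 / 7)
    assert not rep.table.loc["g", "nzv"]


def test_nzv_boundaries_are_strict():
    # ratio exactly 19 (95:5) -> NOT flagged
    at_ratio = pd.Series([0.0] * 95 + [1.0] * 5)
    # ratio 24 (96:4), percentUnique 2 -> flagged
    above = pd.Series([0.0] * 96 + [1.0] * 4)
    # percentUnique exactly 10 (10 distinct / 100 rows) -> NOT flagged
    at_unique = pd.Series([0.0] * 91 + list(range(1, 10)), dtype=float)
    df = pd.DataFrame({"at_ratio": at_ratio, "above": above,
                       "at_unique": at_unique})
    rep = nzv_report(df).table
    assert rep.loc["at_ratio", "freqRatio"] == pytest.approx(19.0)
    assert not rep.loc["at_ratio", "nzv"]
    assert rep.loc["above", "nzv"]
    assert rep.loc["at_unique", "percentUnique"] == pytest.approx(10.0)
    assert not rep.loc["at_unique", "nzv"]


def _brute_force_nzv(col, freq_cut=19.0, unique_cut=10.0):
    values = [v for v in col if not (isinstance(v, float) and math.isnan(v))]
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    ordered = sorted(counts.values(), reverse=True)
    freq_ratio = math.inf if len(ordered) < 2 else ordered[0] / ordered[1]
    pct_unique = 100 * len(ordered) / len(values)
    zero_var = len(ordered) <= 1
    return zero_var or (freq_ratio > freq_cut and pct_unique < unique_cut)


def test_nzv_agrees_with_brute_force_on_random_columns():
    rng = np.random.default_rng(42)
    cols = {}
    for i in range(200):
        kind = i % 4
        n = 80
        if kind == 0:
            cols[f"c{i}"] = rng.normal(size=n)
        elif kind == 1:
            cols[f"c{i}"] = rng.integers(0, rng.integers(2, 6), size=n).astype(float)
        elif kind == 2:
            p = rng.uniform(0.01, 0.2)
            cols[f"c{i}"] = (rng.random(n) < p).astype(float)
        else:
            cols[f"c{i}"] = np.full(n, float(rng.integers(0, 3)))
    df = pd.DataFrame(cols)
    rep = nzv_report(df).table
    for c in df.columns:
        assert rep.loc[c, "nzv"] == _brute_force_nzv(df[c].tolist()), c


def test_drop_nzv_removes_exactly_planted_columns():
    rng = np.random.default_rng(1)
    n = 100
    df = pd.DataFrame({
        "ok": rng.normal(size=n),
        "const": np.zeros(n),
        "rare": np.array([0.0] * 96 + [1.0] * 4),
        "balanced": np.array([0.0] * 50 + [1.0] * 50),
    })
    dm = _dm(df)
    rep = nzv_report(dm)
    out = drop_nzv(dm, rep)
    assert set(out.feature_columns) == {"ok", "balanced"}


def test_nzv_matches_caret_reference_implementation(tmp_path):
    """Dual-route check of the variance filter against R's caret::nearZeroVar.

    Flags must agree exactly; freqRatio/percentUnique must agree numerically
    for non-constant columns (for constants, caret's current version prints
    freqRatio 0 where the classic convention is Inf; flags are unaffected).
    """
    import subprocess

    rng = np.random.default_rng(21)
    n = 80
    df = pd.DataFrame({
        "norm": rng.normal(size=n),
        "const": np.ones(n),
        "rare": np.r_[np.zeros(n - 3), np.ones(3)],
        "ratio19": np.r_[np.zeros(76), np.ones(4)],
        "ints": rng.integers(0, 4, n).astype(float),
        "binary": (rng.random(n) < 0.4).astype(float),
    })
    df.to_csv(tmp_path / "in.tsv", sep="\t", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        "suppressMessages(library(caret))\n"
        f"df <- read.delim('{tmp_path}/in.tsv')\n"
        "m <- nearZeroVar(df, saveMetrics=TRUE, freqCut=95/5, uniqueCut=10)\n"
        f"write.table(data.frame(column=rownames(m), m), '{tmp_path}/out.tsv',"
        " sep='\\t', row.names=FALSE, quote=FALSE)\n")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    oracle = pd.read_csv(tmp_path / "out.tsv", sep="\t").set_index("column")
    mine = nzv_report(df).table
    for c in df.columns:
        assert bool(mine.loc[c, "nzv"]) == bool(oracle.loc[c, "nzv"]), c
        assert bool(mine.loc[c, "zeroVar"]) == bool(oracle.loc[c, "zeroVar"]), c
        if not mine.loc[c, "zeroVar"]:
            assert mine.loc[c, "freqRatio"] == pytest.approx(
                oracle.loc[c, "freqRatio"])
            assert mine.loc[c, "percentUnique"] == pytest.approx(
                oracle.loc[c, "percentUnique"])


def test_nzv_invariants():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({f"c{i}": rng.integers(0, 4, 60).astype(float)
                       for i in range(20)})
    rep = nzv_report(df).table
    assert (rep["freqRatio"] >= 1).all()
    assert (rep.loc[rep["zeroVar"], "nzv"]).all()


# ---- correlation filter ----------------------------------------------------

def test_find_correlated_two_columns_tie_drops_first():
    corr = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"],
                        columns=["a", "b"])
    assert find_correlated(corr, cutoff=0.75) == ["a"]


def test_find_correlated_identity_is_empty():
    corr = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
    assert find_correlated(corr) == []


def test_find_correlated_planted_block():
    rng = np.random.default_rng(3)
    base = rng.normal(size=300)
    df = pd.DataFrame(rng.normal(size=(300, 7)),
                      columns=[f"n{i}" for i in range(7)])
    for j in range(3):
        df[f"b{j}"] = base + rng.normal(0, 0.2, size=300)
    corr = df.corr()
    dropped = find_correlated(corr, cutoff=0.75)
    assert sum(c.startswith("b") for c in dropped) == 2
    remaining = [c for c in df.columns if c not in dropped]
    sub = corr.loc[remaining, remaining].to_numpy()
    np.fill_diagonal(sub, 0.0)
    assert np.abs(sub).max() <= 0.75


def test_find_correlated_rejects_bad_input():
    bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"],
                       columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        find_correlated(bad)
    nan = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"],
                       columns=["a", "b"])
    with pytest.raises(ValueError, match="constant"):
        find_correlated(nan)


def test_find_correlated_drops_member_with_higher_mean_correlation():
    # c correlates with both a and b; (a, c) is the strongest pair and c has
    # the larger mean |r|, so c goes first and nothing else exceeds the cutoff
    corr = pd.DataFrame(
        [[1.0, 0.1, 0.9], [0.1, 1.0, 0.8], [0.9, 0.8, 1.0]],
        index=list("abc"), columns=list("abc"))
    assert find_correlated(corr, cutoff=0.75) == ["c"]


# ---- centering / scaling ---------------------------------------------------

def test_center_scale_closed_form():
    dm = _dm(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    out, state = center_scale(dm)
    np.testing.assert_allclose(out.table["x"], [-1.0, 0.0, 1.0])  # sample sd (n-1)
    assert state.center["x"] == pytest.approx(2.0)
    assert state.scale["x"] == pytest.approx(1.0)


def test_center_scale_training_columns_standardized(small_design):
    table = small_design.table.select_dtypes("number").dropna()
    dm = DesignMatrix.from_frame(table, target="log2_intensity")
    out, _ = center_scale(dm)
    feats = out.feature_columns
    assert np.allclose(out.table[feats].mean(), 0.0, atol=1e-8)
    assert np.allclose(out.table[feats].std(ddof=1), 1.0, atol=1e-8)


def test_center_scale_reapplies_stored_transform():
    train = _dm(pd.DataFrame({"x": [0.0, 10.0]}))
    _, state = center_scale(train)
    test = _dm(pd.DataFrame({"x": [5.0, 20.0]}))
    out, _ = center_scale(test, state)
    # transformed with TRAIN mean 5 / sd 7.071, not its own statistics
    np.testing.assert_allclose(out.table["x"],
                               [(5 - 5) / np.sqrt(50), (20 - 5) / np.sqrt(50)])


def test_center_scale_rejects_constant_column():
    dm = _dm(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))
    with pytest.raises(ValueError, match="zero-variance"):
        center_scale(dm)


# ---- complete case ---------------------------------------------------------

def test_drop_incomplete_matches_brute_force():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
    mask = rng.random(df.shape) < 0.1
    df = df.mask(mask)
    dm = _dm(df)
    out, n_dropped = drop_incomplete(dm)
    expected = int(df.notna().all(axis=1).sum())
    assert out.table.shape[0] == expected
    assert n_dropped == 200 - expected


def test_drop_incomplete_identity_and_single_row():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, np.nan]})
    dm = _dm(df)
    out, n = drop_incomplete(dm)
    assert n == 1 and out.table.shape[0] == 1
    clean = _dm(pd.DataFrame({"a": [1.0, 2.0]}))
    out2, n2 = drop_incomplete(clean)
    assert n2 == 0 and out2.table.shape[0] == 2


def test_drop_incomplete_all_rows_removed_is_an_error():
    df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="worst columns"):
        drop_incomplete(_dm(df))


# ---- pipeline / leakage ----------------------------------------------------

def _toy_train_test():
    rng = np.random.default_rng(9)
    n = 120
    df = pd.DataFrame({
        "f1": rng.normal(size=n),
        "f2": rng.normal(size=n),
        "dup": np.nan,
        "const": 1.0,
        "cat": rng.choice(["x", "y"], size=n),
        "log2_intensity": rng.normal(size=n),
    })
    df["dup"] = df["f1"] * 2 + rng.normal(0, 0.01, size=n)  # r ~ 1 with f1
    train = DesignMatrix.from_frame(df.iloc[:80], categorical=["cat"])
    test = DesignMatrix.from_frame(df.iloc[80:].copy(), categorical=["cat"])
    return train, test


def test_preprocessor_removes_planted_columns_and_decorrelates():
    train, _ = _toy_train_test()
    prep = Preprocessor()
    clean = prep.fit_transform(train)
    assert "const" in prep.state.dropped_nzv
    # one of the near-duplicate pair goes, and one of the two complementary
    # (perfectly anti-correlated) dummy columns
    assert len(set(prep.state.dropped_correlated) & {"f1", "dup"}) == 1
    assert len([c for c in prep.state.dropped_correlated
                if c.startswith("cat.")]) == 1
    corr = correlation_matrix(clean).to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert np.abs(corr).max() <= 0.75


def test_preprocessor_transform_never_uses_test_statistics():
    train, test = _toy_train_test()
    prep = Preprocessor()
    prep.fit_transform(train)
    out1 = prep.transform(test)
    corrupted = DesignMatrix(table=test.table.copy(), manifest=dict(test.manifest),
                             categorical=list(test.categorical), target=test.target)
    corrupted.table.loc[:, "f2"] = corrupted.table["f2"] * 100 + 17
    prep2 = Preprocessor()
    prep2.fit_transform(train)
    out2 = prep2.transform(corrupted)
    # the transform itself is unchanged by corrupting test rows
    assert prep.state.center == prep2.state.center
    assert prep.state.scale == prep2.state.scale
    untouched = [c for c in out1.feature_columns if c != "f2"]
    np.testing.assert_allclose(out1.table[untouched], out2.table[untouched])


def test_state_roundtrips_through_json(tmp_path):
    train, _ = _toy_train_test()
    prep = Preprocessor()
    prep.fit_transform(train)
    path = tmp_path / "state.json"
    prep.state.write(path)
    back = PreprocessState.read(path)
    assert back == prep.state
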