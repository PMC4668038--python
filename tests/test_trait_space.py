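"""Gower dissimilarity with missing data, trait selection, NJ trait trees."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import edgegain as eg
from edgegain.trait_space import (TraitMatrix, aggregate_records,
                                  filter_by_completeness, gower_distance,
                                  nj_tree, select_orthogonal_traits,
                                  trait_association_matrix)

from conftest import random_tree


def tm_from(df, kinds=None):
    kinds = kinds or {c: "continuous" for c in df.columns}
    return TraitMatrix(df, kinds)


# --------------------------------------------------------------- completeness
def test_completeness_filter_counts():
    data = {f"t{j}": [float(j) if j < i else np.nan for i in range(10)]
            for j in range(10)}
    tm = tm_from(pd.DataFrame(data, index=[f"s{i}" for i in range(10)]))
    assert tm.n_observed.tolist() == list(range(10))
    kept = filter_by_completeness(tm, 5)
    assert len(kept.species) == 5
    assert filter_by_completeness(tm, 0).species == tm.species
    sp4 = filter_by_completeness(tm, 4)
    assert "s4" in sp4.species and "s3" not in sp4.species
    with pytest.raises(ValueError):
        filter_by_completeness(tm, 11)
    with pytest.raises(ValueError, match="every species"):
        filter_by_completeness(tm_from(pd.DataFrame(
            {"t": [np.nan, np.nan]}, index=["a", "b"])), 1)


# ------------------------------------------------------------ trait selection
def test_select_all_traits_is_identity():
    df = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 4)),
                      index=[f"s{i}" for i in range(20)],
                      columns=list("abcd"))
    tm = tm_from(df)
    assert select_orthogonal_traits(tm, 4).traits == tm.traits
    with pytest.raises(ValueError):
        select_orthogonal_traits(tm, 0)


def test_duplicate_trait_is_eliminated():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(30)
    df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(30)},
                      index=[f"s{i}" for i in range(30)])
    kept = set(select_orthogonal_traits(tm_from(df), 2).traits)
    assert "c" in kept
    assert len(kept & {"a", "b"}) == 1


@pytest.mark.parametrize("seed", [0, 3, 7])
def test_greedy_selection_matches_exhaustive_optimum(seed):
    rng = np.random.default_rng(seed)
    n = 40
    base = rng.standard_normal((n, 3))
    df = pd.DataFrame({
        "a": base[:, 0],
        "b": base[:, 0] * 0.9 + rng.standard_normal(n) * 0.3,
        "c": base[:, 1],
        "d": base[:, 1] * 0.8 + rng.standard_normal(n) * 0.4,
        "e": base[:, 2],
        "f": rng.standard_normal(n),
    }, index=[f"s{i}" for i in range(n)])
    tm = tm_from(df)
    assoc = trait_association_matrix(tm)
    k = 4
    best_score, best_set = np.inf, None
    for sub in combinations(df.columns, k):
        m = assoc.loc[list(sub), list(sub)].values
        score = m[np.triu_indices(k, 1)].mean()
        if score < best_score:
            best_score, best_set = score, set(sub)
    assert set(select_orthogonal_traits(tm, k).traits) == best_set


def test_association_handles_categoricals():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(60)
    cat = np.where(x > 0, "hi", "lo")  # strongly associated with x
    df = pd.DataFrame({"x": x, "g": cat, "h": rng.choice(list("pq"), 60)},
                      index=[f"s{i}" for i in range(60)])
    tm = TraitMatrix(df, {"x": "continuous", "g": "categorical",
                          "h": "categorical"})
    assoc = trait_association_matrix(tm)
    assert assoc.loc["x", "g"] > 0.5
    assert assoc.loc["x", "h"] < assoc.loc["x", "g"]
    assert ((assoc.values >= 0) & (assoc.values <= 1)).all()


# ----------------------------------------------------------------------- gower
def test_gower_identical_rows_are_zero():
    df = pd.DataFrame({"x": [1.0, 1.0, 5.0], "c": ["u", "u", "v"]},
                      index=["a", "b", "d"])
    tm = TraitMatrix(df, {"x": "continuous", "c": "categorical"})
    d = gower_distance(tm)
    assert d["a", "b"] == 0.0


def test_gower_range_normalisation():
    df = pd.DataFrame({"x": [2.0, 7.0, 12.0]}, index=["a", "b", "c"])
    d = gower_distance(tm_from(df))
    assert d["a", "b"] == pytest.approx(0.5, abs=1e-12)
    assert d["a", "c"] == pytest.approx(1.0, abs=1e-12)


def test_gower_mixed_and_pairwise_deletion():
    df = pd.DataFrame({
        "x": [2.0, 7.0, 12.0],
        "c": ["r", "s", "r"],
        "y": [np.nan, 3.0, 1.0],
    }, index=["a", "b", "d"])
    tm = TraitMatrix(df, {"x": "continuous", "c": "categorical",
                          "y": "continuous"})
    d = gower_distance(tm)
    # a-b share x (|2-7|/10=0.5) and c (mismatch=1); y missing in a
    assert d["a", "b"] == pytest.approx((0.5 + 1.0) / 2, abs=1e-12)
    # b-d share all three: 0.5, 1, |3-1|/2=1
    assert d["b", "d"] == pytest.approx((0.5 + 1.0 + 1.0) / 3, abs=1e-12)
    assert d["a", "d"] == pytest.approx((1.0 + 0.0) / 2, abs=1e-12)


def test_gower_no_overlap_fallback_mean():
    df = pd.DataFrame({
        "x": [2.0, 7.0, 12.0, np.nan],
        "c": ["r", "s", "r", None],
    }, index=["a", "b", "d", "e"])
    tm = TraitMatrix(df, {"x": "continuous", "c": "categorical"})
    d = gower_distance(tm)
    computable = [d["a", "b"], d["a", "d"], d["b", "d"]]
    assert d["e", "a"] == pytest.approx(np.mean(computable), abs=1e-12)
    with pytest.raises(ValueError, match="no_overlap_policy"):
        gower_distance(tm, no_overlap_policy="error")


def test_gower_all_pairs_disjoint_is_error():
    df = pd.DataFrame({"x": [1.0, np.nan], "y": [np.nan, 2.0]},
                      index=["a", "b"])
    with pytest.raises(ValueError, match="no species pair"):
        gower_distance(tm_from(df))


def test_gower_zero_range_trait_contributes_zero(caplog):
    import logging
    df = pd.DataFrame({"x": [3.0, 3.0, 3.0], "y": [0.0, 1.0, 2.0]},
                      index=["a", "b", "c"])
    with caplog.at_level(logging.WARNING, logger="edgegain.trait_space"):
        d = gower_distance(tm_from(df))
    assert any("zero range" in r.message for r in caplog.records)
    assert d["a", "c"] == pytest.approx(0.5)  # (0 + 1.0)/2


@pytest.mark.parametrize("seed", [0, 1])
def test_gower_bounds_symmetry(seed, rng):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.standard_normal((25, 5)),
                      index=[f"s{i}" for i in range(25)])
    df = df.mask(rng.random(df.shape) < 0.3)
    d = gower_distance(tm_from(df))
    m = d.data
    assert np.allclose(m, m.T)
    assert np.all(np.diag(m) == 0)
    assert np.all((m >= 0) & (m <= 1))


# --------------------------------------------------------------------------- nj
def test_nj_three_taxon_closed_form():
    d = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                       ids=list("ABC"))
    tree = nj_tree(d)
    assert not tree.rooted
    lengths = {tree.labels[i]: tree.length[i] for i in tree.tip_indices}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


@pytest.mark.parametrize("n, seed", [(4, 13), (8, 14)])
def test_nj_recovers_additive_metric(n, seed):
    source = random_tree(n, seed)
    d = source.patristic_distances()
    recovered = nj_tree(d)
    d2 = recovered.patristic_distances(labels=list(d.index))
    assert np.allclose(d2.values, d.values, atol=1e-9)
    assert recovered.total_branch_length() == pytest.approx(
        source.total_branch_length(), rel=1e-9)


def test_nj_star_metric_gives_equal_tips():
    n = 5
    d = np.full((n, n), 2.0)
    np.fill_diagonal(d, 0.0)
    tree = nj_tree(DistanceMatrix(d, ids=[f"s{i}" for i in range(n)]))
    tip_lengths = tree.length[tree.tip_indices]
    assert np.allclose(tip_lengths, tip_lengths[0])


def test_nj_total_length_invariant_to_input_order():
    source = random_tree(10, 3)
    d = source.patristic_distances()
    perm = list(reversed(d.index))
    t1 = nj_tree(d)
    t2 = nj_tree(d.loc[perm, perm])
    assert t1.total_branch_length() == pytest.approx(
        t2.total_branch_length(), rel=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ids=["a", "b"])
    d = np.array([[0, 1, 1], [1, 0, np.nan], [1, np.nan, 0]])
    with pytest.raises(ValueError, match="NaN"):
        nj_tree(pd.DataFrame(d, index=list("abc"), columns=list("abc")))


# ---------------------------------------------------------------- aggregation
def test_aggregate_mean_and_modal_tiebreak():
    records = pd.DataFrame({
        "species": ["a", "a", "a", "b"],
        "x": [1.0, 2.0, np.nan, 5.0],
        "c": ["v", "u", "u", "w"],
        "d": ["q", "p", None, "p"],  # tie q/p -> first-sorted 'p'
    })
    tm = aggregate_records(records, {"x": "continuous", "c": "categorical",
                                     "d": "categorical"})
    assert tm.data.loc["a", "x"] == pytest.approx(1.5)
    assert tm.data.loc["a", "c"] == "u"
    assert tm.data.loc["a", "d"] == "p"


def test_trait_matrix_tsv_round_trip(tmp_path):
    df = pd.DataFrame({"x": [1.5, np.nan], "c": ["u", None]}, index=["a", "b"])
    tm = TraitMatrix(df, {"x": "continuous", "c": "categorical"})
    path = tmp_path / "traits.tsv"
    tm.write_tsv(path)
    back = TraitMatrix.read_tsv(path)
    assert back.kinds == tm.kinds
    assert back.data.loc["a", "x"] == 1.5
    assert pd.isna(back.data.loc["b", "x"]) and pd.isna(back.data.loc["b", "c"])
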