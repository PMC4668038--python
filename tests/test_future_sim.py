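"""Threat-shift simulation, scenario evaluation and cross-scheme comparison."""

import numpy as np
import pytest
from scipy.stats import norm

import edgegain as eg
from edgegain.future_sim import (ShiftModel, compare_schemes, evaluate_scenario,
                                 paired_gain_test, results_frame,
                                 run_experiment, simulate_threat_shifts)
from edgegain.prioritization import ProtectionScenario

from conftest import assert_gain_ordering, random_threat, random_tree


# ------------------------------------------------------------------- deltas
def test_delta_rounding_half_away_from_zero():
    rng = np.random.default_rng(0)
    assert ShiftModel(delta_mean=-0.5, delta_sd=0.0).draw_deltas(3, rng).tolist() == [-1, -1, -1]
    assert ShiftModel(delta_mean=0.5, delta_sd=0.0).draw_deltas(2, rng).tolist() == [1, 1]
    assert ShiftModel(delta_mean=0.4, delta_sd=0.0).draw_deltas(2, rng).tolist() == [0, 0]


def test_degenerate_shift_moves_one_category_toward_cr():
    threat = eg.ThreatTable({"a": "LC", "b": "VU", "c": "CR", "d": "EN"})
    model = ShiftModel(n_shifted=4, delta_mean=-1.0, delta_sd=0.0)
    shifted = simulate_threat_shifts(threat, [], model, 0)
    assert shifted.category("a") == "NT"
    assert shifted.category("b") == "EN"
    assert shifted.category("c") == "CR"  # clamped at the top
    assert shifted.category("d") == "CR"


def test_no_shifts_is_identity_and_pool_checks():
    threat = eg.ThreatTable({"a": "LC", "b": "VU", "c": "DD"})
    model = ShiftModel(n_shifted=0)
    assert simulate_threat_shifts(threat, [], model, 0).series.equals(threat.series)
    with pytest.raises(ValueError, match="pool"):
        simulate_threat_shifts(threat, ["a"], ShiftModel(n_shifted=2), 0)


def test_protected_and_dd_species_never_shift():
    threat = eg.ThreatTable({"a": "LC", "b": "VU", "c": "DD", "d": "EN"})
    model = ShiftModel(n_shifted=2, delta_mean=-1.0, delta_sd=0.0)
    for seed in range(10):
        shifted = simulate_threat_shifts(threat, ["b"], model, seed)
        assert shifted.category("b") == "VU"
        assert shifted.category("c") == "DD"


def test_worsening_fraction_matches_normal_cdf():
    """P(round(N(-1,1)) <= -1) = P(X < -0.5) = Phi(0.5) ~ 0.6915."""
    rng = np.random.default_rng(123)
    n = 10 ** 5
    deltas = ShiftModel().draw_deltas(n, rng)
    frac = np.mean(deltas <= -1)
    expect = norm.cdf(0.5)
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(frac - expect) < 3 * se


# ---------------------------------------------------------------- evaluation
def test_evaluate_none_scheme_without_shifts_is_baseline(cherry):
    threat = eg.ThreatTable({"A": "CR", "B": "EN"})
    none = ProtectionScenario("NONE", ())
    val = evaluate_scenario(cherry, threat, none, ShiftModel(n_shifted=0), 0)
    assert val == pytest.approx(eg.expected_diversity(cherry, threat))


def test_evaluate_protect_cr_tip_hand_value(cherry):
    threat = eg.ThreatTable({"A": "CR", "B": "EN"})
    scen = ProtectionScenario("MAX", ("A",))
    val = evaluate_scenario(cherry, threat, scen, ShiftModel(n_shifted=0), 0)
    # A -> LC (0.001): edges 0.999 + 0.214 + (1 - 0.001*0.786)
    assert val == pytest.approx(0.999 + 0.214 + (1 - 0.001 * 0.786))


def test_full_protection_without_shifts(small_bundle):
    b = small_bundle
    protected = b.threat.protect(b.threat.threatened_species())
    high = eg.expected_diversity(b.tree, protected)
    low = eg.expected_diversity(b.tree, b.threat)
    assert high > low
    # protecting more species never decreases expected diversity
    some = b.threat.protect(b.threat.threatened_species()[:10])
    assert low <= eg.expected_diversity(b.tree, some) <= high


# ---------------------------------------------------------------- experiment
SCHEMES = ["RANDOM", "ED", "THREAT", "EDGE", "MAX"]


def test_experiment_is_reproducible(small_bundle):
    b = small_bundle
    model = eg.ShiftModel(n_shifted=30)
    kw = dict(n_protected=10, model=model, n_reps=3, base_seed=9)
    r1 = run_experiment(b.tree, b.threat, SCHEMES, **kw)
    r2 = run_experiment(b.tree, b.threat, SCHEMES, **kw)
    assert results_frame(r1).equals(results_frame(r2))
    assert [r.seed for r in r1] == [9, 10, 11]


def test_zero_shift_fixed_sets_zero_variance(small_bundle):
    b = small_bundle
    model = eg.ShiftModel(n_shifted=0)
    res = run_experiment(b.tree, b.threat, ["ED", "EDGE", "MAX"],
                         n_protected=10, model=model, n_reps=4, base_seed=0)
    df = results_frame(res)
    for s in ("ED", "EDGE", "MAX"):
        assert df.loc[df.scheme == s, "gain"].std() == 0
    assert (df.loc[df.scheme == "NONE", "gain"] == 0).all()
    # greedy MAX dominates on its own objective when shifts are off
    means = df.groupby("scheme")["gain"].mean()
    assert means["MAX"] >= means["ED"] - 1e-9
    assert means["MAX"] >= means["EDGE"] - 1e-9
    summary = compare_schemes(res)
    assert summary.degenerate and np.isnan(summary.anova_f)


def test_experiment_mean_gain_ordering(small_bundle):
    b = small_bundle
    model = eg.ShiftModel(n_shifted=40)
    res = run_experiment(b.tree, b.threat, SCHEMES, n_protected=15,
                         model=model, n_reps=100, base_seed=3)
    m = compare_schemes(res).mean
    best_single = "ED" if m["ED"] >= m["THREAT"] else "THREAT"
    assert_gain_ordering(res, ["MAX", "EDGE", best_single, "RANDOM"])
    t, p = paired_gain_test(res, "RANDOM", None)
    assert m["RANDOM"] > 0 and p < 0.01


def test_compare_schemes_anova_matches_hand_formula():
    """Textbook one-way ANOVA sums of squares on a 3x2 gain table."""
    gains = {"A": [1.0, 2.0], "B": [3.0, 5.0], "C": [2.0, 2.0]}
    res = []
    for i in range(2):
        div = {s: gains[s][i] for s in gains}
        div["NONE"] = 0.0
        res.append(eg.ReplicateResult(i, i, div, dict(div)))
    out = compare_schemes(res, max_scheme="B")
    grand = np.mean([g for v in gains.values() for g in v])
    ss_between = sum(2 * (np.mean(v) - grand) ** 2 for v in gains.values())
    ss_within = sum((g - np.mean(v)) ** 2 for v in gains.values() for g in v)
    f_hand = (ss_between / 2) / (ss_within / 3)
    assert out.anova_f == pytest.approx(f_hand, rel=1e-12)
    assert out.fraction_of_max["B"] == pytest.approx(1.0)
    assert out.fraction_of_max["A"] == pytest.approx(1.5 / 4.0)
    assert out.pairwise_mean_diff["A-B"] == pytest.approx(-2.5)


def test_td_pipeline_is_pd_machinery_on_trait_tree(small_bundle):
    """The trait-diversity arm shares the PD code path: an NJ trait tree plus
    phylogeny-derived scores must run through the same experiment engine."""
    from edgegain.trait_space import gower_distance, nj_tree
    b = small_bundle
    dm = gower_distance(b.traits)
    ttree = nj_tree(dm)
    assert not ttree.rooted
    scores = eg.species_scores(b.tree, b.threat)
    model = eg.ShiftModel(n_shifted=20)
    res = run_experiment(ttree, b.threat, ["RANDOM", "THREAT", "EDGE"],
                         n_protected=10, model=model, n_reps=5, base_seed=2,
                         scores=scores)
    df = results_frame(res)
    assert np.isfinite(df["gain"]).all()
    # expected TD of the baseline equals persistence-weighted NJ tree length
    baseline = eg.expected_diversity(ttree, b.threat)
    wtree = eg.persistence_weighted_tree(ttree, b.threat)
    assert baseline == pytest.approx(wtree.total_branch_length(), rel=1e-12)


def test_compare_schemes_needs_replication():
    one = [eg.ReplicateResult(0, 0, {"A": 1.0, "NONE": 0.0},
                              {"A": 1.0, "NONE": 0.0})]
    with pytest.raises(ValueError):
        compare_schemes(one)
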