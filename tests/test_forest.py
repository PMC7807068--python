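"""Random survival forest: split statistic, CHF, concordance, MD, VIMP,
nested error curves — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glrisk.cohort import ConfigurationError
from glrisk.forest import (
    ForestConfig,
    NestedModelCurve,
    SurvivalForest,
    _Tree,
    drop_error_rates,
    grow_forest,
    harrell_cindex,
    logrank_split_statistic,
    nelson_aalen_on_grid,
    nested_error_curve,
)
from conftest import make_cohort


# ----------------------------------------------------------------------
# Log-rank split statistic
# ----------------------------------------------------------------------

def test_logrank_zero_for_identical_groups():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    e = np.array([1, 1, 0, 1, 1, 0])
    g = np.array([True, True, True, False, False, False])
    assert logrank_split_statistic(t, e, g) == pytest.approx(0.0, abs=1e-12)


def test_logrank_matches_hand_computed_tables():
    """(1,2,3,4), all events, groups (A,A,B,B): the 2x2 tables give
    numerator 7/6 and variance 17/36, so |Z| = 7/sqrt(17)."""
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4, dtype=int)
    g = np.array([True, True, False, False])
    assert logrank_split_statistic(t, e, g) == pytest.approx(
        7 / np.sqrt(17), abs=1e-10
    )


def _brute_force_logrank(t, e, g):
    num = var = 0.0
    for td in np.unique(t[e == 1]):
        at = t >= td
        Y, Y1 = at.sum(), (at & g).sum()
        d = ((t == td) & (e == 1)).sum()
        d1 = ((t == td) & (e == 1) & g).sum()
        num += d1 - d * Y1 / Y
        if Y > 1:
            var += d * (Y1 / Y) * (1 - Y1 / Y) * (Y - d) / (Y - 1)
    return abs(num) / np.sqrt(var) if var > 0 else 0.0


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_logrank_matches_brute_force_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    t = np.round(rng.exponential(5, n), 1)  # rounding forces ties
    e = rng.integers(0, 2, n)
    g = rng.integers(0, 2, n).astype(bool)
    if e.sum() == 0 or g.all() or not g.any():
        return
    assert logrank_split_statistic(t, e, g) == pytest.approx(
        _brute_force_logrank(t, e, g), abs=1e-10
    )


def test_split_search_equals_exhaustive_scan():
    """The chosen (variable, cut point) maximizes the log-rank statistic
    over every admissible split on a 10-subject fixture."""
    rng = np.random.default_rng(3)
    n, p = 10, 3
    X = rng.normal(size=(n, p))
    t = np.sort(rng.exponential(5, n))
    e = np.ones(n, dtype=int)
    cfg = ForestConfig(n_trees=1, mtry=p, nsplit=100, min_events=1, seed=0)
    forest = SurvivalForest(cfg)
    forest.var_names_ = [f"x{j}" for j in range(p)]
    got = forest._best_split(X, t, e, np.arange(n), p, np.random.default_rng(0))
    assert got is not None
    best_stat, best = -1.0, None
    for j in range(p):
        for thr in np.unique(X[:, j])[:-1]:
            g = X[:, j] <= thr
            if e[g].sum() < 1 or e[~g].sum() < 1:
                continue
            s = logrank_split_statistic(t, e, g)
            if s > best_stat:
                best_stat, best = s, (j, thr)
    var, thr = got
    assert logrank_split_statistic(t, e, X[:, var] <= thr) == pytest.approx(
        best_stat, abs=1e-10
    )


# ----------------------------------------------------------------------
# Nelson-Aalen / ensemble CHF
# ----------------------------------------------------------------------

def test_nelson_aalen_closed_form_five_subjects():
    """Times (1,2,3,4,5), events (1,1,0,1,0):
    H(t) jumps 1/5 at t=1, 1/4 at t=2, 1/2 at t=4."""
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([1, 1, 0, 1, 0])
    grid = np.array([1.0, 2.0, 4.0])
    chf = nelson_aalen_on_grid(t, e, grid)
    np.testing.assert_allclose(
        chf, [1 / 5, 1 / 5 + 1 / 4, 1 / 5 + 1 / 4 + 1 / 2], atol=1e-12
    )


def _single_leaf_forest(time, event):
    """One tree, one node, in-bag = the full sample (no bootstrap)."""
    cfg = ForestConfig(n_trees=1, seed=0)
    f = SurvivalForest(cfg)
    n = len(time)
    f.var_names_ = ["x0"]
    f._X = np.zeros((n, 1))
    f._time = np.asarray(time, dtype=float)
    f._event = np.asarray(event, dtype=np.int8)
    f.grid_ = np.unique(f._time[f._event == 1])
    tree = _Tree()
    node = tree.new_node(0)
    tree.leaf_id[node] = 0
    tree.finalize()
    tree.leaf_chf = nelson_aalen_on_grid(f._time, f._event, f.grid_)[None, :]
    tree.inbag = np.arange(n)
    tree.oob = np.arange(0)
    tree.first_split_depth = np.full(1, -1, dtype=np.int32)
    f.trees_ = [tree]
    return f


def test_single_node_tree_chf_is_sample_nelson_aalen():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([1, 1, 0, 1, 0])
    f = _single_leaf_forest(t, e)
    grid, chf = f.ensemble_chf(np.zeros((2, 1)))
    np.testing.assert_allclose(chf[0], nelson_aalen_on_grid(t, e, grid), atol=1e-15)
    grid, inc = f.predicted_incidence(np.zeros((1, 1)))
    assert np.all((0 <= inc) & (inc <= 1))
    assert np.all(np.diff(inc[0]) >= 0)


def test_zero_event_sample_has_zero_chf():
    chf = nelson_aalen_on_grid(
        np.array([1.0, 2.0]), np.array([0, 0]), np.array([1.0, 2.0])
    )
    np.testing.assert_array_equal(chf, 0.0)


# ----------------------------------------------------------------------
# Concordance
# ----------------------------------------------------------------------

def test_cindex_perfect_and_reversed_ordering():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4, dtype=int)
    risk = np.array([4.0, 3.0, 2.0, 1.0])  # earliest failure = highest risk
    assert harrell_cindex(t, e, risk) == 1.0
    assert harrell_cindex(t, e, -risk) == 0.0


def _brute_force_cindex(t, e, r):
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i fails first: needs event at i and (t_i < t_j, or censored tie)
            if e[i] and (t[i] < t[j] or (t[i] == t[j] and not e[j])):
                den += 1
                if r[i] > r[j]:
                    num += 1
                elif r[i] == r[j]:
                    num += 0.5
    return num / den


def test_cindex_matches_pairwise_brute_force():
    rng = np.random.default_rng(8)
    t = np.round(rng.exponential(5, 8), 0) + 1
    e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
    r = np.round(rng.normal(size=8), 1)  # rounded: some tied scores
    assert harrell_cindex(t, e, r) == pytest.approx(
        _brute_force_cindex(t, e, r), abs=1e-12
    )
    # agreement with lifelines' implementation as a second, independent route
    from lifelines.utils import concordance_index

    assert harrell_cindex(t, e, r) == pytest.approx(
        concordance_index(t, -r, e), abs=1e-12
    )


# ----------------------------------------------------------------------
# Bootstrap structure
# ----------------------------------------------------------------------

def test_bootstrap_inbag_and_oob_fractions():
    cohort = make_cohort(n=2000, n_snps=5, seed=5)
    f = grow_forest(cohort, ForestConfig(n_trees=50, seed=9))
    distinct = np.array([len(np.unique(tr.inbag)) for tr in f.trees_]) / cohort.n
    oob = np.array([len(tr.oob) for tr in f.trees_]) / cohort.n
    assert distinct.mean() == pytest.approx(1 - np.exp(-1), abs=0.01)
    assert oob.mean() == pytest.approx(np.exp(-1), abs=0.01)
    for tr in f.trees_:
        assert len(np.unique(tr.inbag)) + len(tr.oob) == cohort.n


def test_strong_variable_wins_root_split():
    """One strongly predictive binary variable among 20 noise variables is
    the root split in a majority of trees."""
    rng = np.random.default_rng(12)
    n = 1500
    x = rng.integers(0, 2, n).astype(float)
    noise = rng.normal(size=(n, 20))
    lam = 0.08 * np.exp(1.5 * x)
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 15, n)
    X = np.c_[x, noise]
    # all variables are candidates at every node so the root choice is a
    # pure contest of split statistics
    f = SurvivalForest(ForestConfig(n_trees=60, seed=14, mtry=21))
    f.fit(X, np.minimum(t, c), (t <= c).astype(int))
    root_vars = [tr.feature[0] for tr in f.trees_]
    assert np.mean(np.array(root_vars) == 0) > 0.5


# ----------------------------------------------------------------------
# Minimal depth
# ----------------------------------------------------------------------

def _hand_tree(first_depths, max_depth):
    tree = _Tree()
    tree.new_node(0)
    tree.leaf_id[0] = 0
    tree.finalize()
    tree.first_split_depth = np.asarray(first_depths, dtype=np.int32)
    tree.max_depth = max_depth
    tree.leaf_chf = np.zeros((1, 1))
    tree.inbag = np.arange(1)
    tree.oob = np.arange(0)
    return tree


def test_minimal_depth_hand_built_trees():
    """Two hand-built trees: tree 1 splits x0 at the root and x1 at depth 2
    (max depth 3); tree 2 uses only x1 at depth 1 (max depth 3), so x0
    contributes 3+1=4 there.  MD must equal the hand averages."""
    f = SurvivalForest(ForestConfig(n_trees=2, seed=0))
    f.var_names_ = ["x0", "x1"]
    f.trees_ = [
        _hand_tree([0, 2], max_depth=3),
        _hand_tree([-1, 1], max_depth=3),
    ]
    md = f.minimal_depth()
    assert md["x0"] == pytest.approx((0 + 4) / 2)
    assert md["x1"] == pytest.approx((2 + 1) / 2)


# ----------------------------------------------------------------------
# Permutation VIMP
# ----------------------------------------------------------------------

def test_constant_column_has_exactly_zero_vimp():
    cohort = make_cohort(n=300, seed=20)
    cov = cohort.covariates.copy()
    cov["flat"] = 1.0
    cohort = make_cohort(n=300, seed=20, covariates=cov)
    f = grow_forest(cohort, ForestConfig(n_trees=30, seed=21))
    vimp = f.permutation_vimp(n_reps=2)
    assert vimp["flat"] == 0.0


def test_planted_variable_has_positive_vimp_noise_near_zero():
    rng = np.random.default_rng(30)
    n = 1200
    x = rng.integers(0, 2, n).astype(float)
    noise = rng.normal(size=(n, 5))
    lam = 0.05 * np.exp(1.2 * x)
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 15, n)
    f = SurvivalForest(ForestConfig(n_trees=80, seed=31))
    f.fit(np.c_[x, noise], np.minimum(t, c), (t <= c).astype(int),
          ["signal"] + [f"n{i}" for i in range(5)])
    vimp = f.permutation_vimp(n_reps=3)
    assert vimp["signal"] > 0
    assert vimp["signal"] > vimp.drop("signal").max()


# ----------------------------------------------------------------------
# Nested error curves and drop errors
# ----------------------------------------------------------------------

def test_nested_curve_null_error_is_half_and_telescopes():
    cohort = make_cohort(n=400, n_snps=3, seed=40, event_rate=0.5)
    curve = nested_error_curve(
        cohort, cohort.snps, ForestConfig(n_trees=25, seed=41)
    )
    assert curve.errors[0] == 0.5
    assert np.all((curve.errors >= 0) & (curve.errors <= 1))
    d = drop_error_rates(curve)
    np.testing.assert_allclose(0.5 - curve.errors[1:], np.cumsum(d), atol=1e-12)


def test_duplicated_variable_adds_no_information():
    rng = np.random.default_rng(50)
    n = 1500
    x = rng.integers(0, 3, n).astype(float)
    lam = 0.05 * np.exp(0.8 * (x >= 1))
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 15, n)
    geno = pd.DataFrame({"rs_a": x, "rs_dup": x})
    from glrisk.cohort import Cohort

    cohort = Cohort(
        subject_ids=np.array([f"S{i}" for i in range(n)]),
        genotypes=geno,
        covariates=pd.DataFrame(index=range(n)),
        time_years=np.minimum(t, c),
        event=(t <= c).astype(int),
    )
    curve = nested_error_curve(
        cohort, ["rs_a", "rs_dup"], ForestConfig(n_trees=60, seed=51)
    )
    d = drop_error_rates(curve)
    assert d[0] > 0.02  # the real variable reduces error
    assert abs(d[1]) < 0.02  # its duplicate adds nothing


def test_drop_errors_of_constant_sequence_are_zero():
    curve = NestedModelCurve(["a", "b", "c"], [0.5, 0.4, 0.4, 0.4])
    np.testing.assert_allclose(drop_error_rates(curve), [0.1, 0.0, 0.0])


def test_empty_ordering_rejected():
    cohort = make_cohort()
    with pytest.raises(ConfigurationError):
        nested_error_curve(cohort, [], ForestConfig(n_trees=5, seed=0))
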