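"""Sparse selection stack: combinations, lasso solver, stability, likelihood."""

import numpy as np
import pytest

from mciconv import (
    enumerate_combinations,
    generate_cohort,
    lasso_fit,
    select_top_features,
    selection_likelihood,
    stability_select,
)
from mciconv.selection import (
    StabilityConfig,
    lambda_max,
    select_features_all_combinations,
    stability_scores,
)
from mciconv.synthetic import SynthConfig
from tests.conftest import desk_stability


# ---------------------------------------------------------------------------
# Combinations


def test_five_categories_give_31_combinations():
    plan = enumerate_combinations(("CT", "CV", "CS", "NL", "ND"))
    assert len(plan) == 31
    assert len(set(plan.combinations)) == 31
    # each category appears in exactly 2^4 = 16 subsets
    for cat in ("CT", "CV", "CS", "NL", "ND"):
        assert sum(cat in c for c in plan.combinations) == 16


@pytest.mark.parametrize("cats, expected", [(("CT",), 1), (("CT", "NL", "ND"), 7)])
def test_smaller_category_sets(cats, expected):
    plan = enumerate_combinations(cats)
    assert len(plan) == expected
    # exhaustive check for the 3-set: all non-empty subsets
    if expected == 7:
        assert set(plan.combinations) == {
            ("CT",), ("NL",), ("ND",), ("CT", "NL"), ("CT", "ND"),
            ("NL", "ND"), ("CT", "NL", "ND"),
        }


def test_combination_order_deterministic_by_size_then_lex():
    plan = enumerate_combinations()
    sizes = [len(c) for c in plan.combinations]
    assert sizes == sorted(sizes)
    assert plan.combinations[0] == ("CT",)
    assert plan.combinations[-1] == ("CT", "CV", "CS", "NL", "ND")
    with pytest.raises(ValueError):
        enumerate_combinations(())
    with pytest.raises(ValueError):
        enumerate_combinations(("CT", "XX"))


# ---------------------------------------------------------------------------
# Lasso solver


def test_lambda_at_least_lambda_max_gives_zero():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((30, 8))
    y = rng.standard_normal(30)
    lmax = lambda_max(X, y)
    assert np.all(lasso_fit(X, y, lmax) == 0)
    assert np.all(lasso_fit(X, y, 2 * lmax) == 0)
    assert np.any(lasso_fit(X, y, 0.5 * lmax) != 0)


def test_zero_penalty_orthonormal_is_projection():
    rng = np.random.default_rng(1)
    Q, _ = np.linalg.qr(rng.standard_normal((20, 5)))
    y = rng.standard_normal(20)
    np.testing.assert_allclose(lasso_fit(Q, y, 0.0), Q.T @ y, atol=1e-8)


def test_univariate_soft_threshold_closed_form():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(50)
    x = (x - x.mean()) / x.std()
    y = 0.7 * x + 0.1 * rng.standard_normal(50)
    lam = 1.0
    w = lasso_fit(x[:, None], y, lam)[0]
    ols = (x @ y) / (x @ x)
    expect = np.sign(ols) * max(abs(ols) - lam / (x @ x), 0.0) * 1.0
    assert w == pytest.approx(expect, abs=1e-8)


def test_lasso_matches_bruteforce_grid_on_two_features():
    """Objective value at the CD solution beats an exhaustive 2-D grid."""
    rng = np.random.default_rng(3)
    for trial in range(5):
        X = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        lam = 0.3 * lambda_max(X, y)
        w = lasso_fit(X, y, lam)

        def obj(v):
            return 0.5 * np.sum((X @ v - y) ** 2) + lam * np.sum(np.abs(v))

        grid = np.linspace(-2, 2, 401)
        best = min(obj(np.array([a, b])) for a in grid for b in grid)
        assert obj(w) <= best + 1e-4


def test_support_monotone_along_path():
    """Larger penalties never yield more nonzeros along a fitted path."""
    from mciconv.selection import _cd_lasso_path

    rng = np.random.default_rng(4)
    X = np.asfortranarray(rng.standard_normal((40, 15)))
    y = rng.standard_normal(40)
    grid = lambda_max(X, y) * np.geomspace(1.0, 0.01, 25)
    coefs = _cd_lasso_path(X, y, grid, 1e-8, 10_000)
    nnz = (np.abs(coefs) > 1e-8).sum(axis=1)
    # allow occasional drops (lasso paths are not strictly monotone) but the
    # trend from lambda_max (0 active) to small lambda must be non-decreasing
    assert nnz[0] == 0
    assert nnz[-1] >= nnz[0]
    assert np.all(np.diff(nnz) >= -1)


def test_lasso_agrees_with_sklearn():
    from sklearn.linear_model import Lasso

    rng = np.random.default_rng(5)
    X = rng.standard_normal((40, 12))
    y = rng.standard_normal(40)
    for ratio in (0.5, 0.1, 0.02):
        lam = ratio * lambda_max(X, y)
        w = lasso_fit(X, y, lam)
        sk = Lasso(alpha=lam / 40, fit_intercept=False, tol=1e-12, max_iter=10**6)
        sk.fit(X, y)
        np.testing.assert_allclose(w, sk.coef_, atol=1e-6)


def test_lasso_input_validation():
    X = np.ones((4, 2))
    with pytest.raises(ValueError, match="finite"):
        lasso_fit(np.array([[np.nan, 1.0]]), np.array([1.0]), 1.0)
    with pytest.raises(ValueError, match="non-negative"):
        lasso_fit(X, np.ones(4), -1.0)


# ---------------------------------------------------------------------------
# Stability selection


def _signal_problem(n=60, m=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    X[:, 3] = y + 0.3 * rng.standard_normal(n)  # one informative column
    return X, y


def test_signal_column_ranked_first():
    X, y = _signal_problem()
    cfg = StabilityConfig(n_subsamples=100, top_k_per_combination=3)
    top = stability_select(X, y, cfg, seed=0)
    assert top[0] == 3
    rng = np.random.default_rng(0)
    scores = stability_scores(X, y, cfg, rng)
    assert scores[3] == pytest.approx(1.0)


def test_top_k_saturation_returns_all():
    X, y = _signal_problem(m=6)
    cfg = StabilityConfig(n_subsamples=10, top_k_per_combination=6)
    assert sorted(stability_select(X, y, cfg, seed=0)) == list(range(6))


def test_duplicated_signal_columns():
    """Exactly duplicated predictors: cyclic coordinate descent assigns the
    shared signal deterministically to the lower column index, which then
    dominates the ranking; the duplicate still outscores its own noise
    baseline only at the unstable small-lambda end."""
    X, y = _signal_problem()
    X[:, 7] = X[:, 3]  # exact duplicate of the signal column
    cfg = StabilityConfig(n_subsamples=50, top_k_per_combination=2)
    top = stability_select(X, y, cfg, seed=1)
    rng = np.random.default_rng(1)
    scores = stability_scores(X, y, cfg, rng)
    assert scores[3] == pytest.approx(1.0)
    assert scores[3] > scores[7]
    assert top[0] == 3


def test_equal_scores_order_by_lower_index():
    """When stability scores tie exactly, ranking falls back to column index."""
    rng = np.random.default_rng(9)
    X = rng.standard_normal((40, 5))
    y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
    cfg = StabilityConfig(n_subsamples=5, n_lambdas=2, lambda_min_ratio=0.9,
                          top_k_per_combination=5)
    rng2 = np.random.default_rng(3)
    scores = stability_scores(X, y, cfg, rng2)
    order = stability_select(X, y, cfg, seed=3)
    for a, b in zip(order, order[1:]):
        assert (scores[a], a) >= (scores[b], a) and (
            scores[a] > scores[b] or a < b
        )


def test_stability_deterministic_given_seed():
    X, y = _signal_problem(seed=2)
    cfg = StabilityConfig(n_subsamples=20, top_k_per_combination=5)
    assert stability_select(X, y, cfg, seed=5) == stability_select(X, y, cfg, seed=5)


def test_single_class_subsamples_skipped():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((10, 4))
    y = np.r_[np.ones(9), -np.ones(1)]  # most subsamples all-positive
    cfg = StabilityConfig(n_subsamples=30, subsample_fraction=0.5, top_k_per_combination=2)
    top = stability_select(X, y, cfg, seed=0)  # must not crash
    assert len(top) == 2


# ---------------------------------------------------------------------------
# Selection likelihood


def _fake_plan_and_names():
    plan = enumerate_combinations()
    names = [f"CT:IPC_L", "CV:IPC_L", "ND:MTG_L"]
    return plan, names


def test_likelihood_counts_combinations():
    plan, names = _fake_plan_and_names()
    # CT:IPC_L selected in every CT-containing combination (16), CV in 1, ND in 0
    per_combo = []
    ct_count = 0
    for combo in plan.combinations:
        sel = []
        if "CT" in combo:
            sel.append("CT:IPC_L")
            ct_count += 1
        if combo == ("CV",):
            sel.append("CV:IPC_L")
        per_combo.append(sel)
    like = selection_likelihood(plan, per_combo, names)
    assert ct_count == 16
    assert like.as_dict()["CT:IPC_L"] == pytest.approx(16 / 31)
    assert like.as_dict()["CV:IPC_L"] == pytest.approx(1 / 31)
    assert like.as_dict()["ND:MTG_L"] == 0.0


def test_likelihood_17_of_31():
    plan, names = _fake_plan_and_names()
    picks = 0
    per_combo = []
    for combo in plan.combinations:
        if "ND" in combo and picks < 17:
            per_combo.append(["ND:MTG_L"])
            picks += 1
        else:
            per_combo.append([])
    # only 16 ND-combinations exist, so emulate 17/31 with a CT feature
    per_combo = []
    picks = 0
    for combo in plan.combinations:
        if ("CT" in combo or "CV" in combo) and picks < 17:
            name = "CT:IPC_L" if "CT" in combo else "CV:IPC_L"
            per_combo.append([name])
            picks += 1
        else:
            per_combo.append([])
    like = selection_likelihood(plan, per_combo, names)
    total = like.indicator.sum()
    assert total == 17
    combined = like.as_dict()["CT:IPC_L"] + like.as_dict()["CV:IPC_L"]
    assert combined == pytest.approx(17 / 31, abs=1e-12)


def test_structural_zero_and_ceiling():
    """A feature can never be selected in a combination lacking its category,
    so the maximum attainable likelihood with five categories is 16/31."""
    plan, names = _fake_plan_and_names()
    with pytest.raises(ValueError, match="lacks category"):
        selection_likelihood(
            plan, [["ND:MTG_L"]] + [[] for _ in range(30)], names
        )  # first combination is ("CT",)
    per_combo = [["CT:IPC_L"] if "CT" in c else [] for c in plan.combinations]
    like = selection_likelihood(plan, per_combo, names)
    assert like.likelihood.max() == pytest.approx(16 / 31)


def test_select_top_features_ordering_and_errors():
    plan, names = _fake_plan_and_names()
    per_combo = []
    for combo in plan.combinations:
        sel = []
        if "CV" in combo:
            sel.append("CV:IPC_L")
        if "CT" in combo and len(sel) == 0:
            sel.append("CT:IPC_L")
        per_combo.append(sel)
    like = selection_likelihood(plan, per_combo, names)
    top = select_top_features(like, 2)
    assert top[0] == "CV:IPC_L"  # 16 combos vs 8 CT-only combos
    with pytest.raises(ValueError, match="positive"):
        select_top_features(like, 0)
    with pytest.raises(ValueError, match="exceeds"):
        select_top_features(like, 4)
    assert select_top_features(like, 1) == ["CV:IPC_L"]


# ---------------------------------------------------------------------------
# End-to-end selection on a synthetic cohort (single training set)


def test_full_stack_recovers_effect_columns():
    from mciconv import assemble_features, network_features

    cohort, truth = generate_cohort(
        SynthConfig(n_mcinc=40, n_mcic=40, effect_size_ct=0.5, seed=21)
    )
    fm = assemble_features(cohort, network_features(cohort))
    like = select_features_all_combinations(fm, desk_stability(), seed=21)
    top10 = select_top_features(like, 10)
    assert len(set(top10) & truth.effect_columns) >= 5
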