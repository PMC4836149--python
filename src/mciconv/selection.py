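"""Combination-iterated sparse feature selection with stability selection.

The selector never commits to one feature-category combination.  All 2^5 - 1
= 31 non-empty subsets of {CT, CV, CS, NL, ND} are enumerated; within each
combination an L1-penalized linear regression (lasso) of the +/-1 diagnostic
labels on the standardized features,

    min_w  1/2 ||X w - y||_2^2 + lambda ||w||_1,

is fitted repeatedly on random subsamples of the training subjects
(stability selection).  A feature's stability score in a combination is its
maximum selection frequency over the lambda grid; the top-K (K = 10) features
per combination are recorded, and the *selection likelihood* of feature l is
the fraction of combinations whose top-K contains l.  The final feature set
is the K features of highest likelihood.

The lasso path is solved by cyclic coordinate descent with warm starts along
a descending lambda grid (numba-compiled: this is the pipeline's hot loop —
it runs once per combination per subsample per outer CV fold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as _itercombs

import numpy as np
from numba import njit

from .data import ALL_CATEGORIES, FeatureMatrix, parse_column_name

__all__ = [
    "CombinationPlan",
    "StabilityConfig",
    "SelectionLikelihood",
    "enumerate_combinations",
    "lasso_fit",
    "lambda_max",
    "stability_select",
    "selection_likelihood",
    "select_top_features",
    "select_features_all_combinations",
]

logger = logging.getLogger(__name__)

_SUPPORT_TOL = 1e-8


# ---------------------------------------------------------------------------
# Combinations


@dataclass(frozen=True)
class CombinationPlan:
    """All non-empty feature-category subsets, in (size, lexicographic) order."""

    combinations: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.combinations)


def enumerate_combinations(categories=ALL_CATEGORIES) -> CombinationPlan:
    """Every non-empty subset of the categories: 2^k - 1 combinations.

    Order is deterministic — by subset size, then lexicographically in the
    canonical category order (CT, CV, CS, NL, ND) — so combination indices
    are stable across runs.
    """
    cats = [c for c in ALL_CATEGORIES if c in set(categories)]
    if not cats:
        raise ValueError(f"need at least one category from {ALL_CATEGORIES}")
    if len(set(categories)) != len(cats):
        unknown = set(categories) - set(ALL_CATEGORIES)
        raise ValueError(f"unknown categories {sorted(unknown)}")
    subsets = []
    for size in range(1, len(cats) + 1):
        subsets.extend(_itercombs(cats, size))
    return CombinationPlan(tuple(subsets))


# ---------------------------------------------------------------------------
# Lasso via cyclic coordinate descent


@njit(cache=True, fastmath=True)
def _cd_sweep(X, r, w, colsq, lam, n, active_only):  # pragma: no cover - numba
    max_delta = 0.0
    m = w.shape[0]
    for j in range(m):
        wj = w[j]
        if active_only and wj == 0.0:
            continue
        if colsq[j] <= 0.0:
            continue
        col = X[:, j]
        rho = colsq[j] * wj
        for i in range(n):
            rho += col[i] * r[i]
        if rho > lam:
            wn = (rho - lam) / colsq[j]
        elif rho < -lam:
            wn = (rho + lam) / colsq[j]
        else:
            wn = 0.0
        if wn != wj:
            delta = wn - wj
            for i in range(n):
                r[i] -= col[i] * delta
            w[j] = wn
            if abs(delta) > max_delta:
                max_delta = abs(delta)
    return max_delta


@njit(cache=True, fastmath=True)
def _cd_lasso_path(X, y, lambdas, tol, max_sweeps):  # pragma: no cover - numba
    """Coefficients at each lambda of a descending grid, warm-started.

    Minimizes 1/2 ||Xw - y||^2 + lambda ||w||_1 by cyclic coordinate descent
    on the residual, glmnet-style: full sweeps establish the active set, then
    cheap active-set-only sweeps iterate to convergence (largest coefficient
    update below ``tol``).  X must be Fortran-ordered for contiguous column
    access.  Returns (n_lambdas, m) coefficients.
    """
    n, m = X.shape
    w = np.zeros(m)
    r = y.copy()
    colsq = np.zeros(m)
    for j in range(m):
        s = 0.0
        col = X[:, j]
        for i in range(n):
            s += col[i] * col[i]
        colsq[j] = s
    out = np.zeros((lambdas.shape[0], m))
    for li in range(lambdas.shape[0]):
        lam = lambdas[li]
        for _ in range(max_sweeps):
            max_delta = _cd_sweep(X, r, w, colsq, lam, n, False)
            if max_delta < tol:
                break
            for _ in range(max_sweeps):
                if _cd_sweep(X, r, w, colsq, lam, n, True) < tol:
                    break
        out[li] = w
    return out


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the lasso solution is identically zero.

    By the KKT conditions of the objective this is ||X^T y||_inf.
    """
    return float(np.max(np.abs(X.T @ y)))


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Minimize 1/2 ||Xw - y||^2 + lam ||w||_1; returns the coefficient vector."""
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if np.any((X**2).sum(axis=0) == 0) and lam == 0:
        raise ValueError("zero-variance column with lambda = 0 has no unique solution")
    return _cd_lasso_path(X, y, np.array([lam]), tol, max_sweeps)[0]


# ---------------------------------------------------------------------------
# Stability selection


@dataclass
class StabilityConfig:
    """Stability-selection parameters.

    ``n_subsamples`` random subsets of ``subsample_fraction`` of the subjects
    are drawn without replacement (``bootstrap=True`` switches to sampling
    with replacement); each is standardized and the lasso path evaluated on a
    geometric lambda grid of ``n_lambdas`` values from lambda_max down to
    ``lambda_min_ratio * lambda_max`` (recomputed per subsample), unless an
    explicit ``lambda_grid`` is supplied.  ``top_k_per_combination`` features
    are kept per combination.
    """

    n_subsamples: int = 100
    subsample_fraction: float = 0.8
    n_lambdas: int = 30
    lambda_min_ratio: float = 0.05
    lambda_grid: np.ndarray | None = None
    top_k_per_combination: int = 10
    bootstrap: bool = False
    cd_tol: float = 1e-4
    cd_max_sweeps: int = 200

    def __post_init__(self) -> None:
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.top_k_per_combination < 1:
            raise ValueError("top_k_per_combination must be >= 1")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be positive and strictly descending")
            self.lambda_grid = g


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # dead columns stay identically zero
    return (X - mu) / sd


def stability_scores(
    X: np.ndarray,
    y: np.ndarray,
    config: StabilityConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature stability score: max selection frequency over the lambda grid."""
    n, m = X.shape
    size = int(np.floor(config.subsample_fraction * n))
    if size < 2:
        raise ValueError(f"subsample of {size} subjects is too small (n={n})")
    n_lam = (
        len(config.lambda_grid) if config.lambda_grid is not None else config.n_lambdas
    )
    counts = np.zeros((n_lam, m))
    used = 0
    for _ in range(config.n_subsamples):
        rows = (
            rng.integers(0, n, size)
            if config.bootstrap
            else rng.permutation(n)[:size]
        )
        ys = y[rows].astype(np.float64)
        if np.all(ys == ys[0]):
            logger.warning("subsample with a single class skipped")
            continue
        Xs = np.asfortranarray(_zscore(X[rows]))
        if config.lambda_grid is not None:
            grid = config.lambda_grid
        else:
            lmax = lambda_max(Xs, ys)
            if lmax <= 0:
                logger.warning("subsample with zero lambda_max skipped")
                continue
            grid = lmax * np.geomspace(1.0, config.lambda_min_ratio, config.n_lambdas)
        coefs = _cd_lasso_path(
            Xs, ys, np.ascontiguousarray(grid), config.cd_tol, config.cd_max_sweeps
        )
        counts += np.abs(coefs) > _SUPPORT_TOL
        used += 1
    if used == 0:
        raise ValueError("no usable subsamples (all single-class)")
    freq = counts / used
    return freq.max(axis=0)


def stability_select(
    X: np.ndarray,
    y: np.ndarray,
    config: StabilityConfig,
    seed: int | np.random.Generator = 0,
    feature_names: list[str] | None = None,
) -> list[int] | list[str]:
    """Top-K feature indices (or names) for one combination's design matrix.

    Features are ranked by stability score, ties broken toward the lower
    column index; deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    k = min(config.top_k_per_combination, m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = stability_scores(X, y, config, rng)
    order = np.lexsort((np.arange(m), -scores))  # score desc, index asc
    top = [int(j) for j in order[:k]]
    if feature_names is not None:
        return [feature_names[j] for j in top]
    return top


# ---------------------------------------------------------------------------
# Selection likelihood across combinations


@dataclass
class SelectionLikelihood:
    """Per-feature selection frequency across category combinations.

    ``likelihood[l]`` is the number of combinations whose per-combination
    top-K contained feature l, divided by the number of combinations;
    ``indicator`` is the underlying (feature x combination) 0/1 table.
    """

    feature_names: list[str]
    likelihood: np.ndarray
    indicator: np.ndarray
    plan: CombinationPlan

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.likelihood))


def selection_likelihood(
    plan: CombinationPlan,
    per_combination_topk: list[list[str]],
    feature_names: list[str],
) -> SelectionLikelihood:
    """Aggregate per-combination top-K lists into the selection likelihood."""
    if len(per_combination_topk) != len(plan):
        raise ValueError(
            f"{len(per_combination_topk)} top-K lists for {len(plan)} combinations"
        )
    index = {name: j for j, name in enumerate(feature_names)}
    indicator = np.zeros((len(feature_names), len(plan)), dtype=np.int8)
    for ci, (combo, selected) in enumerate(zip(plan.combinations, per_combination_topk)):
        allowed = set(combo)
        for name in selected:
            cat, _ = parse_column_name(name)
            if cat not in allowed:
                raise ValueError(
                    f"feature {name!r} attributed to combination {combo} "
                    f"which lacks category {cat!r}"
                )
            indicator[index[name], ci] = 1
    likelihood = indicator.sum(axis=1) / len(plan)
    return SelectionLikelihood(list(feature_names), likelihood, indicator, plan)


def select_top_features(likelihood: SelectionLikelihood, k: int) -> list[str]:
    """K features of highest selection likelihood (ties to lower column index)."""
    if k <= 0:
        raise ValueError(f"K must be positive, got {k}")
    m = len(likelihood.feature_names)
    if k > m:
        raise ValueError(f"K={k} exceeds the {m} features with defined likelihood")
    order = np.lexsort((np.arange(m), -likelihood.likelihood))
    return [likelihood.feature_names[int(j)] for j in order[:k]]


def select_features_all_combinations(
    features: FeatureMatrix,
    config: StabilityConfig,
    seed: int | np.random.Generator = 0,
    plan: CombinationPlan | None = None,
) -> SelectionLikelihood:
    """Run the full selection stack on one training set.

    Enumerates the combinations of the categories present in ``features``,
    runs stability selection within each combination (on that combination's
    columns only), and aggregates into the selection likelihood.
    """
    if plan is None:
        plan = enumerate_combinations(features.categories)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = features.labels
    per_combo: list[list[str]] = []
    for combo in plan.combinations:
        cols = features.category_columns(combo)
        names = [features.columns[j] for j in cols]
        top = stability_select(
            features.values[:, cols], y, config, seed=rng, feature_names=names
        )
        per_combo.append(top)
    return selection_likelihood(plan, per_combo, features.columns)
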