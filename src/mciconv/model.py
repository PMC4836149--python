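"""Model/results interface for MCI-conversion prediction.

:class:`MCIConversionModel` is built from a :class:`~mciconv.data.Cohort`
(or from feature/label TSVs via :meth:`MCIConversionModel.from_tables`);
``fit()`` runs the full pipeline — per-subject thickness networks, nodal
features, combination-iterated stability selection inside every outer LOOCV
training fold, inner-CV-tuned RBF-SVM — and returns an
:class:`MCIConversionResults` carrying the pooled held-out predictions,
confusion metrics, ROC/AUC, per-fold diagnostics and a ``summary()`` table.

Example
-------
>>> from mciconv import MCIConversionModel, SynthConfig, generate_cohort
>>> cohort, truth = generate_cohort(SynthConfig(n_mcinc=20, n_mcic=20, seed=7))
>>> res = MCIConversionModel(cohort, seed=7).fit()
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    LOOCVResult,
    SVMConfig,
    confusion_metrics,
    loocv_classify,
    loocv_select,
    roc_auc,
)
from .data import ALL_CATEGORIES, Cohort, FeatureMatrix, assemble_features, load_feature_table
from .network import KernelParams, compute_kernel_matrix, network_features, select_cost
from .selection import StabilityConfig

__all__ = ["MCIConversionModel", "MCIConversionResults"]

logger = logging.getLogger(__name__)


class MCIConversionModel:
    """Nested-CV classifier of MCI converters vs non-converters.

    Parameters
    ----------
    cohort:
        Subjects with their 204 morphometric features and +1/-1 labels.
    categories:
        Feature categories to use (subset of CT, CV, CS, NL, ND); all five
        by default, yielding the 340-column design.
    cost:
        Connection cost for network binarization.  The default 0.18 is fixed
        a priori; pass ``cost="auto"`` for leak-free per-fold data-driven
        selection over ``cost_grid`` inside each outer training set.  (A
        single whole-cohort selection, as :func:`mciconv.network.select_cost`
        applied before CV, re-uses every subject and is a leakage path — it
        is available but not the default.)
    kernel_alpha:
        Thickness-similarity kernel width.
    top_k:
        Number of final features handed to the SVM.
    stability, svm:
        Stage configurations; defaults as documented on the config classes.
    seed:
        Master seed; per-stage/per-fold streams are spawned from it.
    """

    def __init__(
        self,
        cohort: Cohort,
        categories=ALL_CATEGORIES,
        cost: float | str = 0.18,
        cost_grid: np.ndarray | None = None,
        kernel_alpha: float = 0.01,
        unreachable: str = "graph-size",
        top_k: int = 10,
        stability: StabilityConfig | None = None,
        svm: SVMConfig | None = None,
        seed: int = 0,
    ) -> None:
        cohort.validate_two_groups()
        self.cohort = cohort
        self.categories = tuple(c for c in ALL_CATEGORIES if c in set(categories))
        if not self.categories:
            raise ValueError(f"categories must be a non-empty subset of {ALL_CATEGORIES}")
        if isinstance(cost, str) and cost != "auto":
            raise ValueError("cost must be a fraction in (0,1) or 'auto'")
        self.cost = cost
        self.cost_grid = cost_grid
        self.kernel = KernelParams(alpha=kernel_alpha)
        self.unreachable = unreachable
        self.top_k = int(top_k)
        self.stability = stability if stability is not None else StabilityConfig()
        self.svm = svm if svm is not None else SVMConfig()
        self.seed = int(seed)
        self._network_cache: dict[float, FeatureMatrix] = {}

    @classmethod
    def from_tables(cls, features_path, labels_path, **kwargs) -> "MCIConversionModel":
        """Build the model from a feature TSV and a label TSV."""
        return cls(load_feature_table(features_path, labels_path), **kwargs)

    # -- feature construction ------------------------------------------------

    def _network_block(self, cost: float) -> FeatureMatrix:
        if cost not in self._network_cache:
            self._network_cache[cost] = network_features(
                self.cohort, cost=cost, params=self.kernel, unreachable=self.unreachable
            )
        return self._network_cache[cost]

    def design_matrix(self, cost: float | None = None) -> FeatureMatrix:
        """Assembled feature matrix at a fixed cost (default: the model's)."""
        if cost is None:
            if self.cost == "auto":
                raise ValueError("cost='auto' has no single design matrix; pass cost=")
            cost = float(self.cost)
        needs_network = any(c in ("NL", "ND") for c in self.categories)
        net = self._network_block(cost) if needs_network else None
        return assemble_features(self.cohort, net, self.categories)

    def _per_fold_costs(self) -> list[float]:
        """Data-driven cost per outer fold, selected on training subjects only."""
        nets = [compute_kernel_matrix(s.ct, self.kernel) for s in self.cohort.subjects]
        y = self.cohort.labels
        n = len(self.cohort)
        costs = []
        for i in range(n):
            train = np.arange(n) != i
            costs.append(
                select_cost(
                    [nets[j] for j in range(n) if train[j]], y[train], self.cost_grid
                )
            )
        return costs

    # -- fitting -------------------------------------------------------------

    def fit(self) -> "MCIConversionResults":
        """Run the nested-CV pipeline and collect results."""
        if self.cost == "auto":
            fold_costs = self._per_fold_costs()
            result = self._fit_per_fold_costs(fold_costs)
            return MCIConversionResults(self, result, fold_costs=fold_costs)
        features = self.design_matrix()
        fold_likelihoods = loocv_select(features, self.stability, seed=self.seed)
        result = loocv_classify(
            features, fold_likelihoods, self.top_k, self.svm, seed=self.seed
        )
        return MCIConversionResults(self, result, features=features)

    def _fit_per_fold_costs(self, fold_costs: list[float]) -> LOOCVResult:
        # Per-fold cost means per-fold design matrices; reuse the fixed-cost
        # machinery one fold at a time via single-subject "LOOCV" slices.
        from .classify import _fold_seeds  # internal seed scheme
        from .selection import select_features_all_combinations, select_top_features
        from .classify import SVMConfig as _SVMConfig, inner_grid_search, _zscore_train_apply
        from .classify import PredictionSet
        from sklearn.svm import SVC

        n = len(self.cohort)
        y = self.cohort.labels
        sel_seeds = _fold_seeds(self.seed, n)
        svm_seeds = _fold_seeds(self.seed ^ 0x5EED, n)
        y_pred = np.empty(n, dtype=int)
        scores = np.empty(n)
        fold_features, fold_hp, fold_likes = [], [], []
        for i in range(n):
            features = self.design_matrix(cost=fold_costs[i])
            train = np.arange(n) != i
            fm = FeatureMatrix(
                features.values[train],
                list(features.columns),
                y[train],
                [sid for j, sid in enumerate(features.subject_ids) if train[j]],
            )
            like = select_features_all_combinations(
                fm, self.stability, seed=np.random.default_rng(sel_seeds[i])
            )
            selected = select_top_features(like, self.top_k)
            cols = [features.columns.index(f) for f in selected]
            X_tr, X_te = _zscore_train_apply(
                features.values[np.ix_(train, cols)],
                features.values[np.ix_(~train, cols)],
            )
            cfg = _SVMConfig(
                C_grid=self.svm.C_grid,
                sigma2_grid=self.svm.sigma2_grid,
                inner_folds=self.svm.inner_folds,
                seed=int(svm_seeds[i].generate_state(1)[0] % (2**31)),
                class_weight=self.svm.class_weight,
            )
            C, sig = inner_grid_search(X_tr, y[train], cfg)
            clf = SVC(C=C, gamma=1.0 / sig**2, class_weight=self.svm.class_weight)
            clf.fit(X_tr, y[train])
            raw = float(clf.decision_function(X_te)[0])
            score = raw if clf.classes_[1] == 1 else -raw
            scores[i], y_pred[i] = score, (1 if score > 0 else -1)
            fold_features.append(selected)
            fold_hp.append((C, sig))
            fold_likes.append(like)
        preds = PredictionSet(list(self.cohort.subject_ids), y, y_pred, scores)
        return LOOCVResult(preds, fold_features, fold_hp, fold_likes)


@dataclass
class MCIConversionResults:
    """Fitted-pipeline results: pooled LOOCV predictions and diagnostics."""

    model: MCIConversionModel
    loocv: LOOCVResult
    features: FeatureMatrix | None = None
    fold_costs: list[float] | None = None
    _sweep_cache: dict[int, tuple[float, float]] = field(default_factory=dict, repr=False)

    # -- headline metrics ----------------------------------------------------

    @property
    def predictions(self) -> pd.DataFrame:
        return self.loocv.predictions.to_frame()

    @property
    def confusion(self):
        return confusion_metrics(self.loocv.predictions)

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity

    @property
    def auc(self) -> float:
        return roc_auc(self.loocv.predictions)[1]

    @property
    def roc_points(self) -> pd.DataFrame:
        pts, _ = roc_auc(self.loocv.predictions)
        return pd.DataFrame(pts, columns=["fpr", "tpr", "threshold"])

    def feature_frequency(self) -> pd.DataFrame:
        """Across-outer-fold frequency (%) of final-top-K membership."""
        freq = self.loocv.feature_fold_frequency()
        return pd.DataFrame(
            {"feature": list(freq), "frequency_pct": list(freq.values())}
        )

    def selection_report(self) -> pd.DataFrame:
        """Per-feature report: combination counts, mean likelihood, fold frequency.

        The combination-based selection likelihood is bounded above by 16/31
        when all five categories are present (each category appears in 16 of
        the 31 subsets), so the fold frequency — not the likelihood — is the
        column comparable to reported per-feature selection percentages.
        """
        names = self.loocv.fold_likelihoods[0].feature_names
        mean_like = np.mean(
            [sl.likelihood for sl in self.loocv.fold_likelihoods], axis=0
        )
        mean_combos = np.mean(
            [sl.indicator.sum(axis=1) for sl in self.loocv.fold_likelihoods], axis=0
        )
        freq = self.loocv.feature_fold_frequency()
        df = pd.DataFrame(
            {
                "feature": names,
                "mean_combinations_selected": mean_combos,
                "mean_selection_likelihood": mean_like,
                "fold_frequency_pct": [freq.get(f, 0.0) for f in names],
            }
        )
        return df.sort_values(
            ["fold_frequency_pct", "mean_selection_likelihood"], ascending=False
        ).reset_index(drop=True)

    # -- sweeps --------------------------------------------------------------

    def sweep_top_k(self, ks=range(1, 31), seed: int | None = None) -> pd.DataFrame:
        """AUC as a function of the number K of final features.

        Reuses the per-fold selection likelihoods (K-independent); only the
        SVM stage is refitted per K.  K beyond the feature count yields NaN.
        """
        if self.fold_costs is not None:
            raise NotImplementedError("top-K sweep requires a fixed connection cost")
        assert self.features is not None
        seed = self.model.seed if seed is None else seed
        rows = []
        m = self.features.n_features
        for k in ks:
            k = int(k)
            if k > m:
                rows.append({"K": k, "auc": float("nan"), "accuracy": float("nan")})
                continue
            if k not in self._sweep_cache:
                if k == self.model.top_k:
                    res = self.loocv
                else:
                    res = loocv_classify(
                        self.features,
                        self.loocv.fold_likelihoods,
                        k,
                        self.model.svm,
                        seed=seed,
                    )
                self._sweep_cache[k] = (
                    roc_auc(res.predictions)[1],
                    confusion_metrics(res.predictions).accuracy,
                )
            auc, acc = self._sweep_cache[k]
            rows.append({"K": k, "auc": auc, "accuracy": acc})
        return pd.DataFrame(rows)

    # -- presentation --------------------------------------------------------

    def metrics_row(self, pair: str | None = None) -> dict:
        c = self.confusion
        return {
            "diagnostic_pair": pair or f"MCInc vs. MCIc_{self.model.cohort.pair_tag}",
            "ACC(%)": round(c.accuracy, 2),
            "SEN(%)": round(c.sensitivity, 2),
            "SPE(%)": round(c.specificity, 2),
            "AUC": round(self.auc, 4),
        }

    def summary(self) -> str:
        """Plain-text results table in the style of a statsmodels summary."""
        c = self.confusion
        k = self.model.cohort.counts()
        cost = (
            "per-fold (auto)" if self.fold_costs is not None else f"{self.model.cost:.2f}"
        )
        lines = [
            "MCI conversion prediction - nested LOOCV results",
            "=" * 56,
            f"Subjects:            {len(self.model.cohort)} "
            f"(MCIc {k['MCIc']} / MCInc {k['MCInc']})",
            f"Diagnostic pair:     MCInc vs. MCIc_{self.model.cohort.pair_tag}",
            f"Feature categories:  {', '.join(self.model.categories)}",
            f"Connection cost:     {cost}   kernel alpha: {self.model.kernel.alpha}",
            f"Final features (K):  {self.model.top_k}",
            "-" * 56,
            f"Accuracy:            {c.accuracy:6.2f} %",
            f"Sensitivity:         {c.sensitivity:6.2f} %   (MCIc positive)",
            f"Specificity:         {c.specificity:6.2f} %",
            f"AUC:                 {self.auc:6.4f}",
            f"Confusion counts:    TP={c.counts.tp} FN={c.counts.fn} "
            f"TN={c.counts.tn} FP={c.counts.fp}",
            "-" * 56,
            "Most frequently selected features (outer-fold %):",
        ]
        for _, row in self.feature_frequency().head(10).iterrows():
            lines.append(f"  {row['feature']:<12s} {row['frequency_pct']:6.1f}")
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        """ROC curve on a matplotlib axis (created on demand)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        pts = self.roc_points
        ax.plot(pts["fpr"], pts["tpr"], label=label or f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax
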