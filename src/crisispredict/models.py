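"""Risk models for next-block crisis prediction, as a sklearn-style estimator.

Three families are supported: plain logistic regression (``lr``), elastic-net
logistic regression (``en``), and random forest (``rf``). Hyperparameters are
chosen by 5-fold cross-validated AUROC with folds grouped by patient, so no
patient's rows appear in two folds; the winning configuration is refit on all
training rows. LR/EN features are standardized inside the fitted pipeline
(train-set mean/sd); the forest sees raw features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

FAMILIES = ("lr", "en", "rf")

DEFAULT_GRIDS = {
    "lr": [{}],
    "en": {
        "clf__l1_ratio": [round(0.1 * k, 1) for k in range(1, 10)],
        "clf__C": [0.01, 0.1, 1.0, 10.0],
    },
    "rf": {
        "n_estimators": [200, 500],
        "max_depth": [3, 5, None],
        "max_features": ["sqrt"],
    },
}


def _safe_auroc(estimator, X, y) -> float:
    """AUROC scorer returning the chance value 0.5 on a single-class fold."""
    if len(np.unique(y)) < 2:
        return 0.5
    return roc_auc_score(y, estimator.predict_proba(X)[:, 1])


class CrisisRiskClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched crisis-risk classifier with patient-grouped CV.

    Parameters
    ----------
    family : {"lr", "en", "rf"}
        Model family: logistic regression, elastic-net logistic regression,
        or random forest.
    cv_folds : int
        Folds for hyperparameter selection (grouped by patient when
        ``groups`` is passed to :meth:`fit`).
    seed : int
        Seeds fold shuffling, the saga solver and the forest; fitting is
        deterministic given the seed.
    param_grid : dict or list of dict, optional
        Overrides the family's default hyperparameter grid.
    class_weight : passed through to the underlying sklearn estimator.

    Attributes
    ----------
    estimator_ : the refit best pipeline/forest.
    best_params_ : chosen hyperparameters.
    cv_auroc_ : mean grouped-CV AUROC of the chosen configuration.
    fold_aurocs_ : per-fold AUROCs of the chosen configuration.
    feature_names_in_ : column order fixed at fit time.
    """

    def __init__(self, family: str = "rf", cv_folds: int = 5, seed: int = 0,
                 param_grid=None, class_weight=None):
        self.family = family
        self.cv_folds = cv_folds
        self.seed = seed
        self.param_grid = param_grid
        self.class_weight = class_weight

    def _base_estimator(self):
        if self.family == "lr":
            return Pipeline([
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=np.inf, solver="lbfgs",
                                           max_iter=2000, class_weight=self.class_weight)),
            ])
        if self.family == "en":
            return Pipeline([
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(solver="saga", l1_ratio=0.5, C=1.0,
                                           max_iter=5000, random_state=self.seed,
                                           class_weight=self.class_weight)),
            ])
        if self.family == "rf":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1,
                                          class_weight=self.class_weight)
        raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")

    def _validate_X(self, X, fit: bool):
        if isinstance(X, pd.DataFrame):
            if fit:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            else:
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise ValueError(f"rows are missing model feature(s): {missing}")
                X = X[list(self.feature_names_in_)]
            arr = X.to_numpy(dtype=float)
            names = list(X.columns)
        else:
            arr = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(arr.shape[1])]
            if fit:
                self.feature_names_in_ = np.asarray(names, dtype=object)
            elif arr.shape[1] != len(self.feature_names_in_):
                raise ValueError(
                    f"expected {len(self.feature_names_in_)} features, got {arr.shape[1]}"
                )
        bad = ~np.isfinite(arr)
        if bad.any():
            col = names[int(np.flatnonzero(bad.any(axis=0))[0])]
            raise ValueError(f"non-finite values in feature column {col!r}")
        return arr

    def fit(self, X, y, groups=None):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        arr = self._validate_X(X, fit=True)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contain a single outcome class; cannot fit")
        self.classes_ = classes
        self.n_features_in_ = arr.shape[1]

        grid = self.param_grid if self.param_grid is not None else DEFAULT_GRIDS[self.family]
        min_class = int(np.bincount(y).min())
        n_splits = self.cv_folds
        if groups is not None:
            groups = np.asarray(groups)
            n_splits = min(n_splits, len(np.unique(groups)))
            if n_splits < 2:
                groups = None  # a single patient cannot be group-split
                n_splits = self.cv_folds
        if groups is None:
            n_splits = min(n_splits, min_class)
        if n_splits < 2:
            raise ValueError(
                "too few patients/events for cross-validated selection "
                f"(would need >= 2 folds, got {n_splits})"
            )
        if n_splits < self.cv_folds:
            logger.info("reducing CV folds from %d to %d to match the data",
                        self.cv_folds, n_splits)
        if groups is not None:
            cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                      random_state=self.seed)
            splits = list(cv.split(arr, y, groups))
        else:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=self.seed)
            splits = list(cv.split(arr, y))
        # folds whose training part lacks a class cannot rank hyperparameters
        usable = [s for s in splits if len(np.unique(y[s[0]])) == 2]
        if len(usable) < len(splits):
            logger.info("dropping %d CV fold(s) with single-class training part",
                        len(splits) - len(usable))
        if not usable:
            raise ValueError("every CV fold had single-class training data")
        splits = usable

        search = GridSearchCV(self._base_estimator(), grid, scoring=_safe_auroc,
                              cv=splits, refit=True, error_score="raise")
        search.fit(arr, y)
        self.estimator_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_auroc_ = float(search.best_score_)
        self.fold_aurocs_ = np.array([
            search.cv_results_[f"split{i}_test_score"][search.best_index_]
            for i in range(len(splits))
        ])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._validate_X(X, fit=False))

    def predict_risk(self, X) -> np.ndarray:
        """Per-row probability of a crisis onset within the next horizon."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_risk(X) >= 0.5).astype(int)

    def variable_importance(self, X=None, y=None, n_permutations: int = 10) -> pd.Series:
        """Per-feature importances, sum-normalized to 1.

        LR/EN: absolute standardized coefficients. RF: permutation importance
        (mean AUROC drop over ``n_permutations`` seeded shuffles of each
        column, computed on the supplied rows; negatives clipped to 0).
        """
        check_is_fitted(self, "estimator_")
        names = pd.Index(self.feature_names_in_)
        if self.family in ("lr", "en"):
            imp = np.abs(self.estimator_["clf"].coef_.ravel())
        else:
            if n_permutations < 1:
                raise ValueError("n_permutations must be >= 1")
            if X is None or y is None:
                raise ValueError("random-forest importance needs evaluation rows (X, y)")
            arr = self._validate_X(X, fit=False)
            res = permutation_importance(self.estimator_, arr, np.asarray(y, int),
                                         scoring=_safe_auroc, n_repeats=n_permutations,
                                         random_state=self.seed)
            imp = np.clip(res.importances_mean, 0.0, None)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        else:  # degenerate model: no feature carries signal
            imp = np.full_like(imp, 1.0 / len(imp))
        return pd.Series(imp, index=names, name="importance")


def fit_model(family: str, X, y, groups=None, seed: int = 0, cv_folds: int = 5,
              param_grid=None, class_weight=None) -> CrisisRiskClassifier:
    """Convenience wrapper: construct and fit a :class:`CrisisRiskClassifier`."""
    model = CrisisRiskClassifier(family=family, cv_folds=cv_folds, seed=seed,
                                 param_grid=param_grid, class_weight=class_weight)
    return model.fit(X, y, groups=groups)


def predict_risk(model: CrisisRiskClassifier, X) -> np.ndarray:
    return model.predict_risk(X)
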