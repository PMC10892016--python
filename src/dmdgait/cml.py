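"""Classical-ML classification of gait features (CML-CF branch).

Six classifiers (RF, DT, SVM, KNN, GNB, LR) operate on the eight
temporospatial gait CFs, optionally after projection to 2 principal
components (PCA) or 1 discriminant coordinate (LDA), and are evaluated
with leave-one-subject-out (LOSO) cross-validation: every fold fits the
scaler, projection, and classifier on the other subjects only and
predicts the held-out subject.

`CMLGaitClassifier` is a scikit-learn compatible estimator (works in
pipelines and model selection); the module functions below wrap it for
the LOSO protocol and Table-style sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .gait_features import FEATURE_NAMES

CLASSIFIERS = ("RF", "DT", "SVM", "KNN", "GNB", "LR")
PROJECTIONS = ("none", "pca2", "lda1")

#: Ridge coefficient on the LDA within-class scatter; stabilizes the
#: 1-D discriminant on small LOSO training folds.
LDA_SHRINKAGE = 1e-4

#: The cohort is a balanced two-group design; class priors are pinned at
#: 0.5 so that the 14-vs-15 imbalance of a LOSO training fold cannot tilt
#: prior-sensitive classifiers.
BALANCED_PRIORS = (0.5, 0.5)


def _make_classifier(name: str, seed: int):
    # class_weight / priors balanced throughout: a LOSO training fold of a
    # balanced cohort is 14-vs-15, and that imbalance must not inform the
    # classifier (KNN has no prior to balance).
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=100, class_weight="balanced", random_state=seed
        )
    if name == "DT":
        return DecisionTreeClassifier(class_weight="balanced", random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", class_weight="balanced", random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "GNB":
        return GaussianNB(priors=list(BALANCED_PRIORS))
    if name == "LR":
        return LogisticRegression(
            max_iter=2000, class_weight="balanced", random_state=seed
        )
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def _make_projection(name: str):
    if name == "none":
        return None
    if name == "pca2":
        return PCA(n_components=2)
    if name == "lda1":
        return LinearDiscriminantAnalysis(
            solver="eigen",
            shrinkage=LDA_SHRINKAGE,
            priors=list(BALANCED_PRIORS),
            n_components=1,
        )
    raise ValueError(f"unknown projection {name!r}; expected one of {PROJECTIONS}")


class CMLGaitClassifier(ClassifierMixin, BaseEstimator):
    """Scaler → optional projection → classical classifier.

    Parameters
    ----------
    classifier : {"RF", "DT", "SVM", "KNN", "GNB", "LR"}
        Random forest (100 trees), decision tree, RBF support-vector
        machine, 5-nearest-neighbors, Gaussian naive Bayes with balanced
        priors, or L2 logistic regression.
    projection : {"none", "pca2", "lda1"}
        Optional dimensionality reduction fitted on the training data
        only: 2-component PCA or 1-D ridge-regularized LDA.
    standardize : bool
        Z-score features using training statistics (scale-sensitive
        classifiers and PCA need commensurate features).
    random_state : int
        Seed for the stochastic classifiers.

    Attributes
    ----------
    pipeline_ : sklearn.pipeline.Pipeline
        The fitted scaler/projection/classifier chain.
    classes_ : ndarray
        Class labels seen during fit.
    """

    def __init__(
        self,
        classifier: str = "RF",
        projection: str = "none",
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.classifier = classifier
        self.projection = projection
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain both classes")
        # zero-variance training features carry no signal and make the LDA
        # within-class scatter spuriously invertible along null directions
        steps = [("drop_constant", VarianceThreshold(threshold=0.0))]
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        proj = _make_projection(self.projection)
        if proj is not None:
            steps.append(("project", clone(proj)))
        steps.append(("clf", _make_classifier(self.classifier, self.random_state)))
        self.pipeline_ = Pipeline(steps)
        self.pipeline_.fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.pipeline_.predict(X)

    def transform_scores(self, X) -> np.ndarray:
        """Projection coordinates (PC1/PC2 or LDA1) for X; requires a projection."""
        check_is_fitted(self)
        if self.projection == "none":
            raise ValueError("no projection configured")
        sub = self.pipeline_[:-1]
        return np.asarray(sub.transform(X))


@dataclass
class CMLConfig:
    """One CML-CF run configuration."""

    classifier: str = "RF"
    projection: str = "none"
    activity: str = "ALL"
    seed: int = 0
    standardize: bool = True


@dataclass
class ClassificationRun:
    """LOSO result: one prediction per participant plus reporting scores."""

    config: object
    fold_predictions: dict[str, str]
    true_labels: dict[str, str]
    accuracy: float
    projection_scores: Optional[pd.DataFrame] = None
    fold_train_ids: dict[str, frozenset] = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.fold_predictions)

    def assert_no_leakage(self) -> None:
        """Raise if any held-out participant appeared in its fold's training set."""
        for pid, train_ids in self.fold_train_ids.items():
            if pid in train_ids:
                raise AssertionError(f"participant {pid} leaked into training fold")


def _activity_matrix(table: pd.DataFrame, activity: str):
    """Rows, X, y, groups for one activity (or all activities pooled)."""
    sub = table if activity == "ALL" else table[table["activity"] == activity]
    sub = sub.dropna(subset=FEATURE_NAMES)
    sub = sub[np.isfinite(sub[FEATURE_NAMES]).all(axis=1)]
    if sub.empty:
        raise ValueError(f"no usable rows for activity {activity!r}")
    X = sub[FEATURE_NAMES].to_numpy(dtype=float)
    y = sub["group"].to_numpy(dtype=object)
    groups = sub["participant_id"].to_numpy(dtype=object)
    return sub.reset_index(drop=True), X, y, groups


def loso_evaluate(table: pd.DataFrame, config: CMLConfig) -> ClassificationRun:
    """Leave-one-subject-out evaluation of one configuration.

    Each fold holds out every row of one participant; the scaler,
    projection, and classifier are fitted on the remaining participants
    only.  In pooled ("ALL") mode a participant contributes one row per
    activity and the subject-level call is the majority vote over their
    row predictions (ties go to DMD).  Projection scores for reporting
    come from a final fit on the full table.
    """
    _, X, y, groups = _activity_matrix(table, config.activity)
    unique_pids = sorted(set(groups))
    labels_by_pid = {pid: y[groups == pid][0] for pid in unique_pids}
    counts = pd.Series(list(labels_by_pid.values())).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 participants per class")

    est = CMLGaitClassifier(
        classifier=config.classifier,
        projection=config.projection,
        standardize=config.standardize,
        random_state=config.seed,
    )

    fold_predictions: dict[str, str] = {}
    fold_train_ids: dict[str, frozenset] = {}
    for pid in unique_pids:
        test_mask = groups == pid
        train_mask = ~test_mask
        train_pids = frozenset(groups[train_mask])
        assert pid not in train_pids  # leakage guard
        if len(set(y[train_mask])) < 2:
            raise ValueError(f"training fold for {pid} has a single class")
        model = clone(est).fit(X[train_mask], y[train_mask])
        votes = model.predict(X[test_mask])
        n_dmd = int(np.sum(votes == "DMD"))
        fold_predictions[pid] = "DMD" if n_dmd >= len(votes) - n_dmd else "TD"
        fold_train_ids[pid] = train_pids

    correct = [fold_predictions[p] == labels_by_pid[p] for p in unique_pids]
    accuracy = float(np.mean(correct))

    projection_scores = None
    if config.projection != "none":
        final = clone(est).fit(X, y)
        scores = final.transform_scores(X)
        cols = ["PC1", "PC2"] if config.projection == "pca2" else ["LDA1"]
        projection_scores = pd.DataFrame(scores, columns=cols)
        projection_scores.insert(0, "participant_id", groups)
        if config.projection == "lda1":
            # sign convention: DMD class mean positive
            dmd_mean = projection_scores.loc[y == "DMD", "LDA1"].mean()
            if dmd_mean < 0:
                projection_scores["LDA1"] *= -1

    run = ClassificationRun(
        config=config,
        fold_predictions=fold_predictions,
        true_labels=labels_by_pid,
        accuracy=accuracy,
        projection_scores=projection_scores,
        fold_train_ids=fold_train_ids,
    )
    run.assert_no_leakage()
    return run


def project_pca(table: pd.DataFrame, activity: str = "ALL", n_components: int = 2):
    """Standardized PCA of the feature table.

    Returns (scores DataFrame with PC columns, loadings array, explained
    variance ratios).  Components are orthonormal and ordered by
    decreasing explained variance.
    """
    sub, X, y, groups = _activity_matrix(table, activity)
    if len(sub) < 3:
        raise ValueError("need at least 3 rows for PCA")
    Xs = StandardScaler().fit_transform(X)
    if np.linalg.matrix_rank(Xs) < n_components:
        raise ValueError(f"feature matrix rank below {n_components}")
    pca = PCA(n_components=n_components).fit(Xs)
    scores = pd.DataFrame(
        pca.transform(Xs), columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    scores.insert(0, "participant_id", groups)
    scores["group"] = y
    return scores, pca.components_, pca.explained_variance_ratio_


def project_lda(table: pd.DataFrame, activity: str = "ALL") -> pd.DataFrame:
    """1-D LDA scores of the feature table; DMD class mean is positive."""
    sub, X, y, groups = _activity_matrix(table, activity)
    for cls in ("DMD", "TD"):
        if np.sum(y == cls) < 2:
            raise ValueError(f"need at least 2 rows of class {cls}")
    Xs = StandardScaler().fit_transform(X)
    lda = _make_projection("lda1").fit(Xs, y)
    z = np.asarray(lda.transform(Xs)).ravel()
    if z[y == "DMD"].mean() < 0:
        z = -z
    out = pd.DataFrame({"participant_id": groups, "LDA1": z, "group": y})
    return out


def sweep_configs(
    table: pd.DataFrame,
    activities: Sequence[str],
    classifiers: Sequence[str] = CLASSIFIERS,
    projections: Sequence[str] = PROJECTIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """LOSO accuracy grid over activities × classifiers × projections.

    Returns a table with columns activity, classifier, projection,
    accuracy_pct, and a best-in-column marker per (activity, projection).
    """
    rows = []
    for act in activities:
        for clf in classifiers:
            for proj in projections:
                cfg = CMLConfig(
                    classifier=clf, projection=proj, activity=act, seed=seed
                )
                run = loso_evaluate(table, cfg)
                rows.append(
                    {
                        "activity": act,
                        "classifier": clf,
                        "projection": proj,
                        "accuracy_pct": 100.0 * run.accuracy,
                    }
                )
    grid = pd.DataFrame(rows)
    grid["best_in_column"] = False
    for (act, proj), idx in grid.groupby(["activity", "projection"]).groups.items():
        block = grid.loc[idx]
        grid.loc[block.index[block["accuracy_pct"] == block["accuracy_pct"].max()],
                 "best_in_column"] = True
    return grid
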