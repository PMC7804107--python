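"""One-vs-rest MLP classification of co-stimulated cells.

Two multilayer-perceptron classifiers (three hidden layers, tanh
activation) are trained on the single-stimulus populations, one per
stimulus, each distinguishing its own stimulus from the other
single-stimulus cells. Applied jointly to co-stimulated cells as a
one-vs-rest multilabel pair, the two binary decisions yield a composite
dominance label:

    (+, -) -> A-dominant    (-, +) -> B-dominant
    (+, +) -> mixed         (-, -) -> unclassified

Features are normalized ln values, standardized per gene with
training-set statistics; either all genes or only the cross-inhibited
UCGs can serve as the feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .core_programs import CONDITION_KEY, LOGNORM_LAYER, ProgramSets

LABEL_MIXED = "mixed"
LABEL_UNCLASSIFIED = "unclassified"

FEATURE_SET_ALL = "all_genes"
FEATURE_SET_UCG = "cross_inhibited_ucgs"


class DominanceClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest pair of MLP binary classifiers with composite labels.

    Parameters
    ----------
    hidden_layer_sizes : tuple
        Three hidden layers by default (64, 32, 16).
    activation : str
        'tanh' per the model family this mirrors.
    decision_threshold : float
        Positive-class probability above which a binary classifier votes
        positive (inclusive).
    positive_classes : tuple of str or None
        The two stimulus labels that get a dedicated classifier. None
        means the two classes seen in ``y`` (which must then be exactly
        two); extra labels in ``y`` (e.g. control cells) only serve as
        negatives.

    Attributes
    ----------
    classes_ : ndarray of the two positive classes (A first).
    estimators_ : dict class -> fitted scaler+MLP pipeline.
    feature_names_in_ : feature names when fit from a DataFrame.
    """

    def __init__(
        self,
        hidden_layer_sizes=(64, 32, 16),
        activation="tanh",
        decision_threshold=0.5,
        positive_classes=None,
        max_iter=300,
        random_state=0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.decision_threshold = decision_threshold
        self.positive_classes = positive_classes
        self.max_iter = max_iter
        self.random_state = random_state

    def _validate(self):
        if not 0.0 < self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must lie in (0, 1]")

    def fit(self, X, y):
        self._validate()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if self.positive_classes is None:
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError(
                    "positive_classes must be given when y has != 2 labels"
                )
        else:
            classes = np.asarray(self.positive_classes, dtype=object)
            if len(classes) != 2:
                raise ValueError("exactly two positive classes required")
        self.classes_ = classes
        self.estimators_ = {}
        for cls in classes:
            pipe = Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPClassifier(
                            hidden_layer_sizes=self.hidden_layer_sizes,
                            activation=self.activation,
                            max_iter=self.max_iter,
                            random_state=self.random_state,
                        ),
                    ),
                ]
            )
            pipe.fit(X, (y == cls).astype(int))
            self.estimators_[cls] = pipe
        self.n_features_in_ = X.shape[1]
        return self

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = [f for f in self.feature_names_in_ if f not in X.columns]
                if missing:
                    raise ValueError(
                        f"features missing from input: {missing[:5]}"
                    )
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X):
        """(n, 2) positive-class probabilities, columns in classes_ order."""
        check_is_fitted(self, "estimators_")
        X = self._as_array(X)
        cols = [
            self.estimators_[cls].predict_proba(X)[:, 1] for cls in self.classes_
        ]
        return np.column_stack(cols)

    def predict(self, X):
        """Composite dominance labels from the two thresholded decisions."""
        proba = self.predict_proba(X)
        pos = proba >= self.decision_threshold
        a, b = self.classes_
        labels = np.empty(len(proba), dtype=object)
        labels[pos[:, 0] & ~pos[:, 1]] = f"{a}-dominant"
        labels[~pos[:, 0] & pos[:, 1]] = f"{b}-dominant"
        labels[pos[:, 0] & pos[:, 1]] = LABEL_MIXED
        labels[~pos[:, 0] & ~pos[:, 1]] = LABEL_UNCLASSIFIED
        return labels


@dataclass
class TrainingReport:
    """Held-out and cross-validated accuracy of each binary classifier."""

    accuracy: dict[str, float]
    cv_accuracies: dict[str, np.ndarray]
    class_counts: dict[str, int]
    feature_set: str
    n_features: int


@dataclass
class DominanceLabels:
    """Per co-stimulated cell: composite label plus the two classifier
    positive-class probabilities."""

    table: pd.DataFrame  # index cell_id; columns label, p_A, p_B

    def fractions(self) -> pd.Series:
        return self.table["label"].value_counts(normalize=True)


def _feature_matrix(
    adata: ad.AnnData,
    feature_set: str,
    programs: ProgramSets | None,
    layer: str = LOGNORM_LAYER,
) -> pd.DataFrame:
    if feature_set == FEATURE_SET_ALL:
        genes = list(adata.var_names)
    elif feature_set == FEATURE_SET_UCG:
        if programs is None or not programs.cross_regulation:
            raise ValueError(
                "feature_set='cross_inhibited_ucgs' needs program sets with "
                "cross-regulation labels; run the core-program analysis first"
            )
        genes = sorted(programs.cross_inhibited_ucgs())
        if not genes:
            # no inhibition detected anywhere: fall back to all UCGs
            import warnings

            warnings.warn(
                "no cross-inhibited UCGs; falling back to all UCGs as features"
            )
            genes = sorted(programs.ucg_a | programs.ucg_b)
        if not genes:
            raise ValueError("no UCGs available as features")
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    vals = np.asarray(adata[:, genes].layers[layer])
    return pd.DataFrame(vals, index=adata.obs_names, columns=genes)


def train_ovr(
    adata: ad.AnnData,
    programs: ProgramSets | None = None,
    feature_set: str = FEATURE_SET_ALL,
    stim_conditions: tuple[str, str] = ("stimA", "stimB"),
    include_control_negatives: bool = True,
    train_fraction: float = 0.8,
    cv_folds: int | None = 5,
    hidden_layer_sizes=(64, 32, 16),
    decision_threshold: float = 0.5,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[DominanceClassifier, TrainingReport]:
    """Train the OvR classifier pair on single-stimulus cells.

    The training universe is the single-stimulus cells plus, by default,
    control cells as extra negatives (skipped silently when absent).
    Without unstimulated negatives each binary classifier only has to
    discriminate the two programs and its response to cells expressing
    *both* programs is unidentifiable; adding control cells forces it to
    detect the presence of its own program, which is what makes mixed
    cells land positive for both classifiers. A stratified
    ``train_fraction`` split gives the held-out accuracy per binary
    classifier, and ``cv_folds``-fold stratified CV (None skips it) the
    CV accuracies.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    cond = adata.obs[CONDITION_KEY].astype(str)
    universe = list(stim_conditions)
    if include_control_negatives and (cond == "control").any():
        universe.append("control")
    sel = cond.isin(universe).to_numpy()
    for c in stim_conditions:
        if (cond == c).sum() < 20:
            raise ValueError(f"condition {c!r} needs >= 20 cells for training")
    X = _feature_matrix(adata[sel], feature_set, programs)
    y = cond[sel].to_numpy(dtype=object)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    model = DominanceClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        decision_threshold=decision_threshold,
        positive_classes=tuple(stim_conditions),
        max_iter=max_iter,
        random_state=seed,
    ).fit(X_tr, y_tr)

    proba = model.predict_proba(X_te)
    accuracy = {}
    for i, cls in enumerate(model.classes_):
        pred_pos = proba[:, i] >= decision_threshold
        accuracy[str(cls)] = float(np.mean(pred_pos == (y_te == cls)))

    cv_accuracies: dict[str, np.ndarray] = {}
    if cv_folds is not None and cv_folds >= 2:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        accs = {str(c): [] for c in model.classes_}
        Xa, ya = X.to_numpy(float), y
        for tr_idx, te_idx in skf.split(Xa, ya):
            m = clone(model).fit(Xa[tr_idx], ya[tr_idx])
            pr = m.predict_proba(Xa[te_idx])
            for i, cls in enumerate(m.classes_):
                pred_pos = pr[:, i] >= decision_threshold
                accs[str(cls)].append(float(np.mean(pred_pos == (ya[te_idx] == cls))))
        cv_accuracies = {c: np.asarray(v) for c, v in accs.items()}

    report = TrainingReport(
        accuracy=accuracy,
        cv_accuracies=cv_accuracies,
        class_counts={c: int((y == c).sum()) for c in np.unique(y)},
        feature_set=feature_set,
        n_features=X.shape[1],
    )
    return model, report


def classify_costim(
    model: DominanceClassifier,
    adata: ad.AnnData,
    programs: ProgramSets | None = None,
    costim_condition: str = "costim",
    feature_set: str | None = None,
) -> DominanceLabels:
    """Score co-stimulated cells with both classifiers and label them."""
    check_is_fitted(model, "estimators_")
    cond = adata.obs[CONDITION_KEY].astype(str)
    sel = (cond == costim_condition).to_numpy()
    sub = adata[sel]
    if feature_set is None:
        genes = list(model.feature_names_in_)
        missing = [g for g in genes if g not in adata.var_names]
        if missing:
            raise ValueError(f"model features missing from matrix: {missing[:5]}")
        X = pd.DataFrame(
            np.asarray(sub[:, genes].layers[LOGNORM_LAYER]),
            index=sub.obs_names, columns=genes,
        )
    else:
        X = _feature_matrix(sub, feature_set, programs)
    if sub.n_obs == 0:
        table = pd.DataFrame(columns=["label", "p_A", "p_B"])
        return DominanceLabels(table=table)
    proba = model.predict_proba(X)
    labels = model.predict(X)
    table = pd.DataFrame(
        {"label": labels, "p_A": proba[:, 0], "p_B": proba[:, 1]},
        index=sub.obs_names,
    )
    return DominanceLabels(table=table)


def compare_feature_sets(
    adata: ad.AnnData,
    programs: ProgramSets,
    stim_conditions: tuple[str, str] = ("stimA", "stimB"),
    costim_condition: str = "costim",
    seed: int = 0,
    **train_kwargs,
) -> pd.DataFrame:
    """Dominance label counts with all-gene vs cross-inhibited-UCG
    features, side by side."""
    import warnings

    cond = adata.obs[CONDITION_KEY].astype(str)
    if (cond == costim_condition).sum() == 0:
        warnings.warn("no co-stimulated cells; returning empty comparison")
        return pd.DataFrame()
    cols = {}
    for fs in (FEATURE_SET_ALL, FEATURE_SET_UCG):
        model, _ = train_ovr(
            adata, programs, feature_set=fs, stim_conditions=stim_conditions,
            seed=seed, **train_kwargs,
        )
        labels = classify_costim(model, adata, programs,
                                 costim_condition=costim_condition)
        cols[fs] = labels.table["label"].value_counts()
    out = pd.DataFrame(cols).fillna(0).astype(int)
    return out


def save_model(model: DominanceClassifier, path: str) -> None:
    """Serialize a fitted classifier (features, scalers, weights, config)."""
    check_is_fitted(model, "estimators_")
    joblib.dump(model, path)


def load_model(path: str) -> DominanceClassifier:
    model = joblib.load(path)
    if not isinstance(model, DominanceClassifier):
        raise TypeError(f"{path} does not contain a DominanceClassifier")
    return model
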