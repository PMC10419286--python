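"""Chemometric modelling of preprocessed single-cell Raman spectra.

The classification strategy mirrors standard practice in Raman cytometry:

* **aggregation** — single-cell spectra are noisy, so disjoint random
  groups of ``group_size`` spectra from the same (batch, mouse, group)
  stratum are averaged and re-normalized before modelling. Aggregates
  never mix animals, so no identity leaks across cross-validation folds.
* **PCA + classifier** — principal component analysis (mean-centering
  only; spectra are already vector-normalized) reduces each aggregate to
  its first ``n_components`` scores, which feed a linear discriminant
  analysis (LDA), random forest (RF) or RBF support vector machine (SVM).
* **validation** — stratified k-fold cross-validation, and the stricter
  leave-one-batch-out ("batchwise") scheme in which the whole held-out
  acquisition batch contributes nothing — not even to the PCA — of its
  own fold's training.
* **animal-level majority vote** — each mouse is labelled by the majority
  of its spectrum-level predictions, concentrating a modest per-spectrum
  accuracy into a reliable per-animal call.

Metrics are the mean per-class recall ("balanced accuracy", a.k.a. mean
sensitivity) and Cohen's kappa, both computed from the 2x2 confusion
matrix.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .dataset import GROUPS, SpectralDataset
from .preprocess import vector_normalize

LABELS = list(GROUPS)  # ("sham", "sick") — fixed confusion-matrix order


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, labels=LABELS) -> pd.DataFrame:
    """Counts indexed by (true label, predicted label)."""
    cm = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def _as_array(cm) -> np.ndarray:
    arr = np.asarray(cm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(arr < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    return arr


def balanced_accuracy(cm) -> float:
    """Mean of per-class recalls (the mean sensitivity)."""
    arr = _as_array(cm)
    row_totals = arr.sum(axis=1)
    if np.any(row_totals == 0):
        raise ValueError("every true class needs at least one item")
    return float(np.mean(np.diag(arr) / row_totals))


def cohens_kappa(cm) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Returns 0.0 by convention when expected agreement p_e equals 1 (all
    mass in one cell of the marginals).
    """
    arr = _as_array(cm)
    n = arr.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(arr) / n
    p_e = float(np.sum(arr.sum(axis=1) * arr.sum(axis=0)) / n**2)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def sensitivity_specificity(cm: pd.DataFrame, positive: str = "sick"
                            ) -> tuple[float, float]:
    """Recall of the positive (sick) and negative (sham) classes."""
    neg = [l for l in cm.index if l != positive][0]
    sens = cm.loc[positive, positive] / cm.loc[positive].sum()
    spec = cm.loc[neg, neg] / cm.loc[neg].sum()
    return float(sens), float(spec)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregationSpec:
    """How to average single spectra into aggregates before modelling.

    ``group_size`` 10 suits sepsis-model screening data (one spectrum per
    cell); 12 suits endotoxemia imaging data. ``stratum_keys`` defines the
    "type" within which spectra may be pooled — the default keeps batches,
    animals and disease groups separate.
    """

    group_size: int = 10
    strategy: str = "random_within_stratum"
    stratum_keys: tuple = ("batch_id", "mouse_id", "group")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.strategy != "random_within_stratum":
            raise ValueError("unknown aggregation strategy")


def aggregate_spectra(ds: SpectralDataset, spec: AggregationSpec
                      ) -> SpectralDataset:
    """Average seeded random disjoint groups of ``group_size`` spectra.

    Within each stratum the spectra are randomly partitioned into
    floor(n / group_size) disjoint groups; each group is replaced by its
    channelwise mean, re-vector-normalized. Remainder spectra are
    discarded; strata smaller than ``group_size`` are dropped with a
    warning. Metadata is inherited from the stratum (cell_id becomes
    ``aggregate``).
    """
    rng = np.random.default_rng(spec.seed)
    keys = list(spec.stratum_keys)
    sizes = ds.meta.groupby(keys, sort=True).size()
    if spec.group_size > sizes.max():
        raise ValueError(
            f"group_size {spec.group_size} exceeds the largest stratum "
            f"({int(sizes.max())} spectra)")
    rows, meta_rows = [], []
    for stratum, idx in ds.meta.groupby(keys, sort=True).indices.items():
        idx = np.asarray(idx)
        n_groups = len(idx) // spec.group_size
        if n_groups == 0:
            warnings.warn(
                f"stratum {stratum} has {len(idx)} < {spec.group_size} spectra; dropped")
            continue
        perm = rng.permutation(idx)
        first = ds.meta.iloc[idx[0]]
        for g in range(n_groups):
            members = perm[g * spec.group_size:(g + 1) * spec.group_size]
            mean = ds.intensities[members].mean(axis=0)
            rows.append(vector_normalize(mean))
            meta_rows.append({
                "spectrum_id": f"{first['mouse_id']}|{first['batch_id']}|agg{g}",
                "batch_id": first["batch_id"],
                "mouse_id": first["mouse_id"],
                "group": first["group"],
                "model": first["model"],
                "cell_id": "aggregate",
            })
    out = SpectralDataset(ds.axis.copy(), np.vstack(rows),
                          pd.DataFrame(meta_rows), list(ds.provenance))
    out.log(f"aggregate_spectra: group_size={spec.group_size}, "
            f"strata={keys}, seed={spec.seed}, {len(rows)} aggregates")
    return out


# ---------------------------------------------------------------------------
# PCA + classifier estimator
# ---------------------------------------------------------------------------

class PCAClassifier(BaseEstimator, ClassifierMixin):
    """PCA scores feeding an LDA, random-forest or RBF-SVM classifier.

    Parameters
    ----------
    n_components : int
        Number of principal components kept (5 suits the sepsis model,
        7 the endotoxemia model in the motivating experiments).
    classifier : {"lda", "rf", "svm"}
        Downstream classifier on the PC scores. RF uses 500 trees; SVM is
        RBF with C=1 and bandwidth set by the median pairwise-distance
        heuristic.
    random_state : int
        Seed for the stochastic classifiers.

    Notes
    -----
    PCA is mean-centered but unscaled: the spectra are vector-normalized,
    and per-channel scaling would distort band ratios. For LDA the signed
    discriminant score returned by :meth:`decision_function` follows the
    convention that the sick class scores negative.
    """

    def __init__(self, n_components: int = 5, classifier: str = "lda",
                 random_state: int = 0, rf_n_estimators: int = 500,
                 svm_c: float = 1.0):
        self.n_components = n_components
        self.classifier = classifier
        self.random_state = random_state
        self.rf_n_estimators = rf_n_estimators
        self.svm_c = svm_c

    def _make_clf(self, scores: np.ndarray):
        if self.classifier == "lda":
            return LinearDiscriminantAnalysis()
        if self.classifier == "rf":
            return RandomForestClassifier(n_estimators=self.rf_n_estimators,
                                          random_state=self.random_state)
        if self.classifier == "svm":
            d = pairwise_distances(scores)
            med = np.median(d[np.triu_indices_from(d, k=1)])
            gamma = 1.0 / (2 * med**2) if med > 0 else "scale"
            return SVC(kernel="rbf", C=self.svm_c, gamma=gamma,
                       random_state=self.random_state)
        raise ValueError(f"unknown classifier {self.classifier!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        if np.any(counts < 2):
            raise ValueError("each class needs >= 2 training samples")
        max_pcs = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= max_pcs:
            raise ValueError(
                f"n_components={self.n_components} invalid for "
                f"{X.shape[0]} samples x {X.shape[1]} channels (max {max_pcs})")
        self.pca_ = PCA(n_components=self.n_components,
                        random_state=self.random_state).fit(X)
        scores = self.pca_.transform(X)
        self.clf_ = self._make_clf(scores).fit(scores, y)
        self.classes_ = self.clf_.classes_
        self.sign_ = 1.0
        if self.classifier == "lda":
            # fix sign so the sick training mean scores negative
            raw = self.clf_.decision_function(scores)
            sick_mean = raw[y == "sick"].mean() if "sick" in classes else raw.mean()
            self.sign_ = -1.0 if sick_mean > 0 else 1.0
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "clf_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("predict requires a non-empty 2-D spectrum matrix")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"axis mismatch: model fitted on {self.n_features_in_} channels, "
                f"got {X.shape[1]}")
        return self.clf_.predict(self.pca_.transform(X))

    def decision_function(self, X):
        """Signed LDA score per spectrum (sick side negative)."""
        check_is_fitted(self, "clf_")
        if self.classifier != "lda":
            raise ValueError("decision scores are defined for the LDA classifier")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("axis mismatch in decision_function")
        return self.sign_ * self.clf_.decision_function(self.pca_.transform(X))

    def ld_loading(self) -> np.ndarray:
        """Discriminant direction back-projected into wavenumber space.

        Positive excursions align with the class scoring positive (sham);
        negative ones with the sick class.
        """
        check_is_fitted(self, "clf_")
        if self.classifier != "lda":
            raise ValueError("LD loadings are defined for the LDA classifier")
        w = self.clf_.coef_[0]
        return self.sign_ * (w @ self.pca_.components_)


def fit_model(train: SpectralDataset, n_pcs: int = 5, classifier: str = "lda",
              seed: int = 0) -> PCAClassifier:
    """Fit a :class:`PCAClassifier` on a dataset's spectra and group labels."""
    est = PCAClassifier(n_components=n_pcs, classifier=classifier,
                        random_state=seed)
    return est.fit(train.intensities, train.meta["group"].to_numpy())


def predict(model: PCAClassifier, ds: SpectralDataset) -> pd.DataFrame:
    """Per-spectrum predictions (+ LDA score where defined) with metadata."""
    labels = model.predict(ds.intensities)
    out = ds.meta.copy()
    out["predicted"] = labels
    if model.classifier == "lda":
        out["score"] = model.decision_function(ds.intensities)
    return out


def ld_loading(model: PCAClassifier) -> np.ndarray:
    return model.ld_loading()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Cross-validation outcome at spectrum and animal level."""

    fold_confusions: list
    confusion: pd.DataFrame
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    cohens_kappa: float
    predictions: pd.DataFrame
    vote_table: pd.DataFrame
    vote_confusion: pd.DataFrame
    majority_vote_balanced_accuracy: float
    holdout_predictions: pd.DataFrame | None = None

    def summary(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cohens_kappa": self.cohens_kappa,
            "majority_vote_balanced_accuracy": self.majority_vote_balanced_accuracy,
            "confusion": self.confusion.to_dict(),
            "n_folds": len(self.fold_confusions),
        }


def majority_vote(predictions: pd.DataFrame, tie_label: str = "sick"
                  ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Animal-level vote over per-spectrum predictions.

    ``predictions`` needs columns ``mouse_id, group, predicted``. Exact
    ties go to ``tie_label`` (sick by default: in a screening context a
    tied animal is flagged, favouring sensitivity).

    Returns (vote table, mouse-level confusion matrix, mouse-level
    balanced accuracy).
    """
    rows = []
    for mouse, grp in predictions.groupby("mouse_id", sort=True):
        true = grp["group"].unique()
        if true.size != 1:
            raise ValueError(f"mouse {mouse} carries conflicting group labels")
        n = len(grp)
        if n == 0:
            warnings.warn(f"mouse {mouse} has no predictions; excluded")
            continue
        frac_sick = float((grp["predicted"] == "sick").mean())
        vote = "sick" if frac_sick > 0.5 else ("sham" if frac_sick < 0.5 else tie_label)
        rows.append({"mouse_id": mouse, "group": true[0], "n_spectra": n,
                     "fraction_predicted_sick": frac_sick, "vote": vote})
    table = pd.DataFrame(rows)
    cm = confusion_matrix(table["group"], table["vote"])
    present = cm.loc[cm.sum(axis=1) > 0]  # BA over classes with >=1 mouse
    ba = float(np.mean(np.diag(present[present.index]) / present.sum(axis=1)))
    return table, cm, ba


def _evaluate(predictions: pd.DataFrame, fold_cms: list,
              holdout: pd.DataFrame | None = None) -> EvaluationResult:
    cm = confusion_matrix(predictions["group"], predictions["predicted"])
    sens, spec = sensitivity_specificity(cm)
    votes, vote_cm, vote_ba = majority_vote(predictions)
    return EvaluationResult(
        fold_confusions=fold_cms,
        confusion=cm,
        balanced_accuracy=balanced_accuracy(cm),
        sensitivity=sens,
        specificity=spec,
        cohens_kappa=cohens_kappa(cm),
        predictions=predictions,
        vote_table=votes,
        vote_confusion=vote_cm,
        majority_vote_balanced_accuracy=vote_ba,
        holdout_predictions=holdout,
    )


def kfold_cv(ds: SpectralDataset, k: int = 10, n_pcs: int = 5,
             classifier: str = "lda", seed: int = 0) -> EvaluationResult:
    """Stratified k-fold cross-validation with per-fold PCA refits."""
    y = ds.meta["group"].to_numpy()
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available spectra")
    # leave-one-out and other k beyond the smallest class cannot stratify
    min_class = pd.Series(y).value_counts().min()
    if k <= min_class:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = pd.Series(index=ds.meta.index, dtype=object)
    fold_cms = []
    base = PCAClassifier(n_components=n_pcs, classifier=classifier,
                         random_state=seed)
    for train_idx, test_idx in skf.split(ds.intensities, y):
        est = clone(base).fit(ds.intensities[train_idx], y[train_idx])
        p = est.predict(ds.intensities[test_idx])
        preds.iloc[test_idx] = p
        fold_cms.append(confusion_matrix(y[test_idx], p))
    predictions = ds.meta.copy()
    predictions["predicted"] = preds.to_numpy()
    return _evaluate(predictions, fold_cms)


def spectrum_hashes(ds: SpectralDataset) -> list[str]:
    """Content hash of each spectrum's intensity vector (leakage audits)."""
    return [hashlib.sha256(np.ascontiguousarray(row).tobytes()).hexdigest()
            for row in ds.intensities]


def batchwise_cv(ds: SpectralDataset, n_pcs: int = 5, classifier: str = "lda",
                 seed: int = 0) -> EvaluationResult:
    """Leave-one-batch-out cross-validation.

    Each batch containing both classes serves once as the test fold; its
    spectra, animals and variance contribute nothing to that fold's
    training (the PCA included). Batches with a single class never rotate
    into the test position — they stay in every training split — and are
    additionally predicted by a final model fitted on all spectra
    (returned in ``holdout_predictions``).
    """
    y = ds.meta["group"].to_numpy()
    batches = ds.meta["batch_id"].to_numpy()
    unique_batches = list(pd.unique(batches))
    if len(unique_batches) < 2:
        raise ValueError("batchwise CV needs >= 2 batches")
    rotating, held = [], []
    for b in unique_batches:
        cls = set(y[batches == b])
        (rotating if len(cls) == 2 else held).append(b)
    if held:
        warnings.warn(f"batches {held} contain one class only; "
                      "kept in training, never used as a test fold")
    if len(rotating) == 0:
        raise ValueError("no batch contains both classes")
    base = PCAClassifier(n_components=n_pcs, classifier=classifier,
                         random_state=seed)
    fold_cms = []
    preds = pd.Series(index=ds.meta.index, dtype=object)
    for b in rotating:
        test_mask = batches == b
        est = clone(base).fit(ds.intensities[~test_mask], y[~test_mask])
        p = est.predict(ds.intensities[test_mask])
        preds.iloc[np.flatnonzero(test_mask)] = p
        fold_cms.append(confusion_matrix(y[test_mask], p))
    predictions = ds.meta.loc[preds.notna()].copy()
    predictions["predicted"] = preds[preds.notna()].to_numpy()
    holdout = None
    if held:
        final = clone(base).fit(ds.intensities, y)
        mask = np.isin(batches, held)
        holdout = ds.meta.loc[mask].copy()
        holdout["predicted"] = final.predict(ds.intensities[mask])
    return _evaluate(predictions, fold_cms, holdout)
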