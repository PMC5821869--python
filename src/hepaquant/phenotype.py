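"""Marker phenotyping and ductal / non-ductal discrimination.

Two classifier-shaped pieces of the pipeline, exposed as scikit-learn style
estimators so they compose with sklearn model selection:

* :class:`MarkerClassifier` — one-feature positive/negative call (e.g.
  cytoplasmic DAB OD for PCK or CD45), with a fixed, Otsu or two-component
  Gaussian-mixture threshold.  The reporting contract is the number of
  positive cells expressed as a percentage of total cells.
* :class:`DuctalDiscriminant` — Fisher linear discriminant on
  (nucleus area, nuclear haematoxylin OD, cytoplasmic DAB OD), the three
  features on which ductal marker-positive cells exceed non-ductal
  presumptive progenitors.  FOV-level ductality is a majority vote of
  single-cell calls.

Convenience functions (:func:`classify_marker`, :func:`classify_double_if`,
:func:`train_ductal_model`, :func:`classify_fov_ductality`) wrap the
estimators for cell-table workflows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PhenotypeRule",
    "MarkerClassifier",
    "DuctalDiscriminant",
    "classify_marker",
    "classify_double_if",
    "train_ductal_model",
    "classify_fov_ductality",
    "DUCTAL_FEATURES",
]

#: Feature columns of the ductal discriminant, in order.
DUCTAL_FEATURES = ("area_um2", "od_nuc_haematoxylin", "od_cyt_dab")

#: Coefficient-of-variation floor below which a data-driven threshold is
#: considered unidentifiable (unimodal feature distribution).
CV_FLOOR = 0.05


@dataclass(frozen=True)
class PhenotypeRule:
    """A single-marker positivity rule.

    ``feature`` names a cell-table column (``od_cyt_dab``, ``od_nuc_dab``,
    ``int_cyt_green``, ...).  ``mode`` is ``fixed`` (use ``threshold``),
    ``otsu`` or ``gmm-2`` (data-driven cut).  Positivity is strict:
    feature > threshold.
    """

    marker: str
    feature: str
    mode: str = "otsu"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "otsu", "gmm-2"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed":
            if self.threshold is None or self.threshold < 0:
                raise ValueError("fixed mode requires a non-negative threshold")


class MarkerClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier for single-marker positivity.

    Parameters
    ----------
    mode : {'fixed', 'otsu', 'gmm-2'}
        Threshold selection.  ``fixed`` uses ``threshold`` as given;
        ``otsu`` minimises intra-class variance of the fitted feature
        values; ``gmm-2`` fits a two-component 1-D Gaussian mixture and
        cuts where the weighted component densities cross between the
        means.
    threshold : float, optional
        Required for ``fixed`` mode; ignored otherwise.

    Attributes
    ----------
    threshold_ : float
        The operating threshold after :meth:`fit`.  ``inf`` when a
        data-driven mode finds the feature distribution unimodal (all
        cells called negative).
    """

    def __init__(self, mode: str = "otsu", threshold: float | None = None):
        self.mode = mode
        self.threshold = threshold

    def fit(self, X, y=None):
        x = _as_feature_vector(X)
        if self.mode == "fixed":
            if self.threshold is None or self.threshold < 0:
                raise ValueError("fixed mode requires a non-negative threshold")
            self.threshold_ = float(self.threshold)
            return self
        if self.mode not in ("otsu", "gmm-2"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if x.size == 0 or not _bimodal_guard(x):
            self.threshold_ = np.inf
            return self
        if self.mode == "otsu":
            self.threshold_ = float(threshold_otsu(x))
        else:
            self.threshold_ = _gmm2_threshold(x)
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean positivity per cell (feature strictly above threshold)."""
        check_is_fitted(self, "threshold_")
        x = _as_feature_vector(X)
        return x > self.threshold_

    def summary(self, X) -> dict:
        """Counting contract: n_pos, n_total, percent_pos."""
        pos = self.predict(X)
        n_total = int(pos.size)
        n_pos = int(pos.sum())
        percent = 100.0 * n_pos / n_total if n_total else 0.0
        return {"n_pos": n_pos, "n_total": n_total, "percent_pos": percent}


def _as_feature_vector(X) -> np.ndarray:
    x = np.asarray(X, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    return x


def _bimodal_guard(x: np.ndarray) -> bool:
    """Reject data-driven thresholding on (near-)constant distributions."""
    if x.size < 3 or np.ptp(x) == 0:
        return False
    mean = x.mean()
    if mean <= 0:
        return np.ptp(x) > 0
    return (x.std() / mean) >= CV_FLOOR


def _gmm2_threshold(x: np.ndarray) -> float:
    gmm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gmm.fit(x.reshape(-1, 1))
    means = gmm.means_.ravel()
    lo, hi = np.sort(means)
    if np.isclose(lo, hi):
        return np.inf
    # crossing point of the weighted component densities between the means
    grid = np.linspace(lo, hi, 512)
    resp = gmm.predict_proba(grid.reshape(-1, 1))
    low_comp = int(np.argmin(means))
    cross = np.nonzero(resp[:, low_comp] < 0.5)[0]
    return float(grid[cross[0]]) if cross.size else float((lo + hi) / 2)


def _rule_classifier(rule: PhenotypeRule) -> MarkerClassifier:
    return MarkerClassifier(mode=rule.mode, threshold=rule.threshold)


def classify_marker(
    cells: pd.DataFrame,
    rule: PhenotypeRule,
    classifier: MarkerClassifier | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assign ``phenotype_{marker}`` on a cell table and summarise counts.

    A pre-fitted ``classifier`` (e.g. trained on pooled cells of a batch)
    may be supplied; otherwise the rule's threshold mode is fitted on this
    table's feature values.  Returns the augmented table and the summary
    dict (``n_pos``, ``n_total``, ``percent_pos``).
    """
    if rule.feature not in cells.columns:
        raise KeyError(f"cell table lacks feature column {rule.feature!r}")
    x = cells[rule.feature].to_numpy()
    clf = classifier
    if clf is None:
        clf = _rule_classifier(rule).fit(x)
    pos = clf.predict(x)
    out = cells.copy()
    out[f"phenotype_{rule.marker}"] = np.where(pos, "positive", "negative")
    return out, clf.summary(x)


def classify_double_if(
    cells: pd.DataFrame,
    rule_green: PhenotypeRule,
    rule_red: PhenotypeRule,
    classifier_green: MarkerClassifier | None = None,
    classifier_red: MarkerClassifier | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Four-way double-immunofluorescence call per cell.

    Labels each cell ``green+``, ``red+``, ``double+`` or ``negative`` by
    applying the two channel thresholds independently; double-positives
    are counted in neither single-positive tally, so the four counts
    partition ``n_total``.
    """
    for rule in (rule_green, rule_red):
        if rule.feature not in cells.columns:
            raise KeyError(f"cell table lacks feature column {rule.feature!r}")
    xg = cells[rule_green.feature].to_numpy()
    xr = cells[rule_red.feature].to_numpy()
    cg = classifier_green or _rule_classifier(rule_green).fit(xg)
    cr = classifier_red or _rule_classifier(rule_red).fit(xr)
    g = cg.predict(xg)
    r = cr.predict(xr)
    label = np.select(
        [g & r, g & ~r, ~g & r], ["double+", "green+", "red+"], default="negative"
    )
    out = cells.copy()
    out["if_label"] = label
    counts = {
        "n_total": int(label.size),
        "green_only": int((label == "green+").sum()),
        "red_only": int((label == "red+").sum()),
        "double": int((label == "double+").sum()),
        "negative": int((label == "negative").sum()),
    }
    return out, counts


class DuctalDiscriminant(BaseEstimator, ClassifierMixin):
    """Fisher linear discriminant separating ductal from non-ductal cells.

    Fit on exemplar cells with labels in {'ductal', 'non_ductal'}; the
    stored direction is oriented so ductal cells score higher.  Requires
    at least ``min_per_class`` exemplars of each class.

    Attributes
    ----------
    coef_, intercept_ : ndarray
        Discriminant weights over :attr:`feature_names_` and offset;
        ``decision_function > 0`` means ductal.
    class_means_ : dict
        Per-class feature means (the training summary).
    """

    classes = ("non_ductal", "ductal")

    def __init__(self, feature_names: tuple[str, ...] = DUCTAL_FEATURES,
                 min_per_class: int = 5):
        self.feature_names = feature_names
        self.min_per_class = min_per_class

    def fit(self, X, y):
        X = self._features(X)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        labels, counts = np.unique(y, return_counts=True)
        if set(labels) != {"ductal", "non_ductal"}:
            raise ValueError(
                "training requires both classes 'ductal' and 'non_ductal'; "
                f"got {sorted(labels)}"
            )
        if counts.min() < self.min_per_class:
            raise ValueError(
                f"need >= {self.min_per_class} exemplars per class"
            )
        lda = LinearDiscriminantAnalysis(solver="lsqr")
        lda.fit(X, (y == "ductal").astype(int))
        self.feature_names_ = tuple(self.feature_names)
        self.coef_ = lda.coef_.ravel().copy()
        self.intercept_ = float(lda.intercept_[0])
        self.class_means_ = {
            "ductal": X[y == "ductal"].mean(axis=0).tolist(),
            "non_ductal": X[y == "non_ductal"].mean(axis=0).tolist(),
        }
        return self

    def _features(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"cell table lacks feature columns {missing}")
            X = X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected (n, {len(self.feature_names)}) feature matrix"
                )
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        return X

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._features(X) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, "ductal", "non_ductal")

    def to_json(self, path=None) -> str:
        """Serialise the trained model (feature names, weights, means)."""
        check_is_fitted(self, "coef_")
        payload = {
            "feature_names": list(self.feature_names_),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "class_means": self.class_means_,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "DuctalDiscriminant":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        model = cls(feature_names=tuple(payload["feature_names"]))
        model.feature_names_ = tuple(payload["feature_names"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = float(payload["intercept"])
        model.class_means_ = payload["class_means"]
        return model


def train_ductal_model(
    exemplars: pd.DataFrame, label_column: str = "ductal_label"
) -> DuctalDiscriminant:
    """Train the ductal discriminant from a labelled exemplar table."""
    if label_column not in exemplars.columns:
        raise KeyError(f"exemplar table lacks label column {label_column!r}")
    model = DuctalDiscriminant()
    return model.fit(exemplars, exemplars[label_column].to_numpy())


def classify_fov_ductality(
    positive_cells: pd.DataFrame, model: DuctalDiscriminant
) -> dict:
    """Label one FOV portal-like or central-like from its marker+ cells.

    Majority vote of single-cell ductal calls; ties break to portal-like
    (the claim is about predominance).  Zero positive cells yields the
    explicit sentinel label ``undetermined``.  Also reports the mean of
    each discriminant feature over the positive cells.
    """
    n = len(positive_cells)
    if n == 0:
        return {
            "label": "undetermined",
            "n_positive": 0,
            "n_ductal": 0,
            "mean_features": {f: float("nan") for f in model.feature_names},
        }
    calls = model.predict(positive_cells)
    n_ductal = int((calls == "ductal").sum())
    label = "portal-like" if n_ductal * 2 >= n else "central-like"
    means = {
        f: float(positive_cells[f].mean()) for f in model.feature_names
    }
    return {
        "label": label,
        "n_positive": n,
        "n_ductal": n_ductal,
        "mean_features": means,
    }
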