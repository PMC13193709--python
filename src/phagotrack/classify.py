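"""Track classification: macrophages vs neutrophils/monocytes.

Covers the annotation workflow and the classifier:

* :func:`annotation_order` reproduces the class-balancing heuristic for
  manual annotation — tracks sorted by average cell area, annotated
  alternating between the largest and smallest remaining ones, so both the
  large-cell (macrophage-rich) and small-cell (neutrophil-rich) ends of the
  distribution are covered early.
* :func:`split` makes a stratified, seeded 80:20 training/validation split.
* :class:`TrackClassifier` is a linear hinge-loss max-margin classifier
  (L2-regularized, C=1.0 by default) on the 15 standardized track features;
  standardization statistics are fitted on the training split only.
  Predictions carry signed margins so low-confidence tracks can be flagged
  for manual review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_NAMES

__all__ = [
    "annotation_order",
    "split",
    "TrackClassifier",
    "evaluate",
]


def annotation_order(features_by_track: pd.DataFrame) -> list:
    """Annotation priority: largest, smallest, 2nd largest, 2nd smallest, ...

    ``features_by_track`` must carry ``track_id`` and ``mean_area_um2``
    columns.  Ties in area are broken by ascending track_id.  The returned
    list is a permutation of the input track_ids; for odd counts the
    median-area track comes last.
    """
    if len(features_by_track) == 0:
        return []
    df = features_by_track[["track_id", "mean_area_um2"]]
    by_small = df.sort_values(
        ["mean_area_um2", "track_id"], ascending=[True, True]
    )["track_id"].tolist()
    by_large = df.sort_values(
        ["mean_area_um2", "track_id"], ascending=[False, True]
    )["track_id"].tolist()
    taken: set = set()
    order: list = []
    i = j = 0
    pick_large = True
    while len(order) < len(df):
        src = by_large if pick_large else by_small
        idx = i if pick_large else j
        while src[idx] in taken:
            idx += 1
        order.append(src[idx])
        taken.add(src[idx])
        if pick_large:
            i = idx + 1
        else:
            j = idx + 1
        pick_large = not pick_large
    return order


def split(
    labels: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified seeded train/validation split of labeled tracks.

    ``labels`` needs ``track_id`` and ``class`` columns.  Within each class,
    round(train_fraction * n_class) tracks go to training after a seeded
    shuffle; the two returned tables are disjoint and exhaustive.  Raises if
    any class is empty.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    classes = labels["class"].unique()
    if len(classes) < 2 and train_fraction < 1.0:
        raise ValueError("need at least one track per class for stratification")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cls in sorted(classes):
        grp = labels[labels["class"] == cls].sort_values("track_id")
        n_train = round(train_fraction * len(grp))
        perm = rng.permutation(len(grp))
        train_parts.append(grp.iloc[perm[:n_train]])
        val_parts.append(grp.iloc[perm[n_train:]])
    train = pd.concat(train_parts).reset_index(drop=True)
    val = pd.concat(val_parts).reset_index(drop=True)
    return train, val


@dataclass
class TrackClassifier:
    """Linear max-margin (hinge-loss, L2-regularized) track classifier.

    Features are standardized with means/scales estimated from the training
    split only; a zero-variance feature gets scale 1 (it then contributes
    nothing to the margin).  The fitted model is a weight vector over the 15
    features plus a bias, serializable to JSON.
    """

    C: float = 1.0
    seed: int = 0
    feature_names: tuple[str, ...] = FEATURE_NAMES
    means_: np.ndarray | None = field(default=None, repr=False)
    scales_: np.ndarray | None = field(default=None, repr=False)
    weights_: np.ndarray | None = field(default=None, repr=False)
    bias_: float | None = None
    classes_: tuple[str, str] | None = None

    # ----------------------------------------------------------------- fit
    def fit(self, features: pd.DataFrame, labels: pd.Series) -> "TrackClassifier":
        """Train on a feature table (15 named columns) and class labels."""
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        y = np.asarray(labels)
        classes = sorted(set(map(str, y)))
        if len(classes) != 2:
            raise ValueError("binary classifier requires exactly two classes")
        self.classes_ = (classes[0], classes[1])
        ybin = np.where(y.astype(str) == classes[1], 1, -1)
        self.means_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scales_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.means_) / self.scales_
        svm = SVC(kernel="linear", C=self.C, random_state=self.seed)
        svm.fit(Z, ybin)
        self.weights_ = svm.coef_.ravel().copy()
        self.bias_ = float(svm.intercept_[0])
        return self

    def _check_fitted(self) -> None:
        if self.weights_ is None:
            raise RuntimeError("classifier has not been fitted; call fit() first")

    # ------------------------------------------------------------- predict
    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        """Signed margin per track; positive means the second class."""
        self._check_fitted()
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        Z = (X - self.means_) / self.scales_
        return Z @ self.weights_ + self.bias_

    def predict(
        self, features: pd.DataFrame, margin_cutoff: float = 0.0
    ) -> pd.DataFrame:
        """Predict classes with margins.

        Returns a table with columns ``class``, ``margin`` and
        ``low_confidence`` (|margin| below ``margin_cutoff``, for flagging
        tracks that would merit manual review).
        """
        m = self.decision_function(features)
        cls = np.where(m > 0, self.classes_[1], self.classes_[0])
        return pd.DataFrame(
            {
                "class": cls,
                "margin": m,
                "low_confidence": np.abs(m) < margin_cutoff,
            },
            index=features.index,
        )

    # ----------------------------------------------------------------- I/O
    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "feature_names": list(self.feature_names),
            "means": self.means_.tolist(),
            "scales": self.scales_.tolist(),
            "weights": self.weights_.tolist(),
            "bias": self.bias_,
            "C": self.C,
            "seed": self.seed,
            "classes": list(self.classes_),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrackClassifier":
        payload = json.loads(Path(path).read_text())
        model = cls(C=payload["C"], seed=payload["seed"])
        model.feature_names = tuple(payload["feature_names"])
        model.means_ = np.array(payload["means"])
        model.scales_ = np.array(payload["scales"])
        model.weights_ = np.array(payload["weights"])
        model.bias_ = float(payload["bias"])
        model.classes_ = tuple(payload["classes"])
        return model


def evaluate(
    model: TrackClassifier, features: pd.DataFrame, labels: pd.Series
) -> dict:
    """Validation accuracy and per-class confusion counts."""
    pred = model.predict(features)["class"].to_numpy()
    y = np.asarray(labels).astype(str)
    acc = float(np.mean(pred == y))
    confusion = {
        true: {p: int(np.sum((y == true) & (pred == p))) for p in model.classes_}
        for true in model.classes_
    }
    return {"accuracy": acc, "n": int(len(y)), "confusion": confusion}
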