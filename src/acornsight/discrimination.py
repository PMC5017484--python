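"""Binary viability discrimination.

Two classifiers operate on the seven scalar features:

* an exhaustive threshold sweep that evaluates every level
  T = k/255, k = 0..255 on one component and keeps the level maximising
  accuracy ACC = (TP + TN) / (P + N) — the grid step matches 8-bit
  quantisation of a unit-range feature;
* a Gaussian naive Bayes model over a small feature mixture (R-G-B,
  H-S-V, or grey alone) fitted on a train split and verified on the
  held-out rows, which suits a continuously running scarification line
  better than a threshold that must be re-derived from a full batch.

Conventions fixed here for determinism: a sample is predicted positive
(germinating) when its feature is strictly greater than the threshold
(``above`` polarity; ``below`` mirrors it with strictly less); sweep
ties keep the smallest maximising threshold; naive-Bayes posterior ties
resolve to non-germinating, the conservative call for sowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import COMPONENT_COLUMNS

#: the sweep grid {k/255 : k = 0..255}
THRESHOLD_GRID = np.arange(256) / 255.0

FEATURE_SETS = {
    "RGB": ("fav_r", "fav_g", "fav_b"),
    "HSV": ("fav_h", "fav_s", "fav_v"),
    "grey": ("fav_y",),
}

_VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdClassifier:
    """One-component threshold rule with its training accuracy."""

    component: str
    thr: float
    polarity: str            # "above" (feature > thr is positive) or "below"
    acc: float
    counts: ConfusionCounts

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.polarity == "above":
            return (values > self.thr).astype(int)
        return (values < self.thr).astype(int)


def accuracy(counts: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (P + N)."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for all-zero counts")
    return (counts.tp + counts.tn) / counts.total


def _component_column(component: str) -> str:
    if component in COMPONENT_COLUMNS:
        return COMPONENT_COLUMNS[component]
    if component in COMPONENT_COLUMNS.values():
        return component
    raise KeyError(f"unknown component {component!r}")


def _values_labels(data: pd.DataFrame, component: str) -> tuple[np.ndarray, np.ndarray]:
    if len(data) == 0:
        raise ValueError("empty feature table")
    values = data[_component_column(component)].to_numpy(dtype=float)
    labels = data["label"].to_numpy(dtype=int)
    return values, labels


def _counts_on_grid(values: np.ndarray, labels: np.ndarray,
                    grid: np.ndarray, polarity: str) -> tuple[np.ndarray, ...]:
    if polarity == "above":
        pred = values[None, :] > grid[:, None]
    elif polarity == "below":
        pred = values[None, :] < grid[:, None]
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    pos = labels == 1
    tp = (pred & pos).sum(axis=1)
    fp = (pred & ~pos).sum(axis=1)
    fn = (~pred & pos).sum(axis=1)
    tn = (~pred & ~pos).sum(axis=1)
    return tp, fp, tn, fn


def accuracy_at_threshold(data: pd.DataFrame, component: str, t: float,
                          polarity: str = "above") -> tuple[float, ConfusionCounts]:
    """Accuracy and confusion counts of the rule feature-vs-t."""
    values, labels = _values_labels(data, component)
    tp, fp, tn, fn = _counts_on_grid(values, labels, np.array([t]), polarity)
    counts = ConfusionCounts(int(tp[0]), int(fp[0]), int(tn[0]), int(fn[0]))
    return accuracy(counts), counts


def sweep_threshold(data: pd.DataFrame, component: str,
                    polarity: str = "above") -> ThresholdClassifier:
    """Evaluate every grid level and keep the accuracy-maximising one.

    Ties go to the smallest threshold on the grid.
    """
    values, labels = _values_labels(data, component)
    tp, fp, tn, fn = _counts_on_grid(values, labels, THRESHOLD_GRID, polarity)
    acc = (tp + tn) / len(values)
    k = int(np.argmax(acc))              # first maximum == smallest Thr
    counts = ConfusionCounts(int(tp[k]), int(fp[k]), int(tn[k]), int(fn[k]))
    return ThresholdClassifier(component=component, thr=float(THRESHOLD_GRID[k]),
                               polarity=polarity, acc=float(acc[k]), counts=counts)


def split_train_test(data: pd.DataFrame, n_train: int = 240,
                     seed: int = 0, sequential: bool = False
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test partition without replacement.

    Default is a seeded random split; ``sequential`` takes the first
    ``n_train`` rows in table order instead.
    """
    n = len(data)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must lie in (0, {n})")
    if sequential:
        idx = np.arange(n)
    else:
        idx = np.random.default_rng(seed).permutation(n)
    train = data.iloc[np.sort(idx[:n_train])].reset_index(drop=True)
    test = data.iloc[np.sort(idx[n_train:])].reset_index(drop=True)
    return train, test


@dataclass
class GaussianNBModel:
    """Per-class priors and per-feature normal densities."""

    feature_set: str
    columns: tuple[str, ...]
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))
    priors: np.ndarray | None = None
    means: np.ndarray | None = None        # (n_classes, n_features)
    variances: np.ndarray | None = None    # (n_classes, n_features)

    @property
    def fitted(self) -> bool:
        return self.priors is not None


def fit_gaussian_nb(train: pd.DataFrame, feature_set: str = "HSV") -> GaussianNBModel:
    """Empirical priors and per-class feature means/variances.

    Variances are maximum-likelihood (ddof=0) and floored at 1e-9.
    """
    columns = FEATURE_SETS[feature_set]
    y = train["label"].to_numpy(dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    X = train[list(columns)].to_numpy(dtype=float)
    priors, means, variances = [], [], []
    for c in classes:
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c} needs at least 2 training rows")
        priors.append(len(Xc) / len(X))
        means.append(Xc.mean(axis=0))
        variances.append(np.maximum(Xc.var(axis=0), _VAR_FLOOR))
    return GaussianNBModel(feature_set=feature_set, columns=tuple(columns),
                           classes=classes, priors=np.array(priors),
                           means=np.array(means), variances=np.array(variances))


def predict_nb(model: GaussianNBModel, rows: pd.DataFrame) -> np.ndarray:
    """argmax over classes of log prior + sum of log normal densities.

    Posterior ties resolve to the lowest class code (non-germinating).
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    X = rows[list(model.columns)].to_numpy(dtype=float)
    log_post = np.log(model.priors)[None, :] + np.zeros((len(X), len(model.classes)))
    for ci in range(len(model.classes)):
        mu, var = model.means[ci], model.variances[ci]
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var)
        log_post[:, ci] += ll.sum(axis=1)
    # argmax returns the first maximum: classes are sorted ascending, so a
    # tie resolves to non-germinating (0)
    return model.classes[np.argmax(log_post, axis=1)]
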