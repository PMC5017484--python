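"""Threshold sweep and Gaussian naive Bayes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acornsight import (
    ConfusionCounts,
    accuracy,
    accuracy_at_threshold,
    fit_gaussian_nb,
    predict_nb,
    split_train_test,
    sweep_threshold,
)
from acornsight.discrimination import THRESHOLD_GRID


def table(values, labels, column="fav_v"):
    return pd.DataFrame({"sequence_id": range(1, len(values) + 1),
                         column: values, "label": labels})


def brute_force_sweep(values, labels, polarity="above"):
    """Independent oracle: evaluate every grid point with explicit loops."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    best = (-1.0, None)
    for t in THRESHOLD_GRID:
        if polarity == "above":
            pred = values > t
        else:
            pred = values < t
        acc = float((pred == (labels == 1)).mean())
        if acc > best[0]:
            best = (acc, float(t))
    return best  # (acc, smallest maximising threshold)


# -- accuracy -----------------------------------------------------------

@pytest.mark.parametrize("tp,tn,p,n,expected_pct", [
    (175, 156, 183, 217, 82.8),   # expert panel arithmetic
    (172, 156, 183, 217, 82.0),
    (168, 166, 183, 217, 83.5),
    (177, 150, 183, 217, 81.8),
])
def test_accuracy_reproduces_expert_panel(tp, tn, p, n, expected_pct):
    counts = ConfusionCounts(tp=tp, fp=n - tn, tn=tn, fn=p - tp)
    assert round(100 * accuracy(counts), 1) == expected_pct


def test_accuracy_perfect_classifier():
    assert accuracy(ConfusionCounts(tp=183, fp=0, tn=217, fn=0)) == 1.0


def test_accuracy_undefined_for_empty_counts():
    with pytest.raises(ValueError):
        accuracy(ConfusionCounts(0, 0, 0, 0))


# -- thresholding -------------------------------------------------------

def test_degenerate_thresholds():
    data = table([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1])
    acc0, c0 = accuracy_at_threshold(data, "V", 0.0)
    assert (c0.tp, c0.fp) == (2, 2) and acc0 == 0.5
    acc1, c1 = accuracy_at_threshold(data, "V", 1.0)
    assert (c1.tn, c1.fn) == (2, 2) and acc1 == 0.5


def test_separable_toy_sweep():
    data = table([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1])
    acc, thr = brute_force_sweep(data["fav_v"], data["label"])
    clf = sweep_threshold(data, "V")
    assert clf.acc == acc == 1.0
    # strictly-greater comparator: 0.4 is not positive at t = 0.4, so the
    # smallest maximising grid point is 102/255 (= 0.4)
    assert clf.thr == thr == 102 / 255


def test_all_same_label_sweeps_to_thr_zero():
    data = table([0.3, 0.5, 0.9], [1, 1, 1])
    clf = sweep_threshold(data, "V")
    assert clf.acc == 1.0 and clf.thr == 0.0


def test_confusion_conservation():
    rng = np.random.default_rng(0)
    data = table(rng.uniform(0, 1, 37), rng.integers(0, 2, 37))
    p = int((data["label"] == 1).sum())
    n = len(data) - p
    for t in (0.0, 0.31, 0.77, 1.0):
        _, c = accuracy_at_threshold(data, "V", t)
        assert c.tp + c.fn == p and c.tn + c.fp == n


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_sweep_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 60))
    values = rng.uniform(0, 1, n)
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[0] = 1
    data = table(values, labels)
    oracle_acc, oracle_thr = brute_force_sweep(values, labels)
    clf = sweep_threshold(data, "V")
    assert clf.acc == oracle_acc
    assert clf.thr == oracle_thr


def test_polarity_duality():
    """Flipping polarity and mirroring features gives the same accuracy
    curve on the mirrored grid (the grid maps onto itself: 1 - k/255 =
    (255 - k)/255)."""
    rng = np.random.default_rng(5)
    values = rng.uniform(0, 1, 40)
    labels = rng.integers(0, 2, 40)
    for k in range(0, 256, 17):
        a, _ = accuracy_at_threshold(table(values, labels), "V",
                                     THRESHOLD_GRID[k], "above")
        b, _ = accuracy_at_threshold(table(1.0 - values, labels), "V",
                                     THRESHOLD_GRID[255 - k], "below")
        assert a == b


# -- train/test split ---------------------------------------------------

def test_split_sizes_and_determinism():
    data = table(np.linspace(0, 1, 400), [0, 1] * 200)
    tr1, te1 = split_train_test(data, n_train=240, seed=7)
    tr2, te2 = split_train_test(data, n_train=240, seed=7)
    assert len(tr1) == 240 and len(te1) == 160
    assert tr1.equals(tr2) and te1.equals(te2)
    assert set(tr1["sequence_id"]).isdisjoint(te1["sequence_id"])


def test_split_varies_with_seed():
    data = table(np.linspace(0, 1, 50), [0, 1] * 25)
    tr1, _ = split_train_test(data, n_train=30, seed=1)
    tr2, _ = split_train_test(data, n_train=30, seed=2)
    assert not tr1.equals(tr2)


def test_split_rejects_oversized_train():
    data = table([0.1, 0.9], [0, 1])
    with pytest.raises(ValueError):
        split_train_test(data, n_train=2, seed=0)


def test_sequential_split_takes_first_rows():
    data = table(np.linspace(0, 1, 10), [0, 1] * 5)
    tr, te = split_train_test(data, n_train=6, seed=0, sequential=True)
    assert list(tr["sequence_id"]) == list(range(1, 7))
    assert list(te["sequence_id"]) == list(range(7, 11))


# -- Gaussian naive Bayes ----------------------------------------------

def gaussian_table(rng, n_per_class, means, sd):
    rows = []
    for label, mu in enumerate(means):
        for _ in range(n_per_class):
            r, g, b = rng.normal(mu, sd, 3)
            h, s, v = rng.normal(mu, sd, 3)
            rows.append({"fav_r": r, "fav_g": g, "fav_b": b,
                         "fav_h": h, "fav_s": s, "fav_v": v,
                         "fav_y": rng.normal(mu, sd), "label": label})
    return pd.DataFrame(rows).sample(frac=1, random_state=0).reset_index(drop=True)


def test_nb_recovers_generating_means():
    rng = np.random.default_rng(21)
    sd, n = 0.05, 150
    data = gaussian_table(rng, n, means=(0.3, 0.7), sd=sd)
    model = fit_gaussian_nb(data, "RGB")
    for ci, mu in enumerate((0.3, 0.7)):
        assert np.abs(model.means[ci] - mu).max() < 3 * sd / np.sqrt(n)


def test_nb_symmetric_classes_decide_at_midpoint():
    rng = np.random.default_rng(3)
    data = gaussian_table(rng, 400, means=(0.3, 0.7), sd=0.05)
    model = fit_gaussian_nb(data, "grey")
    probe = pd.DataFrame({"fav_y": [0.40, 0.46, 0.54, 0.60]})
    pred = predict_nb(model, probe)
    assert list(pred) == [0, 0, 1, 1]


def test_nb_grey_model_is_one_dimensional():
    rng = np.random.default_rng(4)
    data = gaussian_table(rng, 20, means=(0.3, 0.7), sd=0.05)
    model = fit_gaussian_nb(data, "grey")
    assert model.means.shape == (2, 1)


def test_nb_point_at_class_mean_classified_to_it():
    rng = np.random.default_rng(6)
    data = gaussian_table(rng, 100, means=(0.3, 0.7), sd=0.05)
    model = fit_gaussian_nb(data, "HSV")
    probe = pd.DataFrame([dict(zip(model.columns, model.means[1]))])
    assert predict_nb(model, probe)[0] == 1


def test_nb_single_class_rejected():
    data = pd.DataFrame({"fav_y": [0.1, 0.2, 0.3], "label": [1, 1, 1]})
    with pytest.raises(ValueError):
        fit_gaussian_nb(data, "grey")


def test_nb_unfitted_model_rejected():
    from acornsight.discrimination import GaussianNBModel

    with pytest.raises(ValueError):
        predict_nb(GaussianNBModel(feature_set="grey", columns=("fav_y",)),
                   pd.DataFrame({"fav_y": [0.5]}))


def test_nb_matches_sklearn_reference():
    """Independent cross-check of fit and prediction against sklearn."""
    from sklearn.naive_bayes import GaussianNB

    rng = np.random.default_rng(17)
    data = gaussian_table(rng, 120, means=(0.35, 0.6), sd=0.08)
    model = fit_gaussian_nb(data, "RGB")
    X = data[list(model.columns)].to_numpy()
    y = data["label"].to_numpy()
    ref = GaussianNB(var_smoothing=1e-12).fit(X, y)
    assert np.allclose(np.sort(model.means, axis=0), np.sort(ref.theta_, axis=0),
                       atol=1e-9)
    probe = rng.uniform(0.2, 0.8, (200, 3))
    probe_df = pd.DataFrame(probe, columns=list(model.columns))
    assert np.array_equal(predict_nb(model, probe_df), ref.predict(probe))
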