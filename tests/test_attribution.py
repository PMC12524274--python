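"""Classifier, ROC/bootstrap, and exact Shapley axioms + oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from klfatlas import attribution as at
from klfatlas import qc, simulate
from conftest import small_config


# ---------------------------------------------------------------- helpers
def permutation_shapley(margin, x, background):
    """Independent oracle: average marginal contribution over all p!
    feature orderings, interventional value function."""
    p = len(x)
    phi = np.zeros(p)
    for order in itertools.permutations(range(p)):
        present = np.zeros(p, dtype=bool)
        prev = _v(margin, x, background, present)
        for j in order:
            present[j] = True
            cur = _v(margin, x, background, present)
            phi[j] += cur - prev
            prev = cur
    return phi / math.factorial(p)


def _v(margin, x, background, present):
    rows = np.where(present, x, background)
    return float(np.mean(margin(rows)))


def _linear_margin(a, b=0.0):
    a = np.asarray(a, float)
    return lambda X: np.asarray(X, float) @ a + b


# ---------------------------------------------------------------- ROC/AUC
def test_roc_auc_examples():
    assert at.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert at.roc_auc([0.5, 0.5, 0.5], [1, 0, 1]) == 0.5
    # pos [0.7, 0.3], neg [0.5]: one concordant, one discordant pair
    assert at.roc_auc([0.7, 0.3, 0.5], [1, 1, 0]) == 0.5
    with pytest.raises(ValueError):
        at.roc_auc([0.5, 0.6], [1, 1])


def test_roc_auc_matches_sklearn():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=300)
    labels = (rng.random(300) < 0.4).astype(int)
    scores[labels == 1] += 0.6
    assert at.roc_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


def test_bootstrap_ci_properties():
    scores = np.array([0.9, 0.8, 0.7, 0.1, 0.2, 0.3])
    labels = np.array([1, 1, 1, 0, 0, 0])
    lo, hi = at.bootstrap_auc_ci(scores, labels, n_boot=200, seed=1)
    assert (lo, hi) == (1.0, 1.0)  # perfect separation in every resample
    rng = np.random.default_rng(5)
    scores = rng.normal(size=120)
    labels = (rng.random(120) < 0.5).astype(int)
    scores[labels == 1] += 0.8
    point = at.roc_auc(scores, labels)
    lo, hi = at.bootstrap_auc_ci(scores, labels, n_boot=300, seed=2)
    assert lo <= point <= hi
    assert at.bootstrap_auc_ci(scores, labels, n_boot=100, seed=3) == \
        at.bootstrap_auc_ci(scores, labels, n_boot=100, seed=3)


# ---------------------------------------------------------------- classifier
def test_classifier_separable_and_null_and_deterministic():
    rng = np.random.default_rng(0)
    n = 1200
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, 5))
    X[:, 0] += 2.5 * y  # strong signal in one feature
    feats = at.PanelFeatures(X=X, y=y, gene_names=list("abcde"),
                             cell_types=np.array(["t"] * n),
                             breed_labels=("ANG", "HST"))
    fitted = at.train_classifier(feats, params={"n_estimators": 60}, seed=4)
    assert fitted.test_auc > 0.95
    again = at.train_classifier(feats, params={"n_estimators": 60}, seed=4)
    assert np.array_equal(fitted.test_scores, again.test_scores)

    null = at.PanelFeatures(X=rng.normal(size=(n, 5)), y=y,
                            gene_names=list("abcde"),
                            cell_types=np.array(["t"] * n),
                            breed_labels=("ANG", "HST"))
    fitted_null = at.train_classifier(null, params={"n_estimators": 60},
                                      seed=4)
    assert abs(fitted_null.test_auc - 0.5) < 0.12


def test_classifier_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(50, 3))
    feats = at.PanelFeatures(X=X, y=np.zeros(50, int), gene_names=list("abc"),
                             cell_types=np.array(["t"] * 50),
                             breed_labels=("ANG", "HST"))
    with pytest.raises(ValueError):
        at.train_classifier(feats)


# ---------------------------------------------------------------- Shapley
def test_shapley_additive_model_closed_form():
    """For f(x) = sum a_j x_j, phi_j = a_j (x_j - mean(bg_j)) exactly."""
    rng = np.random.default_rng(1)
    a = np.array([2.0, -1.0, 0.5, 3.0])
    bg = rng.normal(size=(12, 4))
    x = rng.normal(size=4)
    res = at.exact_shapley(_linear_margin(a, b=0.7), x, bg)
    expected = a * (x - bg.mean(axis=0))
    assert np.allclose(res.values.to_numpy()[0], expected, atol=1e-10)
    assert res.base_value == pytest.approx(
        float(bg.mean(axis=0) @ a + 0.7), abs=1e-10)


def test_shapley_dummy_and_symmetry_axioms():
    rng = np.random.default_rng(2)
    bg = rng.normal(size=(8, 3))

    def margin(X):  # ignores feature 2; symmetric in features 0 and 1
        X = np.asarray(X, float)
        return np.sin(X[:, 0] + X[:, 1])

    x = np.array([0.8, 0.8, 5.0])
    bg[:, 1] = bg[:, 0]  # symmetric background for features 0,1
    res = at.exact_shapley(margin, x, bg)
    phi = res.values.to_numpy()[0]
    assert phi[2] == pytest.approx(0.0, abs=1e-12)      # dummy
    assert phi[0] == pytest.approx(phi[1], abs=1e-10)   # symmetry


def test_shapley_matches_permutation_oracle():
    """Exact coalition enumeration equals the all-orderings average."""
    rng = np.random.default_rng(3)
    for p in (2, 3, 5):
        bg = rng.normal(size=(6, p))
        x = rng.normal(size=p)
        w = rng.normal(size=p)

        def margin(X, w=w):
            X = np.asarray(X, float)
            return np.tanh(X @ w) + 0.3 * X[:, 0] * X[:, -1]

        res = at.exact_shapley(margin, x, bg)
        oracle = permutation_shapley(margin, x, bg)
        assert np.allclose(res.values.to_numpy()[0], oracle, atol=1e-10)


def test_shapley_efficiency_on_trained_model(small_norm):
    feats = at.extract_panel(small_norm, list(simulate.DEFAULT_PANEL_GENES))
    fitted = at.train_classifier(feats, params={"n_estimators": 40}, seed=0)
    shap = at.shapley_for_features(feats, fitted, n_eval=6, n_background=8,
                                   seed=0)
    totals = shap.base_value + shap.values.sum(axis=1).to_numpy()
    margins = fitted.margin(shap.X_eval)
    assert np.abs(totals - margins).max() < 1e-6


def test_shapley_too_many_features_rejected():
    with pytest.raises(ValueError, match="subsample"):
        at.exact_shapley(_linear_margin(np.ones(21)), np.ones(21),
                         np.ones((2, 21)))


# ---------------------------------------------------------------- aggregate
def test_aggregate_zero_phi_and_ranking():
    phi = pd.DataFrame(np.zeros((4, 2)), columns=["g1", "g2"])
    shap = at.ShapleyResult(values=phi, base_value=0.0,
                            background=np.zeros((1, 2)),
                            meta=pd.DataFrame({"breed": ["a"] * 4,
                                               "true_type": ["t"] * 4}))
    rep = at.aggregate(shap)
    assert (rep.global_importance == 0).all()
    assert sorted(rep.ranking) == ["g1", "g2"]
    assert np.allclose(rep.by_breed.to_numpy(), 0.0)


def test_planted_breed_effect_dominates_attribution():
    """The gene carrying the planted breed differential tops the global
    mean |phi| ranking; cells of each breed get opposite mean signs."""
    cfg = small_config(cells_per_replicate=400, seed=9)
    adata, _ = simulate.generate_dataset(cfg)
    norm, _ = qc.qc_pipeline(adata)
    feats = at.extract_panel(norm, list(cfg.panel_genes))
    fitted = at.train_classifier(feats, params={"n_estimators": 80}, seed=9)
    shap = at.shapley_for_features(feats, fitted, n_eval=40, n_background=8,
                                   seed=9)
    rep = at.aggregate(shap)
    assert rep.ranking[0] == "KLF9"
    by_breed = rep.by_breed["KLF9"]
    assert by_breed["HST"] > by_breed["ANG"]  # positive pushes toward HST


def test_stability_check_seed_requirements(small_norm):
    feats = at.extract_panel(small_norm, list(simulate.DEFAULT_PANEL_GENES))
    with pytest.raises(ValueError, match="3 seeds"):
        at.stability_check(feats, seeds=[1])
    stable = at.stability_check(feats, seeds=[1, 2, 3],
                                params={"n_estimators": 40},
                                k=3, n_eval=20, n_background=8)
    assert stable <= set(simulate.DEFAULT_PANEL_GENES)
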